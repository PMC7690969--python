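"""Monte-Carlo validation of the lag scan on the synthetic generator.

Since the original source streams are not deposited, the inferential step
is validated by parameter recovery: couplings of strength 0.6 injected at
lags -3..+3 over 200-day windows must be recovered by the scan, and
zero-strength worlds must stay inside the 95% envelope at the stated lag.
Also reports the family-wise spurious-peak rate of scanning 21 raw lags,
which quantifies the cost of the uncorrected per-lag threshold.
"""

import json
import pathlib
import sys

from infodemic.experiments import lag_recovery_experiment, null_coupling_experiment

ROOT = pathlib.Path(__file__).resolve().parents[1]
SEED = 20200120 % 2**31


def main() -> None:
    out = ROOT / "results" / "experiments"
    out.mkdir(parents=True, exist_ok=True)

    rec = lag_recovery_experiment(strength=0.6, n_reps=200, seed=SEED)
    rec.table.to_csv(out / "lag_recovery.csv", index=False)
    print("Lag recovery, coupling strength 0.6, 200 days, 200 replicates/lag:")
    print(rec.table.to_string(index=False))
    print(f"overall recovery rate: {100 * rec.overall_rate:.1f}%")

    null = null_coupling_experiment(n_reps=200, seed=SEED)
    payload = {
        "recovery": {
            "overall_rate": rec.overall_rate,
            "strength": rec.strength,
            "n_reps": rec.n_reps,
        },
        "null": {
            "stated_lag_clean_rate": null.stated_lag_clean_rate,
            "familywise_clean_rate": null.familywise_clean_rate,
            "n_reps": null.n_reps,
        },
    }
    (out / "experiments.json").write_text(json.dumps(payload, indent=2))
    print(
        f"Null coupling: |r| within the envelope at the stated lag in "
        f"{100 * null.stated_lag_clean_rate:.1f}% of replicates; "
        f"no spurious peak anywhere in {100 * null.familywise_clean_rate:.1f}% "
        "(21 uncorrected lags inflate the family-wise rate, as expected)."
    )


if __name__ == "__main__":
    sys.exit(main())
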