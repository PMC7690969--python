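"""Assemble the aligned daily series bundle and category tallies.

Builds one log-stabilized daily series per comparison quantity (calibrated
epicenter cases, outside-epicenter cases, the four consensus emotion
series, total rumors and the four emotion-tagged rumor series) plus the
category tallies with display-precision shares.
"""

import datetime as dt
import json
import pathlib
import sys

import pandas as pd

import infodemic as inf
from infodemic.labels import BASIC_EMOTIONS

ROOT = pathlib.Path(__file__).resolve().parents[1]


def main() -> None:
    out = ROOT / "results" / "series"
    out.mkdir(parents=True, exist_ok=True)
    data = ROOT / "results" / "data"
    coded = pd.read_csv(ROOT / "results" / "coding" / "consensus.csv")
    rumors = pd.read_csv(data / "rumors.csv")
    cases = pd.read_csv(data / "cases.csv")
    calibrated = pd.read_csv(ROOT / "results" / "calibration" / "calibrated_cases.csv")

    dates = pd.to_datetime(cases.date).dt.date
    window = (dates.min(), dates.max())
    emotion_counts = inf.consensus_counts_by_day(coded, window)
    rseries = inf.rumor_series(rumors, window)

    other = cases[cases.region == "other"].sort_values("date")
    bundle = {
        "cases_hubei": inf.log_stabilize(
            inf.DailySeries(
                dt.date.fromisoformat(str(calibrated.date.iloc[0])),
                calibrated.calibrated_count.to_numpy(dtype=float),
            )
        ),
        "cases_other": inf.log_stabilize(
            inf.DailySeries(
                pd.Timestamp(other.date.iloc[0]).date(),
                other.reported_total.to_numpy(dtype=float),
            )
        ),
        "rumors_total": inf.log_stabilize(rseries.total),
    }
    for lab in BASIC_EMOTIONS:
        bundle[f"emotion_{lab.value}"] = inf.log_stabilize(emotion_counts.by_label[lab])
        bundle[f"rumors_{lab.value}"] = inf.log_stabilize(rseries.by_tag[lab])

    table = pd.DataFrame({"date": [d.isoformat() for d in rseries.total.dates()]})
    for name, s in bundle.items():
        table[name] = s.values
    table.to_csv(out / "series.csv", index=False)

    emotion_tally = inf.category_shares(
        {l.value: int(s.values.sum()) for l, s in emotion_counts.by_label.items()},
        decimals=2,
    )
    rumor_tally = rseries.tally()
    (out / "tallies.json").write_text(
        json.dumps(
            {
                "emotions": {
                    "counts": emotion_tally.counts,
                    "shares_pct": emotion_tally.shares,
                    "unresolved": int(emotion_counts.unresolved.values.sum()),
                },
                "rumors": {
                    "counts": rumor_tally.counts,
                    "shares_pct": rumor_tally.shares,
                },
            },
            indent=2,
        )
    )
    print(f"Series bundle over {window[0]}..{window[1]} -> {out / 'series.csv'}")
    print("Comment emotion shares (%):", emotion_tally.shares)
    print(f"Rumor shares (%), {rumor_tally.total} rumors:", rumor_tally.shares)


if __name__ == "__main__":
    sys.exit(main())
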