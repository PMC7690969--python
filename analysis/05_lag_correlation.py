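"""Scan every comparison pair for lagged cross-correlation peaks.

Runs the standard comparison set (cases vs rumors inside/outside the
epicenter, each emotion vs total rumors, each emotion vs same-emotion
rumors) over lags -10..+10 at alpha = .05, writes per-pair tables and
figure-style plots with the dashed 95% white-noise envelopes, and prints
the peak summary. Positive lag: the first-named series follows the
second.
"""

import datetime as dt
import json
import pathlib
import sys

import pandas as pd

import infodemic as inf
from infodemic.ccf import plot_ccf

ROOT = pathlib.Path(__file__).resolve().parents[1]


def main() -> None:
    out = ROOT / "results" / "ccf"
    out.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(ROOT / "results" / "series" / "series.csv")
    start = dt.date.fromisoformat(str(table.date.iloc[0]))
    bundle = {
        name: inf.DailySeries(start, table[name].to_numpy(dtype=float))
        for name in table.columns
        if name != "date"
    }
    results = inf.run_all_pairs(bundle, max_lag=10, alpha=0.05)

    import matplotlib.pyplot as plt

    summary = {}
    for name, res in results.items():
        stem = name.replace("~", "_vs_")
        res.as_table().to_csv(out / f"{stem}.csv", index=False)
        ax = plot_ccf(res, title=name)
        ax.figure.tight_layout()
        ax.figure.savefig(out / f"{stem}.png", dpi=120)
        plt.close(ax.figure)
        summary[name] = res.summary()
        if res.significant:
            print(
                f"{name:<40} peak r={res.peak_r:+.2f} at lag {res.peak_lag:+d} "
                f"(p={res.peak_p:.2g})"
            )
        else:
            print(f"{name:<40} no significant peak")
    (out / "ccf_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))


if __name__ == "__main__":
    sys.exit(main())
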