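"""Consensus-code the comment stream and assess interrater reliability.

Each comment's final category is the strict plurality of its three coder
labels; ties are kept as an explicit unresolved residual. Reliability is
Fleiss' kappa over the five categories.
"""

import json
import pathlib
import sys

import numpy as np
import pandas as pd

import infodemic as inf
from infodemic.coding import kappa_from_codes
from infodemic.labels import LABEL_CODES

ROOT = pathlib.Path(__file__).resolve().parents[1]


def main() -> None:
    out = ROOT / "results" / "coding"
    out.mkdir(parents=True, exist_ok=True)
    comments = pd.read_csv(ROOT / "results" / "data" / "comments.csv")
    coded = inf.add_consensus(comments)
    coded[["comment_id", "date", "consensus"]].to_csv(out / "consensus.csv", index=False)

    coder_cols = [c for c in coded.columns if c.startswith("coder_")]
    code_of = {lab.value: c for lab, c in LABEL_CODES.items()}
    codes = np.column_stack(
        [coded[c].map(code_of).to_numpy(dtype=np.int64) for c in coder_cols]
    )
    kappa = kappa_from_codes(codes)
    unresolved = int((coded["consensus"] == "unresolved").sum())
    report = {
        "kappa": kappa.kappa,
        "n_items": kappa.n_items,
        "n_raters": kappa.n_raters,
        "interpretation": kappa.interpretation,
        "unresolved_count": unresolved,
    }
    (out / "reliability.json").write_text(json.dumps(report, indent=2))
    print(
        f"Coded {kappa.n_items} comments with {kappa.n_raters} coders: "
        f"kappa={kappa.kappa:.3f} ({kappa.interpretation}), "
        f"{unresolved} unresolved ties "
        f"({100 * unresolved / kappa.n_items:.2f}%)."
    )


if __name__ == "__main__":
    sys.exit(main())
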