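"""Generate the synthetic study inputs.

Writes the three input tables (cases.csv, comments.csv, rumors.csv) for a
50-day window starting 2020-01-20 under the default generator
configuration: an epicenter epidemic curve with a diagnosis-criteria
shock on day 23, ~20,000 coder-labelled comments/day whose
negative-emotion share tracks log case counts, and ~5.5 rumors/day
coupled to the negative-emotion signal at lag 0 with target strength 0.5.
"""

import pathlib
import sys

import infodemic as inf

SEED = 20200120 % 2**31
ROOT = pathlib.Path(__file__).resolve().parents[1]


def main() -> None:
    out = ROOT / "results" / "data"
    config = inf.SyntheticConfig(seed=SEED)
    paths = inf.write_inputs(config, out)
    (out / "config.yaml").write_text(
        "\n".join(f"{k}: {v}" for k, v in config.to_dict().items()) + "\n"
    )
    print(f"Synthetic inputs for {config.n_days} days from {config.start_date}:")
    for name, path in paths.items():
        print(f"  {name}: {path}")
    print(f"  config: {out / 'config.yaml'}")


if __name__ == "__main__":
    sys.exit(main())
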