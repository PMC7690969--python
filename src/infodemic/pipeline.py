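"""End-to-end orchestration: simulate or ingest, code, calibrate, correlate.

One call runs the whole analysis — synthetic generation (or CSV
ingestion), consensus coding with reliability, case-count calibration,
series assembly with tallies, and the full cross-correlation comparison
set — and writes every stage artifact plus a machine-readable summary and
a run manifest. All randomness flows from the single seed in the config,
so two runs with the same config produce byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import pathlib
import time
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .calibration import CalibrationResult, calibrate_series
from .ccf import CrossCorrResult, run_all_pairs
from .coding import (
    add_consensus,
    consensus_counts_by_day,
    kappa_from_codes,
    KappaResult,
)
from .labels import BASIC_EMOTIONS, EMOTIONS, LABEL_CODES, Emotion
from .synthetic import (
    SyntheticConfig,
    simulate_comments,
    simulate_epidemic,
    simulate_rumors,
    truth_emotion_series,
    write_inputs,
)
from .timeseries import (
    DailySeries,
    category_shares,
    log_stabilize,
    rumor_series,
)


@dataclass(frozen=True)
class RunManifest:
    """Provenance of one pipeline run."""

    config_hash: str
    seed: "int | None"
    mode: str
    input_paths: dict
    output_dir: str
    timings: dict
    versions: dict


@dataclass(frozen=True)
class PipelineResult:
    manifest: RunManifest
    kappa: KappaResult
    unresolved_count: int
    calibration: CalibrationResult
    emotion_tally: object
    rumor_tally: object
    ccf: dict[str, CrossCorrResult]
    summary: dict


def _load_inputs(input_dir: pathlib.Path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    paths = {name: input_dir / f"{name}.csv" for name in ("cases", "comments", "rumors")}
    missing = [str(p) for p in paths.values() if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing input tables: {missing}")
    cases = pd.read_csv(paths["cases"])
    comments = pd.read_csv(paths["comments"])
    rumors = pd.read_csv(paths["rumors"])
    return cases, comments, rumors


def _region_frame(cases: pd.DataFrame, region: str) -> pd.DataFrame:
    sub = cases[cases["region"] == region].sort_values("date").reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"no case records for region {region!r}")
    return sub


def _window(cases: pd.DataFrame) -> tuple[dt.date, dt.date]:
    dates = pd.to_datetime(cases["date"]).dt.date
    return dates.min(), dates.max()


def run_pipeline(
    config: SyntheticConfig,
    out_dir,
    mode: str = "synthetic",
    input_dir=None,
    max_lag: int = 10,
    alpha: float = 0.05,
    change_date: "dt.date | None" = None,
    ratio_dates: "list[dt.date] | None" = None,
    write_plots: bool = False,
) -> PipelineResult:
    """Execute every stage and write all artifacts under ``out_dir``.

    In ``synthetic`` mode the three input tables are generated from the
    config and written alongside the outputs; in ``files`` mode they are
    read from ``input_dir``. The calibration boundary defaults to two days
    after the configured shock day (the first day with backlog-free
    reporting), with the ratio estimated from that day and the next —
    the analogue of correcting a Feb-12 criteria change using Feb 14-15
    ratios.
    """
    t0 = time.perf_counter()
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    if mode == "synthetic":
        cases = simulate_epidemic(config)
        comments_sim = simulate_comments(config, cases)
        rumors_sim = simulate_rumors(
            config, truth_emotion_series(comments_sim.truth_counts)
        )
        input_paths = write_inputs(
            config, out / "inputs", cases=cases, comments=comments_sim,
            rumors=rumors_sim,
        )
        comments_df = comments_sim.table
        rumors_df = rumors_sim.table
        cases_df = cases
    elif mode == "files":
        if input_dir is None:
            raise ValueError("files mode needs input_dir")
        cases_df, comments_df, rumors_df = _load_inputs(pathlib.Path(input_dir))
        input_paths = {
            name: str(pathlib.Path(input_dir) / f"{name}.csv")
            for name in ("cases", "comments", "rumors")
        }
    else:
        raise ValueError(f"unknown mode {mode!r}")
    timings["simulate_or_load"] = time.perf_counter() - t0

    # --- consensus coding + reliability ------------------------------------
    t1 = time.perf_counter()
    coded = add_consensus(comments_df)
    coded[["comment_id", "date", "consensus"]].to_csv(out / "consensus.csv", index=False)

    coder_cols = [c for c in coded.columns if c.startswith("coder_")]
    code_of = {lab.value: code for lab, code in LABEL_CODES.items()}
    codes = np.column_stack(
        [coded[c].map(code_of).to_numpy(dtype=np.int64) for c in coder_cols]
    )
    kappa = kappa_from_codes(codes)
    unresolved_count = int((coded["consensus"] == "unresolved").sum())
    reliability = {
        "kappa": kappa.kappa,
        "n_items": kappa.n_items,
        "n_raters": kappa.n_raters,
        "interpretation": kappa.interpretation,
        "unresolved_count": unresolved_count,
    }
    (out / "reliability.json").write_text(json.dumps(reliability, indent=2))
    timings["coding"] = time.perf_counter() - t1

    # --- calibration --------------------------------------------------------
    t2 = time.perf_counter()
    hubei = _region_frame(cases_df, "hubei")
    start = pd.Timestamp(hubei["date"].iloc[0]).date()
    if change_date is None:
        change_date = start + dt.timedelta(days=config.shock_day + 2)
    if ratio_dates is None:
        ratio_dates = [change_date, change_date + dt.timedelta(days=1)]
    calibration = calibrate_series(hubei, change_date, ratio_dates)
    other = _region_frame(cases_df, "other")
    other_series = DailySeries(
        pd.Timestamp(other["date"].iloc[0]).date(),
        other["reported_total"].to_numpy(dtype=float),
    )
    pd.DataFrame(
        {
            "date": calibration.calibrated_series.dates(),
            "region": "hubei",
            "calibrated_count": calibration.calibrated_series.values,
        }
    ).to_csv(out / "calibrated_cases.csv", index=False)
    (out / "calibration.json").write_text(
        json.dumps(
            {
                "ratios": {d.isoformat(): v for d, v in calibration.ratio_by_day.items()},
                "mean_ratio": calibration.mean_ratio,
                "multiplier": calibration.multiplier,
                "change_date": calibration.change_date.isoformat(),
            },
            indent=2,
        )
    )
    timings["calibration"] = time.perf_counter() - t2

    # --- series + tallies ---------------------------------------------------
    t3 = time.perf_counter()
    window = _window(cases_df)
    emotion_counts = consensus_counts_by_day(coded, window)
    rumors = rumor_series(rumors_df, window)

    emotion_totals = {
        lab.value: int(s.values.sum()) for lab, s in emotion_counts.by_label.items()
    }
    emotion_tally = category_shares(
        {k: v for k, v in emotion_totals.items()}, decimals=2
    )
    rumor_tally = rumors.tally()

    bundle: dict[str, DailySeries] = {
        "cases_hubei": log_stabilize(calibration.calibrated_series),
        "cases_other": log_stabilize(other_series),
        "rumors_total": log_stabilize(rumors.total),
    }
    for lab in BASIC_EMOTIONS:
        bundle[f"emotion_{lab.value}"] = log_stabilize(emotion_counts.by_label[lab])
        bundle[f"rumors_{lab.value}"] = log_stabilize(rumors.by_tag[lab])

    series_table = pd.DataFrame(
        {"date": [d.isoformat() for d in rumors.total.dates()]}
    )
    for name, s in bundle.items():
        series_table[name] = s.values
    series_table.to_csv(out / "series.csv", index=False)
    (out / "tallies.json").write_text(
        json.dumps(
            {
                "emotions": {
                    "counts": emotion_tally.counts,
                    "total": emotion_tally.total,
                    "shares_pct": emotion_tally.shares,
                    "unresolved": unresolved_count,
                },
                "rumors": {
                    "counts": rumor_tally.counts,
                    "total": rumor_tally.total,
                    "shares_pct": rumor_tally.shares,
                },
            },
            indent=2,
        )
    )
    timings["series"] = time.perf_counter() - t3

    # --- cross-correlation ---------------------------------------------------
    t4 = time.perf_counter()
    ccf_results = run_all_pairs(bundle, max_lag=max_lag, alpha=alpha)
    ccf_dir = out / "ccf"
    ccf_dir.mkdir(exist_ok=True)
    for name, res in ccf_results.items():
        res.as_table().to_csv(ccf_dir / f"{name.replace('~', '_vs_')}.csv", index=False)
        if write_plots:
            from .ccf import plot_ccf
            import matplotlib.pyplot as plt

            ax = plot_ccf(res, title=name)
            ax.figure.savefig(ccf_dir / f"{name.replace('~', '_vs_')}.png", dpi=120)
            plt.close(ax.figure)
    timings["ccf"] = time.perf_counter() - t4

    # --- summary + manifest ---------------------------------------------------
    summary = {
        "mode": mode,
        "seed": config.seed,
        "window": [window[0].isoformat(), window[1].isoformat()],
        "reliability": reliability,
        "calibration": {
            "mean_ratio": calibration.mean_ratio,
            "multiplier": calibration.multiplier,
            "change_date": calibration.change_date.isoformat(),
        },
        "tallies": {
            "emotions": {"counts": emotion_tally.counts, "shares_pct": emotion_tally.shares},
            "rumors": {"counts": rumor_tally.counts, "shares_pct": rumor_tally.shares},
            "rumors_excluded_outside_window": rumors.n_excluded,
        },
        "ccf": {name: res.summary() for name, res in ccf_results.items()},
        "parameters": {"max_lag": max_lag, "alpha": alpha},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.seed,
        mode=mode,
        input_paths=input_paths,
        output_dir=str(out),
        timings=timings,
        versions={"infodemic": __version__, "numpy": np.__version__},
    )
    (out / "manifest.json").write_text(
        json.dumps(dataclasses.asdict(manifest), indent=2)
    )
    return PipelineResult(
        manifest=manifest,
        kappa=kappa,
        unresolved_count=unresolved_count,
        calibration=calibration,
        emotion_tally=emotion_tally,
        rumor_tally=rumor_tally,
        ccf=ccf_results,
        summary=summary,
    )


def make_report(summary: Mapping) -> str:
    """Render one pipeline summary as a human-readable text report."""
    lines = []
    lines.append("Emotion-rumor infoveillance run")
    lines.append("=" * 31)
    lines.append(f"mode: {summary['mode']}   seed: {summary['seed']}")
    lines.append(f"window: {summary['window'][0]} .. {summary['window'][1]}")
    rel = summary["reliability"]
    lines.append("")
    lines.append(
        f"Interrater reliability: kappa={rel['kappa']:.2f} "
        f"({rel['interpretation']}; {rel['n_items']} items x {rel['n_raters']} raters, "
        f"{rel['unresolved_count']} unresolved)"
    )
    cal = summary["calibration"]
    lines.append(
        f"Case calibration: mean clinical/nucleic ratio {cal['mean_ratio']:.2f} "
        f"-> multiplier {cal['multiplier']:.2f} "
        f"(pre-{cal['change_date']} days scaled)"
    )
    lines.append("")
    lines.append("Comment emotion tallies:")
    tal = summary["tallies"]["emotions"]
    for cat in [e.value for e in EMOTIONS]:
        if cat in tal["counts"]:
            lines.append(
                f"  {cat:<10} {tal['counts'][cat]:>9}  ({tal['shares_pct'][cat]}%)"
            )
    lines.append("Rumor tallies:")
    tal = summary["tallies"]["rumors"]
    for cat in [e.value for e in EMOTIONS]:
        if cat in tal["counts"]:
            lines.append(
                f"  {cat:<10} {tal['counts'][cat]:>9}  ({tal['shares_pct'][cat]}%)"
            )
    lines.append("")
    lines.append("Cross-correlation peaks (positive lag: first series follows):")
    any_sig = False
    for name, res in summary["ccf"].items():
        if res["significant"]:
            any_sig = True
            lines.append(
                f"  {name:<40} peak r={res['peak_r']:+.2f} at lag {res['peak_lag']:+d} "
                f"(p={res['peak_p']:.2g})"
            )
        else:
            lines.append(f"  {name:<40} no significant peak (alpha={res['alpha']})")
    if not any_sig:
        lines.append("  -- no pair reached significance --")
    return "\n".join(lines) + "\n"
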