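"""Time-lagged Pearson cross-correlation with significance envelopes.

The core inferential step: for two aligned daily series x and y, the
cross-correlation at integer lag k is

    r(k) = corr(x_{t+k}, y_t),  computed over the n - |k| overlapping days.

Sign convention (fixed and used everywhere): a POSITIVE k means x lags
(follows) y by k days; a NEGATIVE k means x leads y. Each r(k) carries a
two-sided p-value from the t test with n_pairs - 2 degrees of freedom and
the white-noise 95% envelope half-width z_{0.975} / sqrt(n_pairs) — the
dashed band within which cross-correlations of two uncorrelated series
fall with ~95% probability at a single lag. The peak is the lag of
maximum |r| among lags significant at level alpha; no multiple-testing
correction is applied across lags by default (a Bonferroni option
exists), and the reported peak p-value is the per-lag p, which
peak-selection inflates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .errors import UndefinedCorrelationError
from .labels import BASIC_EMOTIONS
from .timeseries import DailySeries

#: Minimum overlap so every lag window keeps >= 3 pairs.
def _min_length(max_lag: int) -> int:
    return 2 * max_lag + 3


@dataclass(frozen=True)
class CrossCorrResult:
    """Per-lag correlation scan between two daily series."""

    lags: np.ndarray
    r: np.ndarray
    p: np.ndarray
    envelope_half_width: np.ndarray
    n_pairs: np.ndarray
    alpha: float
    peak_lag: "int | None"
    peak_r: "float | None"
    peak_p: "float | None"

    @property
    def significant(self) -> bool:
        """Whether any lag passed the alpha threshold."""
        return self.peak_lag is not None

    def as_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "lag": self.lags,
                "r": self.r,
                "p": self.p,
                "envelope": self.envelope_half_width,
                "n_pairs": self.n_pairs,
            }
        )

    def summary(self) -> dict:
        return {
            "significant": self.significant,
            "peak_lag": self.peak_lag,
            "peak_r": self.peak_r,
            "peak_p": self.peak_p,
            "alpha": self.alpha,
        }


def _as_values(series) -> np.ndarray:
    if isinstance(series, DailySeries):
        return series.values
    return np.asarray(series, dtype=float)


def lagged_pearson(x, y, k: int) -> tuple[float, float, int]:
    """Pearson r, two-sided p and pair count at lag ``k``.

    ``r(k) = corr(x_{t+k}, y_t)`` over the overlapping days; positive k
    means x follows y. Raises :class:`UndefinedCorrelationError` when a
    windowed segment has zero variance (a correlation of 0 would be a
    silent lie there).
    """
    xv, yv = _as_values(x), _as_values(y)
    if xv.size != yv.size:
        raise ValueError("series must be aligned to the same length before lagging")
    n = xv.size
    if abs(k) > n - 3:
        raise ValueError(f"|lag| must be <= {n - 3} for series of length {n}")
    if k >= 0:
        xs, ys = xv[k:], yv[: n - k]
    else:
        xs, ys = xv[: n + k], yv[-k:]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise UndefinedCorrelationError(
            f"zero variance in a windowed segment at lag {k}"
        )
    res = stats.pearsonr(xs, ys)
    return float(res.statistic), float(res.pvalue), xs.size


def ccf_scan(
    x,
    y,
    max_lag: int = 10,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> CrossCorrResult:
    """Scan lags -max_lag..max_lag and extract the significant peak.

    The envelope half-width at lag k is z_{1-alpha/2} / sqrt(n - |k|), the
    large-sample white-noise band. The peak is the lag maximizing |r|
    among lags with p below the threshold (alpha, or alpha / n_lags with
    ``bonferroni``); ties break toward the smallest |lag|, then toward the
    negative lag. If no lag is significant the peak fields are None.
    """
    xv, yv = _as_values(x), _as_values(y)
    n = xv.size
    if n != yv.size:
        raise ValueError("series must be aligned to the same length")
    if n < _min_length(max_lag):
        raise ValueError(
            f"series of length {n} too short for max_lag={max_lag}; "
            f"need at least {_min_length(max_lag)} days"
        )

    lags = np.arange(-max_lag, max_lag + 1)
    r = np.full(lags.size, np.nan)
    p = np.full(lags.size, np.nan)
    n_pairs = n - np.abs(lags)
    for i, k in enumerate(lags):
        try:
            r[i], p[i], _ = lagged_pearson(xv, yv, int(k))
        except UndefinedCorrelationError:
            continue  # recorded as NaN; excluded from the peak
    if np.all(np.isnan(r)):
        raise UndefinedCorrelationError(
            "correlation undefined at every lag (constant series?)"
        )

    z = stats.norm.ppf(1.0 - alpha / 2.0)
    envelope = z / np.sqrt(n_pairs)

    threshold = alpha / lags.size if bonferroni else alpha
    sig = np.where(~np.isnan(p) & (p < threshold))[0]
    if sig.size:
        # max |r|; ties -> smallest |lag|, then the negative lag
        order = sorted(
            sig, key=lambda i: (-abs(r[i]), abs(int(lags[i])), int(lags[i]))
        )
        best = order[0]
        peak_lag, peak_r, peak_p = int(lags[best]), float(r[best]), float(p[best])
    else:
        peak_lag = peak_r = peak_p = None

    return CrossCorrResult(
        lags=lags,
        r=r,
        p=p,
        envelope_half_width=envelope,
        n_pairs=n_pairs,
        alpha=alpha,
        peak_lag=peak_lag,
        peak_r=peak_r,
        peak_p=peak_p,
    )


#: The comparison set of the full analysis: epidemic curves and each basic
#: emotion against the total rumor stream, plus each emotion against the
#: same-emotion rumors.
def standard_pairs() -> list[tuple[str, str]]:
    pairs = [
        ("cases_other", "rumors_total"),
        ("cases_hubei", "rumors_total"),
    ]
    pairs += [(f"emotion_{lab.value}", "rumors_total") for lab in BASIC_EMOTIONS]
    pairs += [
        (f"emotion_{lab.value}", f"rumors_{lab.value}") for lab in BASIC_EMOTIONS
    ]
    return pairs


def run_all_pairs(
    series_bundle: Mapping[str, DailySeries],
    max_lag: int = 10,
    alpha: float = 0.05,
) -> dict[str, CrossCorrResult]:
    """CCF scan over the standard comparison set.

    ``series_bundle`` maps names to log-stabilized daily series and must
    contain: cases_hubei, cases_other, emotion_<label> for the four basic
    emotions, rumors_total, and rumors_<label> for the four basic
    emotions. Keys are '<x>~<y>' with the scan convention r(k) =
    corr(x_{t+k}, y_t).
    """
    pairs = standard_pairs()
    needed = sorted({name for pair in pairs for name in pair})
    missing = [name for name in needed if name not in series_bundle]
    if missing:
        raise KeyError(f"series bundle is missing: {missing}")

    results: dict[str, CrossCorrResult] = {}
    for xname, yname in pairs:
        results[f"{xname}~{yname}"] = ccf_scan(
            series_bundle[xname], series_bundle[yname], max_lag=max_lag, alpha=alpha
        )
    return results


def plot_ccf(result: CrossCorrResult, title: str = "", ax=None):
    """Stem plot of r against lag with the dashed 95% envelopes."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.2))
    ax.vlines(result.lags, 0, result.r, color="tab:blue", lw=1.5)
    ax.plot(result.lags, result.r, "o", color="tab:blue", ms=3)
    ax.plot(result.lags, result.envelope_half_width, "b--", lw=0.8)
    ax.plot(result.lags, -result.envelope_half_width, "b--", lw=0.8)
    ax.axhline(0, color="k", lw=0.6)
    if result.significant:
        ax.plot(result.peak_lag, result.peak_r, "r*", ms=10)
    ax.set_xlabel("lag (days)")
    ax.set_ylabel("cross-correlation")
    if title:
        ax.set_title(title, fontsize=9)
    return ax
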