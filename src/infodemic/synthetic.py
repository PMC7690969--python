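"""Seeded generator for coupled epidemic / emotion / rumor data.

The raw streams the analysis was designed for (news-outlet comment feeds,
fact-checking platform rumor lists, daily official case counts) are not
redistributable, so every downstream stage is exercised on synthetic data
with the same statistical structure:

* an epidemic curve with exponential growth to a peak then decay, where a
  mid-series diagnosis-criteria change withholds clinically diagnosed
  cases from the reported totals until the accumulated backlog is dumped
  over two days (the reporting spike the calibration stage removes);
* a heavy-tailed daily comment stream in which each comment carries a
  latent true emotion (five categories, neutral modal, anger > fear >
  happiness ~ sadness) whose negative-emotion odds rise with log case
  counts, observed through >= 3 noisy coders;
* a rumor stream whose daily counts mix independent noise with the total
  negative-emotion signal shifted by a configurable lead/lag, calibrated
  so the population cross-correlation at the injected lag approximates a
  requested strength.

All randomness flows from one seed, fanned out to fixed per-stage
substreams so adding a stage never perturbs earlier stages' draws. With
``noise_scale=0`` the epidemic counts are the latent expectations kept as
reals, which makes the calibration-recovery identities exact.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidConfigError
from .labels import EMOTIONS, Emotion, LABEL_CODES, N_CATEGORIES, NEGATIVE_EMOTIONS
from .timeseries import DailySeries

#: Fixed substream index per stage (seed fan-out is part of the contract).
_STAGE_KEYS = {"epidemic": 0, "comments": 1, "coders": 2, "rumors": 3}

# Default category mix, canonical order (happiness, sadness, anger, fear,
# neutral). Together with the case coupling below it reproduces the
# observed ordering of comment shares (neutral dominant, then anger, fear,
# happiness ~ sadness) at realistic magnitudes; documented constants, not
# estimates from any dataset.
_DEFAULT_BASE_PROBS = (0.0141, 0.0127, 0.0482, 0.0135, 0.9115)

#: Default rumor tag mix (neutral modal, fear next), canonical order.
_DEFAULT_TAG_PROBS = (0.069, 0.025, 0.043, 0.225, 0.638)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the coupled epidemic-emotion-rumor generator.

    Defaults describe a 50-day national epidemic window starting
    2020-01-20 with the reporting-criteria shock on day 23, a true
    clinical/nucleic ratio of 0.91, ~20,000 comments/day (about one
    million over the window) and ~5.5 rumors/day.
    """

    seed: int
    n_days: int = 50
    start_date: dt.date = dt.date(2020, 1, 20)

    # epidemic curve
    epidemic_initial_cases: float = 60.0
    epidemic_growth_rate: float = 0.22  # per-day exponential rate, rising phase
    epidemic_decay_rate: float = 0.07  # per-day rate after the peak
    epidemic_peak_day: int = 17
    shock_day: int = 23  # day index of the criteria change (2020-02-12)
    shock_clinical_ratio: float = 0.91  # true clinical/nucleic ratio
    backlog_release_fractions: tuple[float, float] = (0.8, 0.2)
    other_region_scale: float = 0.6  # outside-epicenter curve, no shock
    noise_scale: float = 0.15  # 0 disables count noise (latent reals)

    # comment stream
    comment_volume_mean: float = 20_000.0
    comment_volume_dispersion: float = 6.0  # NB shape; smaller = heavier tail
    emotion_base_probs: tuple[float, ...] = _DEFAULT_BASE_PROBS
    emotion_case_coupling: float = 0.15  # gain on log1p(cases) -> anger/fear odds

    # coders
    n_coders: int = 3
    coder_accuracy: float = 0.955  # P(coder reports the true label)

    # rumor stream
    rumor_volume_mean: float = 5.5
    rumor_lag_days: int = 0  # >0: rumors lead emotions by this many days
    rumor_coupling_strength: float = 0.5  # target cross-correlation at the lag
    rumor_lognoise_sd: float = 0.7  # log-scale sd of the rumor intensity
    rumor_tag_probs: tuple[float, ...] = _DEFAULT_TAG_PROBS

    def __post_init__(self) -> None:
        probs = np.asarray(self.emotion_base_probs, dtype=float)
        tagp = np.asarray(self.rumor_tag_probs, dtype=float)
        checks = [
            (self.n_days >= 5, "n_days must be >= 5"),
            (probs.size == N_CATEGORIES, "emotion_base_probs must have 5 entries"),
            (np.all(probs >= 0), "emotion_base_probs entries must be >= 0"),
            (abs(probs.sum() - 1.0) <= 1e-9, "emotion_base_probs must sum to 1"),
            (tagp.size == N_CATEGORIES, "rumor_tag_probs must have 5 entries"),
            (np.all(tagp >= 0) and abs(tagp.sum() - 1.0) <= 1e-9,
             "rumor_tag_probs must be a probability vector"),
            (0.0 < self.coder_accuracy <= 1.0, "coder_accuracy must be in (0, 1]"),
            (self.n_coders >= 3, "n_coders must be >= 3"),
            (abs(self.rumor_lag_days) <= 10, "|rumor_lag_days| must be <= 10"),
            (abs(self.rumor_lag_days) < self.n_days,
             "|rumor_lag_days| must be smaller than n_days"),
            (0 < self.shock_day < self.n_days - 1,
             "shock_day must lie strictly inside the window (with room for the"
             " second backlog-release day)"),
            (self.epidemic_growth_rate > 0, "epidemic_growth_rate must be > 0"),
            (self.epidemic_decay_rate >= 0, "epidemic_decay_rate must be >= 0"),
            (self.epidemic_initial_cases > 0, "epidemic_initial_cases must be > 0"),
            (0 <= self.epidemic_peak_day < self.n_days,
             "epidemic_peak_day must lie in the window"),
            (self.comment_volume_mean > 0, "comment_volume_mean must be > 0"),
            (self.comment_volume_dispersion > 0,
             "comment_volume_dispersion must be > 0"),
            (self.rumor_volume_mean > 0, "rumor_volume_mean must be > 0"),
            (0.0 <= self.rumor_coupling_strength <= 1.0,
             "rumor_coupling_strength must be in [0, 1]"),
            (self.rumor_lognoise_sd > 0, "rumor_lognoise_sd must be > 0"),
            (self.shock_clinical_ratio >= 0, "shock_clinical_ratio must be >= 0"),
            (self.noise_scale >= 0, "noise_scale must be >= 0"),
            (abs(sum(self.backlog_release_fractions) - 1.0) <= 1e-9
             and all(f >= 0 for f in self.backlog_release_fractions),
             "backlog_release_fractions must be non-negative and sum to 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise InvalidConfigError(msg)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["start_date"] = self.start_date.isoformat()
        d["emotion_base_probs"] = list(self.emotion_base_probs)
        d["rumor_tag_probs"] = list(self.rumor_tag_probs)
        d["backlog_release_fractions"] = list(self.backlog_release_fractions)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        if "seed" not in d:
            raise InvalidConfigError("config must carry a seed")
        if isinstance(d.get("start_date"), str):
            d["start_date"] = dt.date.fromisoformat(d["start_date"])
        for key in ("emotion_base_probs", "rumor_tag_probs", "backlog_release_fractions"):
            if key in d:
                d[key] = tuple(d[key])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SyntheticConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)  # YAML is a superset of JSON
        if not isinstance(data, Mapping):
            raise InvalidConfigError("config file must hold a key-value mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        import hashlib

        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def dates(self) -> list[dt.date]:
        return [self.start_date + dt.timedelta(days=i) for i in range(self.n_days)]

    def rng(self, stage: str) -> np.random.Generator:
        """Substream for one stage, derived from the single global seed."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STAGE_KEYS[stage],))
        )


# ---------------------------------------------------------------------------
# Epidemic


def _noisy_counts(rng: np.random.Generator, mu: np.ndarray, noise_scale: float) -> np.ndarray:
    """Gamma-mixed Poisson (negative binomial) counts around ``mu``.

    ``noise_scale`` is the extra-Poisson coefficient of variation; 0 returns
    the latent expectations unchanged (as reals).
    """
    if noise_scale == 0:
        return mu.astype(float)
    shape = 1.0 / noise_scale**2
    lam = mu * rng.gamma(shape, 1.0 / shape, size=mu.shape)
    return rng.poisson(lam).astype(float)


def simulate_epidemic(config: SyntheticConfig) -> pd.DataFrame:
    """Daily case counts for the epicenter ("hubei") and elsewhere ("other").

    Columns: date, region, nucleic_count, clinical_count, reported_total,
    true_total. ``clinical_count`` is the generator's ledger of clinical
    cases arising each day; before ``shock_day`` they are withheld from
    ``reported_total`` and the backlog is released on the shock day and the
    day after (split by ``backlog_release_fractions``), producing the
    familiar reporting spike. Total true cases equal total reported cases
    over the full window. The outside-epicenter curve has no clinical
    component and no shock.
    """
    rng = config.rng("epidemic")
    t = np.arange(config.n_days)
    log_mu = (
        np.log(config.epidemic_initial_cases)
        + config.epidemic_growth_rate * np.minimum(t, config.epidemic_peak_day)
        - config.epidemic_decay_rate * np.maximum(t - config.epidemic_peak_day, 0)
    )
    mu = np.exp(log_mu)

    nucleic_hb = _noisy_counts(rng, mu, config.noise_scale)
    if config.noise_scale == 0:
        clinical_hb = config.shock_clinical_ratio * nucleic_hb
    else:
        clinical_hb = rng.poisson(config.shock_clinical_ratio * nucleic_hb).astype(float)
    nucleic_other = _noisy_counts(rng, config.other_region_scale * mu, config.noise_scale)

    s = config.shock_day
    backlog = clinical_hb[:s].sum()
    f1, f2 = config.backlog_release_fractions
    dump1 = f1 * backlog
    if config.noise_scale > 0:
        dump1 = float(np.round(dump1))
    dump2 = backlog - dump1

    reported_hb = np.where(t < s, nucleic_hb, nucleic_hb + clinical_hb)
    reported_hb = reported_hb.astype(float)
    reported_hb[s] += dump1
    reported_hb[s + 1] += dump2

    dates = config.dates()
    frames = [
        pd.DataFrame(
            {
                "date": dates,
                "region": "hubei",
                "nucleic_count": nucleic_hb,
                "clinical_count": clinical_hb,
                "reported_total": reported_hb,
                "true_total": nucleic_hb + clinical_hb,
            }
        ),
        pd.DataFrame(
            {
                "date": dates,
                "region": "other",
                "nucleic_count": nucleic_other,
                "clinical_count": 0.0,
                "reported_total": nucleic_other,
                "true_total": nucleic_other,
            }
        ),
    ]
    return pd.concat(frames, ignore_index=True)


def national_true_series(cases: pd.DataFrame) -> DailySeries:
    """Latent daily true case totals summed over regions (generator ledger)."""
    daily = cases.groupby("date")["true_total"].sum().sort_index()
    start = pd.Timestamp(daily.index[0]).date()
    return DailySeries(start, daily.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Comments


@dataclass(frozen=True)
class SimulatedComments:
    """Coder-labelled comment stream plus the generator's latent truth."""

    table: pd.DataFrame  # comment_id, date, coder_1..coder_k
    truth_counts: pd.DataFrame  # one row per day, one column per category
    true_codes: np.ndarray = field(repr=False)  # latent label code per comment


def emotion_day_probs(config: SyntheticConfig, log_cases: np.ndarray) -> np.ndarray:
    """Per-day category probabilities: base odds tilted on anger and fear.

    The tilt adds ``emotion_case_coupling * log1p(cases)`` to the log-odds
    of the two negative categories, then renormalizes — valid probabilities
    for any gain.
    """
    logits = np.log(np.asarray(config.emotion_base_probs, dtype=float))[None, :].repeat(
        log_cases.size, axis=0
    )
    for lab in NEGATIVE_EMOTIONS:
        logits[:, LABEL_CODES[lab]] += config.emotion_case_coupling * log_cases
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    return probs


def simulate_emotion_days(
    config: SyntheticConfig, cases: pd.DataFrame
) -> pd.DataFrame:
    """Daily latent true-emotion counts (fast path, no per-comment rows).

    One row per day with the total comment volume and its split over the
    five categories. ``simulate_comments`` expands the same counts into
    per-comment coder labels, so this table doubles as the generator's
    truth ledger.
    """
    _check_case_coverage(config, cases)
    rng = config.rng("comments")
    driver = national_true_series(cases)
    log_cases = np.log1p(driver.values)
    probs = emotion_day_probs(config, log_cases)

    shape = config.comment_volume_dispersion
    lam = config.comment_volume_mean * rng.gamma(shape, 1.0 / shape, size=config.n_days)
    volumes = rng.poisson(lam)
    volumes = np.maximum(volumes, 1)  # a day with zero comments breaks nothing, but
    # keeping >=1 keeps shares defined per day
    counts = np.vstack([rng.multinomial(v, p) for v, p in zip(volumes, probs)])

    out = pd.DataFrame(counts, columns=[lab.value for lab in EMOTIONS])
    out.insert(0, "date", config.dates())
    out["volume"] = volumes
    return out


def _check_case_coverage(config: SyntheticConfig, cases: pd.DataFrame) -> None:
    from .errors import AlignmentError

    have = set(pd.to_datetime(cases["date"]).dt.date)
    need = set(config.dates())
    missing = sorted(need - have)
    if missing:
        raise AlignmentError(f"case table misses {len(missing)} days, e.g. {missing[0]}")


def simulate_comments(config: SyntheticConfig, cases: pd.DataFrame) -> SimulatedComments:
    """Expand daily emotion counts into per-comment coder labels.

    Each comment's latent label follows the day's tilted category mix; each
    of the ``n_coders`` coders reports it with probability
    ``coder_accuracy`` and otherwise one of the other four categories
    uniformly at random.
    """
    truth = simulate_emotion_days(config, cases)
    rng = config.rng("coders")

    label_cols = [lab.value for lab in EMOTIONS]
    day_counts = truth[label_cols].to_numpy()
    n_total = int(day_counts.sum())

    true_codes = np.repeat(
        np.tile(np.arange(N_CATEGORIES), config.n_days),
        day_counts.ravel(),
    )
    day_index = np.repeat(np.arange(config.n_days), day_counts.sum(axis=1))

    k = config.n_coders
    correct = rng.random((n_total, k)) < config.coder_accuracy
    offsets = rng.integers(1, N_CATEGORIES, size=(n_total, k))
    coder_codes = np.where(
        correct, true_codes[:, None], (true_codes[:, None] + offsets) % N_CATEGORIES
    )

    names = np.array([lab.value for lab in EMOTIONS])
    dates = np.array(config.dates(), dtype=object)
    table = pd.DataFrame(
        {
            "comment_id": [f"c{idx:08d}" for idx in range(n_total)],
            "date": dates[day_index],
        }
    )
    for j in range(k):
        table[f"coder_{j + 1}"] = names[coder_codes[:, j]]
    return SimulatedComments(table=table, truth_counts=truth, true_codes=true_codes)


def truth_emotion_series(truth_counts: pd.DataFrame) -> dict[Emotion, DailySeries]:
    """The generator's latent per-day emotion count series."""
    start = pd.Timestamp(truth_counts["date"].iloc[0]).date()
    return {
        lab: DailySeries(start, truth_counts[lab.value].to_numpy(dtype=float))
        for lab in EMOTIONS
    }


# ---------------------------------------------------------------------------
# Rumors


@dataclass(frozen=True)
class SimulatedRumors:
    """Dated, emotion-tagged rumor records plus the daily count ledger."""

    table: pd.DataFrame  # rumor_id, date, emotion_tag
    daily_counts: DailySeries


def _coupling_attenuation(config: SyntheticConfig) -> float:
    """Approximate corr(log1p(count), latent intensity) for the rumor model.

    Poisson sampling around the log-normal intensity dilutes the latent
    correlation; on the log1p scale the conditional variance of a Poisson
    count with mean m is roughly m/(1+m)^2, giving
    c = s / sqrt(s^2 + m/(1+m)^2) for log-scale sd s. The latent coupling
    is boosted by 1/c so the realized cross-correlation at the injected
    lag approximates the configured strength.
    """
    s = config.rumor_lognoise_sd
    m = config.rumor_volume_mean
    v_pois = m / (1.0 + m) ** 2
    return s / np.sqrt(s**2 + v_pois)


def simulate_rumors(
    config: SyntheticConfig, emotion_series: Mapping[Emotion, DailySeries]
) -> SimulatedRumors:
    """Daily rumor counts lag-coupled to the negative-emotion signal.

    The latent log-intensity mixes the standardized log negative-emotion
    count, shifted by ``rumor_lag_days`` (positive: rumors lead emotions),
    with independent Gaussian noise, weighted so the population
    cross-correlation between log rumor counts and log emotion counts at
    the injected lag is approximately ``rumor_coupling_strength``. Counts
    are Poisson around the resulting intensity; each rumor draws an
    emotion tag from ``rumor_tag_probs`` (neutral modal).
    """
    missing = [lab.value for lab in NEGATIVE_EMOTIONS if lab not in emotion_series]
    if missing:
        raise InvalidConfigError(f"emotion series missing for: {missing}")
    neg = np.sum(
        [emotion_series[lab].values for lab in NEGATIVE_EMOTIONS], axis=0
    )
    n = neg.size
    if n != config.n_days:
        raise InvalidConfigError(
            f"emotion series cover {n} days; config expects {config.n_days}"
        )
    if abs(config.rumor_lag_days) >= n:
        raise InvalidConfigError("|rumor_lag_days| must be smaller than the window")

    z = np.log1p(neg)
    sd = z.std()
    z = (z - z.mean()) / sd if sd > 0 else np.zeros_like(z)
    # positive lag: rumors at t reflect the emotion signal at t + lag
    idx = np.clip(np.arange(n) + config.rumor_lag_days, 0, n - 1)
    z_shift = z[idx]

    rng = config.rng("rumors")
    eps = rng.standard_normal(n)
    rho = min(1.0, config.rumor_coupling_strength / _coupling_attenuation(config))
    latent = rho * z_shift + np.sqrt(max(0.0, 1.0 - rho**2)) * eps

    s = config.rumor_lognoise_sd
    lam = config.rumor_volume_mean * np.exp(s * latent - 0.5 * s**2)
    counts = rng.poisson(lam)

    tag_codes = rng.choice(
        N_CATEGORIES, size=int(counts.sum()), p=np.asarray(config.rumor_tag_probs)
    )
    names = np.array([lab.value for lab in EMOTIONS])
    dates = np.array(config.dates(), dtype=object)
    table = pd.DataFrame(
        {
            "rumor_id": [f"r{idx:06d}" for idx in range(int(counts.sum()))],
            "date": np.repeat(dates, counts),
            "emotion_tag": names[tag_codes],
        }
    )
    start = config.start_date
    return SimulatedRumors(
        table=table, daily_counts=DailySeries(start, counts.astype(float))
    )


# ---------------------------------------------------------------------------
# File output


def write_inputs(
    config: SyntheticConfig, out_dir, cases=None, comments=None, rumors=None
) -> dict[str, str]:
    """Write cases.csv, comments.csv and rumors.csv (UTF-8, ISO dates).

    Pre-simulated objects may be passed to avoid re-running stages; any
    omitted stage is simulated here from the config.
    """
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cases is None:
        cases = simulate_epidemic(config)
    if comments is None:
        comments = simulate_comments(config, cases)
    if rumors is None:
        rumors = simulate_rumors(config, truth_emotion_series(comments.truth_counts))

    paths = {}
    cases_out = cases.drop(columns=["true_total"])
    for name, frame in (
        ("cases", cases_out),
        ("comments", comments.table),
        ("rumors", rumors.table),
    ):
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = str(path)
    return paths
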