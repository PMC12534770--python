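"""Synthetic weather, vulnerability, and post data with known ground truth.

Every downstream stage of the pipeline is validated against data generated
here, because the quantities of interest (path coefficients, indirect
effects, odds ratios) are then known by construction.

Weather: per region, daily mean temperature follows a seasonal sinusoid
plus AR(1) noise — mu + A*sin(2*pi*(doy - phase)/365.25) + e_t with
e_t = phi*e_{t-1} + innovation, innovations scaled so the stationary
standard deviation equals ``noise_sd``.  Autocorrelated noise makes runs of
extreme days cluster, as heat waves do.  Precipitation is zero with
probability 1 - wet_day_prob and otherwise a gamma draw.

Posts: counts per region-day are Poisson.  Each post's scores follow a
linear structural model with a single weather exposure x (the extreme-hot
flag or the temperature anomaly), three mediators (affiliation, analytic
thinking, somatosensory experience), a well-being outcome and a
pro-environmental flag:

    M_k = alpha_k + a_k * x + e_k          (e correlated across mediators)
    Y   = alpha_Y + c' * x + sum_k b_k * M_k + e_Y
    P(pro_env) = logistic(g0 + g_x*x + g_Y*Y + sum_k g_k*M_k)

so the total effect of x on Y is c = c' + sum_k a_k*b_k by construction.
Mediator residuals are trivariate Gaussian with only the (1,2) and (1,3)
correlations free, matching the fitted path model; the (2,3) residual
correlation is fixed at zero.

A text mode turns target category percentages into token sequences whose
scores reproduce the targets exactly, giving a round-trip oracle for the
scorer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lexicon import Lexicon
from .weather import SEASON_BY_MONTH

__all__ = [
    "RegionClimate",
    "StructuralTruth",
    "SyntheticConfig",
    "SyntheticConfigError",
    "generate_weather",
    "generate_vulnerability",
    "generate_posts",
    "generate_post_texts",
]


class SyntheticConfigError(ValueError):
    pass


@dataclass
class RegionClimate:
    """Climate parameters for one synthetic region."""

    mean_temp: float = 15.0          # deg C
    seasonal_amplitude: float = 10.0  # deg C
    phase_day: float = 105.0          # day-of-year of the upward zero crossing
    ar1_coef: float = 0.6             # temperature-noise autocorrelation
    noise_sd: float = 3.0             # stationary noise SD, deg C
    wet_day_prob: float = 0.3
    wet_gamma_shape: float = 0.8
    wet_gamma_scale: float = 8.0      # mm

    def __post_init__(self) -> None:
        if not 0.0 <= self.ar1_coef < 1.0:
            raise SyntheticConfigError(f"ar1_coef must be in [0,1), got {self.ar1_coef}")
        if not 0.0 <= self.wet_day_prob <= 1.0:
            raise SyntheticConfigError(
                f"wet_day_prob must be in [0,1], got {self.wet_day_prob}"
            )
        if self.noise_sd < 0:
            raise SyntheticConfigError("noise_sd must be >= 0")


@dataclass
class StructuralTruth:
    """Ground-truth coefficients of the generating structural model.

    ``a``: exposure -> mediator paths (affiliation, analytic, somatosensory);
    ``b``: mediator -> well-being paths; ``c_prime``: direct effect.
    ``logit_coefs``: (intercept, exposure, well-being, m1, m2, m3) on the
    pro-environmental log-odds.  ``summer_temp_interaction`` optionally adds
    an exposure-by-summer term to the outcome equation for moderation tests.
    """

    a: tuple[float, float, float] = (-0.5, -0.3, 0.2)
    b: tuple[float, float, float] = (0.9, 0.3, 0.1)
    c_prime: float = -0.2
    mediator_intercepts: tuple[float, float, float] = (3.0, 30.0, 2.0)
    y_intercept: float = 1.0
    mediator_resid_sds: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mediator_resid_corr12: float = 0.3
    mediator_resid_corr13: float = 0.2
    y_resid_sd: float = 1.0
    logit_coefs: tuple[float, ...] = (0.0, -0.2, 0.05, 0.3, 0.02, 0.04)
    summer_temp_interaction: float = 0.0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.mediator_resid_sds) or self.y_resid_sd < 0:
            raise SyntheticConfigError("residual SDs must be >= 0")
        for r in (self.mediator_resid_corr12, self.mediator_resid_corr13):
            if not -1.0 < r < 1.0:
                raise SyntheticConfigError("residual correlations must be in (-1,1)")
        if self.mediator_resid_corr12**2 + self.mediator_resid_corr13**2 >= 1.0:
            raise SyntheticConfigError(
                "residual correlations imply a non-positive-definite covariance"
            )

    @property
    def total_effect(self) -> float:
        """c = c' + sum_k a_k*b_k, an identity of the linear model."""
        return self.c_prime + sum(ak * bk for ak, bk in zip(self.a, self.b))

    def mediator_resid_cov(self) -> np.ndarray:
        s = np.asarray(self.mediator_resid_sds, float)
        corr = np.eye(3)
        corr[0, 1] = corr[1, 0] = self.mediator_resid_corr12
        corr[0, 2] = corr[2, 0] = self.mediator_resid_corr13
        return corr * np.outer(s, s)


@dataclass
class SyntheticConfig:
    n_regions: int = 3
    date_start: str = "2022-01-01"
    date_end: str = "2022-12-31"
    baseline_years: int = 20
    region_climate: list[RegionClimate] = field(default_factory=list)
    posts_per_region_day_mean: float = 2.0
    exposure: str = "extreme_hot"    # or "temp_change"
    structural: StructuralTruth = field(default_factory=StructuralTruth)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions <= 0:
            raise SyntheticConfigError(f"n_regions must be positive, got {self.n_regions}")
        if pd.Timestamp(self.date_end) < pd.Timestamp(self.date_start):
            raise SyntheticConfigError("date_end precedes date_start")
        if self.posts_per_region_day_mean < 0:
            raise SyntheticConfigError("posts_per_region_day_mean must be >= 0")
        if self.exposure not in ("extreme_hot", "temp_change"):
            raise SyntheticConfigError(f"unknown exposure {self.exposure!r}")
        if not self.region_climate:
            # Stagger region means so vulnerability/regional contrasts exist.
            self.region_climate = [
                RegionClimate(mean_temp=12.0 + 4.0 * i) for i in range(self.n_regions)
            ]
        if len(self.region_climate) != self.n_regions:
            raise SyntheticConfigError(
                "region_climate length must equal n_regions"
            )

    @property
    def region_names(self) -> list[str]:
        return [f"R{i+1:02d}" for i in range(self.n_regions)]

    @property
    def baseline_start(self) -> pd.Timestamp:
        start = pd.Timestamp(self.date_start)
        return start - pd.DateOffset(years=self.baseline_years)


def generate_weather(config: SyntheticConfig) -> pd.DataFrame:
    """One row per region-day from baseline start through ``date_end``.

    Deterministic given ``config.seed``; one independent substream per
    region so adding regions never perturbs existing ones.
    """
    start = config.baseline_start
    end = pd.Timestamp(config.date_end)
    dates = pd.date_range(start, end, freq="D")
    doy = dates.day_of_year.to_numpy(float)
    frames = []
    root = np.random.default_rng(config.seed)
    streams = root.spawn(config.n_regions)
    for region, rc, rng in zip(config.region_names, config.region_climate, streams):
        seasonal = rc.mean_temp + rc.seasonal_amplitude * np.sin(
            2 * np.pi * (doy - rc.phase_day) / 365.25
        )
        n = len(dates)
        noise = np.zeros(n)
        if rc.noise_sd > 0:
            innov_sd = rc.noise_sd * np.sqrt(1.0 - rc.ar1_coef**2)
            z = rng.normal(0.0, 1.0, n)
            noise[0] = rc.noise_sd * z[0]  # stationary start
            for t in range(1, n):
                noise[t] = rc.ar1_coef * noise[t - 1] + innov_sd * z[t]
        tmean = seasonal + noise
        wet = rng.random(n) < rc.wet_day_prob
        precip = np.zeros(n)
        if wet.any():
            precip[wet] = rng.gamma(rc.wet_gamma_shape, rc.wet_gamma_scale, wet.sum())
        frames.append(
            pd.DataFrame(
                {
                    "region": region,
                    "date": dates,
                    "tmean": tmean,
                    "tmax": tmean + 4.0,
                    "precip": precip,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_vulnerability(config: SyntheticConfig) -> pd.DataFrame:
    """Region-level vulnerability indices (population density, exposure,
    sensitivity, adaptability), drawn once per region."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104729]))
    n = config.n_regions
    return pd.DataFrame(
        {
            "region": config.region_names,
            "population_density": rng.lognormal(5.0, 1.0, n),
            "exposure": rng.normal(0.5, 0.15, n).clip(0, 1),
            "sensitivity": rng.normal(0.5, 0.15, n).clip(0, 1),
            "adaptability": rng.normal(0.5, 0.15, n).clip(0, 1),
        }
    )


def _emotion_percentages(ewb: np.ndarray, rng: np.random.Generator):
    """Dress the structural well-being index in plausible affect percentages.

    posemo - negemo reproduces Y exactly; discrete negative emotions are
    non-structural noise loosely tied to the negative pole.
    """
    posemo = np.clip(ewb, 0.0, None) + 2.0
    negemo = posemo - ewb
    anger = np.abs(rng.normal(0.5, 0.5, ewb.size)) + 0.1 * negemo
    anxiety = np.abs(rng.normal(0.5, 0.5, ewb.size)) + 0.1 * negemo
    sadness = np.abs(rng.normal(0.5, 0.5, ewb.size)) + 0.1 * negemo
    return posemo, negemo, anger, anxiety, sadness


def generate_posts(config: SyntheticConfig, indicators: pd.DataFrame) -> pd.DataFrame:
    """Score-mode synthetic posts: structural scores without any text.

    ``indicators`` must cover every region-day from ``date_start`` to
    ``date_end``; a missing region-day raises a join error naming it.
    Returns one row per post with the same columns the scorer produces.
    """
    truth = config.structural
    start, end = pd.Timestamp(config.date_start), pd.Timestamp(config.date_end)
    idx = indicators.set_index(["region", "date"]).sort_index()
    if idx.index.has_duplicates:
        raise SyntheticConfigError("duplicate (region, date) rows in indicators")
    dates = pd.date_range(start, end, freq="D")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 15485863]))
    chol = np.linalg.cholesky(
        truth.mediator_resid_cov() + 1e-12 * np.eye(3)
    ) if max(truth.mediator_resid_sds) > 0 else np.zeros((3, 3))
    records = []
    post_counter = 0
    a = np.asarray(truth.a)
    b = np.asarray(truth.b)
    g = np.asarray(truth.logit_coefs, float)
    for region in config.region_names:
        for date in dates:
            try:
                row = idx.loc[(region, date)]
            except KeyError:
                raise KeyError(
                    f"no weather indicators for region-day ({region}, {date.date()})"
                ) from None
            n_posts = rng.poisson(config.posts_per_region_day_mean)
            if n_posts == 0:
                continue
            if config.exposure == "extreme_hot":
                x = float(row["extreme_hot"])
            else:
                x = float(row["temp_change"])
            if np.isnan(x):
                raise KeyError(
                    f"missing {config.exposure} for region-day ({region}, {date.date()})"
                )
            e_med = rng.normal(size=(n_posts, 3)) @ chol.T
            M = np.asarray(truth.mediator_intercepts) + a * x + e_med
            is_summer = SEASON_BY_MONTH[date.month] == "summer"
            y = (
                truth.y_intercept
                + truth.c_prime * x
                + truth.summer_temp_interaction * x * is_summer
                + M @ b
                + rng.normal(0.0, truth.y_resid_sd, n_posts)
            )
            eta = g[0] + g[1] * x + g[2] * y + M @ g[3:6]
            pro_env = (rng.random(n_posts) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
            posemo, negemo, anger, anxiety, sadness = _emotion_percentages(y, rng)
            for j in range(n_posts):
                records.append(
                    {
                        "post_id": f"P{post_counter:07d}",
                        "date": date,
                        "region": region,
                        "posemo": posemo[j],
                        "negemo": negemo[j],
                        "anger": anger[j],
                        "anxiety": anxiety[j],
                        "sadness": sadness[j],
                        "affiliation": M[j, 0],
                        "analytic": M[j, 1],
                        "somatosensory": M[j, 2],
                        "ewb": y[j],
                        "pro_env": int(pro_env[j]),
                    }
                )
                post_counter += 1
    return pd.DataFrame.from_records(records)


def generate_post_texts(
    targets: pd.DataFrame, lexicon: Lexicon, tokens_per_post: int
) -> pd.DataFrame:
    """Text-mode posts whose scores reproduce target percentages exactly.

    ``targets`` has columns ``post_id``/``date``/``region`` plus one column
    per lexicon category giving the target percentage.  Each target times
    ``tokens_per_post`` must be an integer token count; anything else is an
    error, never silently rounded.  Categories used must be disjoint in this
    mode, and filler tokens are out-of-lexicon by construction.
    """
    cats = [c for c in targets.columns if c in lexicon.categories]
    # one representative token per category, with the wildcard marker stripped
    rep = {}
    claimed: set[str] = set()
    for c in cats:
        tok = sorted(lexicon.categories[c])[0].rstrip("*")
        rep[c] = tok
        claimed.add(tok)
    for c in cats:
        others = set().union(*(lexicon.categories[o] for o in cats if o != c))
        for e in lexicon.categories[c]:
            if e in others:
                raise SyntheticConfigError(
                    f"text mode needs disjoint categories; {e!r} is shared by {c!r}"
                )
        for o in cats:
            if o != c and lexicon.matches(o, rep[c]):
                raise SyntheticConfigError(
                    f"token {rep[c]!r} for {c!r} also matches category {o!r}"
                )
    records = []
    for row in targets.itertuples(index=False):
        counts = {}
        for c in cats:
            implied = getattr(row, c) * tokens_per_post / 100.0
            k = round(implied)
            if abs(implied - k) > 1e-9:
                raise SyntheticConfigError(
                    f"target {getattr(row, c)}% of {tokens_per_post} tokens for "
                    f"{c!r} implies non-integer count {implied}"
                )
            counts[c] = int(k)
        n_filler = tokens_per_post - sum(counts.values())
        if n_filler < 0:
            raise SyntheticConfigError(
                f"targets for post {row.post_id} exceed 100% of tokens"
            )
        tokens = [rep[c] for c in cats for _ in range(counts[c])]
        tokens += [f"zz{i}zz" for i in range(n_filler)]
        records.append(
            {
                "post_id": row.post_id,
                "date": getattr(row, "date", pd.Timestamp("2022-01-01")),
                "region": getattr(row, "region", "R01"),
                "text": " ".join(tokens),
            }
        )
    return pd.DataFrame.from_records(records)
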