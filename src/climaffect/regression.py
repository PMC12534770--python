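"""Moderation and nested logistic models for weather, mood, and behaviour.

Moderation: Gaussian linear models of the well-being index on a weather
term, a moderator (the season factor or a dichotomized vulnerability flag),
and their interaction.  Factors are treatment-coded with spring and "low"
as reference levels; z statistics (estimate / SE) are tested against the
normal distribution and interactions are probed with simple slopes at
chosen moderator values.

Pro-environmental tendency: four nested logistic models adding predictor
blocks cumulatively — weather, then well-being, then the three cognitive
scores, then the four vulnerability flags — reported as odds ratios with
Wald intervals and McFadden pseudo-R².  The log-likelihood is monotone
non-decreasing across nested blocks.

Collinearity is screened with variance inflation factors: VIF_j =
1 / (1 - R²_j) from regressing predictor j on the others; predictors with
VIF > 5 are removed iteratively, largest first, recomputing after each
removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "RegressionFit",
    "ModelError",
    "fit_moderation",
    "probe_interaction",
    "fit_logistic_nested",
    "vif_screen",
]

Z_CRIT = float(stats.norm.ppf(0.975))


class ModelError(ValueError):
    pass


@dataclass
class RegressionFit:
    """A fitted linear or logistic model in table form.

    ``table`` has one row per term: estimate, se, z, p, ci_low, ci_high and
    (for logistic models) odds ratios with their CIs.  CIs are Wald
    intervals on the link scale.
    """

    family: str                  # "linear" | "logistic"
    terms: list[str]
    table: pd.DataFrame
    n: int
    cov_params: pd.DataFrame
    llf: float | None = None
    llnull: float | None = None
    pseudo_r2: float | None = None
    reference_levels: dict[str, str] = field(default_factory=dict)

    def coef(self, term: str) -> float:
        return float(self.table.loc[term, "estimate"])


def _coef_table(params, bse, family: str) -> pd.DataFrame:
    z = params / bse
    p = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {
            "estimate": params,
            "se": bse,
            "z": z,
            "p": p,
            "ci_low": params - Z_CRIT * bse,
            "ci_high": params + Z_CRIT * bse,
        }
    )
    if family == "logistic":
        out["odds_ratio"] = np.exp(out["estimate"])
        out["or_ci_low"] = np.exp(out["ci_low"])
        out["or_ci_high"] = np.exp(out["ci_high"])
    return out


def fit_moderation(
    rows: pd.DataFrame,
    outcome: str,
    exposure: str,
    moderator: str,
    moderator_type: str = "factor",
    reference: str | None = None,
) -> RegressionFit:
    """Linear model: outcome ~ exposure * moderator, treatment coding.

    ``moderator_type`` "factor" treats the moderator as a categorical
    variable with ``reference`` (default: spring for season, otherwise the
    lexicographically first level) as the reference group; "numeric" enters
    it linearly (dichotomized flags coded 0/1 fall here).  Levels with no
    observations are dropped by the design matrix.
    """
    cols = [outcome, exposure, moderator]
    data = rows[cols].dropna().copy()
    if moderator_type == "factor":
        levels = sorted(map(str, data[moderator].unique()))
        if reference is None:
            reference = "spring" if "spring" in levels else levels[0]
        if reference not in levels:
            raise ModelError(f"reference level {reference!r} not present")
        data[moderator] = data[moderator].astype(str)
        if len(levels) == 1:
            # a single-level moderator carries no contrast
            formula = f"{outcome} ~ {exposure}"
        else:
            formula = (
                f"{outcome} ~ {exposure} * C({moderator}, Treatment('{reference}'))"
            )
        refs = {moderator: reference}
    elif moderator_type == "numeric":
        data[moderator] = data[moderator].astype(float)
        formula = f"{outcome} ~ {exposure} * {moderator}"
        refs = {}
    else:
        raise ValueError(f"unknown moderator_type {moderator_type!r}")
    model = smf.ols(formula, data=data)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ModelError("collinear design matrix in moderation model")
    res = model.fit()
    table = _coef_table(res.params, res.bse, "linear")
    return RegressionFit(
        family="linear",
        terms=list(res.params.index),
        table=table,
        n=int(res.nobs),
        cov_params=res.cov_params(),
        llf=float(res.llf),
        reference_levels=refs,
    )


def probe_interaction(
    fit: RegressionFit, exposure_term: str, interaction_term: str, values
) -> pd.DataFrame:
    """Simple slopes of the outcome on the exposure at probe moderator values.

    slope(v) = beta_exposure + beta_interaction * v, with the SE from the
    coefficient covariance.  Probe values are typically mean +/- 1 SD for a
    continuous moderator or {0, 1} for a flag/factor contrast.
    """
    for term in (exposure_term, interaction_term):
        if term not in fit.terms:
            raise ModelError(f"term {term!r} not in fitted model")
    b1 = fit.coef(exposure_term)
    b3 = fit.coef(interaction_term)
    v11 = fit.cov_params.loc[exposure_term, exposure_term]
    v33 = fit.cov_params.loc[interaction_term, interaction_term]
    v13 = fit.cov_params.loc[exposure_term, interaction_term]
    rows = []
    for v in values:
        slope = b1 + b3 * v
        se = float(np.sqrt(v11 + v * v * v33 + 2.0 * v * v13))
        z = slope / se
        rows.append(
            {
                "moderator_value": v,
                "slope": slope,
                "se": se,
                "z": z,
                "p": 2.0 * stats.norm.sf(abs(z)),
                "ci_low": slope - Z_CRIT * se,
                "ci_high": slope + Z_CRIT * se,
            }
        )
    return pd.DataFrame(rows)


def fit_logistic_nested(
    rows: pd.DataFrame, outcome: str, blocks: list[list[str]]
) -> list[RegressionFit]:
    """Nested logistic models with cumulative predictor blocks.

    Model m uses the union of the first m blocks.  Fits are maximum
    likelihood (Newton scoring, tolerance 1e-8 on the score); odds ratios
    carry Wald CIs and McFadden pseudo-R² = 1 - llf / llnull.  Complete
    separation and non-convergence raise errors.
    """
    fits = []
    terms: list[str] = []
    for block in blocks:
        terms = terms + [t for t in block if t not in terms]
        cols = [outcome] + terms
        data = rows[cols].dropna()
        ybin = data[outcome].astype(float)
        if not ybin.isin([0.0, 1.0]).all():
            raise ModelError(f"outcome {outcome!r} must be binary 0/1")
        X = sm.add_constant(data[terms].astype(float), has_constant="add")
        try:
            res = sm.Logit(ybin, X).fit(disp=0, maxiter=100, tol=1e-8)
        except Exception as err:  # statsmodels raises several exception types
            raise ModelError(f"logistic fit failed for terms {terms}: {err}") from err
        if not res.mle_retvals.get("converged", True):
            raise ModelError(f"logistic fit did not converge for terms {terms}")
        table = _coef_table(res.params, res.bse, "logistic")
        fits.append(
            RegressionFit(
                family="logistic",
                terms=list(res.params.index),
                table=table,
                n=int(res.nobs),
                cov_params=res.cov_params(),
                llf=float(res.llf),
                llnull=float(res.llnull),
                pseudo_r2=float(1.0 - res.llf / res.llnull),
            )
        )
    return fits


def vif_screen(design: pd.DataFrame, threshold: float = 5.0):
    """Variance inflation factors with iterative removal above the threshold.

    Each predictor is regressed on all the others (intercept included);
    VIF = 1/(1 - R²).  Perfect collinearity gives an infinite VIF and is
    removed first.  Removal is one predictor at a time, largest VIF first,
    recomputing until all remaining VIFs are <= threshold.

    Returns (vif_table, removed) where ``vif_table`` holds the final VIFs of
    the retained predictors and ``removed`` lists dropped predictors in
    removal order.
    """
    if design.shape[1] < 2:
        raise ModelError("VIF screening needs at least 2 predictors")
    if (design.std(ddof=0) == 0).any():
        const = design.columns[design.std(ddof=0) == 0][0]
        raise ModelError(f"constant column {const!r} among screened predictors")

    def _vifs(cols: list[str]) -> pd.Series:
        out = {}
        for j in cols:
            others = [c for c in cols if c != j]
            X = sm.add_constant(design[others].to_numpy(float), has_constant="add")
            yj = design[j].to_numpy(float)
            beta, *_ = np.linalg.lstsq(X, yj, rcond=None)
            resid = yj - X @ beta
            tss = ((yj - yj.mean()) ** 2).sum()
            r2 = 1.0 - (resid @ resid) / tss
            out[j] = float("inf") if r2 >= 1.0 - 1e-14 else 1.0 / (1.0 - r2)
        return pd.Series(out)

    cols = list(design.columns)
    removed: list[str] = []
    vifs = _vifs(cols)
    while len(cols) > 1 and vifs.max() > threshold:
        worst = vifs.idxmax()
        removed.append(str(worst))
        cols.remove(worst)
        if len(cols) == 1:
            vifs = pd.Series({cols[0]: 1.0})
            break
        vifs = _vifs(cols)
    table = vifs.rename("vif").to_frame()
    return table, removed
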