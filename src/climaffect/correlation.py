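"""Mixed-type correlation matrices with per-pair method selection and FDR.

Pairs of continuous variables get a Pearson coefficient, a continuous and a
binary variable a point-biserial coefficient, and two binary variables the
Matthews (phi) coefficient.  Point-biserial and phi are numerically the
Pearson coefficient evaluated on 0/1 codings, and that is how they are
computed here; the method label records the conventional name.

One two-sided p-value formula is used throughout: t = r*sqrt((n-2)/(1-r^2))
against t(n-2).  Phi is sometimes tested with a chi-square statistic
instead; the t form is used for uniformity across the matrix and is the
standard test for Pearson and point-biserial coefficients.  All
upper-triangle p-values of a matrix form a single family for the
Benjamini-Hochberg false-discovery-rate adjustment.

Missing data are removed pairwise (per-pair deletion), and the retained n
is reported per pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["CorrelationMatrix", "correlate_pair", "fdr_adjust", "correlation_matrix"]


@dataclass
class CorrelationMatrix:
    variables: list[str]
    types: dict[str, str]
    r: pd.DataFrame
    method: pd.DataFrame
    p_raw: pd.DataFrame
    p_fdr: pd.DataFrame
    n: pd.DataFrame
    failures: dict[tuple[str, str], str] = field(default_factory=dict)

    def to_long(self) -> pd.DataFrame:
        """Long-format (var1, var2, r, method, n, p_raw, p_fdr) upper triangle."""
        rows = []
        for i, v1 in enumerate(self.variables):
            for v2 in self.variables[i + 1 :]:
                rows.append(
                    {
                        "var1": v1,
                        "var2": v2,
                        "r": self.r.loc[v1, v2],
                        "method": self.method.loc[v1, v2],
                        "n": self.n.loc[v1, v2],
                        "p_raw": self.p_raw.loc[v1, v2],
                        "p_fdr": self.p_fdr.loc[v1, v2],
                    }
                )
        return pd.DataFrame(rows)


def _method_label(type_x: str, type_y: str) -> str:
    kinds = {type_x, type_y}
    if kinds == {"continuous"}:
        return "pearson"
    if kinds == {"binary"}:
        return "matthews"
    return "point_biserial"


def correlate_pair(
    x, y, type_x: str = "continuous", type_y: str = "continuous"
) -> tuple[float, float, str, int]:
    """Correlation of one pair after pairwise missing removal.

    Returns (r, two-sided p, method label, n used).  Zero variance in either
    vector leaves r undefined (NaN) with p NaN; the caller records the
    reason.  Binary vectors must be coded 0/1.
    """
    method = _method_label(type_x, type_y)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 complete pairs, got {n}")
    for name, v, t in (("x", x, type_x), ("y", y, type_y)):
        if t == "binary" and not np.isin(v, (0.0, 1.0)).all():
            raise ValueError(f"binary vector {name} must be coded 0/1")
    if x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan"), method, n
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, p, method, n


def fdr_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlation_matrix(
    rows: pd.DataFrame, variables: dict[str, str]
) -> CorrelationMatrix:
    """All-pairs mixed correlations with one FDR family per matrix.

    ``variables`` maps column name -> declared type ("continuous" or
    "binary").  Pairs with zero variance are reported as missing with a
    reason and excluded from the FDR family.
    """
    names = list(variables)
    if len(names) < 2:
        raise ValueError("need at least 2 variables")
    k = len(names)
    r = pd.DataFrame(np.eye(k), index=names, columns=names)
    p_raw = pd.DataFrame(np.full((k, k), np.nan), index=names, columns=names)
    p_fdr = p_raw.copy()
    nmat = pd.DataFrame(0, index=names, columns=names)
    method = pd.DataFrame("", index=names, columns=names)
    failures: dict[tuple[str, str], str] = {}
    pairs, pvals = [], []
    for i, v1 in enumerate(names):
        for v2 in names[i + 1 :]:
            rij, pij, m, n = correlate_pair(
                rows[v1], rows[v2], variables[v1], variables[v2]
            )
            r.loc[v1, v2] = r.loc[v2, v1] = rij
            method.loc[v1, v2] = method.loc[v2, v1] = m
            nmat.loc[v1, v2] = nmat.loc[v2, v1] = n
            p_raw.loc[v1, v2] = p_raw.loc[v2, v1] = pij
            if np.isnan(rij):
                failures[(v1, v2)] = "zero variance in at least one variable"
            else:
                pairs.append((v1, v2))
                pvals.append(pij)
    if pvals:
        adj = fdr_adjust(pvals)
        for (v1, v2), q in zip(pairs, adj):
            p_fdr.loc[v1, v2] = p_fdr.loc[v2, v1] = q
    return CorrelationMatrix(
        variables=names,
        types=dict(variables),
        r=r,
        method=method,
        p_raw=p_raw,
        p_fdr=p_fdr,
        n=nmat,
        failures=failures,
    )
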