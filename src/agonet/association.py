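"""Spearman rank correlations among network scores and with traits.

Correlations pool animals across pens (pen structure is ignored, matching
how the individual-score tables are usually reported). The correlation
coefficient is the Pearson correlation of mid-ranks; p-values use the
t approximation t = rho * sqrt((n-2)/(1-rho^2)) on n-2 degrees of
freedom, two-sided, with an optional seeded permutation alternative for
small samples. Stars follow the usual convention: * p < 0.05, ** p < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "spearman",
    "correlation_matrix",
    "trait_correlation_table",
    "CorrelationGrid",
]


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    rho: float
    p_value: float
    n: int
    stars: str


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def spearman(
    x,
    y,
    *,
    names: tuple[str, str] = ("x", "y"),
    method: str = "t",
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> CorrelationResult:
    """Spearman rank correlation with pairwise-complete observations.

    ``method="t"`` (default) uses the t approximation for the p-value;
    ``method="permutation"`` uses a seeded permutation test with
    ``n_permutations`` resamples. A constant vector yields rho = NaN
    (undefined) with empty stars.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 complete pairs, got {n}")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return CorrelationResult(*names, float("nan"), float("nan"), n, "")
    if method == "t":
        rho, p = stats.spearmanr(x, y)
        rho, p = float(rho), float(p)
    elif method == "permutation":
        rho = float(stats.spearmanr(x, y).statistic)
        rng = np.random.default_rng(seed)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(ry)
            r = float(np.corrcoef(rx, perm)[0, 1])
            if abs(r) >= abs(rho) - 1e-12:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(*names, rho, p, n, _stars(p))


@dataclass(frozen=True)
class CorrelationGrid:
    """Rectangular grid of pairwise correlation results."""

    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    stars: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Long-form tidy table: one row per variable pair."""
        rows = []
        for rv in self.rho.index:
            for cv in self.rho.columns:
                rows.append(
                    {
                        "row": rv,
                        "column": cv,
                        "rho": self.rho.loc[rv, cv],
                        "p_value": self.p.loc[rv, cv],
                        "n": self.n.loc[rv, cv],
                        "stars": self.stars.loc[rv, cv],
                    }
                )
        return pd.DataFrame(rows)

    def render(self, *, upper_triangle: bool = False) -> str:
        """Plain-text rendering with significance stars appended."""
        cells = self.rho.copy().astype(object)
        for rv in self.rho.index:
            for cv in self.rho.columns:
                val = self.rho.loc[rv, cv]
                if upper_triangle and list(self.rho.index).index(rv) >= list(
                    self.rho.columns
                ).index(cv):
                    cells.loc[rv, cv] = ""
                    continue
                star = self.stars.loc[rv, cv]
                cells.loc[rv, cv] = (
                    "" if pd.isna(val) else f"{val:.2f} {star}".rstrip()
                )
        return cells.to_string()


def _grid(
    left: pd.DataFrame, right: pd.DataFrame, **kwargs
) -> CorrelationGrid:
    rho = pd.DataFrame(index=left.columns, columns=right.columns, dtype=float)
    p = rho.copy()
    n = pd.DataFrame(index=left.columns, columns=right.columns, dtype=int)
    stars = pd.DataFrame(
        "", index=left.columns, columns=right.columns, dtype=object
    )
    for a in left.columns:
        for b in right.columns:
            res = spearman(left[a], right[b], names=(a, b), **kwargs)
            rho.loc[a, b] = res.rho
            p.loc[a, b] = res.p_value
            n.loc[a, b] = res.n
            stars.loc[a, b] = res.stars
    return CorrelationGrid(rho=rho, p=p, n=n, stars=stars)


def correlation_matrix(scores: pd.DataFrame, **kwargs) -> CorrelationGrid:
    """Pairwise Spearman correlations among individual network scores.

    ``scores``: one row per animal, one column per measure, pooled over
    pens. The grid is symmetric with unit diagonal.
    """
    if scores.shape[1] < 2:
        raise ValueError("need at least 2 measures")
    return _grid(scores, scores, **kwargs)


def trait_correlation_table(
    scores: pd.DataFrame, traits: pd.DataFrame, **kwargs
) -> CorrelationGrid:
    """Correlate each network measure (rows) with each trait (columns).

    Tables are matched on their index (animal id); animals missing from
    either side are dropped, and pairwise-incomplete values are dropped
    per cell. No overlapping animals is fatal.
    """
    common = scores.index.intersection(traits.index)
    if common.empty:
        raise ValueError("no overlapping animals between scores and traits")
    return _grid(scores.loc[common], traits.loc[common], **kwargs)
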