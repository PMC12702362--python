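"""Purifying-selection analysis of per-position conservation.

For each position the *normalized position count* (npc) is the fraction of
scored substitutions with log2 fold change > 0 — substitution tolerance with
respect to inhibition (0 h) or functional stability (48 h, refined table).
Conservation scores (higher = more evolutionarily labile) are regressed on
npc, positions are split at the two npc medians into quadrants Q1-Q4, and
conservation differences are tested with a one-way ANOVA + Tukey HSD and a
two-way (inhibition class x stability class) type-II ANOVA with interaction.

Quadrant convention (Cartesian, x = npc 0 h, y = npc 48 h; ties at a median
go to the low half): Q1 = (high, high), Q2 = (low, high), Q3 = (low, low),
Q4 = (high, low).  Q4 is thus inhibition-permissive / stability-constrained
and Q3 constrained for both functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm

from .errors import AnalysisError, DesignError, RegressionError
from .variants import parse_variant

QUADRANTS = ("Q1", "Q2", "Q3", "Q4")


def normalized_position_counts(scores: pd.Series) -> pd.Series:
    """Fraction of scored substitutions per position with score > 0.

    ``scores`` is keyed by variant string; positions without scored variants
    are absent from the result.
    """
    df = pd.DataFrame(
        {
            "position": [parse_variant(v).position for v in scores.index],
            "enriched": scores.to_numpy(dtype=float) > 0.0,
        }
    )
    npc = df.groupby("position")["enriched"].mean()
    npc.name = "npc"
    return npc.sort_index()


@dataclass
class RegressionResult:
    """Ordinary least-squares line of conservation on npc."""

    slope: float
    intercept: float
    r2: float
    pvalue: float
    n: int

    def summary(self) -> str:
        return (
            f"slope = {self.slope:.3g}, R^2 = {self.r2:.3g}, "
            f"p = {self.pvalue:.2g} (n = {self.n})"
        )


def conservation_regression(
    npc: pd.Series, conservation: pd.Series
) -> RegressionResult:
    """Regress conservation on npc over positions present in both.

    Raises
    ------
    RegressionError
        With fewer than 3 shared positions or zero npc variance.
    """
    common = npc.index.intersection(conservation.index)
    if len(common) < 3:
        raise RegressionError(
            f"regression needs >= 3 positions with both values (got {len(common)})"
        )
    x = npc.loc[common].to_numpy(dtype=float)
    y = conservation.loc[common].to_numpy(dtype=float)
    if np.ptp(x) == 0.0:
        raise RegressionError("npc has zero variance; slope undefined")
    if np.ptp(y) == 0.0:
        # constant response: flat fit with zero explained variance
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, len(common))
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        pvalue=float(fit.pvalue),
        n=len(common),
    )


def assign_quadrants(npc_0h: pd.Series, npc_48h: pd.Series) -> pd.DataFrame:
    """Median-split quadrant labels for positions present in both screens."""
    common = npc_0h.index.intersection(npc_48h.index)
    if len(common) == 0:
        raise AnalysisError("no position has npc values in both screens")
    x = npc_0h.loc[common].to_numpy(dtype=float)
    y = npc_48h.loc[common].to_numpy(dtype=float)
    med_x, med_y = float(np.median(x)), float(np.median(y))
    hi_x, hi_y = x > med_x, y > med_y
    label = np.where(
        hi_x & hi_y, "Q1",
        np.where(~hi_x & hi_y, "Q2", np.where(~hi_x & ~hi_y, "Q3", "Q4")),
    )
    return pd.DataFrame(
        {
            "npc_0h": x,
            "npc_48h": y,
            "inhibition_permissive": hi_x,
            "stability_permissive": hi_y,
            "quadrant": label,
        },
        index=pd.Index(common, name="position"),
    )


@dataclass
class QuadrantResult:
    """Median-quadrant segmentation with conservation comparisons."""

    table: pd.DataFrame            # per position, incl. quadrant + conservation
    medians: tuple[float, float]   # (median npc 0 h, median npc 48 h)
    quadrant_means: dict[str, float]
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame            # pairwise adjusted p-values

    def summary(self) -> str:
        means = ", ".join(
            f"{q} {self.quadrant_means[q]:.3g}" for q in QUADRANTS
        )
        return (
            f"Quadrant conservation means: {means}\n"
            f"one-way ANOVA F = {self.anova_f:.3g}, p = {self.anova_p:.2g}"
        )


def quadrant_analysis(
    npc_0h: pd.Series,
    npc_48h: pd.Series,
    conservation: pd.Series,
    min_per_quadrant: int = 2,
) -> QuadrantResult:
    """Conservation across median quadrants: one-way ANOVA + Tukey HSD.

    Tukey uses the studentized-range distribution with the Tukey-Kramer
    adjustment for unequal quadrant sizes.

    Raises
    ------
    AnalysisError
        Naming any quadrant with fewer than ``min_per_quadrant`` positions.
    """
    quad = assign_quadrants(npc_0h, npc_48h)
    common = quad.index.intersection(conservation.index)
    quad = quad.loc[common].copy()
    quad["conservation"] = conservation.loc[common].astype(float)
    groups = {q: quad.loc[quad["quadrant"] == q, "conservation"].to_numpy()
              for q in QUADRANTS}
    short = [q for q, g in groups.items() if len(g) < min_per_quadrant]
    if short:
        raise AnalysisError(
            f"quadrant(s) {', '.join(short)} have fewer than "
            f"{min_per_quadrant} positions"
        )
    if np.ptp(quad["conservation"].to_numpy()) == 0.0:
        # zero variance everywhere: no group effect, by convention F = 0
        f_stat, p = 0.0, 1.0
        hsd = None
    else:
        f_stat, p = stats.f_oneway(*(groups[q] for q in QUADRANTS))
        hsd = stats.tukey_hsd(*(groups[q] for q in QUADRANTS))
    rows = []
    for i in range(4):
        for j in range(i + 1, 4):
            rows.append(
                {
                    "group_a": QUADRANTS[i],
                    "group_b": QUADRANTS[j],
                    "mean_difference": float(
                        groups[QUADRANTS[i]].mean() - groups[QUADRANTS[j]].mean()
                    ),
                    "p_adj": float(hsd.pvalue[i, j]) if hsd is not None else 1.0,
                }
            )
    med_x = float(np.median(quad["npc_0h"]))
    med_y = float(np.median(quad["npc_48h"]))
    return QuadrantResult(
        table=quad,
        medians=(med_x, med_y),
        quadrant_means={q: float(groups[q].mean()) for q in QUADRANTS},
        anova_f=float(f_stat),
        anova_p=float(p),
        tukey=pd.DataFrame(rows),
    )


@dataclass
class AnovaResult:
    """Two-way type-II ANOVA with interaction."""

    f_inhibition: float
    p_inhibition: float
    f_stability: float
    p_stability: float
    f_interaction: float
    p_interaction: float
    df_num: int
    df_denom: int
    ss: dict[str, float]
    group_means: dict[tuple[bool, bool], float]

    def summary(self) -> str:
        return (
            f"two-way ANOVA (type II), residual df = {self.df_denom}:\n"
            f"  inhibition  F(1,{self.df_denom}) = {self.f_inhibition:.3g}, "
            f"p = {self.p_inhibition:.2g}\n"
            f"  stability   F(1,{self.df_denom}) = {self.f_stability:.3g}, "
            f"p = {self.p_stability:.2g}\n"
            f"  interaction F(1,{self.df_denom}) = {self.f_interaction:.3g}, "
            f"p = {self.p_interaction:.2g}"
        )


def two_way_anova(
    inhibition_class, stability_class, conservation
) -> AnovaResult:
    """Type-II two-way ANOVA of conservation on two binary position classes.

    Factors are the median-split permissiveness classes; the denominator df is
    n - 4.  Raises :class:`DesignError` when a factor is constant or the two
    factors are confounded (identical or complementary columns).
    """
    a = np.asarray(inhibition_class, dtype=bool)
    b = np.asarray(stability_class, dtype=bool)
    y = np.asarray(conservation, dtype=float)
    if len(np.unique(a)) < 2:
        raise DesignError("inhibition class is constant")
    if len(np.unique(b)) < 2:
        raise DesignError("stability class is constant")
    if np.array_equal(a, b) or np.array_equal(a, ~b):
        raise DesignError("inhibition and stability classes are confounded")
    df = pd.DataFrame({"y": y, "A": a, "B": b})
    if df.groupby(["A", "B"]).size().reindex(
        [(False, False), (False, True), (True, False), (True, True)]
    ).isna().any():
        raise DesignError("an (inhibition, stability) cell is empty")
    fit = smf.ols("y ~ C(A) * C(B)", data=df).fit()
    table = anova_lm(fit, typ=2)
    get = lambda term, col: float(table.loc[term, col])
    means = df.groupby(["A", "B"])["y"].mean()
    return AnovaResult(
        f_inhibition=get("C(A)", "F"),
        p_inhibition=get("C(A)", "PR(>F)"),
        f_stability=get("C(B)", "F"),
        p_stability=get("C(B)", "PR(>F)"),
        f_interaction=get("C(A):C(B)", "F"),
        p_interaction=get("C(A):C(B)", "PR(>F)"),
        df_num=1,
        df_denom=int(table.loc["Residual", "df"]),
        ss={
            "inhibition": get("C(A)", "sum_sq"),
            "stability": get("C(B)", "sum_sq"),
            "interaction": get("C(A):C(B)", "sum_sq"),
            "residual": get("Residual", "sum_sq"),
        },
        group_means={k: float(v) for k, v in means.items()},
    )
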