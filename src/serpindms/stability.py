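"""Positional analysis of functional stability scores.

The 48 h screen's log2 enrichment (functional stability score) confounds slow
latency with plain loss of inhibitory function, so it is first refined by the
0 h screen: variants whose inhibition score is below zero are dropped (a score
of exactly zero is retained).  Refined scores are aggregated per position into
a mutational acceptance score, smoothed with a nearest-k tricube LOWESS
(local degree 1, no robustness iterations), and classified into stabilizing /
destabilizing / neutral regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, SmoothingError
from .variants import parse_variant

REGION_STABILIZING = "stabilizing"
REGION_DESTABILIZING = "destabilizing"
REGION_NEUTRAL = "neutral"


def refine_functional_stability(
    inhibition_scores: pd.Series, stability_scores: pd.Series
) -> pd.DataFrame:
    """Join the two screens and flag the refined subset.

    A variant is refined iff it was scored in both screens and its 0 h
    inhibition score is >= 0 (the filter removes scores strictly below zero).

    Parameters
    ----------
    inhibition_scores, stability_scores : pandas.Series
        log2 fold changes keyed by variant string (passed-filter variants).

    Returns
    -------
    pandas.DataFrame
        Indexed by variant, columns ``position``, ``inhibition_score``,
        ``functional_stability_score``, ``refined``.
    """
    common = inhibition_scores.index.intersection(stability_scores.index)
    if len(common) == 0:
        raise InputError("the two score tables share no variants")
    inh = inhibition_scores.loc[common].astype(float)
    stab = stability_scores.loc[common].astype(float)
    out = pd.DataFrame(
        {
            "position": [parse_variant(v).position for v in common],
            "inhibition_score": inh,
            "functional_stability_score": stab,
            "refined": inh >= 0.0,
        },
        index=common,
    )
    out.index.name = "variant"
    return out


def positional_acceptance(
    refined_scores: pd.DataFrame, aggregate: str = "mean"
) -> pd.Series:
    """Mutational acceptance score per position.

    Aggregates refined functional stability scores at each position
    (``mean`` by default; ``sum`` available).  Positions without refined
    variants are absent from the result.
    """
    if aggregate not in ("mean", "sum"):
        raise InputError(f"aggregate must be 'mean' or 'sum', got {aggregate!r}")
    sub = refined_scores[refined_scores["refined"]]
    acc = sub.groupby("position")["functional_stability_score"].agg(aggregate)
    acc.name = "mutational_acceptance"
    return acc.sort_index()


def lowess_smooth(values: pd.Series, window_points: int = 20) -> pd.Series:
    """LOWESS with a fixed-size nearest-neighbor window.

    At each position with a value, a degree-1 weighted least-squares line is
    fit over the ``window_points`` nearest positions that carry values
    (tricube weights on distance scaled by the window radius; zero robustness
    iterations) and evaluated at the position.  Positions without values are
    excluded from neighbor sets and from the output.

    Raises
    ------
    SmoothingError
        If fewer positions carry values than ``window_points``.
    """
    series = values.dropna().sort_index()
    n = len(series)
    if window_points < 2:
        raise SmoothingError("window_points must be >= 2")
    if n < window_points:
        raise SmoothingError(
            f"{n} positions with values < smoothing window {window_points}"
        )
    x = series.index.to_numpy(dtype=float)
    y = series.to_numpy(dtype=float)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        nearest = np.argsort(d, kind="mergesort")[:window_points]
        dmax = d[nearest].max()
        if dmax == 0:
            out[i] = y[nearest].mean()
            continue
        w = (1.0 - (d[nearest] / dmax) ** 3) ** 3
        xs, ys = x[nearest], y[nearest]
        sw = w.sum()
        xbar = (w * xs).sum() / sw
        ybar = (w * ys).sum() / sw
        sxx = (w * (xs - xbar) ** 2).sum()
        if sxx <= 0:
            out[i] = ybar
            continue
        slope = (w * (xs - xbar) * (ys - ybar)).sum() / sxx
        out[i] = ybar + slope * (x[i] - xbar)
    return pd.Series(out, index=series.index, name="lowess")


def _merge_runs(positions: np.ndarray) -> list[tuple[int, int]]:
    """Merge sorted integer positions into maximal consecutive intervals."""
    if positions.size == 0:
        return []
    breaks = np.where(np.diff(positions) > 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [positions.size - 1]])
    return [(int(positions[s]), int(positions[e])) for s, e in zip(starts, ends)]


@dataclass
class RegionCalls:
    """Per-position region classes and merged 1-based inclusive intervals."""

    classes: pd.Series
    stabilizing: list[tuple[int, int]]
    destabilizing: list[tuple[int, int]]
    upper_threshold: float
    lower_threshold: float

    def summary(self) -> str:
        fmt = lambda iv: ", ".join(f"{a}-{b}" for a, b in iv) or "none"
        return (
            f"Region calls (upper >= {self.upper_threshold:.4g}, "
            f"lower < {self.lower_threshold:g}):\n"
            f"  stabilizing:   {fmt(self.stabilizing)}\n"
            f"  destabilizing: {fmt(self.destabilizing)}"
        )


def call_regions(
    lowess_values: pd.Series,
    upper: str | float = "percentile",
    upper_percentile: float = 75.0,
    lower: float = 0.0,
) -> RegionCalls:
    """Classify positions by the smoothed acceptance profile.

    A position is destabilizing when its LOWESS value is below ``lower``
    (default 0); otherwise stabilizing when at or above the upper threshold
    (the 75th percentile of the LOWESS series by default, or its mean with
    ``upper='mean'``, or an explicit number); otherwise neutral.
    Destabilizing takes precedence, so an all-negative profile yields no
    stabilizing region even though its top quartile trivially clears the
    percentile cut.  Contiguous (consecutive-position) same-class runs are
    merged into 1-based inclusive intervals.
    """
    if len(lowess_values) == 0:
        raise InputError("no LOWESS values to classify")
    vals = lowess_values.sort_index()
    arr = vals.to_numpy(dtype=float)
    if upper == "percentile":
        thr = float(np.percentile(arr, upper_percentile))
    elif upper == "mean":
        thr = float(arr.mean())
    else:
        thr = float(upper)
    classes = np.where(
        arr < lower,
        REGION_DESTABILIZING,
        np.where(arr >= thr, REGION_STABILIZING, REGION_NEUTRAL),
    )
    classes = pd.Series(classes, index=vals.index, name="region_class")
    pos = vals.index.to_numpy()
    stab = _merge_runs(pos[classes.to_numpy() == REGION_STABILIZING])
    destab = _merge_runs(pos[classes.to_numpy() == REGION_DESTABILIZING])
    return RegionCalls(classes, stab, destab, thr, float(lower))


def region_jaccard(
    called: list[tuple[int, int]], planted: list[tuple[int, int]]
) -> float:
    """Jaccard index between two interval sets, measured on positions."""
    as_set = lambda ivs: set(p for a, b in ivs for p in range(a, b + 1))
    a, b = as_set(called), as_set(planted)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)
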