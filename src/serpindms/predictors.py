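"""Stratified comparison of external predictor scores against screen classes.

Variants are split by a DMS score (inhibition or functional stability) into
an upper stratum (score > 0: functional / stabilized) and a lower stratum
(score <= 0: reduced / destabilized, folding wild-type-like effects into the
lower class).  Group means carry normal-approximation 95% CIs, and the class
difference is tested with a linear mixed model — predictor ~ class with a
random intercept per position (REML, Wald p) — because substitutions at one
position share structural context and are not independent draws.

Sign convention: the reported coefficient is the effect of membership in the
*lower* stratum, so a positive coefficient means the reduced/destabilized
class has the higher predictor value (the expected pattern for pathogenicity
scores and folding ddG).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import ModelError, StratificationError
from .variants import parse_variant

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided normal 95% quantile


@dataclass
class StratifiedResult:
    """Descriptive comparison of a predictor between two DMS strata."""

    grouping: str
    n_high: int
    n_low: int
    mean_high: float
    mean_low: float
    ci_high: tuple[float, float]
    ci_low: tuple[float, float]
    difference: float  # mean_low - mean_high

    def summary(self) -> str:
        return (
            f"Stratified by {self.grouping}:\n"
            f"  score > 0:  n={self.n_high}, mean={self.mean_high:.4g} "
            f"(95% CI {self.ci_high[0]:.4g}-{self.ci_high[1]:.4g})\n"
            f"  score <= 0: n={self.n_low}, mean={self.mean_low:.4g} "
            f"(95% CI {self.ci_low[0]:.4g}-{self.ci_low[1]:.4g})\n"
            f"  difference (low - high): {self.difference:.4g}"
        )


@dataclass
class MixedModelResult:
    """Class fixed effect from predictor ~ class + (1 | position)."""

    coefficient: float
    se: float
    pvalue: float
    n_positions: int
    ols_fallback: bool = False

    def summary(self) -> str:
        tag = " (OLS fallback)" if self.ols_fallback else ""
        return (
            f"class effect {self.coefficient:.4g} +/- {self.se:.4g}, "
            f"p = {self.pvalue:.3g}, {self.n_positions} positions{tag}"
        )


def _join(dms_scores: pd.Series, predictor: pd.Series) -> pd.DataFrame:
    common = dms_scores.index.intersection(predictor.index)
    dropped = (len(dms_scores) - len(common), len(predictor) - len(common))
    if len(common) == 0:
        raise StratificationError(
            "DMS scores and predictor table share no variants"
        )
    if any(dropped):
        logger.info(
            "join dropped %d DMS-only and %d predictor-only variants", *dropped
        )
    return pd.DataFrame(
        {
            "dms": dms_scores.loc[common].astype(float),
            "value": predictor.loc[common].astype(float),
            "position": [parse_variant(v).position for v in common],
        },
        index=common,
    )


def _ci(values: np.ndarray) -> tuple[float, float]:
    m = values.mean()
    half = Z_95 * values.std(ddof=1) / np.sqrt(len(values))
    return (float(m - half), float(m + half))


def stratify_by_dms(
    dms_scores: pd.Series,
    predictor: pd.Series,
    grouping: str = "inhibition",
    threshold: float = 0.0,
) -> StratifiedResult:
    """Per-stratum means and 95% CIs of a predictor, split at ``threshold``.

    Raises
    ------
    StratificationError
        If the join is empty or either stratum has fewer than 2 variants.
    """
    df = _join(dms_scores, predictor)
    high = df.loc[df["dms"] > threshold, "value"].to_numpy()
    low = df.loc[df["dms"] <= threshold, "value"].to_numpy()
    if len(high) < 2 or len(low) < 2:
        raise StratificationError(
            f"need >= 2 variants per stratum (got {len(high)} > {threshold}, "
            f"{len(low)} <= {threshold})"
        )
    return StratifiedResult(
        grouping=grouping,
        n_high=len(high),
        n_low=len(low),
        mean_high=float(high.mean()),
        mean_low=float(low.mean()),
        ci_high=_ci(high),
        ci_low=_ci(low),
        difference=float(low.mean() - high.mean()),
    )


def mixed_model_test(
    values, classes, positions, reml: bool = True
) -> MixedModelResult:
    """Wald test of the class effect with a random intercept per position.

    ``classes`` is boolean (True = lower stratum).  Falls back to ordinary
    least squares, with a logged warning, when the random-intercept variance
    estimates to (numerically) zero or the mixed fit fails.

    Raises
    ------
    ModelError
        With fewer than 2 distinct positions or a single class.
    """
    y = np.asarray(values, dtype=float)
    cls = np.asarray(classes, dtype=float)
    pos = np.asarray(positions)
    if len(np.unique(pos)) < 2:
        raise ModelError("mixed model needs >= 2 distinct positions")
    if len(np.unique(cls)) < 2:
        raise ModelError("both classes must be present")
    df = pd.DataFrame({"value": y, "cls": cls, "position": pos})
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = sm.MixedLM.from_formula("value ~ cls", groups="position", data=df)
            fit = md.fit(reml=reml, method=["lbfgs", "bfgs"])
        re_var = float(fit.cov_re.iloc[0, 0])
        resid_var = float(fit.scale)
        degenerate = not np.isfinite(re_var) or re_var <= 1e-8 * max(resid_var, 1e-12)
    except Exception:  # singular fits, convergence failures
        fit = None
        degenerate = True
    if degenerate:
        logger.warning(
            "random-intercept variance degenerate; falling back to OLS"
        )
        ols = smf.ols("value ~ cls", data=df).fit()
        return MixedModelResult(
            coefficient=float(ols.params["cls"]),
            se=float(ols.bse["cls"]),
            pvalue=float(ols.pvalues["cls"]),
            n_positions=len(np.unique(pos)),
            ols_fallback=True,
        )
    return MixedModelResult(
        coefficient=float(fit.params["cls"]),
        se=float(fit.bse["cls"]),
        pvalue=float(fit.pvalues["cls"]),
        n_positions=len(np.unique(pos)),
    )


@dataclass
class StratifiedComparison:
    """Descriptive strata plus the positional mixed-model test."""

    stratified: StratifiedResult
    mixed: MixedModelResult
    predictor_name: str

    def summary(self) -> str:
        return (
            f"[{self.predictor_name}] {self.stratified.summary()}\n"
            f"  mixed model: {self.mixed.summary()}"
        )


def stratified_comparison(
    dms_scores: pd.Series,
    predictor: pd.Series,
    grouping: str = "inhibition",
    threshold: float = 0.0,
    predictor_name: str = "predictor",
) -> StratifiedComparison:
    """Run :func:`stratify_by_dms` and :func:`mixed_model_test` on one join."""
    strat = stratify_by_dms(dms_scores, predictor, grouping, threshold)
    df = _join(dms_scores, predictor)
    mixed = mixed_model_test(
        df["value"], (df["dms"] <= threshold), df["position"]
    )
    return StratifiedComparison(strat, mixed, predictor_name)


def compare_conformations(
    dms_scores: pd.Series,
    ddg_table: pd.DataFrame,
    grouping: str = "inhibition",
    threshold: float = 0.0,
) -> dict[str, StratifiedComparison]:
    """Side-by-side ddG comparison in the active and latent conformations.

    ``ddg_table`` must carry ``ddg_active`` and ``ddg_latent`` columns keyed
    by variant; the stratification and mixed model run once per conformation.
    """
    for col in ("ddg_active", "ddg_latent"):
        if col not in ddg_table.columns:
            raise StratificationError(f"ddG table lacks column {col!r}")
    return {
        conf: stratified_comparison(
            dms_scores,
            ddg_table[f"ddg_{conf}"],
            grouping=grouping,
            threshold=threshold,
            predictor_name=f"ddG {conf}",
        )
        for conf in ("active", "latent")
    }
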