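"""Negative-binomial enrichment scoring of variant count tables.

:class:`EnrichmentModel` turns a variant x sample count table plus sample
metadata into per-variant enrichment records for one contrast (selected
condition over input): baseMean, log2 fold change, a delta-method standard
error under a negative-binomial noise model, a Wald p-value, and
Benjamini-Hochberg adjusted p-values computed over the variants that pass the
baseMean filter.

The procedure is deliberately a defined, self-contained engine — median-of-
ratios size factors, method-of-moments dispersions shrunk toward a fitted
mean-dispersion trend, Wald test on the log ratio of pseudocounted normalized
means, BH over passed-filter variants — not a port of any published
differential-abundance package, although the output column names
(``baseMean``, ``log2FoldChange``, ``lfcSE``, ``pvalue``, ``padj``) match the
de-facto standard so externally produced tables can be ingested
interchangeably.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, NormalizationError, QCError

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8
DEFAULT_PRIOR_DISPERSION = 0.05


def compute_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample, the factor is the median over variants (with strictly
    positive counts in *every* sample) of count / geometric-row-mean.

    Raises
    ------
    NormalizationError
        If no variant has positive counts in all samples.
    """
    if counts.shape[1] < 2:
        raise NormalizationError("size factors need at least 2 samples")
    x = counts.to_numpy(dtype=float)
    all_pos = (x > 0).all(axis=1)
    if not all_pos.any():
        raise NormalizationError(
            "no variant with positive counts in every sample; cannot normalize"
        )
    logx = np.log(x[all_pos])
    log_geo = logx.mean(axis=1, keepdims=True)
    log_sf = np.median(logx - log_geo, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean of factors = 1
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


def _condition_map(samples: pd.DataFrame, columns) -> dict[str, list[str]]:
    by_cond: dict[str, list[str]] = {}
    for name in columns:
        cond = samples.loc[name, "condition"]
        by_cond.setdefault(cond, []).append(name)
    return by_cond


def _fit_dispersion_trend(base_mean: np.ndarray, raw: np.ndarray):
    """Least-squares fit of alpha ~ a0 + a1 / mu on variants with raw > 0,
    coefficients clipped to be nonnegative.  Falls back to the median raw
    dispersion when the fit is impossible."""
    ok = (raw > 0) & (base_mean > 0)
    fallback = float(np.median(raw[raw > 0])) if (raw > 0).any() else DEFAULT_PRIOR_DISPERSION
    if ok.sum() < 10:
        return lambda mu: np.full_like(np.asarray(mu, dtype=float), fallback)
    X = np.column_stack([np.ones(ok.sum()), 1.0 / base_mean[ok]])
    coef, *_ = np.linalg.lstsq(X, raw[ok], rcond=None)
    a0, a1 = np.maximum(coef, 0.0)
    if a0 == 0.0 and a1 == 0.0:
        return lambda mu: np.full_like(np.asarray(mu, dtype=float), fallback)
    return lambda mu: a0 + a1 / np.maximum(np.asarray(mu, dtype=float), 1e-8)


def estimate_dispersions(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    samples: pd.DataFrame,
    prior_dispersion: float = DEFAULT_PRIOR_DISPERSION,
) -> pd.Series:
    """Per-variant NB dispersion by method of moments, trend-shrunk.

    Within each condition having >= 2 replicates the raw estimate is
    ``max(0, (s^2 - mean) / mean^2)`` on size-factor-normalized counts;
    estimates are pooled across such conditions weighted by replicates - 1,
    then shrunk 50/50 toward a fitted mean-dispersion trend and floored at
    1e-8.  With no replicated condition, returns the configured prior for
    every variant (logged warning).
    """
    norm = counts / size_factors.reindex(counts.columns).to_numpy()
    by_cond = _condition_map(samples, counts.columns)
    num = np.zeros(len(counts))
    wsum = 0.0
    for cond, cols in by_cond.items():
        if len(cols) < 2:
            continue
        sub = norm[cols].to_numpy()
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = np.where(mu > 0, (var - mu) / np.square(mu), 0.0)
        w = len(cols) - 1
        num += w * np.maximum(alpha, 0.0)
        wsum += w
    if wsum == 0:
        logger.warning(
            "no condition with >= 2 replicates; using prior dispersion %g",
            prior_dispersion,
        )
        return pd.Series(prior_dispersion, index=counts.index, name="dispersion")
    raw = num / wsum
    base_mean = norm.to_numpy().mean(axis=1)
    trend = _fit_dispersion_trend(base_mean, raw)
    shrunk = 0.5 * raw + 0.5 * trend(base_mean)
    return pd.Series(
        np.maximum(shrunk, DISPERSION_FLOOR), index=counts.index, name="dispersion"
    )


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, clipped to 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass
class EnrichmentResults:
    """Fitted enrichment scores for one contrast.

    ``frame`` carries one row per variant with columns ``position``,
    ``wt_aa``, ``alt_aa``, ``baseMean``, ``log2FoldChange``, ``lfcSE``,
    ``stat``, ``pvalue``, ``padj``, ``dispersion``, ``passed_filter``;
    ``padj`` is NaN for variants failing the baseMean filter (BH is computed
    over passed variants only).
    """

    frame: pd.DataFrame
    contrast: tuple[str, str]
    base_mean_threshold: float
    fdr: float
    size_factors: pd.Series = field(repr=False)

    @property
    def scores(self) -> pd.Series:
        """log2 fold changes of passed-filter variants."""
        f = self.frame
        return f.loc[f["passed_filter"], "log2FoldChange"]

    @property
    def n_scored(self) -> int:
        return int(self.frame["passed_filter"].sum())

    @property
    def n_enriched(self) -> int:
        return int((self.scores > 0).sum())

    @property
    def n_depleted(self) -> int:
        return int((self.scores <= 0).sum())

    def significant(self, fdr: float | None = None) -> pd.DataFrame:
        """Passed-filter variants with ``padj`` below the FDR threshold."""
        if fdr is None:
            fdr = self.fdr
        f = self.frame
        return f[f["passed_filter"] & (f["padj"] < fdr)]

    def summary(self) -> str:
        sel, ref = self.contrast
        sig = self.significant()
        lines = [
            f"Enrichment contrast: {sel} vs {ref}",
            f"  variants:            {len(self.frame)}",
            f"  passed baseMean>={self.base_mean_threshold:g}: {self.n_scored}",
            f"  enriched (lfc > 0):  {self.n_enriched}"
            f" ({int((sig['log2FoldChange'] > 0).sum())} at FDR<{self.fdr:g})",
            f"  depleted (lfc <= 0): {self.n_depleted}"
            f" ({int((sig['log2FoldChange'] <= 0).sum())} at FDR<{self.fdr:g})",
        ]
        return "\n".join(lines)


class EnrichmentModel:
    """Wald test of selected-vs-input enrichment under NB count noise.

    Parameters
    ----------
    counts : pandas.DataFrame
        Integer reads, variants x samples.
    samples : pandas.DataFrame
        Indexed by sample name with columns ``condition`` and ``replicate``.
    contrast : (selected_condition, input_condition)
    base_mean_threshold : float
        baseMean filter below which variants receive no adjusted p.
    fdr : float
        FDR used by :meth:`EnrichmentResults.significant` and summaries.
    pseudocount : float
        Added to both normalized condition means before the log ratio, so
        fully depleted variants score finitely.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        samples: pd.DataFrame,
        contrast: tuple[str, str] = ("sel0h", "input"),
        base_mean_threshold: float = 50.0,
        fdr: float = 0.10,
        pseudocount: float = 0.5,
        prior_dispersion: float = DEFAULT_PRIOR_DISPERSION,
    ):
        if counts.index.has_duplicates:
            raise InputError("duplicate variant keys in count table")
        if (counts.to_numpy() < 0).any():
            raise InputError("negative counts in count table")
        missing = [c for c in counts.columns if c not in samples.index]
        if missing:
            raise InputError(f"samples table lacks metadata for {missing}")
        conditions = set(samples.loc[list(counts.columns), "condition"])
        for cond in contrast:
            if cond not in conditions:
                raise InputError(
                    f"contrast condition {cond!r} absent from count table"
                )
        self.counts = counts
        self.samples = samples
        self.contrast = tuple(contrast)
        self.base_mean_threshold = float(base_mean_threshold)
        self.fdr = float(fdr)
        self.pseudocount = float(pseudocount)
        self.prior_dispersion = float(prior_dispersion)

    def _contrast_columns(self):
        sel_cond, ref_cond = self.contrast
        by_cond = _condition_map(self.samples, self.counts.columns)
        return by_cond[sel_cond], by_cond[ref_cond]

    def fit(self) -> EnrichmentResults:
        """Estimate per-variant records for the configured contrast."""
        sel_cols, ref_cols = self._contrast_columns()
        cols = ref_cols + sel_cols
        sub = self.counts[cols]
        sf = compute_size_factors(sub)
        dispersion = estimate_dispersions(
            sub, sf, self.samples, prior_dispersion=self.prior_dispersion
        )
        norm = sub / sf.to_numpy()
        base_mean = norm.to_numpy().mean(axis=1)

        pc = self.pseudocount
        alpha = dispersion.to_numpy()
        ln2 = np.log(2.0)

        def cond_stats(cols_):
            m = norm[cols_].to_numpy().mean(axis=1)
            # plug-in variance of the normalized replicate mean under NB
            # (pseudocounted mean as the working mean, so zero-count variants
            # still carry sampling uncertainty)
            mu = m + pc
            s = sf[cols_].to_numpy()
            var = (mu[:, None] / s[None, :] + alpha[:, None] * mu[:, None] ** 2).sum(
                axis=1
            ) / len(cols_) ** 2
            return m, var

        m_sel, var_sel = cond_stats(sel_cols)
        m_ref, var_ref = cond_stats(ref_cols)
        with np.errstate(divide="ignore"):
            log2fc = np.log2(m_sel + pc) - np.log2(m_ref + pc)
        se = np.sqrt(
            var_sel / np.square(m_sel + pc) + var_ref / np.square(m_ref + pc)
        ) / ln2
        se = np.maximum(se, 1e-12)
        z = log2fc / se
        pvalue = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1), 1.0)

        passed = base_mean >= self.base_mean_threshold
        padj = np.full(len(sub), np.nan)
        if passed.any():
            padj[passed] = benjamini_hochberg(pvalue[passed])

        from .variants import parse_variant  # local to avoid cycle at import

        parsed = [parse_variant(v) for v in sub.index]
        frame = pd.DataFrame(
            {
                "position": [v.position for v in parsed],
                "wt_aa": [v.wt_aa for v in parsed],
                "alt_aa": [v.alt_aa for v in parsed],
                "baseMean": base_mean,
                "log2FoldChange": log2fc,
                "lfcSE": se,
                "stat": z,
                "pvalue": pvalue,
                "padj": padj,
                "dispersion": alpha,
                "passed_filter": passed,
            },
            index=sub.index,
        )
        return EnrichmentResults(
            frame, self.contrast, self.base_mean_threshold, self.fdr, sf
        )


@dataclass
class PCAResult:
    """Sample coordinates in enrichment space plus variance fractions."""

    coordinates: pd.DataFrame          # samples x PCs
    explained_variance_ratio: np.ndarray

    def summary(self) -> str:
        evr = self.explained_variance_ratio
        parts = ", ".join(f"PC{i + 1} {v:.0%}" for i, v in enumerate(evr[:3]))
        return f"Sample PCA on log2 normalized counts: {parts}"


def sample_pca(counts: pd.DataFrame, size_factors: pd.Series | None = None) -> PCAResult:
    """PCA of ``log2(normalized count + 1)`` with samples as observations.

    Variant axes are centered; variance fractions are computed over the full
    spectrum and sum to 1.

    Raises
    ------
    QCError
        With fewer than 3 samples.
    """
    if counts.shape[1] < 3:
        raise QCError("sample PCA needs at least 3 samples")
    if size_factors is None:
        size_factors = compute_size_factors(counts)
    norm = counts / size_factors.reindex(counts.columns).to_numpy()
    X = np.log2(norm.to_numpy(dtype=float) + 1.0).T  # samples x variants
    X = X - X.mean(axis=0, keepdims=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        U, s, _ = np.linalg.svd(X, full_matrices=False)
    var = np.square(s)
    total = var.sum()
    if total <= 0:
        evr = np.zeros_like(var)
        evr[0] = 1.0
    else:
        evr = var / total
    coords = pd.DataFrame(
        U * s,
        index=counts.columns,
        columns=[f"PC{i + 1}" for i in range(len(s))],
    )
    return PCAResult(coords, evr)
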