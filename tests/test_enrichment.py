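"""Enrichment engine: size factors, dispersions, Wald scoring, BH, PCA.

Brute-force oracles here are written with plain loops and
``statistics``/direct formulas, independent of the vectorized implementation
paths they check.
"""

import math
import statistics

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import serpindms as s
from serpindms.enrichment import benjamini_hochberg, estimate_dispersions
from serpindms.errors import InputError, NormalizationError, QCError


def _variant_names(n):
    wt = "ACDEFGHIKLMNPQRSTVWY"
    return [f"{wt[i % 19]}{i + 1}{'Y' if wt[i % 19] != 'Y' else 'W'}"
            for i in range(n)]


def _table(matrix, conditions):
    """Counts DataFrame + samples metadata from a raw matrix and per-column
    condition labels."""
    matrix = np.asarray(matrix)
    reps = {}
    cols = []
    rows = []
    for cond in conditions:
        reps[cond] = reps.get(cond, 0) + 1
        name = f"{cond}_{reps[cond]}"
        cols.append(name)
        rows.append({"sample": name, "condition": cond,
                     "replicate": reps[cond]})
    counts = pd.DataFrame(matrix, columns=cols,
                          index=_variant_names(matrix.shape[0]))
    return counts, pd.DataFrame(rows).set_index("sample")


# --------------------------------------------------------------------------
# size factors


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts, _ = _table(np.tile([[10], [40], [7]], (1, 4)),
                           ["input"] * 2 + ["sel0h"] * 2)
        sf = s.compute_size_factors(counts)
        np.testing.assert_allclose(sf, 1.0, rtol=1e-12)

    def test_doubled_sample_scale_equivariance(self):
        rng = np.random.default_rng(0)
        base = rng.integers(5, 500, size=10)
        counts, _ = _table(np.column_stack([base, 2 * base]),
                           ["input", "sel0h"])
        sf = s.compute_size_factors(counts)
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0, rel=1e-12)

    def test_worked_three_by_three_matrix(self):
        # rows all proportional -> factors proportional to (1, 2, 1) exactly;
        # rescaled to geometric mean 1: (2^-1/3, 2^2/3, 2^-1/3)
        counts, _ = _table([[10, 20, 10], [100, 200, 100], [4, 8, 4]],
                           ["input", "sel0h", "sel0h"])
        sf = s.compute_size_factors(counts)
        np.testing.assert_allclose(
            sf, [2 ** (-1 / 3), 2 ** (2 / 3), 2 ** (-1 / 3)], rtol=1e-12
        )
        assert math.prod(sf) ** (1 / 3) == pytest.approx(1.0, rel=1e-12)

    def test_no_all_positive_variant_is_an_error(self):
        counts, _ = _table([[0, 5], [5, 0]], ["input", "sel0h"])
        with pytest.raises(NormalizationError):
            s.compute_size_factors(counts)


# --------------------------------------------------------------------------
# dispersions


class TestDispersions:
    @staticmethod
    def _poisson_like(alpha, n_var=300, reps=50, mu=200.0, seed=0):
        rng = np.random.default_rng(seed)
        if alpha == 0:
            mat = rng.poisson(mu, size=(n_var, reps))
        else:
            size = 1.0 / alpha
            mat = rng.negative_binomial(size, size / (size + mu),
                                        size=(n_var, reps))
        return _table(mat, ["input"] * reps)

    def test_poisson_counts_estimate_near_zero(self):
        counts, samples = self._poisson_like(alpha=0.0)
        sf = s.compute_size_factors(counts)
        disp = estimate_dispersions(counts, sf, samples)
        assert disp.median() < 0.01

    def test_negative_binomial_dispersion_recovered(self):
        counts, samples = self._poisson_like(alpha=0.2)
        sf = s.compute_size_factors(counts)
        disp = estimate_dispersions(counts, sf, samples)
        assert 0.1 <= disp.median() <= 0.3

    def test_single_replicate_falls_back_to_prior(self):
        counts, samples = _table([[10, 20], [30, 15], [7, 9]],
                                 ["input", "sel0h"])
        sf = s.compute_size_factors(counts)
        disp = estimate_dispersions(counts, sf, samples, prior_dispersion=0.07)
        assert (disp == 0.07).all()


# --------------------------------------------------------------------------
# contrast scoring


class TestScoreContrast:
    def test_identity_contrast_scores_zero_everywhere(self):
        rng = np.random.default_rng(1)
        block = rng.integers(10, 400, size=(30, 3))
        counts, samples = _table(np.hstack([block, block]),
                                 ["input"] * 3 + ["sel0h"] * 3)
        res = s.EnrichmentModel(counts, samples, ("sel0h", "input")).fit()
        np.testing.assert_allclose(res.frame["log2FoldChange"], 0.0,
                                   atol=1e-12)

    def test_fourfold_enrichment_closed_form(self):
        # one variant goes 100 -> 400 against a stable background, so size
        # factors stay 1 and, with pseudocount 0, log2fc = 2 exactly
        background = np.tile([[100]], (10, 6))
        row = np.array([[100, 100, 100, 400, 400, 400]])
        counts, samples = _table(np.vstack([background, row]),
                                 ["input"] * 3 + ["sel0h"] * 3)
        res = s.EnrichmentModel(counts, samples, ("sel0h", "input"),
                                pseudocount=0.0).fit()
        np.testing.assert_allclose(s.compute_size_factors(counts), 1.0,
                                   rtol=1e-12)
        assert res.frame["log2FoldChange"].iloc[-1] == pytest.approx(2.0,
                                                                     abs=1e-12)

    def test_benjamini_hochberg_worked_example(self):
        padj = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.5]))
        np.testing.assert_allclose(padj, [0.04, 0.04, 0.04, 0.5], rtol=1e-12)

    def test_swapped_contrast_negates_scores(self, small_screen):
        fwd = s.EnrichmentModel(small_screen.counts, small_screen.samples,
                                ("sel0h", "input")).fit()
        rev = s.EnrichmentModel(small_screen.counts, small_screen.samples,
                                ("input", "sel0h")).fit()
        np.testing.assert_allclose(fwd.frame["log2FoldChange"],
                                   -rev.frame["log2FoldChange"], atol=1e-10)

    def test_base_mean_filter_is_exact(self, small_fitted):
        frame = small_fitted.res_0h.frame
        thr = small_fitted.res_0h.base_mean_threshold
        assert frame["passed_filter"].equals(frame["baseMean"] >= thr)
        # BH only over passed-filter variants: padj defined exactly there
        assert frame["padj"].notna().equals(frame["passed_filter"])
        passed = frame[frame["passed_filter"]]
        assert (passed["padj"] >= passed["pvalue"] - 1e-15).all()

    def test_missing_condition_is_input_error(self, small_screen):
        with pytest.raises(InputError):
            s.EnrichmentModel(small_screen.counts, small_screen.samples,
                              ("sel96h", "input"))


# --------------------------------------------------------------------------
# oracle equivalence on random small instances


def _bh_oracle(pvals):
    """Step-up BH by definition, O(n^2) loops."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [None] * m
    for rank_from_end in range(m - 1, -1, -1):
        i = order[rank_from_end]
        candidate = min(1.0, pvals[i] * m / (rank_from_end + 1))
        if rank_from_end < m - 1:
            candidate = min(candidate, adj[order[rank_from_end + 1]])
        adj[i] = candidate
    return adj


def _wald_oracle(matrix, n_input, n_sel, pseudocount=0.5):
    """Loop-based re-derivation of the whole scoring chain for one contrast:
    median-of-ratios -> moment dispersions (trend-shrunk) -> Wald p."""
    n_var, n_samp = matrix.shape
    # size factors
    log_ratios = [[] for _ in range(n_samp)]
    for i in range(n_var):
        row = matrix[i]
        if all(c > 0 for c in row):
            geo = math.exp(sum(math.log(c) for c in row) / n_samp)
            for j in range(n_samp):
                log_ratios[j].append(math.log(row[j] / geo))
    log_sf = [statistics.median(lr) for lr in log_ratios]
    mean_log_sf = sum(log_sf) / n_samp
    sf = [math.exp(v - mean_log_sf) for v in log_sf]
    norm = [[matrix[i][j] / sf[j] for j in range(n_samp)]
            for i in range(n_var)]
    in_cols = list(range(n_input))
    sel_cols = list(range(n_input, n_input + n_sel))
    # raw moment dispersions pooled over conditions with >= 2 replicates
    raw = []
    base_mean = []
    for i in range(n_var):
        base_mean.append(sum(norm[i]) / n_samp)
        num, wsum = 0.0, 0.0
        for cols in (in_cols, sel_cols):
            if len(cols) < 2:
                continue
            vals = [norm[i][j] for j in cols]
            mu = sum(vals) / len(vals)
            var = sum((v - mu) ** 2 for v in vals) / (len(vals) - 1)
            alpha = (var - mu) / mu**2 if mu > 0 else 0.0
            num += (len(cols) - 1) * max(alpha, 0.0)
            wsum += len(cols) - 1
        raw.append(num / wsum)
    # trend: least squares of raw ~ a0 + a1/mu over raw > 0, clipped >= 0
    pts = [(1.0 / base_mean[i], raw[i]) for i in range(n_var)
           if raw[i] > 0 and base_mean[i] > 0]
    if len(pts) < 10:
        positives = [r for r in raw if r > 0]
        trend = lambda mu: statistics.median(positives) if positives else 0.05
    else:
        X = np.array([[1.0, x] for x, _ in pts])
        yv = np.array([y for _, y in pts])
        a0, a1 = np.linalg.lstsq(X, yv, rcond=None)[0]
        a0, a1 = max(a0, 0.0), max(a1, 0.0)
        if a0 == 0.0 and a1 == 0.0:
            positives = [r for r in raw if r > 0]
            med = statistics.median(positives) if positives else 0.05
            trend = lambda mu: med
        else:
            trend = lambda mu: a0 + a1 / max(mu, 1e-8)
    out = []
    for i in range(n_var):
        alpha = max(0.5 * raw[i] + 0.5 * trend(base_mean[i]), 1e-8)
        m_in = sum(norm[i][j] for j in in_cols) / len(in_cols)
        m_sel = sum(norm[i][j] for j in sel_cols) / len(sel_cols)
        lfc = math.log2(m_sel + pseudocount) - math.log2(m_in + pseudocount)

        def var_of_mean(m, cols):
            mu = m + pseudocount
            return sum(mu / sf[j] + alpha * mu**2 for j in cols) / len(cols) ** 2

        se = math.sqrt(
            var_of_mean(m_sel, sel_cols) / (m_sel + pseudocount) ** 2
            + var_of_mean(m_in, in_cols) / (m_in + pseudocount) ** 2
        ) / math.log(2)
        se = max(se, 1e-12)
        z = lfc / se
        p = 2 * stats.norm.sf(abs(z))
        out.append((base_mean[i], lfc, se, max(p, np.nextafter(0, 1))))
    return sf, out


class TestOracleEquivalence:
    def test_bh_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(1, 40))
            p = rng.uniform(size=n) ** rng.uniform(0.3, 3)
            np.testing.assert_allclose(benjamini_hochberg(p), _bh_oracle(list(p)),
                                       rtol=1e-12)

    def test_wald_chain_matches_loop_oracle_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n_var = int(rng.integers(5, 25))
            n_in = int(rng.integers(2, 4))
            n_sel = int(rng.integers(2, 4))
            mat = rng.integers(1, 2000, size=(n_var, n_in + n_sel))
            counts, samples = _table(mat, ["input"] * n_in + ["sel0h"] * n_sel)
            res = s.EnrichmentModel(counts, samples, ("sel0h", "input"),
                                    base_mean_threshold=0.0).fit()
            sf_o, rec_o = _wald_oracle(mat, n_in, n_sel)
            np.testing.assert_allclose(res.size_factors, sf_o, rtol=1e-10)
            frame = res.frame
            for i, (bm, lfc, se, p) in enumerate(rec_o):
                assert frame["baseMean"].iloc[i] == pytest.approx(bm, rel=1e-10)
                assert frame["log2FoldChange"].iloc[i] == pytest.approx(
                    lfc, rel=1e-10, abs=1e-12)
                assert frame["lfcSE"].iloc[i] == pytest.approx(se, rel=1e-10)
                assert frame["pvalue"].iloc[i] == pytest.approx(p, rel=1e-8)


# --------------------------------------------------------------------------
# sample PCA


class TestSamplePCA:
    def test_duplicated_sample_groups_coincide(self):
        rng = np.random.default_rng(2)
        a = rng.integers(10, 1000, size=(50, 1))
        b = rng.integers(10, 1000, size=(50, 1))
        counts, _ = _table(np.hstack([a, a, b, b]),
                           ["input"] * 2 + ["sel0h"] * 2)
        pca = s.sample_pca(counts)
        coords = pca.coordinates.to_numpy()
        np.testing.assert_allclose(coords[0], coords[1], atol=1e-8)
        np.testing.assert_allclose(coords[2], coords[3], atol=1e-8)

    def test_variance_fractions_sum_to_one(self, small_screen):
        pca = s.sample_pca(small_screen.counts)
        assert pca.explained_variance_ratio.sum() == pytest.approx(1.0,
                                                                   abs=1e-8)

    def test_condition_groups_separate_on_first_components(self, default_screen):
        # qualitative analogue of the screen's sample-QC plot: input / 0 h /
        # 48 h replicate groups form distinct clusters in enrichment space
        from sklearn.metrics import silhouette_score

        pca = s.sample_pca(default_screen.counts)
        labels = default_screen.samples.loc[pca.coordinates.index, "condition"]
        score = silhouette_score(pca.coordinates.iloc[:, :2], labels)
        assert score > 0

    def test_fewer_than_three_samples_is_qc_error(self):
        counts, _ = _table([[5, 6], [7, 8]], ["input", "sel0h"])
        with pytest.raises(QCError):
            s.sample_pca(counts)
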