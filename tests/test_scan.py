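"""Association engine: residualization, per-pair statistics against an
OLS oracle, cis/trans classification, BH FDR, top-per-gene reduction,
QQ data, and the scan's emission/count semantics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import eqtlscan.association as sc
from eqtlscan.config import PipelineConfig
from eqtlscan.errors import AlignmentError, CollinearityError, ConfigError


class TestResidualize:
    def test_intercept_only_centers_rows(self):
        M = np.arange(12.0).reshape(2, 6)
        X = np.ones((6, 1))
        R = sc.residualize(M, X)
        assert np.allclose(R.mean(axis=1), 0.0, atol=1e-12)

    def test_projector_is_idempotent(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(10), rng.normal(size=10)])
        M = rng.normal(size=(3, 10))
        R1 = sc.residualize(M, X)
        R2 = sc.residualize(R1, X)
        assert np.allclose(R1, R2, atol=1e-12)
        assert np.abs(R1 @ X).max() < 1e-10  # orthogonal to every column

    def test_matches_explicit_ols_residuals(self):
        import statsmodels.api as sm
        age = np.array([10.0, 12.0, 20.0, 30.0, 8.0])
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        X = np.column_stack([np.ones(5), age])
        ours = sc.residualize(y[None, :], X)[0]
        theirs = sm.OLS(y, X).fit().resid
        assert np.allclose(ours, theirs, atol=1e-12)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(5), np.ones(5)])
        with pytest.raises(CollinearityError):
            sc.residualize(np.zeros((1, 5)), X)


class TestAssocStats:
    def test_orthogonal_vectors_give_null_stats(self):
        e = np.array([1.0, -1.0, 1.0, -1.0])
        g = np.array([1.0, 1.0, -1.0, -1.0])
        out = sc.assoc_stats(e, g, df=2)
        assert out.beta == 0.0 and out.t == 0.0 and out.p == 1.0

    def test_perfect_correlation_does_not_crash(self):
        g = np.array([-1.5, -0.5, 0.5, 1.5])
        out = sc.assoc_stats(2.0 * g, g, df=2)
        assert out.beta == pytest.approx(2.0)
        assert 0.0 < out.p <= np.finfo(float).tiny  # underflow reported, not clamped to 0
        assert out.var_explained < 1.0

    def test_matches_simple_regression_oracle(self):
        """Fixed 8-sample vectors: (beta, se, t, p) equal the textbook
        OLS of expression on dosage + intercept to 1e-10."""
        import statsmodels.api as sm
        e = np.array([2.1, 3.0, 1.2, 4.8, 3.3, 2.2, 5.1, 0.7])
        g = np.array([0.0, 1.0, 0.0, 2.0, 1.0, 1.0, 2.0, 0.0])
        X = np.ones((8, 1))
        er = sc.residualize(e[None, :], X)[0]
        gr = sc.residualize(g[None, :], X)[0]
        ours = sc.assoc_stats(er, gr, df=6)
        fit = sm.OLS(e, sm.add_constant(g)).fit()
        assert ours.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert ours.se == pytest.approx(fit.bse[1], abs=1e-10)
        assert ours.t == pytest.approx(fit.tvalues[1], abs=1e-10)
        assert ours.p == pytest.approx(fit.pvalues[1], abs=1e-10)
        lo, hi = fit.conf_int()[1]
        assert ours.ci95_low == pytest.approx(lo, abs=1e-10)
        assert ours.ci95_high == pytest.approx(hi, abs=1e-10)
        assert abs(abs(ours.t) - abs(ours.beta / ours.se)) < 1e-10

    def test_zero_genotype_variance_flagged(self):
        out = sc.assoc_stats(np.array([1.0, -1.0]), np.zeros(2), df=1)
        assert np.isnan(out.p)


class TestClassifyPair:
    GENE = pd.Series({"chrom": "21", "start": 17_000_000, "end": 17_100_000})

    def test_inside_gene_is_cis_distance_zero(self):
        assert sc.classify_pair("21", 17_035_557, self.GENE) == ("cis", 0)

    def test_cross_chromosome_is_always_trans(self):
        assert sc.classify_pair("6", 17_035_557, self.GENE)[0] == "trans"

    @pytest.mark.parametrize("pos,expect", [
        (17_200_000, ("cis", 100_000)),   # exactly 100 kb past the end
        (17_200_001, ("trans", 100_001)),
        (16_900_000, ("cis", 100_000)),
        (16_899_999, ("trans", 100_001)),
    ])
    def test_window_boundary_inclusive(self, pos, expect):
        assert sc.classify_pair("21", pos, self.GENE, cis_window=100_000) == expect


def brute_force_bh(p, m):
    """Literal BH definition: q_i = min over p_j >= p_i of m*p_j/rank_j."""
    p = np.asarray(p, dtype=float)
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(len(p), dtype=int)
    ranks[order] = np.arange(1, len(p) + 1)
    q = np.empty(len(p))
    for i in range(len(p)):
        cand = [m * p[j] / ranks[j] for j in range(len(p)) if p[j] >= p[i]]
        q[i] = min(1.0, min(cand))
    return q


class TestBhFdr:
    def test_four_point_example(self):
        q = sc.bh_fdr([0.01, 0.02, 0.03, 0.04], 4)
        assert q.tolist() == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert sc.bh_fdr([0.5], 1).tolist() == [0.5]

    def test_matches_statsmodels_when_m_equals_len(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(5)
        p = rng.uniform(size=100)
        ours = sc.bh_fdr(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs, atol=1e-12)

    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=40), st.integers(0, 500))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_brute_force_definition(self, p, extra_m):
        m = len(p) + extra_m
        assert np.allclose(sc.bh_fdr(p, m), brute_force_bh(p, m), atol=1e-12)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(6)
        p = np.sort(rng.uniform(size=50))
        q = sc.bh_fdr(p, 200)
        assert (np.diff(q) >= -1e-15).all()

    def test_m_total_too_small_rejected(self):
        with pytest.raises(ConfigError):
            sc.bh_fdr([0.1, 0.2], 1)


class TestTopPerGene:
    def _rec(self, snp_id, gene_id, fdr, p):
        return {"snp_id": snp_id, "gene_id": gene_id, "beta": 1.0, "se": 0.1,
                "t": 10.0, "p": p, "fdr": fdr, "class": "cis", "distance": 0,
                "var_explained": 0.5, "ci95_low": 0.8, "ci95_high": 1.2}

    def test_lowest_fdr_kept(self):
        recs = pd.DataFrame([
            self._rec("1:100", "G1", 0.02, 1e-4),
            self._rec("1:200", "G1", 0.01, 1e-5),
        ])
        top = sc.top_per_gene(recs, 0.05)
        assert top["snp_id"].tolist() == ["1:200"]

    def test_position_tie_break(self):
        recs = pd.DataFrame([
            self._rec("1:200", "G1", 0.01, 1e-5),
            self._rec("1:100", "G1", 0.01, 1e-5),
        ])
        assert sc.top_per_gene(recs, 0.05)["snp_id"].tolist() == ["1:100"]

    def test_non_significant_genes_absent(self):
        recs = pd.DataFrame([self._rec("1:100", "G1", 0.2, 0.01)])
        assert len(sc.top_per_gene(recs, 0.05)) == 0

    def test_one_row_per_gene(self, tiny_cohort):
        cis, _, _ = _scan_tiny(tiny_cohort)
        top = sc.top_per_gene(cis, 0.05)
        assert top["gene_id"].is_unique
        # each kept row has the minimal FDR among its gene's significant rows
        sig = cis[cis["fdr"] <= 0.05]
        for row in top.itertuples(index=False):
            assert row.fdr == sig.loc[sig["gene_id"] == row.gene_id, "fdr"].min()


class TestQqData:
    def test_closed_form_grid(self):
        out = sc.qq_data([0.125, 0.375, 0.625, 0.875])
        assert np.allclose(out["expected_quantile"], out["observed_quantile"])

    def test_uniform_grid_near_diagonal(self):
        m = 200
        out = sc.qq_data((np.arange(1, m + 1)) / m)
        # i/m vs (i-0.5)/m differ most at the smallest p: log10(2) ~ 0.3
        assert np.abs(out["expected_quantile"] - out["observed_quantile"]).max() <= 0.35

    def test_signal_lifts_top_point(self):
        p = np.concatenate([[1e-10], np.linspace(0.05, 1.0, 99)])
        out = sc.qq_data(p)
        top = out["observed_quantile"].idxmax()
        assert out["observed_quantile"][top] > out["expected_quantile"][top] + 5


def _scan_tiny(tiny_cohort, config=None):
    return sc.scan(
        tiny_cohort["latent"], tiny_cohort["dosages"], tiny_cohort["covariates"],
        tiny_cohort["genes"], tiny_cohort["variants"], config or PipelineConfig(),
    )


class TestScan:
    def test_test_count_partition(self, tiny_cohort):
        _, _, counts = _scan_tiny(tiny_cohort)
        n_pairs = len(tiny_cohort["genes"]) * len(tiny_cohort["variants"])
        assert counts["n_cis_tests"] + counts["n_trans_tests"] == n_pairs

    def test_emission_respects_thresholds(self, tiny_cohort):
        cis, trans, _ = _scan_tiny(tiny_cohort)
        assert (cis["p"] < 0.02).all()
        assert (trans["p"] < 1e-6).all()
        assert (cis["class"] == "cis").all() and (trans["class"] == "trans").all()

    def test_fdr_uses_total_class_tests(self, tiny_cohort):
        cis, _, counts = _scan_tiny(tiny_cohort)
        q = sc.bh_fdr(cis["p"].to_numpy(), counts["n_cis_tests"])
        assert np.allclose(cis["fdr"].to_numpy(), q, atol=1e-12)

    def test_planted_cis_effects_are_recovered(self, tiny_cohort):
        cis, _, _ = _scan_tiny(tiny_cohort)
        truth = tiny_cohort["truth"]
        planted = truth[(truth["class"] == "cis") & (truth["mode"] == "additive")]
        sig = cis[cis["fdr"] <= 0.05]
        hits = planted.merge(sig, on=["snp_id", "gene_id"])
        assert len(hits) >= 0.8 * len(planted)
        # recovered betas carry the planted sign
        assert (np.sign(hits["beta_x"]) == np.sign(hits["beta_y"])).all()

    def test_emitted_records_match_per_pair_ols(self, tiny_cohort):
        """Spot-check engine equivalence on the tiny panel: every cis
        record equals a naive per-pair regression with age covariate."""
        import statsmodels.api as sm
        cis, _, _ = _scan_tiny(tiny_cohort)
        samples = list(tiny_cohort["latent"].columns)
        age = tiny_cohort["covariates"].loc[samples, "age"].to_numpy()
        for row in cis.head(25).itertuples(index=False):
            y = tiny_cohort["latent"].loc[row.gene_id, samples].to_numpy(float)
            g = tiny_cohort["dosages"].loc[samples, row.snp_id].to_numpy(float)
            X = sm.add_constant(np.column_stack([g, age]))
            fit = sm.OLS(y, X).fit()
            assert row.beta == pytest.approx(fit.params[1], abs=1e-8)
            assert row.se == pytest.approx(fit.bse[1], abs=1e-8)
            assert row.t == pytest.approx(fit.tvalues[1], abs=1e-8)
            assert row.p == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_missing_genotypes_drop_samples_pairwise(self, tiny_cohort):
        """Punching missing calls into one SNP must reproduce the OLS fit
        on the complete samples only."""
        import statsmodels.api as sm
        cis, _, _ = _scan_tiny(tiny_cohort)
        row = cis.iloc[0]
        dosages = tiny_cohort["dosages"].copy()
        samples = list(tiny_cohort["latent"].columns)
        dosages.loc[samples[:5], row.snp_id] = -1
        cis2, _, _ = sc.scan(
            tiny_cohort["latent"], dosages, tiny_cohort["covariates"],
            tiny_cohort["genes"], tiny_cohort["variants"], PipelineConfig(),
        )
        hit = cis2[(cis2["snp_id"] == row.snp_id) & (cis2["gene_id"] == row.gene_id)]
        assert len(hit) == 1
        keep = samples[5:]
        y = tiny_cohort["latent"].loc[row.gene_id, keep].to_numpy(float)
        g = tiny_cohort["dosages"].loc[keep, row.snp_id].to_numpy(float)
        age = tiny_cohort["covariates"].loc[keep, "age"].to_numpy()
        fit = sm.OLS(y, sm.add_constant(np.column_stack([g, age]))).fit()
        assert hit["beta"].iloc[0] == pytest.approx(fit.params[1], abs=1e-8)
        assert hit["p"].iloc[0] == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_sample_mismatch_raises(self, tiny_cohort):
        cov = tiny_cohort["covariates"].iloc[:-1]
        with pytest.raises(AlignmentError):
            sc.scan(tiny_cohort["latent"], tiny_cohort["dosages"], cov,
                    tiny_cohort["genes"], tiny_cohort["variants"], PipelineConfig())
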