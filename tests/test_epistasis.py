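import numpy as np
import pytest

import hildscan as h
from hildscan.genotypes import MISSING, GenotypeMatrix

import oracle
from conftest import make_random_panel


class TestEncodeAdditive:
    def test_coding(self):
        np.testing.assert_array_equal(h.encode_additive([0, 1]), [1.0, -1.0])

    def test_interaction_code_is_product(self):
        a1 = np.array([1, 1, -1, -1.0])
        a2 = np.array([1, -1, 1, -1.0])
        np.testing.assert_array_equal(a1 * a2, [1, -1, -1, 1.0])

    def test_missing_propagates(self):
        out = h.encode_additive([0, MISSING, 1])
        assert np.isnan(out[1]) and out[0] == 1.0


class TestTwoLocusFit:
    def test_fig1_exact_coefficients(self, fig1):
        G, y, idx = fig1
        fit = h.fit_two_locus_model(y, G.codes[:, idx["M1"]], G.codes[:, idx["M2"]])
        # single causal locus, no interaction in the generative model, yet:
        assert fit.beta1 == pytest.approx(-0.25, abs=1e-12)
        assert fit.beta2 == pytest.approx(-0.25, abs=1e-12)
        assert fit.beta12 == pytest.approx(0.25, abs=1e-12)
        assert fit.p12 < 1e-10  # zero-noise: essentially exact

    def test_exact_additive_phenotype_has_zero_interaction(self):
        g1 = np.array([0, 0, 1, 1] * 5, dtype=np.int8)
        g2 = np.array([0, 1, 0, 1] * 5, dtype=np.int8)
        y = h.encode_additive(g1)
        fit = h.fit_two_locus_model(y, g1, g2)
        assert fit.beta1 == pytest.approx(1.0)
        assert fit.beta2 == pytest.approx(0.0, abs=1e-12)
        assert fit.beta12 == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 50:
            g1 = (rng.random(30) < rng.uniform(0.2, 0.8)).astype(np.int8)
            g2 = (rng.random(30) < rng.uniform(0.2, 0.8)).astype(np.int8)
            y = rng.normal(size=30)
            ref = oracle.ols_two_locus(y, g1, g2)
            if ref is None:
                continue
            fit = h.fit_two_locus_model(y, g1, g2)
            np.testing.assert_allclose([fit.intercept, *fit.betas], ref[0], atol=1e-10)
            np.testing.assert_allclose([fit.se1, fit.se2, fit.se12], ref[1][1:], atol=1e-10)
            np.testing.assert_allclose([fit.p1, fit.p2, fit.p12], ref[2][1:], atol=1e-10)
            checked += 1

    def test_empty_class_flags_aliasing(self):
        g1 = np.array([0, 0, 0, 1, 1, 1], dtype=np.int8)
        g2 = np.array([0, 0, 1, 1, 1, 0], dtype=np.int8)
        # class (0,0) x ... here: classes (0,0),(0,1),(1,1),(1,0) all present -> not aliased
        g2b = np.array([0, 0, 0, 1, 1, 1], dtype=np.int8)  # identical loci: 2 classes only
        fit = h.fit_two_locus_model(np.arange(6.0), g1, g2b)
        assert fit.aliased and np.isnan(fit.p12)
        fit_ok = h.fit_two_locus_model(np.arange(6.0), g1, g2)
        assert not fit_ok.aliased

    def test_allele_relabeling_flips_sign_not_pvalue(self):
        rng = np.random.default_rng(8)
        g1 = (rng.random(40) < 0.5).astype(np.int8)
        g2 = (rng.random(40) < 0.5).astype(np.int8)
        y = rng.normal(size=40)
        a = h.fit_two_locus_model(y, g1, g2)
        b = h.fit_two_locus_model(y, 1 - g1, g2)
        assert b.beta1 == pytest.approx(-a.beta1)
        assert b.beta12 == pytest.approx(-a.beta12)
        assert b.p12 == pytest.approx(a.p12)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="complete"):
            h.fit_two_locus_model(np.ones(4), np.array([0, 1, 0, 1]), np.array([0, 0, 1, 1]))


class TestBonferroni:
    def test_all_pairs_of_1_6m_markers(self):
        thr = h.bonferroni_threshold(0.05, h.n_pairs(1_600_000))
        assert float(f"{thr:.1e}") == pytest.approx(3.9e-14)

    def test_identity_cases(self):
        assert h.bonferroni_threshold(0.05, 1) == 0.05
        assert h.bonferroni_threshold(0.05, 1.5625e8) == pytest.approx(3.2e-10)


class TestScan:
    def test_matches_single_fits(self):
        G = make_random_panel(60, 8, seed=12)
        y = np.random.default_rng(0).normal(size=60)
        res = h.epistasis_scan(y, G, 1.0, keep_all=True)
        for _, row in res.table.iterrows():
            fit = h.fit_two_locus_model(y, G.codes[:, int(row.marker_i)], G.codes[:, int(row.marker_j)])
            assert row.p12 == pytest.approx(fit.p12, abs=1e-10)
            assert row.beta12 == pytest.approx(fit.beta12, abs=1e-10)
        assert res.n_tests == 28

    def test_strong_planted_interaction_ranks_first(self):
        rng = np.random.default_rng(42)
        G = make_random_panel(200, 10, seed=13, maf_low=0.3, maf_high=0.7)
        spec = h.ArchitectureSpec(causal_indices=(2, 7), effects=(0.0, 0.0),
                                  noise_sd=1.0, mode="true_epistasis", interaction_effect=1.0)
        y = h.simulate_phenotype(G, spec, seed=1)
        res = h.epistasis_scan(y.values, G, 1.0, keep_all=True)
        top = res.table.iloc[0]
        assert {int(top.marker_i), int(top.marker_j)} == {2, 7}

    def test_type_one_error_near_nominal(self):
        # FWER at the per-pair Bonferroni level: ~ alpha per replicate
        thr = h.bonferroni_threshold(0.05, h.n_pairs(20))
        hits = 0
        for rep in range(60):
            rng = np.random.default_rng(rep)
            p = rng.uniform(0.1, 0.9, 20)
            codes = (rng.random((200, 20)) < p).astype(np.int8)
            G = GenotypeMatrix(codes, np.array([f"i{k}" for k in range(200)], dtype=object),
                               h.make_marker_map(20, seed=rep))
            y = rng.normal(size=200)
            if len(h.epistasis_scan(y, G, thr).table):
                hits += 1
        # Binomial(60, ~0.05): reject only far outside the nominal rate
        assert hits <= 9

    def test_threshold_one_returns_all_pairs(self):
        G = make_random_panel(30, 5, seed=14)
        y = np.random.default_rng(1).normal(size=30)
        res = h.epistasis_scan(y, G, 1.0, keep_all=True)
        assert len(res.table) + res.n_aliased == 10


class TestKinship:
    def test_duplicated_individuals_share_diagonal(self):
        G = make_random_panel(6, 40, seed=15)
        codes = G.codes.copy()
        codes[5] = codes[0]
        G = GenotypeMatrix(codes, G.individual_ids, G.markers)
        K = h.genomic_kinship(G)
        assert K[0, 5] == pytest.approx(K[0, 0])
        assert K[0, 5] == pytest.approx(K[5, 5])

    def test_symmetric_psd(self):
        K = h.genomic_kinship(make_random_panel(25, 60, seed=16))
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() > -1e-10

    def test_hand_computed_toy(self):
        codes = np.array([[0, 0, 1, 1], [0, 1, 0, 1], [1, 1, 1, 0]], dtype=np.int8)
        G = GenotypeMatrix(codes, np.array(list("abc"), dtype=object),
                           h.make_marker_map(4, seed=0, n_chromosomes=1))
        X = codes.astype(float)
        Z = (X - X.mean(0)) / X.std(0)
        np.testing.assert_allclose(h.genomic_kinship(G), Z @ Z.T / 4, atol=1e-12)


class TestKinshipRefit:
    def test_identity_kinship_recovers_ols(self):
        rng = np.random.default_rng(2)
        g1 = (rng.random(80) < 0.5).astype(np.int8)
        g2 = (rng.random(80) < 0.5).astype(np.int8)
        y = rng.normal(size=80)
        ols = h.fit_two_locus_model(y, g1, g2)
        mm = h.refit_with_kinship(y, g1, g2, np.eye(80))
        np.testing.assert_allclose(mm.betas, ols.betas, atol=1e-6)
        assert mm.corrected

    def test_fixed_zero_variance_is_exact_ols(self):
        rng = np.random.default_rng(4)
        g1 = (rng.random(50) < 0.5).astype(np.int8)
        g2 = (rng.random(50) < 0.5).astype(np.int8)
        y = rng.normal(size=50)
        K = h.genomic_kinship(make_random_panel(50, 30, seed=17))
        ols = h.fit_two_locus_model(y, g1, g2)
        mm = h.refit_with_kinship(y, g1, g2, K, fix_lambda=0.0)
        np.testing.assert_allclose(mm.betas, ols.betas, atol=1e-12)
        assert mm.p12 == pytest.approx(ols.p12, abs=1e-12)

    def test_non_psd_kinship_rejected(self):
        K = -np.eye(10)
        with pytest.raises(ValueError, match="semi-definite"):
            h.refit_with_kinship(np.ones(10), np.array([0, 1] * 5), np.array([0, 0, 1, 1, 0] * 2), K)

    def test_correction_deflates_structure_driven_interaction(self):
        """Polygenic background (h2 = 0.5) in a structured population inflates
        the uncorrected interaction test; the kinship refit removes it."""
        def one(rep):
            rng = np.random.default_rng(1000 + rep)
            k_hap, m, n = 10, 60, 150
            haps = (rng.random((k_hap, m)) < rng.uniform(0.2, 0.8, m)).astype(np.int8)
            freq = rng.dirichlet(np.ones(k_hap))
            codes = haps[rng.choice(k_hap, size=n, p=freq)]
            G = GenotypeMatrix(codes, np.array([f"i{k}" for k in range(n)], dtype=object),
                               h.make_marker_map(m, seed=rep))
            b = rng.normal(0, 1, m - 2)
            g = codes[:, 2:] @ b
            g = (g - g.mean()) / (g.std() + 1e-12)
            y = g + rng.normal(0, 1, n)
            try:
                f0 = h.fit_two_locus_model(y, codes[:, 0], codes[:, 1])
            except ValueError:
                return None
            if f0.aliased:
                return None
            f1 = h.refit_with_kinship(y, codes[:, 0], codes[:, 1], h.genomic_kinship(G))
            return f0.p12, f1.p12

        res = [r for r in (one(i) for i in range(50)) if r is not None]
        assert len(res) >= 15
        assert np.median([r[0] for r in res]) < np.median([r[1] for r in res])


class TestEstimators:
    def test_two_locus_estimator_api(self, fig1):
        G, y, idx = fig1
        X = G.codes[:, [idx["M1"], idx["M2"]]]
        est = h.TwoLocusEpistasis().fit(X, y.values)
        assert est.coef_[2] == pytest.approx(0.25)
        np.testing.assert_allclose(est.predict(X), y.values, atol=1e-12)
        assert est.get_params() == {"kinship": None}

    def test_scan_estimator_two_stage(self, complex_locus):
        G, y, truth = complex_locus
        est = h.EpistasisScan(alpha=0.05).fit(G, y.values)
        assert est.n_tests_ == h.n_pairs(G.n_markers)
        assert len(est.results_) >= 1
        assert {"p12_corrected", "beta12_corrected"} <= set(est.results_.columns)

    def test_explicit_n_tests_mode(self):
        G = make_random_panel(40, 6, seed=18)
        y = np.random.default_rng(3).normal(size=40)
        est = h.EpistasisScan(alpha=0.05, n_tests=10, kinship_refit=False).fit(G, y)
        assert est.threshold_ == pytest.approx(0.005)
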