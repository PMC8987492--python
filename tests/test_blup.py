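import numpy as np
import pytest

from boablup import (BreedOriginBLUP, DesignSet, OriginMap, SNPBlup,
                     VarianceSpec, build_design, filter_markers,
                     make_variance_spec, snp_blup_sigma_a2)

from conftest import make_panel

LABELS = ("AN", "HF")


def _gls_oracle(y, X, Zc, D, se2):
    """Direct generalized-least-squares solve of the joint normal model."""
    V = Zc @ D @ Zc.T + se2 * np.eye(y.size)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    a = D @ Zc.T @ Vi @ (y - X @ beta)
    return beta, a


def _random_origin_design(rng, n, m):
    haps = rng.integers(0, 2, (n, 2, m))
    orig = rng.integers(0, 2, (n, 2, m))
    z = [(haps * (orig == k)).sum(axis=1).astype(float) for k in range(2)]
    x = orig.reshape(n, -1)
    c_hf = (orig == 1).mean(axis=(1, 2))
    X = np.column_stack([1 - c_hf, c_hf])
    y = rng.normal(size=n)
    return y, X, z


class TestDenseOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_origin_model_matches_gls(self, seed):
        """MME solution equals direct inversion of the joint system."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        m = int(rng.integers(1, 6))
        y, X, z = _random_origin_design(rng, n, m)
        rho = float(rng.uniform(-0.5, 0.95))
        v = np.array([0.05, 0.08])
        sigma = np.diag(v) + rho * np.sqrt(np.outer(v, v)) * (1 - np.eye(2))
        vs = VarianceSpec(sigma, 0.7, LABELS)
        d = DesignSet(y, X, z, np.arange(m), LABELS)
        res = BreedOriginBLUP(d, vs).fit(method="dense")
        beta, a = _gls_oracle(y, X, np.concatenate(z, axis=1),
                              np.kron(sigma, np.eye(m)), 0.7)
        assert np.abs(res.beta - beta).max() < 1e-8
        assert np.abs(res.marker_effects.ravel() - a).max() < 1e-8

    @pytest.mark.parametrize("seed", range(4))
    def test_snp_blup_matches_gls(self, seed):
        rng = np.random.default_rng(100 + seed)
        n, m = int(rng.integers(4, 11)), int(rng.integers(1, 6))
        z = rng.integers(0, 3, (n, m)).astype(float)
        y = rng.normal(size=n)
        fit = SNPBlup(y, z, 0.04, 0.7).fit(method="dense")
        beta, a = _gls_oracle(y, np.ones((n, 1)), z, 0.04 * np.eye(m), 0.7)
        assert np.abs(fit.beta - beta).max() < 1e-8
        assert np.abs(fit.marker_effects[0] - a).max() < 1e-8

    def test_cg_solver_agrees_with_dense(self):
        rng = np.random.default_rng(9)
        n, m = 60, 40
        y, X, z = _random_origin_design(rng, n, m)
        vs = VarianceSpec(0.01 * np.array([[1, 0.5], [0.5, 1]]), 0.7, LABELS)
        d = DesignSet(y, X, z, np.arange(m), LABELS)
        dense = BreedOriginBLUP(d, vs).fit(method="dense")
        cg = BreedOriginBLUP(d, vs).fit(method="cg")
        assert np.abs(dense.marker_effects - cg.marker_effects).max() < 1e-6


class TestEquivalences:
    def test_snp_blup_equals_gblup_predictions(self):
        """GEBVs agree with GBLUP using G = Z Z' sigma_a2 (reference and new)."""
        rng = np.random.default_rng(10)
        n, m, sa2, se2 = 12, 6, 0.03, 0.7
        z = rng.integers(0, 3, (n, m)).astype(float)
        z_new = rng.integers(0, 3, (5, m)).astype(float)
        y = rng.normal(size=n)
        fit = SNPBlup(y, z, sa2, se2).fit()
        V = z @ z.T * sa2 + se2 * np.eye(n)
        Vi = np.linalg.inv(V)
        ones = np.ones((n, 1))
        beta = np.linalg.solve(ones.T @ Vi @ ones, ones.T @ Vi @ y)
        resid = y - ones @ beta
        g_ref = (z @ z.T * sa2) @ Vi @ resid
        g_new = (z_new @ z.T * sa2) @ Vi @ resid
        assert np.abs(fit.predict_gebv(z) - g_ref).max() < 1e-8
        assert np.abs(fit.predict_gebv(z_new) - g_new).max() < 1e-8

    def test_infinite_shrinkage_limit(self):
        rng = np.random.default_rng(11)
        z = rng.integers(0, 3, (20, 5)).astype(float)
        y = rng.normal(2.0, 1.0, 20)
        fit = SNPBlup(y, z, 1e-12, 0.7).fit()
        assert np.abs(fit.marker_effects).max() < 1e-6
        assert abs(fit.beta[0] - y.mean()) < 1e-4

    def test_single_group_origin_model_equals_snp_blup(self):
        """K=1 collapses the block structure to standard SNP-BLUP."""
        rng = np.random.default_rng(12)
        n, m = 15, 8
        z = rng.integers(0, 3, (n, m)).astype(float)
        y = rng.normal(size=n)
        vs = VarianceSpec(np.array([[0.02]]), 0.7, ("AN",))
        d = DesignSet(y, np.ones((n, 1)), [z], np.arange(m), ("AN",))
        boa = BreedOriginBLUP(d, vs).fit()
        ref = SNPBlup(y, z, 0.02, 0.7).fit()
        assert np.allclose(boa.marker_effects, ref.marker_effects, atol=1e-10)
        assert np.allclose(boa.beta, ref.beta, atol=1e-10)

    def test_unobserved_group_shrinks_toward_observed(self):
        """With Z_2 = 0, a_hat_2 = (sigma_21 / sigma_1^2) a_hat_1."""
        rng = np.random.default_rng(13)
        n, m, rho = 25, 6, 0.6
        z1 = rng.integers(0, 3, (n, m)).astype(float)
        z2 = np.zeros_like(z1)
        y = rng.normal(size=n)
        sigma = 0.05 * np.array([[1, rho], [rho, 1]])
        d = DesignSet(y, np.ones((n, 1)), [z1, z2], np.arange(m), LABELS)
        res = BreedOriginBLUP(d, VarianceSpec(sigma, 0.7, LABELS)).fit()
        assert np.abs(res.marker_effects[1] - rho * res.marker_effects[0]).max() < 1e-10

    def test_origin_split_to_multibreed_continuity(self):
        """As r -> 1 with equal variances, origin GEBVs approach multi-breed."""
        rng = np.random.default_rng(14)
        n, m, sa2, se2 = 40, 10, 0.02, 0.7
        y, _, z = _random_origin_design(rng, n, m)
        X = np.ones((n, 1))
        base = SNPBlup(y, z[0] + z[1], sa2, se2).fit().predict_gebv(z[0] + z[1])
        devs = []
        for r in (0.9, 0.99, 0.999):
            sigma = sa2 * np.array([[1, r], [r, 1]])
            d = DesignSet(y, X, z, np.arange(m), LABELS)
            res = BreedOriginBLUP(d, VarianceSpec(sigma, se2, LABELS)).fit()
            devs.append(np.abs(res.predict_gebv(z) - base).max())
        assert devs[0] > devs[1] > devs[2]
        assert devs[2] < 1e-2


class TestPredictGebv:
    def test_hand_computed_two_marker_example(self):
        res_effects = np.array([[0.1, -0.2], [0.05, 0.3]])  # (K, M)
        fit = _fake_fit(res_effects)
        gebv = fit.predict_gebv([np.array([[1.0, 0.0]]), np.array([[1.0, 2.0]])])
        assert np.allclose(gebv, [1 * 0.1 + 1 * 0.05 + 2 * 0.3])

    def test_equal_effect_rows_reduce_to_plain_dosage(self):
        rng = np.random.default_rng(15)
        a = rng.normal(size=4)
        fit = _fake_fit(np.vstack([a, a]))
        z1 = rng.integers(0, 2, (6, 4)).astype(float)
        z2 = rng.integers(0, 2, (6, 4)).astype(float)
        assert np.allclose(fit.predict_gebv([z1, z2]), (z1 + z2) @ a)

    def test_gebv_excludes_fixed_effects(self):
        rng = np.random.default_rng(16)
        n, m = 30, 5
        z = rng.integers(0, 3, (n, m)).astype(float)
        y = rng.normal(5.0, 1.0, n)  # large intercept
        fit = SNPBlup(y, z, 0.02, 0.7).fit()
        gebv = fit.predict_gebv(z)
        # marker part only: shifting y by a constant leaves GEBVs unchanged
        fit2 = SNPBlup(y + 100.0, z, 0.02, 0.7).fit()
        assert np.allclose(gebv, fit2.predict_gebv(z), atol=1e-6)

    def test_permutation_symmetry(self):
        rng = np.random.default_rng(17)
        n, m = 20, 6
        y, X, z = _random_origin_design(rng, n, m)
        vs = VarianceSpec(0.02 * np.array([[1, 0.5], [0.5, 1]]), 0.7, LABELS)
        res = BreedOriginBLUP(DesignSet(y, X, z, np.arange(m), LABELS), vs).fit()
        perm = rng.permutation(n)
        zp = [zz[perm] for zz in z]
        res_p = BreedOriginBLUP(
            DesignSet(y[perm], X[perm], zp, np.arange(m), LABELS), vs).fit()
        assert np.allclose(res.marker_effects, res_p.marker_effects, atol=1e-8)
        assert np.allclose(res.predict_gebv(z)[perm], res_p.predict_gebv(zp),
                           atol=1e-8)

    def test_shrinkage_bounds_gebv_variance(self):
        rng = np.random.default_rng(18)
        z = rng.integers(0, 3, (50, 20)).astype(float)
        y = rng.normal(size=50)
        fit = SNPBlup(y, z, 0.01, 0.7).fit()
        assert fit.predict_gebv(z).var() <= y.var()


def _fake_fit(effects):
    from boablup.blup import MMEResults
    k = effects.shape[0]
    return MMEResults(model=None, beta=np.zeros(k), marker_effects=effects,
                      group_labels=LABELS[:k],
                      variance_spec=VarianceSpec(np.eye(k) * 0.1, 0.7, LABELS[:k]),
                      diagnostics={}, model_kind="boa")


class TestDesignConstruction:
    def test_marker_filter_rules(self):
        # 4 markers: low MAF in AN / monomorphic in HF / good / QTL
        an = make_panel(np.zeros((50, 2, 4), np.uint8), breed="AN")
        hf = make_panel(np.zeros((50, 2, 4), np.uint8), breed="HF")
        an.haplotypes[:1, 0, 0] = 1          # MAF 0.01 in AN
        hf.haplotypes[:20, :, 0] = 1
        an.haplotypes[:20, :, 1] = 1         # segregates in AN only
        an.haplotypes[:25, :, 2] = 1         # MAF 0.5 both
        hf.haplotypes[25:, :, 2] = 1
        an.haplotypes[:25, :, 3] = 1
        hf.haplotypes[25:, :, 3] = 1
        mask = filter_markers({"AN": an, "HF": hf}, qtl_indices=[3], maf_min=0.03)
        assert mask.tolist() == [False, False, True, False]
        with pytest.raises(ValueError, match="no markers"):
            filter_markers({"AN": an, "HF": hf}, qtl_indices=[2, 3], maf_min=0.03)

    def test_build_design_indicator_and_partition(self):
        haps = np.zeros((2, 2, 3), np.uint8)
        haps[0, 0, 1] = 1           # ind0 het at marker 1, alt on paternal
        haps[1] = 1                 # ind1 homozygous alt everywhere
        codes = np.zeros((2, 2, 3), np.uint8)
        codes[0, 0] = 1             # ind0 paternal haplotype HF origin
        codes[1] = 1                # ind1 entirely HF (purebred)
        panel = make_panel(haps)
        d = build_design(panel, OriginMap(codes, LABELS), np.zeros(2))
        assert d.Z[0][0, 1] == 0 and d.Z[1][0, 1] == 1
        assert np.allclose(d.X[1], [0.0, 1.0])
        assert np.allclose(d.Z[0][1], 0.0)
        assert np.allclose(d.Z[0] + d.Z[1], panel.dosages())
        assert np.allclose(d.X.sum(axis=1), 1.0)

    def test_variance_spec_structure(self):
        n = 200
        haps = np.zeros((n, 2, 10), np.uint8)
        haps[: n // 2] = 1          # every marker at frequency 0.5
        an = make_panel(haps, breed="AN")
        hf = make_panel(haps.copy(), breed="HF")
        mask = np.ones(10, bool)
        vs = make_variance_spec({"AN": an, "HF": hf}, mask, r=0.75)
        expected = 0.3 / (10 * 2 * 0.25)
        assert np.allclose(np.diag(vs.sigma), expected)
        assert np.allclose(vs.sigma[0, 1], 0.75 * expected)
        assert vs.sigma_e2 == pytest.approx(0.7)
        vs0 = make_variance_spec({"AN": an, "HF": hf}, mask, r=0.0)
        assert vs0.sigma[0, 1] == 0.0

    def test_sigma_a2_closed_form(self):
        n = 100
        haps = np.zeros((n, 2, 1000), np.uint8)
        haps[: n // 2] = 1
        panel = make_panel(haps)
        assert snp_blup_sigma_a2(panel, np.ones(1000, bool), 0.3) == \
            pytest.approx(0.3 / 500.0)

    def test_variance_spec_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            VarianceSpec(np.array([[1.0, 0.5], [0.2, 1.0]]), 0.7, LABELS)
        with pytest.raises(ValueError, match="semidefinite"):
            VarianceSpec(np.array([[1.0, 2.0], [2.0, 1.0]]), 0.7, LABELS)
        with pytest.raises(ValueError, match="sigma_e2"):
            VarianceSpec(np.eye(2), 0.0, LABELS)
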