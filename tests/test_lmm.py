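"""LMM core: covariance structures, oracle equivalence, gradients, fitting
and sampling."""

import numpy as np
import pytest
from scipy import stats

from gxcset import (
    FittedModel,
    KroneckerSetLMM,
    RegionGenotypes,
    StudyDesign,
    TraitContextCovariance,
    dense_oracle,
    fit,
    materialize,
    reml_objective,
    sample_phenotypes,
)
from gxcset.lmm import _NoiseCov, n_params

KINDS = ("null", "block", "rank1", "full")


def _random_instance(rng, layout, n=9, s=3, k=2, c=2):
    G = rng.standard_normal((n, s))
    G = (G - G.mean(0)) / G.std(0)
    region = RegionGenotypes(G)
    F = np.column_stack([np.ones(n), rng.standard_normal((n, k - 1))]) if k else None
    if layout == "complete":
        design = StudyDesign(layout="complete", Y=rng.standard_normal((n, c)), F=F)
    else:
        ctx = rng.integers(0, c, n)
        while np.bincount(ctx, minlength=c).min() < 2:
            ctx = rng.integers(0, c, n)
        design = StudyDesign(
            layout="stratified", y=rng.standard_normal(n), contexts=ctx, F=F, n_contexts=c
        )
    return design, region


class TestMaterialize:
    def test_block_zero(self):
        cov = TraitContextCovariance("block", 2)
        assert np.array_equal(materialize(cov, [0.0]), np.zeros((2, 2)))

    def test_rank1_ones(self):
        cov = TraitContextCovariance("rank1", 2)
        assert np.array_equal(materialize(cov, [1.0, 1.0]), np.ones((2, 2)))

    def test_full_identity(self):
        cov = TraitContextCovariance("full", 2)
        # lower-triangular order: A11, A21, A22
        assert np.array_equal(materialize(cov, [1.0, 0.0, 1.0]), np.eye(2))

    def test_wrong_length_raises(self):
        cov = TraitContextCovariance("rank1", 2)
        with pytest.raises(ValueError):
            materialize(cov, [1.0])

    @pytest.mark.parametrize("kind", KINDS)
    @pytest.mark.parametrize("c", [2, 3])
    def test_psd_for_random_parameters(self, kind, c):
        rng = np.random.default_rng(5)
        cov = TraitContextCovariance(kind, c)
        for _ in range(20):
            M = materialize(cov, rng.standard_normal(cov.n_free) * 2)
            vals = np.linalg.eigvalsh(M)
            assert vals.min() >= -1e-10
        assert cov.n_free == {"null": 0, "block": 1, "rank1": c, "full": c * (c + 1) // 2}[kind]


class TestObjective:
    def test_standard_normal_density_at_zero(self):
        # Cs = 0, Cn = I, no covariates, Y = 0 -> ll = -N*C/2 * log(2*pi)
        region = RegionGenotypes(np.array([[1.0, -1], [-1, 1], [0, 0]]) + 1e-9)
        G = np.random.default_rng(0).standard_normal((3, 2))
        G = (G - G.mean(0)) / G.std(0)
        region = RegionGenotypes(G)
        design = StudyDesign(layout="complete", Y=np.zeros((3, 2)), F=None)
        nll = reml_objective(design, region, "null", [], [0.0, 0.0, 0.0])
        assert np.isclose(-nll, -0.5 * 6 * np.log(2 * np.pi))

    @pytest.mark.parametrize("layout", ["complete", "stratified"])
    def test_oracle_equivalence_random_instances(self, layout):
        # 50 random small instances across all four covariance kinds
        rng = np.random.default_rng(17)
        for trial in range(50):
            design, region = _random_instance(rng, layout, n=7 + trial % 4)
            kind = KINDS[trial % 4]
            ts = rng.standard_normal(n_params(kind, 2))
            nn = 3 if layout == "complete" else 2
            tn = 0.4 * rng.standard_normal(nn)
            a = reml_objective(design, region, kind, ts, tn)
            b = dense_oracle(design, region, kind, ts, tn)
            assert abs(a - b) < 1e-8

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        design, region = _random_instance(rng, "complete", n=10)
        ts, tn = np.array([0.5, 0.2]), np.array([0.1, 0.0, 0.1])
        v1 = dense_oracle(design, region, "rank1", ts, tn)
        perm = rng.permutation(10)
        design_p = StudyDesign(layout="complete", Y=design.Y[perm], F=design.F[perm])
        region_p = RegionGenotypes(region.G[perm])
        v2 = dense_oracle(design_p, region_p, "rank1", ts, tn)
        assert abs(v1 - v2) < 1e-9

    def test_gaussian_scaling_identity(self):
        # scaling Y by 2 and (Cs, Cn) by 4 shifts the restricted log-likelihood
        # by the Jacobian term (n - p) * log 2
        rng = np.random.default_rng(4)
        design, region = _random_instance(rng, "complete", n=8, k=2)
        a = np.array([0.5, 0.3])
        tn = np.array([0.2, 0.1, -0.1])
        L = _NoiseCov(2).factor(tn)
        tn2 = tn.copy()
        tn2[[0, 2]] += np.log(2.0)  # diagonal is exponentiated
        tn2[1] *= 2.0
        v1 = dense_oracle(design, region, "rank1", a, tn)
        design2 = StudyDesign(layout="complete", Y=2 * design.Y, F=design.F)
        v2 = dense_oracle(design2, region, "rank1", 2 * a, tn2)
        n, p = 16, 4
        assert np.isclose(v2 - v1, (n - p) * np.log(2.0), atol=1e-8)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(6)
        design, region = _random_instance(rng, "complete", n=12, s=4)
        for kind in ("block", "rank1", "full"):
            ks = n_params(kind, 2)
            th = 0.5 * rng.standard_normal(ks + 3)

            def f(t):
                return reml_objective(design, region, kind, t[:ks], t[ks:])

            _, g = reml_objective(
                design, region, kind, th[:ks], th[ks:], with_grad=True
            )
            gfd = np.array(
                [
                    (f(th + 1e-5 * e) - f(th - 1e-5 * e)) / 2e-5
                    for e in np.eye(th.size)
                ]
            )
            np.testing.assert_allclose(g, gfd, rtol=1e-4, atol=1e-6)

    def test_stratified_off_diagonal_cn_never_enters(self):
        # the stratified likelihood only reads diag(Cn): perturbing
        # off-diagonals of the materialized matrix leaves it unchanged
        rng = np.random.default_rng(7)
        design, region = _random_instance(rng, "stratified", n=12)
        from gxcset.lmm import _StratifiedWorkspace

        ws = _StratifiedWorkspace(design, region)
        Cs = np.array([[0.5, 0.2], [0.2, 0.4]])
        Cn = np.diag([1.0, 1.5])
        v1 = ws.nll(Cs, Cn)
        Cn_off = Cn.copy()
        Cn_off[0, 1] = Cn_off[1, 0] = 0.7
        v2 = ws.nll(Cs, Cn_off)
        assert v1 == v2

    def test_dense_oracle_size_guard(self):
        rng = np.random.default_rng(8)
        G = rng.standard_normal((300, 2))
        G = (G - G.mean(0)) / G.std(0)
        region = RegionGenotypes(G)
        design = StudyDesign(layout="complete", Y=rng.standard_normal((300, 2)), F=None)
        with pytest.raises(ValueError, match="dense oracle"):
            dense_oracle(design, region, "null", [], [0.0, 0.0, 0.0])

    def test_non_finite_theta_raises(self):
        rng = np.random.default_rng(9)
        design, region = _random_instance(rng, "complete")
        with pytest.raises(ValueError):
            reml_objective(design, region, "block", [np.nan], [0.0, 0.0, 0.0])


class TestFit:
    def test_block_parameter_recovery(self, region_factory):
        region = region_factory(n=2000, s=100, seed=10)
        truth = FittedModel(
            "block", 0.5 * np.ones((2, 2)), np.eye(2), np.zeros((0, 2)),
            0.0, True, 0, 0, None, None,
        )
        design0 = StudyDesign(layout="complete", Y=np.zeros((2000, 2)), F=None)
        Y = sample_phenotypes(truth, design0, region, seed=11)
        design = StudyDesign(layout="complete", Y=Y, F=np.ones((2000, 1)))
        m = fit(design, region, cov_kind="block", seed=0)
        assert m.converged
        assert abs(m.Cs[0, 0] - 0.5) < 0.1

    def test_recovery_error_decreases_with_sample_size(self, region_factory):
        # Frobenius error of the fitted full Cs shrinks from N=200 to N=2000
        Cs_true = np.array([[0.4, 0.1], [0.1, 0.3]])
        errs = {}
        for n in (200, 2000):
            per = []
            for rep in range(3):
                region = region_factory(n=n, s=20, seed=100 + rep)
                truth = FittedModel(
                    "full", Cs_true, np.eye(2), np.zeros((0, 2)), 0.0, True, 0, 0, None, None
                )
                d0 = StudyDesign(layout="complete", Y=np.zeros((n, 2)), F=None)
                Y = sample_phenotypes(truth, d0, region, seed=200 + rep)
                design = StudyDesign(layout="complete", Y=Y, F=np.ones((n, 1)))
                m = fit(design, region, cov_kind="full", seed=rep)
                per.append(np.linalg.norm(m.Cs - Cs_true))
            errs[n] = np.mean(per)
        assert errs[2000] < errs[200]

    def test_pure_noise_trace_bound(self, region_factory):
        region = region_factory(n=300, s=15, seed=12)
        rng = np.random.default_rng(13)
        Y = rng.standard_normal((300, 2))
        design = StudyDesign(layout="complete", Y=Y, F=np.ones((300, 1)))
        m = fit(design, region, cov_kind="full", seed=0)
        assert np.trace(m.Cs) <= np.trace(np.cov(Y.T)) + 1e-6

    def test_nested_model_loglik_monotone(self, region_500, persistent_design):
        lls = [
            fit(persistent_design, region_500, cov_kind=k, seed=0).reml
            for k in ("null", "block", "rank1", "full")
        ]
        for lo, hi in zip(lls, lls[1:]):
            assert hi >= lo - 1e-6

    def test_stratified_fit_runs(self, region_factory):
        rng = np.random.default_rng(14)
        region = region_factory(n=400, s=15, seed=15)
        ctx = rng.integers(0, 2, 400)
        u = region.G[:, 2] * 0.5
        y = u * np.where(ctx == 0, 1.0, -1.0) + rng.standard_normal(400)
        design = StudyDesign(
            layout="stratified", y=y, contexts=ctx, F=np.ones((400, 1)), n_contexts=2
        )
        m = fit(design, region, cov_kind="full", seed=0)
        assert m.converged
        assert m.Cn.shape == (2, 2)
        assert np.all(np.diag(m.Cn) > 0)


class TestSampling:
    def test_iid_standard_normal_when_cs_zero(self, region_factory):
        region = region_factory(n=10_000, s=5, seed=16)
        m = FittedModel(
            "null", np.zeros((2, 2)), np.eye(2), np.zeros((0, 2)), 0.0, True, 0, 0, None, None
        )
        design = StudyDesign(layout="complete", Y=np.zeros((10_000, 2)), F=None)
        Y = sample_phenotypes(m, design, region, seed=17)
        stat, p = stats.kstest(Y.ravel(), "norm")
        assert p > 0.01

    def test_covariance_matches_closed_form(self, region_factory):
        region = region_factory(n=4, s=3, seed=18)
        Cs = np.array([[0.5, 0.25], [0.25, 0.5]])
        Cn = np.array([[1.0, 0.3], [0.3, 1.0]])
        m = FittedModel("full", Cs, Cn, np.zeros((0, 2)), 0.0, True, 0, 0, None, None)
        design = StudyDesign(layout="complete", Y=np.zeros((4, 2)), F=None)
        draws = np.array(
            [
                sample_phenotypes(m, design, region, seed=s).T.ravel()
                for s in range(5000)
            ]
        )
        emp = np.cov(draws.T)
        V = np.kron(Cs, region.Rs) + np.kron(Cn, np.eye(4))
        np.testing.assert_allclose(emp, V, atol=0.1)

    def test_mean_is_fixed_effect_prediction(self, region_factory):
        region = region_factory(n=50, s=4, seed=19)
        B = np.array([[2.0, -1.0]])
        F = np.ones((50, 1))
        m = FittedModel("null", np.zeros((2, 2)), 0.01 * np.eye(2), B, 0.0, True, 0, 0, None, None)
        design = StudyDesign(layout="complete", Y=np.zeros((50, 2)), F=F)
        draws = np.mean(
            [sample_phenotypes(m, design, region, seed=s) for s in range(400)], axis=0
        )
        np.testing.assert_allclose(draws, F @ B, atol=0.05)

    def test_deterministic_given_seed(self, region_factory):
        region = region_factory(n=20, s=4, seed=20)
        m = FittedModel(
            "block", 0.2 * np.ones((2, 2)), np.eye(2), np.zeros((0, 2)), 0.0, True, 0, 0, None, None
        )
        design = StudyDesign(layout="complete", Y=np.zeros((20, 2)), F=None)
        a = sample_phenotypes(m, design, region, seed=21)
        b = sample_phenotypes(m, design, region, seed=21)
        np.testing.assert_array_equal(a, b)


class TestEstimatorFacade:
    def test_sklearn_params_and_fitted_attributes(self, region_500, persistent_design):
        est = KroneckerSetLMM(cov_kind="block", restarts=2, random_state=1)
        assert est.get_params()["cov_kind"] == "block"
        est.set_params(cov_kind="full")
        est.fit(region_500.G, persistent_design.Y, F=persistent_design.F)
        assert est.Cs_.shape == (2, 2)
        assert np.isfinite(est.reml_)
        assert est.converged_

    def test_scaling_in_sub_quadratic_time(self, region_factory):
        # per-evaluation cost grows sub-quadratically in N at fixed S
        import time

        from gxcset.lmm import _CompleteWorkspace

        times = {}
        for n in (500, 4000):
            region = region_factory(n=n, s=20, seed=22)
            rng = np.random.default_rng(23)
            design = StudyDesign(
                layout="complete", Y=rng.standard_normal((n, 2)), F=np.ones((n, 1))
            )
            ws = _CompleteWorkspace(design, region)
            reml_objective(design, region, "full", [0.3, 0.1, 0.2], [0.0, 0.1, 0.0], workspace=ws)
            t0 = time.perf_counter()
            for _ in range(30):
                reml_objective(
                    design, region, "full", [0.3, 0.1, 0.2], [0.0, 0.1, 0.0], workspace=ws
                )
            times[n] = time.perf_counter() - t0
        assert times[4000] / times[500] < 8 * 8 * 0.9  # well below quadratic
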