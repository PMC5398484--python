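"""Set tests: LLR properties, null generation, empirical p-values and the
single-variant baseline."""

import numpy as np
import pytest
from scipy import stats

from gxcset import (
    InteractionSetTest,
    NullPool,
    RegionTestResult,
    SimulationConfig,
    StudyDesign,
    classify_architecture,
    draw_null_llrs,
    effective_tests,
    heterogeneity_baseline_score,
    pool_and_pvalues,
    simulate_illustration_region,
    simulate_independent_genotypes,
    simulate_phenotypes,
    single_variant_interaction_scan,
    standardize_region,
)
from gxcset.settest import test_region as run_region_tests


def _toy_result(region_id, llrs):
    return RegionTestResult(region_id=region_id, models={}, llr=llrs, converged=True)


class TestRegionTest:
    def test_llrs_nonnegative_and_reported(self, persistent_design, region_500):
        res = run_region_tests(persistent_design, region_500, restarts=2, seed=0)
        assert set(res.llr) == {"assoc", "inter", "het"}
        assert all(v >= 0 for v in res.llr.values())

    def test_boundary_mass_under_persistent_effects(
        self, region_500, background_cohort, covariates_500
    ):
        # PSD constraints put positive probability mass at exactly-zero LLRs
        # when only persistent effects are simulated (the QQ-plot step):
        # the rank-one null then attains the full-model optimum
        zeros = 0
        inter_vals = []
        for rep in range(12):
            b = simulate_phenotypes(
                SimulationConfig(seed=3000 + rep), region_500, background_cohort
            )
            d = StudyDesign(layout="complete", Y=b.Y, F=covariates_500)
            res = run_region_tests(d, region_500, restarts=2, seed=rep)
            zeros += res.llr["het"] < 1e-9
            inter_vals.append(res.llr["inter"])
        assert zeros >= 1
        # interaction LLRs stay near the boundary (no signal to detect)
        assert np.median(inter_vals) < 5.0

    def test_strong_rescaling_dominates_persistent_null(
        self, region_500, background_cohort, covariates_500
    ):
        # eta = -1 (opposite effects) at v_r = 0.1 gives interaction LLRs far
        # above anything seen under persistent-only simulations
        per, res_llrs = [], []
        for rep in range(12):
            bp = simulate_phenotypes(
                SimulationConfig(seed=4000 + rep), region_500, background_cohort
            )
            d = StudyDesign(layout="complete", Y=bp.Y, F=covariates_500)
            per.append(
                run_region_tests(d, region_500, restarts=2, seed=rep, tests=("inter",)).llr["inter"]
            )
            br = simulate_phenotypes(
                SimulationConfig(
                    architecture="rescaling", proportionality=-1.0,
                    region_variance=0.1, seed=5000 + rep,
                ),
                region_500,
                background_cohort,
            )
            dr = StudyDesign(layout="complete", Y=br.Y, F=covariates_500)
            res_llrs.append(
                run_region_tests(dr, region_500, restarts=2, seed=rep, tests=("inter",)).llr["inter"]
            )
        thresh = max(per)
        assert np.mean(np.array(res_llrs) > thresh) >= 0.9

    def test_heterogeneity_locus_has_largest_het_llr(self):
        # three-locus illustration: the heterogeneity locus wins the
        # heterogeneity test in the majority of replicates
        wins = 0
        n_rep = 5
        for rep in range(n_rep):
            b = simulate_illustration_region(seed=600 + rep)
            llrs = []
            for reg in b.extras["locus_regions"]:
                d = StudyDesign(layout="complete", Y=b.Y, F=np.ones((b.n_individuals, 1)))
                llrs.append(
                    run_region_tests(d, reg, restarts=2, seed=rep, tests=("het",)).llr["het"]
                )
            wins += int(np.argmax(llrs) == 2)
        assert wins > n_rep / 2


class TestNullDraws:
    def test_counts_and_phenotypes_untouched(self, persistent_design, region_500):
        Y_before = persistent_design.Y.copy()
        nulls = draw_null_llrs(persistent_design, region_500, J=4, seed=1, restarts=1)
        assert all(v.shape == (4,) for v in nulls.values())
        assert all(np.all(v >= 0) for v in nulls.values())
        np.testing.assert_array_equal(persistent_design.Y, Y_before)

    def test_deterministic_given_seed(self, persistent_design, region_500):
        a = draw_null_llrs(persistent_design, region_500, J=3, seed=5, restarts=1, tests=("inter",))
        b = draw_null_llrs(persistent_design, region_500, J=3, seed=5, restarts=1, tests=("inter",))
        np.testing.assert_array_equal(a["inter"], b["inter"])

    def test_j_must_be_positive(self, persistent_design, region_500):
        with pytest.raises(ValueError):
            draw_null_llrs(persistent_design, region_500, J=0, seed=0)

    def test_observed_rank_uniform_within_null_pools(
        self, background_cohort, covariates_500, region_500
    ):
        # self-consistency of the parametric bootstrap: under a persistent
        # simulation the observed interaction LLR is exchangeable with its
        # own bootstrap nulls, so its rank is uniform
        J = 7
        ranks = []
        for rep in range(36):
            b = simulate_phenotypes(
                SimulationConfig(seed=7000 + rep), region_500, background_cohort
            )
            d = StudyDesign(layout="complete", Y=b.Y, F=covariates_500)
            res = run_region_tests(d, region_500, restarts=1, seed=rep, tests=("inter",))
            nulls = draw_null_llrs(
                d, region_500, J=J, seed=rep, restarts=1, result=res, tests=("inter",)
            )
            # ties (boundary zeros) broken at random for exchangeability
            rng = np.random.default_rng(rep)
            obs = res.llr["inter"] + 1e-9 * rng.random()
            pool = nulls["inter"] + 1e-9 * rng.random(J)
            ranks.append(int(np.sum(pool < obs)))
        counts = np.bincount(ranks, minlength=J + 1)
        chi2 = ((counts - len(ranks) / (J + 1)) ** 2 / (len(ranks) / (J + 1))).sum()
        # chi-square uniformity at alpha = 0.01 with J+1 bins
        assert chi2 < stats.chi2.ppf(0.99, df=J)


class TestPooledPValues:
    def test_p_formula_exact_on_toy_pool(self):
        results = [_toy_result(f"r{i}", {"inter": float(i)}) for i in range(5)]
        nulls = NullPool(
            llrs={"inter": np.arange(20.0).reshape(5, 4)},
            region_ids=[f"r{i}" for i in range(5)],
            seeds=[0] * 5,
        )
        pv = pool_and_pvalues(results, nulls)
        # observed i has 20 - i nulls >= it (ties count)
        expected = (1.0 + 20 - np.arange(5)) / 21.0
        np.testing.assert_allclose(pv.p["inter"], expected)
        assert np.all(pv.q["inter"] >= pv.p["inter"] - 1e-15)

    def test_floor_and_ceiling(self):
        results = [_toy_result("a", {"het": 100.0}), _toy_result("b", {"het": 0.0})]
        nulls = NullPool(
            llrs={"het": np.arange(1.0, 9.0).reshape(2, 4)},
            region_ids=["a", "b"],
            seeds=[0, 0],
        )
        pv = pool_and_pvalues(results, nulls)
        assert pv.p["het"][0] == 1.0 / 9.0  # 1/(J*T + 1) floor
        assert pv.p["het"][1] == 1.0  # below every null

    def test_empty_pool_raises(self):
        results = [_toy_result("a", {"inter": 1.0})]
        nulls = NullPool(llrs={"inter": np.empty((0, 0))}, region_ids=[], seeds=[])
        with pytest.raises(ValueError):
            pool_and_pvalues(results, nulls)


class TestSingleVariantBaseline:
    def test_causal_variant_attains_min_interaction_p(self):
        # LD-free region, one context-exclusive causal variant
        hits = 0
        for rep in range(10):
            dm = simulate_independent_genotypes(1000, [0.3] * 30, seed=800 + rep)
            region = standardize_region(dm, maf_min=0.0)
            cfg = SimulationConfig(
                architecture="rescaling", proportionality=0.0, n_causal=1,
                region_variance=0.05, seed=900 + rep,
            )
            b = simulate_phenotypes(cfg, region, np.eye(1000) * 0.0 + np.eye(1000))
            d = StudyDesign(layout="complete", Y=b.Y, F=np.ones((1000, 1)))
            res = single_variant_interaction_scan(d, region)
            causal = b.causal_indices[0][0]
            hits += int(res["lead_variant"] == causal)
        assert hits >= 9

    def test_interaction_p_uniform_under_persistent_effects(self):
        pvals = []
        for rep in range(40):
            dm = simulate_independent_genotypes(500, [0.3] * 50, seed=850 + rep)
            region = standardize_region(dm, maf_min=0.0)
            b = simulate_phenotypes(
                SimulationConfig(seed=950 + rep), region, np.eye(500)
            )
            d = StudyDesign(layout="complete", Y=b.Y, F=np.ones((500, 1)))
            res = single_variant_interaction_scan(d, region)
            pvals.extend(res["p_interaction"])
        stat, p = stats.kstest(np.asarray(pvals), "uniform")
        assert p > 0.01

    def test_bonferroni_adjustment_exact(self, persistent_design, region_500):
        res = single_variant_interaction_scan(persistent_design, region_500)
        S = region_500.n_variants
        assert res["region_p"] == min(1.0, S * np.nanmin(res["p_interaction"]))


class TestEffectiveTests:
    def test_orthogonal_columns_full_count(self):
        from gxcset import RegionGenotypes

        n = 64
        H = np.linalg.qr(np.random.default_rng(1).standard_normal((n, 10)))[0]
        G = (H - H.mean(0)) / H.std(0)
        region = RegionGenotypes(G)
        assert effective_tests(region) == 10

    def test_duplicated_column_reduces_count(self, region_factory):
        region = region_factory(n=100, s=10, seed=2)
        from gxcset import RegionGenotypes

        G = np.column_stack([region.G, region.G[:, 0]])
        dup = RegionGenotypes(G)
        assert effective_tests(dup) < 11

    def test_identical_columns_collapse_to_one(self):
        from gxcset import RegionGenotypes

        g = np.random.default_rng(3).standard_normal(50)
        g = (g - g.mean()) / g.std()
        region = RegionGenotypes(np.tile(g[:, None], (1, 8)))
        assert effective_tests(region) == 1


class TestLeadVariantRules:
    def test_baseline_score_cases(self):
        assert heterogeneity_baseline_score((True, True), 1.0) == 0.0
        assert heterogeneity_baseline_score((True, True), 0.19) == pytest.approx(0.81)
        assert heterogeneity_baseline_score((True, False), 0.0) == 0.0

    def test_classification_rules(self):
        assert classify_architecture((True, True), 0.1)["label"] == "distinct-leads"
        shared = classify_architecture((True, True), 0.9, effect_signs=(1.0, -2.0))
        assert shared["label"] == "shared-lead"
        assert shared["direction"] == "opposite-direction"
        same = classify_architecture((True, True), 0.95, effect_signs=(0.5, 2.0))
        assert same["direction"] == "same-direction"
        assert classify_architecture((True, True), 0.5)["label"] == "unresolved"
        assert classify_architecture((True, False), 0.9)["label"] == "unresolved"
        assert classify_architecture((True, True), None)["label"] == "unresolved"

    def test_secondary_sublabels(self):
        r = classify_architecture(
            (True, True), 0.9, effect_signs=(1, 1), secondary_significant=(True, False)
        )
        assert r["sublabel"] == "context-specific-secondary"
        r2 = classify_architecture(
            (True, True), 0.9, effect_signs=(1, 1),
            secondary_significant=(True, True), secondary_r2=0.1,
        )
        assert r2["sublabel"] == "context-specific-secondary"
        r3 = classify_architecture(
            (True, True), 0.9, effect_signs=(1, 1),
            secondary_significant=(True, True), secondary_r2=0.9,
        )
        assert r3["sublabel"] == "none"


class TestInteractionSetTestFacade:
    def test_fit_and_null_llrs(self, region_500, persistent_design):
        est = InteractionSetTest(restarts=1, random_state=0)
        est.fit(region_500.G, persistent_design.Y, F=persistent_design.F)
        assert est.llr_assoc_ >= 0
        assert est.llr_inter_ >= 0
        assert est.llr_het_ >= 0
        nulls = est.null_llrs(J=2, seed=3)
        assert set(nulls) == {"assoc", "inter", "het"}
        assert est.get_params() == {"restarts": 1, "random_state": 0}
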