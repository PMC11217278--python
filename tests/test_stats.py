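import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from subparc import stats as st
from subparc import synthio
from subparc.errors import ConfigError, StatsPreconditionError


def make_cohort(n_per_group, seed=0):
    return synthio.generate_cohort(
        synthio.CohortSpec(n_per_group=n_per_group, seed=seed))


class TestLeveneGate:
    def test_constant_groups(self):
        route, stat, p = st.levene_gate([np.ones(5), np.ones(6) * 2.0])
        assert (route, stat, p) == ("parametric", 0.0, 1.0)

    def test_constructed_heteroscedasticity(self, rng):
        a = rng.standard_normal(50)
        b = rng.standard_normal(50) * 10.0
        route, _, p = st.levene_gate([a, b])
        assert route == "nonparametric" and p < 0.05

    def test_equal_variance_calibration(self):
        # equal-SD groups, n=200: parametric route in >= 90% of 100 seeds
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            groups = [rng.standard_normal(200) for _ in range(3)]
            route, _, _ = st.levene_gate(groups)
            hits += route == "parametric"
        assert hits >= 90

    def test_small_group_rejected(self):
        with pytest.raises(StatsPreconditionError):
            st.levene_gate([np.ones(1), np.ones(5)])

    def test_vectorised_matches_scipy(self, rng):
        Y = rng.standard_normal((60, 30))
        gidx = np.repeat([0, 1, 2], 20)
        _, W, p = st.levene_routes(Y, gidx)
        for j in range(30):
            w_ref, p_ref = sps.levene(
                *[Y[gidx == g, j] for g in range(3)], center="median")
            assert W[j] == pytest.approx(w_ref, rel=1e-10)
            assert p[j] == pytest.approx(p_ref, rel=1e-10)


class TestAncova:
    def test_reduces_to_oneway_anova_without_covariates(self, rng):
        y = rng.standard_normal(60)
        group = pd.Series(np.repeat(["A", "B", "C"], 20))
        res = st.ancova_group(y, group, covariates=None)
        f_ref, p_ref = sps.f_oneway(y[:20], y[20:40], y[40:])
        assert res.statistic == pytest.approx(f_ref, abs=1e-8)
        assert res.p == pytest.approx(p_ref, abs=1e-8)

    def test_type_one_calibration(self):
        # null Group effect, n=50/group, 1000 replicate features:
        # rejection at alpha=.05 within [0.037, 0.063]; p uniform
        rng = np.random.default_rng(12)
        n = 150
        cohort = pd.DataFrame({
            "group": np.repeat(["A", "B", "C"], 50),
            "age": rng.uniform(50, 80, n),
            "sex": rng.choice(["M", "F"], n),
        })
        Y = rng.standard_normal((n, 1000)) + 0.05 * cohort["age"].to_numpy()[:, None]
        Xr = st._encode_covariates(cohort, ["age", "sex"])
        G, _ = st._group_dummies(cohort["group"])
        _, p, _, _, _ = st.ancova_f_many(Y, Xr, G)
        rate = float(np.mean(p < 0.05))
        assert 0.037 <= rate <= 0.063
        assert sps.kstest(p, "uniform").pvalue > 0.01

    def test_power_construction(self, rng):
        n = 60
        group = pd.Series(np.repeat(["A", "B", "C"], 20))
        y = rng.standard_normal(n)
        y[group == "B"] += 3.0
        cov = pd.DataFrame({"age": rng.uniform(50, 80, n),
                            "sex": rng.choice(["M", "F"], n)})
        res = st.ancova_group(y, group, cov)
        assert res.p < 1e-6
        assert res.eta_sq_p > 0.3

    def test_pairwise_contrasts_present(self, rng):
        y = rng.standard_normal(45)
        group = pd.Series(np.repeat(["HC", "ePD", "iRBD"], 15))
        res = st.ancova_group(y, group)
        assert len(res.pairwise) == 3
        pair = res.pairwise[0]
        assert pair.df == 28  # n1 + n2 - 2, as printed

    def test_rank_deficiency_names_columns(self):
        cohort = pd.DataFrame({
            "group": ["A"] * 10 + ["B"] * 10,
            "age": np.r_[np.ones(10), np.zeros(10)],  # aliased with group
            "site": ["s1"] * 10 + ["s2"] * 10,
        })
        y = np.arange(20, dtype=float)
        with pytest.raises(StatsPreconditionError, match="aliased"):
            st.ancova_group(y, cohort["group"], cohort,
                            covariate_names=("age", "site"))

    def test_eta_squared_in_unit_interval(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            y = r.standard_normal(30)
            group = pd.Series(np.repeat(["A", "B", "C"], 10))
            res = st.ancova_group(y, group)
            assert 0.0 <= res.eta_sq_p <= 1.0


class TestKruskalDunn:
    def test_hand_computed_example(self):
        # ranks 1..9 in three blocks: H = 7.2, p = chi2.sf(7.2, 2) ~ 0.027
        res = st.kruskal_dunn({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        assert res.statistic == pytest.approx(7.2, abs=1e-10)
        assert res.p == pytest.approx(0.0273, abs=5e-4)

    def test_identical_groups(self):
        res = st.kruskal_dunn({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert res.statistic == 0.0 and res.p == 1.0

    def test_matches_independent_reference(self, rng):
        # oracle: second from-scratch rank implementation with tie correction
        for _ in range(25):
            sizes = rng.integers(5, 15, size=3)
            data = [np.round(rng.standard_normal(s), 1) for s in sizes]
            res = st.kruskal_dunn({f"g{i}": d for i, d in enumerate(data)})
            pooled = np.concatenate(data)
            N = len(pooled)
            ranks = sps.rankdata(pooled)
            bounds = np.cumsum([0, *sizes])
            rbar = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(3)]
            h = 12.0 / (N * (N + 1)) * sum(
                sizes[i] * rbar[i] ** 2 for i in range(3)) - 3 * (N + 1)
            _, cnt = np.unique(pooled, return_counts=True)
            h /= 1.0 - ((cnt**3 - cnt).sum()) / (N**3 - N)
            assert res.statistic == pytest.approx(h, abs=1e-10)
            var = N * (N + 1) / 12.0 - ((cnt**3 - cnt).sum()) / (12 * (N - 1))
            for pw, (i, j) in zip(res.pairwise, itertools.combinations(range(3), 2)):
                z = (rbar[i] - rbar[j]) / np.sqrt(var * (1 / sizes[i] + 1 / sizes[j]))
                assert pw.statistic == pytest.approx(z, abs=1e-10)

    def test_rank_invariance_monotone_transform(self, rng):
        data = {f"g{i}": rng.standard_normal(12) for i in range(3)}
        res_a = st.kruskal_dunn(data)
        res_b = st.kruskal_dunn({k: np.exp(3 * v) for k, v in data.items()})
        assert res_a.statistic == pytest.approx(res_b.statistic, rel=1e-12)
        for pa, pb in zip(res_a.pairwise, res_b.pairwise):
            assert pa.statistic == pytest.approx(pb.statistic, rel=1e-12)


class TestAdjustPvalues:
    def test_bonferroni_arithmetic(self):
        assert st.adjust_pvalues([0.0004], "bonferroni", 96)[0] == pytest.approx(0.0384)

    def test_p_one_stays_one(self):
        assert st.adjust_pvalues([1.0], "bonferroni", 96)[0] == 1.0
        assert st.adjust_pvalues([1.0], "benjamini-hochberg", 96)[0] == 1.0

    def test_bh_superset_and_bruteforce(self, rng):
        # oracle: definition-based adjusted p for both methods
        for _ in range(30):
            m = int(rng.integers(5, 40))
            p = rng.random(m)
            bonf = st.adjust_pvalues(p, "bonferroni", m)
            bh = st.adjust_pvalues(p, "benjamini-hochberg", m)
            assert set(np.flatnonzero(bonf < 0.05)) <= set(np.flatnonzero(bh < 0.05))
            assert np.allclose(bonf, np.minimum(1, p * m))
            order = np.argsort(p)
            ref = np.empty(m)
            for rank_pos, idx in enumerate(order):
                candidates = [
                    min(1.0, p[order[j]] * m / (j + 1))
                    for j in range(rank_pos, m)
                ]
                ref[idx] = min(candidates)
            assert np.allclose(bh, ref)

    def test_invalid_p_rejected(self):
        with pytest.raises(ConfigError):
            st.adjust_pvalues([1.2], "bonferroni")
        with pytest.raises(ConfigError):
            st.adjust_pvalues([0.5], "holm")


class TestBayesEquivalence:
    def test_exact_null_duplicated_data(self, rng):
        y = np.tile(rng.standard_normal(40), 2)
        group = pd.Series(["a"] * 40 + ["b"] * 40)
        res = st.bayes_equivalence(y, group)
        assert res.bf10 < 1.0
        assert res.method == "BIC"

    def test_null_direction_calibration(self):
        bfs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = rng.standard_normal(120)
            group = pd.Series(np.repeat(["a", "b"], 60))
            bfs.append(st.bayes_equivalence(y, group).bf10)
        assert np.median(bfs) < 1.0

    def test_alternative_direction_calibration(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = rng.standard_normal(120)
            y[60:] += 2.0
            group = pd.Series(np.repeat(["a", "b"], 60))
            hits += st.bayes_equivalence(y, group).bf10 > 3.0
        assert hits >= 95

    def test_too_few_observations(self):
        y = np.arange(4.0)
        group = pd.Series(["a", "a", "b", "b"])
        cov = pd.DataFrame({"age": [1.0, 2, 3, 4], "sex": ["M", "F", "M", "F"]})
        with pytest.raises(StatsPreconditionError):
            st.bayes_equivalence(y, group, cov)


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert st.spearman_assoc(x, x * 2 + 1)[0] == 1.0
        assert st.spearman_assoc(x, -x)[0] == -1.0

    def test_exact_permutation_n6(self, rng):
        # oracle: enumerate all 720 rank permutations
        for _ in range(5):
            x = rng.standard_normal(6)
            y = rng.standard_normal(6)
            r, p = st.spearman_assoc(x, y)
            rx, ry = sps.rankdata(x), sps.rankdata(y)
            r_obs = np.corrcoef(rx, ry)[0, 1]
            count = 0
            for perm in itertools.permutations(rx):
                if abs(np.corrcoef(perm, ry)[0, 1]) >= abs(r_obs) - 1e-12:
                    count += 1
            assert r == pytest.approx(r_obs)
            assert p == pytest.approx(count / 720.0)

    def test_large_n_t_approximation(self, rng):
        x = rng.standard_normal(50)
        y = x + rng.standard_normal(50)
        r, p = st.spearman_assoc(x, y)
        r_ref, p_ref = sps.spearmanr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_degenerate_inputs_null(self):
        assert st.spearman_assoc([1, 2, 3], [1, 2, 3]) == (None, None)
        assert st.spearman_assoc(np.ones(10), np.arange(10)) == (None, None)

    def test_rank_invariance(self, rng):
        x, y = rng.standard_normal(20), rng.standard_normal(20)
        r1, p1 = st.spearman_assoc(x, y)
        r2, p2 = st.spearman_assoc(np.exp(x), y**3)
        assert r1 == pytest.approx(r2) and p1 == pytest.approx(p2)


class TestRunBattery:
    def test_smoke_and_invariants(self):
        cohort = make_cohort({"HC": 20, "iRBD": 12, "ePD": 14}, seed=3)
        eff = synthio.EffectSpec(shift=0.08)
        feats = synthio.simulate_features(
            cohort, [eff],
            columns=["snc_caudal_motor_surface_md", "snc_limbic_surface_md",
                     "snc_total_bundle_fa"],
            subject_sd=0.03, seed=3)
        report = st.run_battery(feats, cohort, family_size=3)
        assert len(report) == 3
        assert (report["p_adj"] >= report["p"] - 1e-12).all()
        assert set(report["route"]) <= {"parametric", "nonparametric"}
        assert report["levene_p"].between(0, 1).all()
        shifted = report.set_index("feature").loc["snc_caudal_motor_surface_md"]
        assert shifted["p_adj"] < 0.05

    def test_omnibus_pvalues_agree_with_battery(self):
        cohort = make_cohort({"HC": 15, "iRBD": 15, "ePD": 15}, seed=5)
        feats = synthio.simulate_features(
            cohort, columns=[f"f{i}" for i in range(8)], seed=5)
        report = st.run_battery(feats, cohort, family_size=8)
        p_fast, _ = st.omnibus_pvalues(
            feats.to_numpy(), cohort, covariate_names=("age", "sex"))
        assert np.allclose(np.sort(report["p"]), np.sort(p_fast), atol=1e-10)
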