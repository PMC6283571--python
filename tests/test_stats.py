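import numpy as np
import pandas as pd
import pytest

import immunoscape as im


class TestPairedSignedRank:
    def test_antisymmetric_differences_give_p_near_one(self):
        normal = np.arange(10, dtype=float)
        tumor = normal + np.resize([2.0, -2.0], 10)
        _, p = im.paired_signed_rank(tumor, normal)
        assert p > 0.75

    def test_six_positive_pairs_exact_two_sided_p(self):
        # all-positive signs: one-tailed exact probability 1/2^6 -> two-sided 2/64
        normal = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        tumor = normal + np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
        _, p = im.paired_signed_rank(tumor, normal)
        assert p == pytest.approx(2 / 64)

    def test_constant_shift_attains_minimal_p(self):
        normal = np.linspace(1, 9, 9)
        tumor = normal + 3.0
        _, p_shift = im.paired_signed_rank(tumor, normal)
        assert p_shift == pytest.approx(2 / 2**9)

    def test_all_zero_differences_rejected(self):
        vals = np.arange(6, dtype=float)
        with pytest.raises(ValueError, match="degenerate pairing"):
            im.paired_signed_rank(vals, vals)

    def test_rank_sum_available_for_unpaired(self):
        x = np.array([5.0, 6, 7, 8])
        y = np.array([1.0, 2, 3, 4])
        _, p = im.rank_sum(x, y)
        assert p < 0.05


class TestKruskalWallis:
    def test_fully_separated_ranks_match_hand_formula(self):
        # groups {1,2},{3,4},{5,6}: rank sums 3,7,11 -> H = 12/(6*7)*89.5 - 21
        scores = np.array([1.0, 2, 3, 4, 5, 6])
        stages = np.array(["I", "I", "II", "II", "III", "III"])
        h, _, _ = im.kruskal_wallis_stages(scores, stages)
        assert h == pytest.approx(12 / 42 * 89.5 - 21)

    def test_identical_groups_high_p(self):
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(10):
            scores = rng.normal(size=40)
            stages = np.resize(["I", "II", "III", "IV"], 40)
            _, p, _ = im.kruskal_wallis_stages(scores, stages)
            pvals.append(p)
        assert np.mean(np.asarray(pvals) < 0.05) <= 0.2

    def test_small_stage_excluded_with_warning(self, caplog):
        scores = np.array([1.0, 2, 3, 4, 5])
        stages = np.array(["I", "I", "II", "II", "IV"])
        with caplog.at_level("WARNING", logger="immunoscape.stats"):
            h, p, pairs = im.kruskal_wallis_stages(scores, stages)
        assert any("IV" in r.message for r in caplog.records)
        assert set(pairs["stage_a"]) | set(pairs["stage_b"]) == {"I", "II"}

    def test_monotone_shift_most_significant_for_extreme_pair(self):
        """With scores declining stage by stage, the I-vs-IV contrast should
        reach significance before the adjacent pairs."""
        rng = np.random.default_rng(1)
        shifts = {"I": 0.0, "II": -0.4, "III": -0.8, "IV": -1.2}
        stages = np.repeat(["I", "II", "III", "IV"], 30)
        scores = np.concatenate([rng.normal(shifts[s], 1.0, 30) for s in ("I", "II", "III", "IV")])
        _, _, pairs = im.kruskal_wallis_stages(scores, stages)
        pairs = pairs.set_index(["stage_a", "stage_b"])
        p_extreme = pairs.loc[("I", "IV"), "p_adjusted"]
        assert p_extreme < 0.05
        assert p_extreme == pairs["p_adjusted"].min()


class TestOlsAssociation:
    def test_exact_linear_relation_recovered(self):
        rng = np.random.default_rng(2)
        b = rng.normal(size=50)
        t = rng.normal(size=50)
        pdl1 = 2.0 * b
        fit = im.ols_pdl1_association(pdl1, b, t).set_index("term")
        assert fit.loc["bscore", "coefficient"] == pytest.approx(2.0, abs=1e-10)
        assert abs(fit.loc["tscore", "coefficient"]) < 1e-10

    def test_null_coefficients_covered_by_two_se(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(40):
            pdl1 = rng.normal(size=60)
            b, t = rng.normal(size=60), rng.normal(size=60)
            fit = im.ols_pdl1_association(pdl1, b, t).set_index("term")
            row = fit.loc["bscore"]
            hits += abs(row["coefficient"]) <= 2 * row["std_error"]
        assert hits >= 32  # ~95% nominal coverage

    def test_collinear_predictors_rejected(self):
        b = np.arange(10, dtype=float)
        with pytest.raises(ValueError, match="rank-deficient|collinear"):
            im.ols_pdl1_association(np.ones(10), b, 2 * b)


class TestStratifyQuadrants:
    def test_worked_example(self):
        pdl1 = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("wxyz"))
        b = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("wxyz"))
        groups = im.stratify_quadrants(pdl1, b)
        assert list(groups["group"]) == ["D", "D", "B", "B"]

    def test_perfect_rank_correlation_only_a_and_c(self):
        vals = pd.Series(np.arange(8, dtype=float), index=[f"s{i}" for i in range(8)])
        groups = im.stratify_quadrants(vals, vals * 3 + 1)
        assert set(groups["group"]) == {"A", "C"}

    def test_partition_covers_all_samples(self, small_cohort_groups):
        groups, _, _ = small_cohort_groups
        counts = groups["group"].value_counts()
        assert counts.sum() == len(groups)
        assert set(counts.index) <= {"A", "B", "C", "D"}

    def test_positive_coupling_fills_diagonal_quadrants(self, small_cohort_groups):
        groups, _, _ = small_cohort_groups
        counts = groups["group"].value_counts()
        assert counts["A"] > counts["B"] and counts["A"] > counts["D"]
        assert counts["C"] > counts["B"] and counts["C"] > counts["D"]

    def test_constant_variable_rejected(self):
        pdl1 = pd.Series([1.0, 1.0, 1.0, 1.0])
        b = pd.Series([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="degenerate stratification"):
            im.stratify_quadrants(pdl1, b)


class TestKmLogrank:
    def test_identical_groups_chi2_zero(self):
        times = np.tile([1.0, 2, 3, 4, 5], 2)
        events = np.tile([1, 0, 1, 1, 0], 2).astype(bool)
        labels = np.repeat(["a", "b"], 5)
        comp = im.km_logrank(times, events, labels)
        assert comp.logrank_chi2 == pytest.approx(0.0, abs=1e-12)
        assert comp.logrank_p == pytest.approx(1.0)

    def test_hand_product_limit(self):
        # group g: times [1, 2+, 3], events [1,0,1] -> S(1)=2/3, S(3)=0
        times = np.array([1.0, 2.0, 3.0, 5.0, 6.0])
        events = np.array([1, 0, 1, 1, 0], dtype=bool)
        labels = np.array(["g", "g", "g", "h", "h"])
        comp = im.km_logrank(times, events, labels)
        curve = comp.km_curves["g"].set_index("time")["survival"]
        assert curve.loc[1.0] == pytest.approx(2 / 3)
        assert curve.loc[3.0] == pytest.approx(0.0)
        assert (comp.km_curves["g"]["survival"].diff().dropna() <= 1e-12).all()

    def test_curves_start_at_one(self):
        times = np.array([2.0, 3.0, 4.0, 5.0])
        events = np.array([1, 1, 1, 1], dtype=bool)
        labels = np.array(["a", "a", "b", "b"])
        comp = im.km_logrank(times, events, labels)
        for curve in comp.km_curves.values():
            assert curve["survival"].iloc[0] == pytest.approx(1.0)  # t=0 row

    def test_logrank_invariant_under_time_rescaling(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(100, 60)
        events = rng.random(60) < 0.7
        labels = np.resize(["a", "b"], 60)
        c1 = im.km_logrank(times, events, labels)
        c2 = im.km_logrank(times * 365.0, events, labels)
        assert c1.logrank_chi2 == pytest.approx(c2.logrank_chi2)

    def test_protective_hazard_detected_in_simulation(self):
        """log HR = log(0.5) on the B latent: the high-B curve should dominate
        and the log-rank test reject in nearly all replicates at n=400."""
        detected = 0
        n_rep = 10
        for seed in range(n_rep):
            params = im.CohortSimulationParams(
                n_tumor=400, n_normal_pairs=5, n_genes=60, bcell_set_size=10,
                tcell_set_size=10, log_hr_bcell=np.log(0.5), seed=seed,
            )
            expr, clinical, _, truth = im.simulate_cohort(params)
            tumors = clinical.tumor_samples()
            clin = clinical.data.set_index("sample_id").loc[tumors]
            b = pd.Series(truth["b_latent"]).loc[tumors]
            labels = np.where(b > b.median(), "high", "low")
            comp = im.km_logrank(clin["os_days"], clin["event"], labels)
            better = comp.mean_survival["high"] > comp.mean_survival["low"]
            detected += better and comp.logrank_p < 0.05
        assert detected >= 9


class TestCoxRegression:
    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(6)
        times = rng.exponential(100, 200)
        events = rng.random(200) < 0.8
        cov = pd.DataFrame({"x": rng.normal(size=200)})
        fit = im.cox_regression(times, events, cov)
        row = fit.table.iloc[0]
        assert abs(row["coefficient"]) <= 2 * row["std_error"]

    def test_duplicated_covariate_rank_deficient(self):
        rng = np.random.default_rng(7)
        times = rng.exponential(100, 50)
        events = np.ones(50, dtype=bool)
        x = rng.integers(0, 2, 50).astype(float)
        with pytest.raises(ValueError, match="rank-deficient"):
            im.cox_regression(times, events, pd.DataFrame({"a": x, "b": x}))

    def test_univariate_mode_fits_each_covariate_alone(self):
        rng = np.random.default_rng(8)
        n = 150
        times = rng.exponential(100, n)
        events = rng.random(n) < 0.8
        cov = pd.DataFrame({"x": rng.normal(size=n), "grp": rng.choice(["low", "high"], n)})
        fit = im.cox_regression(times, events, cov, mode="univariate")
        assert fit.model == "univariate"
        assert set(fit.table["covariate"]) == {"x", "grp[high]"}
        assert (fit.table["hazard_ratio"] > 0).all()

    def test_categorical_reference_levels(self):
        rng = np.random.default_rng(9)
        n = 120
        times = rng.exponential(100, n)
        events = rng.random(n) < 0.8
        cov = pd.DataFrame(
            {
                "stage": rng.choice(["I", "II", "III"], n),
                "sex": rng.choice(["male", "female"], n),
            }
        )
        fit = im.cox_regression(times, events, cov)
        names = set(fit.table["covariate"])
        assert names == {"stage[II]", "stage[III]", "sex[female]"}
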