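import numpy as np
import pandas as pd
import pytest

from lifecourse import OracleRateModel, simulate_cohort
from lifecourse.evaluation import (
    annual_risk_from_logit,
    calibration_bin_edges,
    calibration_curve,
    combine_delong,
    delong_auc_variance,
    incidence_cross_entropy,
    longitudinal_eval,
    nelson_aalen_cumhaz,
    observed_incidence,
    stratified_auc,
    subgroup_variance_test,
)


class TestAnnualRisk:
    def test_printed_identity(self):
        """logit = ln(1/365.25) gives 1 - e^-1."""
        assert annual_risk_from_logit(np.log(1 / 365.25)) == pytest.approx(
            1 - np.exp(-1)
        )

    def test_boundaries(self):
        assert annual_risk_from_logit(-np.inf) == 0.0
        assert annual_risk_from_logit(50.0) == 1.0

    def test_monotone(self):
        x = np.linspace(-20, 5, 100)
        assert np.all(np.diff(annual_risk_from_logit(x)) >= 0)


class TestObservedIncidence:
    def test_absent_token_all_zero(self, tiny_cohort, tiny_vocab):
        inc = observed_incidence(tiny_cohort, tiny_vocab,
                                 tiny_vocab.pad_index)
        assert (inc["events"] == 0).all()

    def test_at_risk_non_increasing(self, tiny_cohort, tiny_vocab):
        inc = observed_incidence(tiny_cohort, tiny_vocab,
                                 tiny_vocab.index("D00"))
        for _, grp in inc.groupby("sex"):
            assert np.all(np.diff(grp["at_risk"]) <= 0)

    def test_empty_cohort_rejected(self, tiny_vocab):
        with pytest.raises(ValueError):
            observed_incidence([], tiny_vocab, 0)


class TestCalibrationCurve:
    def test_bin_edges_are_factor_five_ladder(self):
        e = calibration_bin_edges()
        assert e[0] == 1e-6 and e[-1] == 1.0
        assert np.allclose(e[1:-1] / e[:-2], 5.0)

    def test_single_bin_observed_rate(self):
        pred = np.full(200, 3e-3)
        case = np.zeros(200, bool)
        case[:20] = True
        curve = calibration_curve(pred, case, band_years=5.0)
        assert len(curve) == 1
        assert curve["observed_annual"].iloc[0] == pytest.approx(0.1 / 5)

    def test_scaling_predictions_shifts_bins_not_observed(self):
        rng = np.random.default_rng(0)
        pred = 10 ** rng.uniform(-4, -2, 500)
        case = rng.random(500) < 0.1
        c1 = calibration_curve(pred, case)
        c10 = calibration_curve(pred * 10, case)
        assert c10["bin_low"].min() > c1["bin_low"].min()
        assert c10["n_cases"].sum() == c1["n_cases"].sum()

    def test_oracle_predictions_sit_on_diagonal(self):
        """Outcomes drawn from the predicted risks themselves must land
        each occupied bin near the diagonal."""
        rng = np.random.default_rng(1)
        pred = 10 ** rng.uniform(-3.5, -0.5, 60_000)
        outcome = rng.random(60_000) < pred
        curve = calibration_curve(pred, outcome, band_years=1.0)
        occ = curve[curve["n_cases"] >= 10]
        ratio = occ["observed_annual"] / occ["predicted_mean"]
        assert np.all(ratio > 0.7) and np.all(ratio < 1.4)


class TestStratifiedAUC:
    def brute_force_auc(self, cases, controls):
        wins = sum(
            1.0 if c > k else 0.5 if c == k else 0.0
            for c in cases for k in controls
        )
        return wins / (len(cases) * len(controls))

    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.7, 0.1, 0.2, 0.3])
        y = np.array([1, 1, 1, 0, 0, 0], bool)
        ages = np.full(6, 52.0)
        res = stratified_auc(scores, y, ages)
        assert res.mean == 1.0

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(2)
        n = 4000
        scores = rng.random(n)
        y = rng.random(n) < 0.2
        ages = rng.uniform(50, 80, n)
        res = stratified_auc(scores, y, ages)
        assert res.mean == pytest.approx(0.5, abs=0.05)

    def test_equals_brute_force_pair_counting(self):
        """Bracket AUC matches exhaustive case-control pair counting,
        including the midpoint tie convention."""
        cases = [0.9, 0.8, 0.4, 0.4]
        controls = [0.5, 0.4, 0.2, 0.1]
        scores = np.array(cases + controls)
        y = np.array([1] * 4 + [0] * 4, bool)
        ages = np.full(8, 61.0)
        res = stratified_auc(scores, y, ages)
        assert res.mean == pytest.approx(self.brute_force_auc(cases, controls))

    def test_no_qualifying_bracket_flagged_not_half(self):
        scores = np.array([0.5, 0.4])
        y = np.array([1, 0], bool)
        res = stratified_auc(scores, y, np.array([55.0, 55.0]))
        assert not res.valid
        assert np.isnan(res.mean)

    def test_delong_variance_matches_closed_form_small_case(self):
        """On 2 cases / 2 controls the placement variances are hand-
        computable."""
        auc, var = delong_auc_variance(np.array([3.0, 1.0]), np.array([2.0, 0.0]))
        # psi rows: case 3 -> (1,1); case 1 -> (0,1)
        assert auc == pytest.approx(0.75)
        v10 = np.array([1.0, 0.5])
        v01 = np.array([0.5, 1.0])
        expected = v10.var(ddof=1) / 2 + v01.var(ddof=1) / 2
        assert var == pytest.approx(expected)


class TestCombineDeLong:
    def test_equal_brackets_shrink_variance(self):
        mu, var, _ = combine_delong([0.7] * 4, [0.01] * 4)
        assert mu == pytest.approx(0.7)
        assert var == pytest.approx(0.01 / 4)

    def test_single_bracket_unchanged(self):
        mu, var, _ = combine_delong([0.66], [0.02])
        assert (mu, var) == (0.66, pytest.approx(0.02))

    def test_ci_coverage_on_null_simulations(self):
        """95% CI covers the true null AUC (0.5) in [93%, 97%] of 1,000
        simulated datasets."""
        rng = np.random.default_rng(7)
        covered = 0
        n_sim = 1000
        for _ in range(n_sim):
            mus, vars_ = [], []
            for _b in range(3):
                cases = rng.normal(size=25)
                controls = rng.normal(size=40)
                a, v = delong_auc_variance(cases, controls)
                mus.append(a)
                vars_.append(v)
            _, _, (lo, hi) = combine_delong(mus, vars_)
            covered += lo <= 0.5 <= hi
        assert 0.93 <= covered / n_sim <= 0.97


class TestSubgroupVariance:
    def test_hand_example(self):
        """mu1=0.8, mu2=0.7, sigma=0.05 each: pooled 0.75, residuals +-1,
        chi-square 2."""
        res = subgroup_variance_test([0.8, 0.7], [0.05**2, 0.05**2])
        assert res.pooled_mean == pytest.approx(0.75)
        assert sorted(res.residuals["residual"]) == pytest.approx([-1.0, 1.0])
        assert res.chi2 == pytest.approx(2.0)
        assert res.dof == 1

    def test_identical_subgroups_zero_statistic(self):
        res = subgroup_variance_test([0.7, 0.7, 0.7], [0.01, 0.01, 0.01])
        assert res.chi2 == pytest.approx(0.0)

    def test_null_flag_rate_below_bonferroni_nominal(self):
        """Simulating a common true AUC, the disease-level flag rate
        stays at or below the Bonferroni level."""
        rng = np.random.default_rng(11)
        n_dis = 400
        alpha, n_comp = 0.05, 50
        flags = 0
        for _ in range(n_dis):
            sigma = 0.03
            mus = 0.7 + rng.normal(0, sigma, size=4)
            res = subgroup_variance_test(mus, [sigma**2] * 4, alpha=alpha,
                                         n_comparisons=n_comp)
            flags += res.flagged
        assert flags / n_dis <= alpha / n_comp * 5 + 0.01

    def test_insufficient_subgroups_rejected(self):
        with pytest.raises(ValueError, match="two subgroups"):
            subgroup_variance_test([0.7], [0.01])


class TestIncidenceCrossEntropy:
    def test_matched_distributions_give_binary_entropy(self):
        p = 0.3
        h = -p * np.log(p) - (1 - p) * np.log(1 - p)
        assert incidence_cross_entropy(p, p) == pytest.approx(h)

    def test_zero_p_reduces_to_log_survival(self):
        assert incidence_cross_entropy(0.0, 0.2) == pytest.approx(-np.log(0.8))

    def test_printed_example(self):
        assert incidence_cross_entropy(0.01, 0.02) == pytest.approx(0.0593, abs=5e-4)

    def test_conflicting_boundary_surfaces_infinity(self):
        assert np.isinf(incidence_cross_entropy(0.5, 1.0))


class TestNelsonAalen:
    def test_no_events_identically_zero(self):
        t, h = nelson_aalen_cumhaz(np.array([]), np.array([5.0, 7.0]))
        assert np.all(h == 0)

    def test_single_event_step_height(self):
        t, h = nelson_aalen_cumhaz(np.array([2.0]), np.array([5.0] * 9))
        assert h.max() == pytest.approx(1 / 10)

    def test_hand_computed_increments(self):
        """Sum of d_i/n_i against a worked 5-subject example."""
        t, h = nelson_aalen_cumhaz(np.array([1.0, 3.0]), np.array([2.0, 4.0, 9.0]))
        # at t=1: 1/5; at t=3: +1/3
        final = 1 / 5 + 1 / 3
        assert h.max() == pytest.approx(final)

    def test_constant_hazard_linear_cumhaz(self):
        rng = np.random.default_rng(3)
        lam = 0.25
        times = rng.exponential(1 / lam, size=5000)
        t, h = nelson_aalen_cumhaz(times, np.array([]))
        at = np.searchsorted(t, 4.0)
        assert h[at] == pytest.approx(lam * 4.0, rel=0.05)


class TestLongitudinalEval:
    @pytest.fixture(scope="class")
    def eval_cohort(self, recovery_preset):
        return simulate_cohort(1200, recovery_preset.hazard_model, seed=44)

    def test_gap_covering_followup_flags_empty(self, tiny_cohort, tiny_preset):
        oracle = OracleRateModel(tiny_preset.hazard_model)
        report = longitudinal_eval(tiny_cohort, oracle, cutoff_age_years=60,
                                   gap_years=100.0)
        assert report.empty

    def test_oracle_rates_discriminate(self, eval_cohort, recovery_oracle):
        """Ground-truth rates must beat chance on their own cohort."""
        report = longitudinal_eval(
            eval_cohort, recovery_oracle, cutoff_age_years=60.0, min_cases=10
        )
        assert not report.empty
        assert report.per_token["auc"].mean() > 0.55

    def test_shuffled_histories_lose_discrimination(
        self, eval_cohort, recovery_oracle
    ):
        """Pairing predictions with other persons' outcomes destroys the
        history signal on an interaction-bearing cohort."""
        report = longitudinal_eval(
            eval_cohort, recovery_oracle, cutoff_age_years=60.0, min_cases=10
        )
        rng = np.random.default_rng(0)
        shuffled = list(eval_cohort)
        # swap event histories between persons of the same sex
        vocab = recovery_oracle.vocab
        by_sex = {}
        for t in shuffled:
            by_sex.setdefault(t.sex_token(vocab), []).append(t)
        swapped = []
        from dataclasses import replace

        for sex, group in by_sex.items():
            perm = rng.permutation(len(group))
            for i, j in enumerate(perm):
                swapped.append(
                    replace(group[int(j)], person_id=group[i].person_id)
                )
        # outcomes keep their own histories; predictions come from the
        # swapped ones -> evaluate swapped predictions on original outcomes
        class Shuffler:
            vocab = recovery_oracle.vocab

            def __init__(self, mapping):
                self.mapping = mapping

            def rate_vector(self, traj):
                other = self.mapping[traj.person_id]
                keep = other.ages <= traj.ages[-1]
                proxy = replace(
                    other, ages=other.ages[keep], tokens=other.tokens[keep]
                )
                if len(proxy) == 0:
                    proxy = replace(other, ages=traj.ages[:1], tokens=traj.tokens[:1])
                return recovery_oracle.rate_vector(proxy)

        mapping = {t.person_id: s for t, s in zip(shuffled, swapped)}
        shuffled_report = longitudinal_eval(
            eval_cohort, Shuffler(mapping), cutoff_age_years=60.0, min_cases=10
        )
        merged = report.per_token.merge(
            shuffled_report.per_token, on="token", suffixes=("_true", "_shuf")
        )
        assert merged["auc_true"].mean() > merged["auc_shuf"].mean()

    def test_report_serialization(self, tmp_path, eval_cohort, recovery_oracle):
        report = longitudinal_eval(
            eval_cohort, recovery_oracle, cutoff_age_years=60.0, min_cases=10
        )
        report.write(tmp_path)
        assert (tmp_path / "per_token.tsv").exists()
        back = pd.read_csv(tmp_path / "per_token.tsv", sep="\t")
        assert len(back) == len(report.per_token)
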