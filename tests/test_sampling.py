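import numpy as np
import pytest
from scipy import stats

from lifecourse import OracleRateModel
from lifecourse.sampling import generate_cohort, rollout, sample_next_event
from lifecourse.trajectory import DAYS_PER_YEAR, Trajectory
from lifecourse.evaluation import observed_incidence


class TestSampleNextEvent:
    def test_single_positive_rate_always_fires(self):
        rng = np.random.default_rng(0)
        rates = np.array([0.0, 0.25, 0.0])
        draws = [sample_next_event(rates, rng) for _ in range(5000)]
        toks = {t for t, _ in draws}
        assert toks == {1}
        mean_dt = np.mean([dt for _, dt in draws])
        assert mean_dt == pytest.approx(4.0, rel=0.05)

    def test_token_frequencies_follow_rate_fractions(self):
        """Rates (1, 3): the faster token wins 75% of draws."""
        rng = np.random.default_rng(1)
        rates = np.array([1.0, 3.0])
        wins = sum(sample_next_event(rates, rng)[0] == 1 for _ in range(20000))
        assert wins / 20000 == pytest.approx(0.75, abs=0.01)

    def test_min_time_is_exponential_in_total_rate(self):
        rng = np.random.default_rng(2)
        rates = np.array([0.5, 1.5])  # total 2/day -> mean 0.5 days
        dts = np.array([sample_next_event(rates, rng)[1] for _ in range(20000)])
        assert dts.mean() == pytest.approx(0.5, abs=0.02)

    def test_distributional_correctness_chi2_and_ks(self):
        """Token identity chi-square vs lambda/sum and waiting-time KS vs
        Exponential(sum) both pass at alpha = 0.01, n = 50,000."""
        rng = np.random.default_rng(3)
        rates = np.array([0.2, 0.05, 0.6, 0.15])
        n = 50_000
        toks = np.empty(n, int)
        dts = np.empty(n)
        for i in range(n):
            toks[i], dts[i] = sample_next_event(rates, rng)
        expected = rates / rates.sum() * n
        chi2_p = stats.chisquare(np.bincount(toks, minlength=4), expected).pvalue
        ks_p = stats.kstest(dts, "expon", args=(0, 1 / rates.sum())).pvalue
        assert chi2_p > 0.01
        assert ks_p > 0.01

    def test_time_rescaling(self):
        """Multiplying all rates by c divides mean waiting times by c."""
        rng = np.random.default_rng(4)
        base = np.array([0.3, 0.7])
        m1 = np.mean([sample_next_event(base, rng)[1] for _ in range(20000)])
        m4 = np.mean([sample_next_event(4 * base, rng)[1] for _ in range(20000)])
        assert m1 / m4 == pytest.approx(4.0, rel=0.05)

    def test_all_zero_rates_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            sample_next_event(np.zeros(3), np.random.default_rng(0))


class TestRollout:
    def test_prompt_at_stop_age_returned_unchanged(self, tiny_preset):
        oracle = OracleRateModel(tiny_preset.hazard_model)
        v = oracle.vocab
        prompt = Trajectory("p", np.array([0.0, 80 * DAYS_PER_YEAR]),
                            np.array([v.sex_indices[0], v.index("D00")]),
                            window_end=90 * DAYS_PER_YEAR)
        out = rollout(prompt, oracle, stop_age_years=80.0, seed=0)
        assert out is prompt

    def test_high_death_rate_terminates_rollout(self, tiny_preset):
        hm = tiny_preset.hazard_model
        forced = OracleRateModel(hm)
        v = hm.vocab
        boosted = hm.intercept.copy()
        boosted[v.death_index] = np.log(1.0)  # one death per day
        forced.hazard_model = type(hm)(
            vocab=v, intercept=boosted, age_slope=hm.age_slope,
            sex_effect=hm.sex_effect,
        )
        prompt = Trajectory("p", np.array([0.0]), np.array([v.sex_indices[1]]))
        out = rollout(prompt, forced, stop_age_years=80.0, seed=1)
        assert out.tokens[-1] == v.death_index
        assert np.all(out.tokens[:-1] != v.death_index)

    def test_ages_strictly_increase_and_prefix_preserved(self, tiny_preset):
        oracle = OracleRateModel(tiny_preset.hazard_model)
        v = oracle.vocab
        prompt = Trajectory("p", np.array([0.0, 40 * DAYS_PER_YEAR]),
                            np.array([v.sex_indices[0], v.index("D01")]))
        out = rollout(prompt, oracle, stop_age_years=80.0, seed=2)
        assert np.array_equal(out.tokens[:2], prompt.tokens)
        assert np.all(np.diff(out.ages) > 0)

    def test_no_repeat_diseases(self, tiny_preset):
        oracle = OracleRateModel(tiny_preset.hazard_model)
        v = oracle.vocab
        for seed in range(10):
            prompt = Trajectory("p", np.array([0.0]),
                                np.array([v.sex_indices[seed % 2]]))
            out = rollout(prompt, oracle, stop_age_years=95.0, seed=seed)
            diseases = [t for t in out.tokens
                        if v.token_class(int(t)) == "disease"]
            assert len(diseases) == len(set(diseases))


class TestGenerateCohort:
    def test_zero_size(self, tiny_preset):
        oracle = OracleRateModel(tiny_preset.hazard_model)
        assert generate_cohort(0, oracle, seed=0) == []

    def test_random_sex_split_reproducible(self, tiny_preset):
        oracle = OracleRateModel(tiny_preset.hazard_model)
        v = oracle.vocab
        c1 = generate_cohort(200, oracle, stop_age_years=1.0, seed=5)
        c2 = generate_cohort(200, oracle, stop_age_years=1.0, seed=5)
        sexes = [t.tokens[0] for t in c1]
        assert sexes == [t.tokens[0] for t in c2]
        frac_male = np.mean([s == v.sex_indices[1] for s in sexes])
        assert abs(frac_male - 0.5) < 3 * 0.5 / np.sqrt(200)

    def test_conditional_rollouts_match_heldout_incidence(self, tiny_preset):
        """Rollouts prompted with real histories up to age 60 reproduce
        the direct simulator's incidence at ages 70-75 (conditioning
        consistency of the sampler)."""
        from dataclasses import replace

        from lifecourse import simulate_cohort

        hm = tiny_preset.hazard_model
        v = hm.vocab
        oracle = OracleRateModel(hm)
        held = simulate_cohort(500, hm, seed=77, recruitment_age_years=None)
        cut = 60 * DAYS_PER_YEAR
        prompts = []
        for t in held:
            death = t.death_age(v)
            if death is not None and death <= cut:
                continue
            keep = t.ages <= cut
            if not keep.any():
                continue
            prompts.append(replace(t, ages=t.ages[keep], tokens=t.tokens[keep]))
        rolled = [
            rollout(p, oracle, stop_age_years=76.0,
                    rng=np.random.default_rng(np.random.SeedSequence([3, i])))
            for i, p in enumerate(prompts[:250])
        ]
        held_ids = {p.person_id for p in rolled}
        direct = [t for t in held if t.person_id in held_ids]

        def window_events(cohort, tok):
            lo, hi = 70 * DAYS_PER_YEAR, 75 * DAYS_PER_YEAR
            return sum(
                bool(np.any((t.tokens == tok) & (t.ages >= lo) & (t.ages < hi)))
                for t in cohort
            )

        for code in ("D00", "death"):
            tok = v.index(code) if code != "death" else v.death_index
            a = window_events(rolled, tok)
            b = window_events(direct, tok)
            assert abs(a - b) <= 4 * np.sqrt(a + b + 1), (code, a, b)

    def test_oracle_rollouts_reproduce_oracle_incidence(self, tiny_preset):
        """Sampling from the ground-truth rate model must reproduce the
        simulator's own age-specific incidence (both implement the same
        competing-exponentials process)."""
        from lifecourse import simulate_cohort

        hm = tiny_preset.hazard_model
        v = hm.vocab
        oracle = OracleRateModel(hm)
        rolled = generate_cohort(400, oracle, stop_age_years=80.0, seed=9)
        direct = simulate_cohort(400, hm, seed=31, max_age_years=80.0,
                                 recruitment_age_years=None)
        tok = v.index("D00")
        inc_r = observed_incidence(rolled, v, tok, age_bin_years=20, max_age_years=80)
        inc_d = observed_incidence(direct, v, tok, age_bin_years=20, max_age_years=80)
        merged = inc_r.merge(inc_d, on=["sex", "age_years"], suffixes=("_r", "_d"))
        ev_r = merged["events_r"].sum()
        ev_d = merged["events_d"].sum()
        # total event counts agree within Poisson error
        assert abs(ev_r - ev_d) < 4 * np.sqrt(ev_r + ev_d + 1)
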