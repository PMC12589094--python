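import numpy as np
import pytest

from lifecourse import OracleRateModel, simulate_cohort
from lifecourse.attribution import (
    aggregate_effect_matrix,
    export_embeddings,
    hazard_ratio_nonparametric,
    shapley_attribution,
    time_resolved_effect,
)
from lifecourse.trajectory import DAYS_PER_YEAR, Trajectory


def make_traj(vocab, events):
    ages = np.array([a * DAYS_PER_YEAR for a, _ in events])
    toks = np.array([vocab.index(c) for _, c in events])
    return Trajectory("p", ages, toks)


@pytest.fixture(scope="module")
def oracle(recovery_preset):
    return OracleRateModel(recovery_preset.hazard_model, exclude_occurred=False)


class TestShapley:
    def test_single_maskable_token_two_point_formula(self, oracle):
        v = oracle.vocab
        traj = make_traj(v, [(0.0, "sex_female"), (50.0, "D00"), (60.0, "no_event")])
        tgt = v.index("D05")
        res = shapley_attribution(
            traj, oracle, targets=tgt, mask_positions=np.array([1])
        )
        assert res.phi.shape == (1, 1)
        assert res.phi[0, 0] == pytest.approx(
            res.f_full[0] - res.f_masked[0], abs=1e-9
        )
        # D00 -> D05 planted multiplier is x3 (permanent)
        assert res.phi[0, 0] == pytest.approx(np.log(3.0), abs=1e-9)

    def test_efficiency_holds_for_both_methods(self, oracle):
        v = oracle.vocab
        traj = make_traj(
            v,
            [(0.0, "sex_male"), (40.0, "D00"), (45.0, "D01"), (50.0, "D02"),
             (52.0, "D04"), (55.0, "smoking_high"), (60.0, "no_event")],
        )
        for force in (False, True):
            res = shapley_attribution(
                traj, oracle, targets=[v.index("D05"), v.death_index],
                force_hierarchical=force,
            )
            assert np.allclose(
                res.phi.sum(axis=0), res.f_full - res.f_masked, atol=1e-9
            )

    def test_hierarchical_matches_exact_on_six_token_fixture(self, oracle):
        """Owen values on the chronological tree coincide with exhaustive
        2^6-subset Shapley for the log-linear hazard game."""
        v = oracle.vocab
        traj = make_traj(
            v,
            [(0.0, "sex_female"), (35.0, "D00"), (42.0, "D01"), (48.0, "D02"),
             (52.0, "D04"), (55.0, "smoking_high"), (60.0, "no_event")],
        )
        positions = np.arange(6)  # all but the probe
        targets = [v.index("D05"), v.index("D06"), v.index("D03"), v.death_index]
        exact = shapley_attribution(
            traj, oracle, targets=targets, mask_positions=positions, max_exact=6
        )
        hier = shapley_attribution(
            traj, oracle, targets=targets, mask_positions=positions,
            force_hierarchical=True,
        )
        assert exact.method == "exact" and hier.method == "hierarchical"
        assert np.allclose(exact.phi, hier.phi, atol=1e-6)

    def test_symmetry_for_duplicate_effect_tokens(self, recovery_preset):
        """Two sources with identical planted effects on the target get
        equal attributions."""
        from lifecourse.simulate import HazardModel

        hm = recovery_preset.hazard_model
        v = hm.vocab
        sym = HazardModel(
            vocab=v,
            intercept=hm.intercept,
            age_slope=hm.age_slope,
            sex_effect=hm.sex_effect,
            inter_source=np.array([v.index("D00"), v.index("D01")]),
            inter_target=np.array([v.index("D05"), v.index("D05")]),
            inter_beta=np.array([np.log(2.0), np.log(2.0)]),
            inter_halflife=np.array([np.inf, np.inf]),
        )
        oracle = OracleRateModel(sym, exclude_occurred=False)
        traj = make_traj(
            v, [(0.0, "sex_female"), (50.0, "D00"), (50.0, "D01"),
                (60.0, "no_event")]
        )
        res = shapley_attribution(traj, oracle, targets=v.index("D05"))
        i0 = np.flatnonzero(res.tokens == v.index("D00"))[0]
        i1 = np.flatnonzero(res.tokens == v.index("D01"))[0]
        assert res.phi[i0, 0] == pytest.approx(res.phi[i1, 0], abs=1e-9)

    def test_non_predictable_target_rejected(self, oracle):
        v = oracle.vocab
        traj = make_traj(v, [(0.0, "sex_female"), (60.0, "no_event")])
        with pytest.raises(ValueError, match="predictable"):
            shapley_attribution(traj, oracle, targets=v.pad_index)


class TestTransformerGame:
    def test_efficiency_on_transformer_value_function(self, trained_tiny):
        v = trained_tiny.vocab
        traj = make_traj(
            v, [(0.0, "sex_male"), (40.0, "D00"), (50.0, "D01"),
                (60.0, "no_event")]
        )
        res = trained_tiny.shapley(traj, targets=v.death_index)
        assert np.allclose(res.phi.sum(axis=0), res.f_full - res.f_masked,
                           atol=1e-4)


class TestCohortAggregation:
    @pytest.fixture(scope="class")
    def small_cohort(self, recovery_preset):
        return simulate_cohort(120, recovery_preset.hazard_model, seed=21,
                               recruitment_age_years=None)

    def test_planted_interaction_positive_and_dominant(self, oracle, small_cohort):
        v = oracle.vocab
        tgt = v.index("D05")
        mat = aggregate_effect_matrix(
            small_cohort, oracle, min_occurrences=3, targets=[tgt]
        )
        row = mat[mat["target"] == "D05"].set_index("source")["mean_effect"]
        assert row["D00"] > 0
        assert row["D00"] == row.max()

    def test_self_effect_excluded(self, oracle, small_cohort):
        mat = aggregate_effect_matrix(
            small_cohort, oracle, min_occurrences=1,
            targets=[oracle.vocab.index("D05")],
        )
        assert not ((mat["source"] == "D05") & (mat["target"] == "D05")).any()

    def test_null_pair_centred_on_zero(self, oracle, small_cohort):
        """A token with no planted effect on the target attributes ~0."""
        v = oracle.vocab
        mat = aggregate_effect_matrix(
            small_cohort, oracle, min_occurrences=3, targets=[v.index("D05")]
        )
        # exclude the planted source and the sex tokens (sex genuinely
        # shifts D05 through its sex effect; masking swaps it)
        null_rows = mat[
            (mat["target"] == "D05")
            & (~mat["source"].isin(["D00", "sex_female", "sex_male"]))
        ]
        assert np.abs(null_rows["mean_effect"]).max() < 1e-6


class TestTimeResolvedEffect:
    def test_decaying_interaction_half_life_recovered(self, oracle, recovery_preset):
        """D01 -> death decays with half-life 5y; the fitted half-life
        from the binned curve lands within 50%."""
        v = oracle.vocab
        cohort = []
        for k, lag in enumerate(np.linspace(0.5, 14.5, 60)):
            cohort.append(
                make_traj(v, [(0.0, "sex_female"), (50.0, "D01"),
                              (50.0 + lag, "no_event")])
            )
        bins = np.arange(0.0, 16.0, 2.0)
        curve = time_resolved_effect(cohort, oracle, v.index("D01"),
                                     v.death_index, bins)
        occ = curve.dropna()
        # log2(effect) declines linearly with slope -1/h
        mid = (occ["bin_low"] + occ["bin_high"]) / 2
        slope = np.polyfit(mid, np.log2(occ["mean_effect"]), 1)[0]
        h = -1 / slope
        assert 2.5 < h < 7.5

    def test_permanent_interaction_flat(self, oracle):
        v = oracle.vocab
        cohort = [
            make_traj(v, [(0.0, "sex_female"), (50.0, "D00"),
                          (50.0 + lag, "no_event")])
            for lag in np.linspace(0.5, 14.5, 30)
        ]
        bins = np.arange(0.0, 16.0, 4.0)
        curve = time_resolved_effect(cohort, oracle, v.index("D00"),
                                     v.index("D05"), bins).dropna()
        assert np.allclose(curve["mean_effect"], np.log(3.0), atol=1e-6)

    def test_zero_interaction_zero_curve(self, oracle):
        v = oracle.vocab
        cohort = [
            make_traj(v, [(0.0, "sex_female"), (50.0, "D10"),
                          (50.0 + lag, "no_event")])
            for lag in np.linspace(0.5, 9.5, 20)
        ]
        bins = np.array([0.0, 5.0, 10.0])
        curve = time_resolved_effect(cohort, oracle, v.index("D10"),
                                     v.index("D05"), bins).dropna()
        assert np.abs(curve["mean_effect"]).max() < 1e-9


class TestNonparametricHazardRatio:
    @pytest.fixture(scope="class")
    def hr_setup(self):
        """Two-token model with a planted permanent x3 multiplier."""
        from lifecourse.simulate import HazardModel
        from lifecourse.vocab import build_vocabulary

        vocab = build_vocabulary(["A", "B"])
        V = len(vocab)
        intercept = np.full(V, -np.inf)
        # source kept rare: controls acquiring the source during follow-up
        # dilute the crude (uncensored) comparison-group hazard
        intercept[vocab.index("A")] = np.log(0.02 / DAYS_PER_YEAR)
        intercept[vocab.index("B")] = np.log(0.01 / DAYS_PER_YEAR)
        hm = HazardModel(
            vocab, intercept, np.zeros(V), np.zeros(V),
            inter_source=np.array([vocab.index("A")]),
            inter_target=np.array([vocab.index("B")]),
            inter_beta=np.array([np.log(3.0)]),
            inter_halflife=np.array([np.inf]),
        )
        cohort = simulate_cohort(1500, hm, seed=5, max_age_years=60,
                                 recruitment_age_years=None)
        return vocab, cohort

    def test_planted_multiplier_in_plateau(self, hr_setup):
        vocab, cohort = hr_setup
        hr = hazard_ratio_nonparametric(
            cohort, vocab, vocab.index("A"), vocab.index("B"),
            controls_per_case=5, kernel_bandwidth_years=2.0,
            grid_years=np.linspace(1, 8, 15), seed=0,
        )
        assert len(hr) > 0
        assert np.all(hr["hr"] > 0)
        plateau = hr["hr"].median()
        assert 1.8 < plateau < 5.0

    def test_no_effect_pair_near_unity(self):
        from lifecourse.simulate import HazardModel
        from lifecourse.vocab import build_vocabulary

        vocab = build_vocabulary(["A", "B"])
        V = len(vocab)
        intercept = np.full(V, -np.inf)
        intercept[vocab.index("A")] = np.log(0.08 / DAYS_PER_YEAR)
        intercept[vocab.index("B")] = np.log(0.02 / DAYS_PER_YEAR)
        hm = HazardModel(vocab, intercept, np.zeros(V), np.zeros(V))
        cohort = simulate_cohort(1500, hm, seed=6, max_age_years=60,
                                 recruitment_age_years=None)
        hr = hazard_ratio_nonparametric(
            cohort, vocab, vocab.index("A"), vocab.index("B"),
            kernel_bandwidth_years=3.0, grid_years=np.linspace(2, 12, 15),
            seed=0,
        )
        assert 0.6 < hr["hr"].median() < 1.6

    def test_concordance_with_time_resolved_attribution(self, hr_setup):
        """The nonparametric hazard ratio and the masking attribution
        agree on the sign of a planted effect."""
        from lifecourse.simulate import HazardModel, OracleRateModel

        vocab, cohort = hr_setup
        hr = hazard_ratio_nonparametric(
            cohort, vocab, vocab.index("A"), vocab.index("B"),
            kernel_bandwidth_years=3.0, grid_years=np.linspace(2, 12, 15),
            seed=0,
        )
        intercept = np.full(len(vocab), -np.inf)
        intercept[vocab.index("A")] = np.log(0.08 / DAYS_PER_YEAR)
        intercept[vocab.index("B")] = np.log(0.01 / DAYS_PER_YEAR)
        hm = HazardModel(
            vocab, intercept, np.zeros(len(vocab)), np.zeros(len(vocab)),
            inter_source=np.array([vocab.index("A")]),
            inter_target=np.array([vocab.index("B")]),
            inter_beta=np.array([np.log(3.0)]),
            inter_halflife=np.array([np.inf]),
        )
        oracle = OracleRateModel(hm, exclude_occurred=False)
        traj = make_traj(vocab, [(0.0, "sex_female"), (40.0, "A"),
                                 (45.0, "no_event")])
        res = shapley_attribution(traj, oracle, targets=vocab.index("B"))
        k = np.flatnonzero(res.tokens == vocab.index("A"))[0]
        assert np.sign(res.phi[k, 0]) == np.sign(np.log(hr["hr"].median()))


class TestEmbeddings:
    def test_matrix_shape_and_neighbours(self, trained_tiny):
        emb, nb = export_embeddings(trained_tiny.network, top_k=3)
        v = trained_tiny.vocab
        assert emb.shape == (len(v), trained_tiny.config.embed_dim)
        assert len(nb) == len(v)
        assert all(len(x) == 3 for x in nb["neighbours"])

    def test_paper_scale_embedding_is_1270_by_120(self):
        from lifecourse.model import ModelConfig, TrajectoryTransformer
        from lifecourse.vocab import build_vocabulary

        vocab = build_vocabulary([f"C{i:04d}" for i in range(1256)])
        net = TrajectoryTransformer(ModelConfig.paper_scale(len(vocab)), vocab)
        emb, _ = export_embeddings(net, top_k=1)
        assert emb.shape == (1270, 120)
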