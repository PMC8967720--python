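import numpy as np
import pandas as pd
import pytest

from ceakit.cea import CEEstimate
from ceakit.markov import (
    DEAD,
    N_SPPB,
    N_STATES,
    ConstantTransitionModel,
    IdentityTransitionModel,
    LifeTable,
    MarkovSpec,
    StateValues,
    build_transition_matrix,
    fit_state_values,
    fit_transition_model,
    lifetime_cea,
    population_weighted,
    run_cohort,
    snap_to_age_grid,
    start_distribution_from_sppb,
    transition_provider,
)
from ceakit.synthetic import generate_ordinal_panel


def flat_values(cost=1000.0, utility=0.7):
    return StateValues(
        annual_cost=np.full(N_SPPB, cost), utility=np.full(N_SPPB, utility)
    )


def uniform_start():
    return np.full(N_SPPB, 1.0 / N_SPPB)


@pytest.fixture(scope="module")
def fitted_model():
    panel, truth = generate_ordinal_panel(5000, seed=8)
    return fit_transition_model(panel), truth


class TestFitTransitionModel:
    def test_parameter_recovery_within_2se(self, fitted_model):
        model, truth = fitted_model
        for est, se, true in zip(model.params[:3], model.bse[:3], truth["beta"]):
            assert abs(est - true) < 2 * se

    def test_probabilities_sum_to_one(self, fitted_model):
        model, _ = fitted_model
        for s in (0, 5, 12):
            for age in (65, 80, 95):
                probs = model.predict_probs(s, age, 1)
                assert probs.sum() == pytest.approx(1.0, abs=1e-9)
                assert (probs >= 0).all()

    def test_persistent_panel_modal_next_is_current(self):
        states = np.repeat(np.arange(2, 11), 40)
        panel = pd.DataFrame(
            {"sppb": states, "sppb_next": states,
             "age": np.full(states.size, 75.0),
             "female": np.tile([0, 1], states.size // 2)}
        )
        model = fit_transition_model(panel)
        for s in range(2, 11):
            probs = model.predict_probs(s, 75.0, 1)
            assert probs.argmax() == s

    def test_single_next_state_flagged_degenerate(self):
        panel = pd.DataFrame(
            {"sppb": [3, 4, 5, 6], "sppb_next": [7, 7, 7, 7],
             "age": [70.0] * 4, "female": [0, 1, 0, 1]}
        )
        model = fit_transition_model(panel)
        assert model.degenerate
        probs = model.predict_probs(5, 70.0, 0)
        assert probs[7] == 1.0

    def test_out_of_range_sppb_rejected(self):
        panel = pd.DataFrame(
            {"sppb": [3, 13], "sppb_next": [4, 5], "age": [70.0, 71.0],
             "female": [0, 1]}
        )
        with pytest.raises(ValueError, match="0..12"):
            fit_transition_model(panel)


class TestBuildTransitionMatrix:
    def lt(self, q):
        return LifeTable(pd.DataFrame(
            {"age": [75, 75], "female": [0, 1], "qx": [q, q]}
        ))

    def test_certain_death(self):
        P = build_transition_matrix(IdentityTransitionModel(), 75, 1, self.lt(0.999999))
        assert np.allclose(P[:N_SPPB, DEAD], 0.999999)

    def test_no_death_identity_model(self):
        P = build_transition_matrix(IdentityTransitionModel(), 75, 1, self.lt(1e-9))
        assert np.allclose(np.diag(P)[:N_SPPB], 1.0 - 1e-9)

    def test_uniform_model_hand_arithmetic(self):
        class Uniform:
            degenerate = False

            def predict_probs(self, s, age, female):
                return np.full(N_SPPB, 1.0 / N_SPPB)

        P = build_transition_matrix(Uniform(), 75, 0, self.lt(0.1))
        assert np.allclose(P[:N_SPPB, :N_SPPB], 0.9 / 13)
        assert np.allclose(P[:N_SPPB, DEAD], 0.1)
        assert P[DEAD, DEAD] == 1.0

    def test_rows_stochastic(self, fitted_model, life_table):
        model, _ = fitted_model
        for age in range(65, 100, 5):
            P = build_transition_matrix(model, age, 1, life_table)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)


class TestRunCohort:
    def constant_provider(self, P):
        return lambda age: P

    def test_all_dead_start(self):
        start = np.zeros(N_STATES)
        start[DEAD] = 1.0
        spec = MarkovSpec(75, 1, start, horizon=10)
        P = np.eye(N_STATES)
        trace = run_cohort(spec, self.constant_provider(P), flat_values())
        assert trace.discounted_qaly == 0.0
        assert trace.discounted_cost == 0.0

    def test_identity_ten_cycles_undiscounted(self):
        start = np.zeros(N_STATES)
        start[6] = 1.0
        spec = MarkovSpec(75, 1, start, discount_rate=0.0, horizon=10)
        trace = run_cohort(
            spec, self.constant_provider(np.eye(N_STATES)), flat_values(utility=0.7)
        )
        assert trace.discounted_qaly == pytest.approx(7.0)

    def test_toy_matrix_power_oracle(self):
        # two living states (0, 1) + dead; occupancy after t cycles must
        # equal start @ P^t (numpy matrix power as independent oracle)
        P = np.eye(N_STATES)
        P[0, 0], P[0, 1], P[0, DEAD] = 0.6, 0.3, 0.1
        P[1, 0], P[1, 1], P[1, DEAD] = 0.2, 0.7, 0.1
        start = np.zeros(N_STATES)
        start[0], start[1] = 0.5, 0.5
        spec = MarkovSpec(75, 1, start, horizon=3)
        trace = run_cohort(spec, self.constant_provider(P), flat_values())
        for t in range(4):
            expected = start @ np.linalg.matrix_power(P, t)
            assert np.allclose(trace.occupancy[t], expected, atol=1e-12)

    def test_identical_starts_zero_increment(self, fitted_model, life_table):
        model, _ = fitted_model
        start = uniform_start()
        values = StateValues(
            annual_cost=5000 - 200 * np.arange(N_SPPB),
            utility=0.5 + 0.03 * np.arange(N_SPPB),
        )
        spec = MarkovSpec(75, 1, start)
        result = lifetime_cea(0.0, 0.0, start, start, spec, model, values, life_table)
        assert result.delta_cost == 0.0
        assert result.delta_qaly == 0.0

    def test_occupancy_conserved_and_dead_monotone(self, fitted_model, life_table):
        model, _ = fitted_model
        spec = MarkovSpec(70, 0, uniform_start())
        provider = transition_provider(model, 0, life_table)
        trace = run_cohort(spec, provider, flat_values())
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.diff(trace.occupancy[:, DEAD]) >= -1e-12)

    def test_discounted_below_undiscounted(self, fitted_model, life_table):
        model, _ = fitted_model
        spec = MarkovSpec(75, 1, uniform_start(), discount_rate=0.035)
        provider = transition_provider(model, 1, life_table)
        trace = run_cohort(spec, provider, flat_values())
        assert trace.discounted_cost < trace.undiscounted_cost
        assert trace.discounted_qaly < trace.undiscounted_qaly

    def test_band_life_years_sum_to_life_expectancy(self, fitted_model, life_table):
        model, _ = fitted_model
        spec = MarkovSpec(65, 1, uniform_start())
        provider = transition_provider(model, 1, life_table)
        trace = run_cohort(spec, provider, flat_values())
        total_bands = sum(trace.life_years_by_band.values())
        assert total_bands == pytest.approx(trace.life_expectancy, abs=1e-9)

    def test_zero_horizon(self):
        spec = MarkovSpec(75, 1, uniform_start(), horizon=0)
        trace = run_cohort(spec, lambda age: np.eye(N_STATES), flat_values())
        assert trace.discounted_qaly == 0.0
        assert trace.occupancy.shape == (1, N_STATES)

    def test_half_cycle_correction_reduces_accrual(self, fitted_model, life_table):
        model, _ = fitted_model
        provider = transition_provider(model, 1, life_table)
        base = run_cohort(MarkovSpec(75, 1, uniform_start()), provider, flat_values())
        hcc = run_cohort(
            MarkovSpec(75, 1, uniform_start(), half_cycle_correction=True),
            provider,
            flat_values(),
        )
        assert hcc.discounted_qaly < base.discounted_qaly


class TestMortalityNeutrality:
    def test_life_expectancy_identical_across_arms(self, fitted_model, life_table):
        model, _ = fitted_model
        rng = np.random.default_rng(0)
        start_int = rng.dirichlet(np.ones(N_SPPB))
        start_ctl = rng.dirichlet(np.ones(N_SPPB))
        provider = transition_provider(model, 1, life_table)
        traces = [
            run_cohort(MarkovSpec(75, 1, s), provider, flat_values())
            for s in (start_int, start_ctl)
        ]
        assert traces[0].life_expectancy == pytest.approx(
            traces[1].life_expectancy, abs=1e-9
        )

    def test_dominating_start_gains_qalys(self, fitted_model, life_table):
        model, _ = fitted_model
        start_ctl = np.zeros(N_SPPB)
        start_ctl[4] = 1.0
        start_int = np.zeros(N_SPPB)
        start_int[8] = 1.0
        values = StateValues(
            annual_cost=np.full(N_SPPB, 1000.0),
            utility=0.4 + 0.04 * np.arange(N_SPPB),
        )
        spec = MarkovSpec(75, 1, start_int)
        result = lifetime_cea(
            0.0, 0.0, start_int, start_ctl, spec, model, values, life_table
        )
        assert result.delta_qaly > 0


class TestFitStateValues:
    def test_exact_linear_recovery(self):
        s = np.tile(np.arange(N_SPPB), 10)
        data = pd.DataFrame(
            {"sppb": s, "annual_cost": 5000.0 - 200.0 * s, "utility": 0.5 + 0.02 * s}
        )
        values = fit_state_values(data)
        assert np.allclose(values.annual_cost, 5000.0 - 200.0 * np.arange(N_SPPB))
        assert np.allclose(values.utility, 0.5 + 0.02 * np.arange(N_SPPB))

    def test_constant_utility(self):
        s = np.tile(np.arange(N_SPPB), 5)
        data = pd.DataFrame(
            {"sppb": s, "annual_cost": np.full(s.size, 100.0),
             "utility": np.full(s.size, 0.7)}
        )
        values = fit_state_values(data)
        assert np.allclose(values.utility, 0.7)

    def test_noisy_slope_recovery(self):
        rng = np.random.default_rng(2)
        s = rng.integers(0, 13, 2000)
        data = pd.DataFrame(
            {
                "sppb": s,
                "annual_cost": 3000 - 100 * s + rng.normal(0, 500, s.size),
                "utility": 0.5 + 0.03 * s + rng.normal(0, 0.1, s.size),
            }
        )
        values = fit_state_values(data)
        slope = (values.utility[12] - values.utility[0]) / 12
        se = 0.1 / np.sqrt(s.size) / np.std(s)  # approximate slope SE
        assert abs(slope - 0.03) < 2 * se * 3  # generous
        assert np.all(np.diff(values.utility) >= 0)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            fit_state_values(pd.DataFrame(columns=["sppb", "annual_cost", "utility"]))


class TestAggregation:
    def test_single_profile_weight_one(self):
        est = CEEstimate(delta_cost=-100.0, delta_qaly=0.05)
        result = population_weighted([est], [1.0])
        assert result.delta_cost == -100.0
        assert result.delta_qaly == 0.05

    def test_opposite_deltas_cancel(self):
        a = CEEstimate(delta_cost=50.0, delta_qaly=0.02)
        b = CEEstimate(delta_cost=-50.0, delta_qaly=-0.02)
        result = population_weighted([a, b], [0.5, 0.5])
        assert result.delta_cost == pytest.approx(0.0)
        assert result.delta_qaly == pytest.approx(0.0)

    def test_hand_computed_weighted_mean(self):
        results = [
            CEEstimate(delta_cost=-290.0, delta_qaly=0.072),
            CEEstimate(delta_cost=-200.0, delta_qaly=0.058),
        ]
        agg = population_weighted(results, [0.66, 0.34])
        assert agg.delta_cost == pytest.approx(0.66 * -290 + 0.34 * -200)
        assert agg.delta_qaly == pytest.approx(0.66 * 0.072 + 0.34 * 0.058)

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            population_weighted([CEEstimate(0, 0)], [0.9])


class TestHelpers:
    def test_start_distribution_histogram(self):
        dist = start_distribution_from_sppb([4, 4, 8, 12])
        assert dist[4] == pytest.approx(0.5)
        assert dist[8] == pytest.approx(0.25)
        assert dist.sum() == pytest.approx(1.0)

    def test_mean_age_maps_to_grid(self):
        assert snap_to_age_grid(77) == 75
        assert snap_to_age_grid(83) == 85

    def test_life_table_validation(self):
        with pytest.raises(ValueError, match="\\(0, 1\\)"):
            LifeTable(pd.DataFrame({"age": [70], "female": [1], "qx": [1.5]}))

    def test_equal_start_trial_deltas_pass_through(self, fitted_model, life_table):
        model, _ = fitted_model
        start = uniform_start()
        spec = MarkovSpec(75, 1, start)
        result = lifetime_cea(
            -103.0, 0.040, start, start, spec, model, flat_values(), life_table
        )
        assert result.delta_cost == pytest.approx(-103.0)
        assert result.delta_qaly == pytest.approx(0.040)
        assert result.icer.label == "dominant"
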