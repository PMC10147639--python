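"""Plasticity kernels and weight dynamics: closed forms, bounds, Dale signs."""

import numpy as np
import pytest

from thetanet import (
    EXCITATORY,
    INHIBITORY,
    EPS_NUM,
    NetworkState,
    PlasticityRule,
    kernel_lambda0,
    kernel_lambda1,
    kernel_table,
    update_weights,
    weight_derivative,
)
from thetanet.plasticity import DEPRESSION_SCALE, POTENTIATION_SCALE


class TestKernels:
    @pytest.mark.parametrize(
        "dtheta, expected",
        [(0.0, 1.0), (np.pi, -1.0), (np.pi / 2, 0.0)],
    )
    def test_cosine_kernel_values(self, dtheta, expected):
        assert kernel_lambda0(dtheta) == pytest.approx(expected, abs=1e-12)

    def test_asymmetric_kernel_at_zero(self):
        # both branches give 1 - exp(-2*pi) at the join
        assert kernel_lambda1(0.0) == pytest.approx(1.0 - np.exp(-2.0 * np.pi), abs=1e-12)

    def test_asymmetric_kernel_at_minus_pi(self):
        assert kernel_lambda1(-np.pi) == pytest.approx(
            np.exp(-10.0 * np.pi) - 1.0, abs=1e-12
        )

    def test_two_pi_periodicity(self):
        for d in (0.3, -1.2, 2.9):
            assert kernel_lambda1(d) == pytest.approx(kernel_lambda1(d + 2 * np.pi), abs=1e-12)
            assert kernel_lambda1(d) == pytest.approx(kernel_lambda1(d - 2 * np.pi), abs=1e-12)

    def test_kernels_are_even(self):
        grid = np.linspace(1e-9, np.pi - 1e-9, 101)
        np.testing.assert_allclose(kernel_lambda1(grid), kernel_lambda1(-grid), atol=1e-12)
        np.testing.assert_allclose(kernel_lambda0(grid), kernel_lambda0(-grid), atol=1e-12)

    def test_continuity_at_branch_joins(self):
        eps = 1e-12
        assert abs(kernel_lambda1(-eps) - kernel_lambda1(0.0)) < 1e-9
        assert abs(kernel_lambda1(np.pi - eps) - kernel_lambda1(-np.pi)) < 1e-9

    def test_depression_window_five_times_potentiation_window(self):
        # the defining e-fold constants ...
        assert DEPRESSION_SCALE / POTENTIATION_SCALE == 5.0
        # ... and the function actually decays at those rates: fit log-slopes
        # on stretches where the opposite lobe's contribution is negligible
        x_pot = np.linspace(0.05, 0.25, 20)
        slope_pot = np.polyfit(x_pot, np.log(kernel_lambda1(x_pot)), 1)[0]
        x_dep = np.linspace(2.3, 2.9, 20)
        slope_dep = np.polyfit(x_dep, np.log(-kernel_lambda1(x_dep)), 1)[0]
        ratio = (1.0 / slope_dep) / (-1.0 / slope_pot)
        assert ratio == pytest.approx(5.0, rel=0.03)

    def test_kernel_extrema_agree_within_tolerance(self):
        grid = np.linspace(-np.pi, np.pi, 200001)
        l0, l1 = kernel_lambda0(grid), kernel_lambda1(grid)
        assert abs(l0.max() - l1.max()) < 2e-3
        assert abs(l0.min() - l1.min()) < 2e-3
        # extrema located at matching phases: max near 0, min near +-pi
        assert abs(grid[np.argmax(l1)]) < 0.05
        assert abs(abs(grid[np.argmin(l1)]) - np.pi) < 0.05

    def test_kernel_table_matches_function_and_wraps(self):
        tab = kernel_table("asymmetric_exponential", size=4096)
        assert tab[0] == pytest.approx(tab[-1], abs=1e-12)  # 2*pi periodic ends
        grid = np.linspace(-np.pi, np.pi, 4097)
        np.testing.assert_allclose(tab, kernel_lambda1(grid), atol=1e-12)


class TestWeightDerivative:
    def test_soft_bounds_are_absorbing(self, ei_rule):
        for kappa in (0.0, 1.0):
            assert weight_derivative(kappa, 0.3, EXCITATORY, EXCITATORY, True, ei_rule) == 0.0

    def test_fast_gate_only_for_excitatory_pairs(self, ei_rule):
        slow = weight_derivative(0.5, 0.0, EXCITATORY, INHIBITORY, True, ei_rule)
        fast = weight_derivative(0.5, 0.0, EXCITATORY, EXCITATORY, True, ei_rule)
        ungated = weight_derivative(0.5, 0.0, EXCITATORY, EXCITATORY, False, ei_rule)
        lam = kernel_lambda1(0.0)
        assert slow == pytest.approx(ei_rule.eps_slow * 0.25 * lam)
        assert ungated == pytest.approx(ei_rule.eps_slow * 0.25 * lam)
        assert fast == pytest.approx((ei_rule.eps_slow + ei_rule.eps_fast) * 0.25 * lam)

    def test_inhibitory_synapse_weakens_in_phase_strengthens_anti_phase(self, ei_rule):
        # in phase: dkappa > 0, i.e. towards 0 (inhibition fades)
        assert weight_derivative(-0.5, 0.0, INHIBITORY, EXCITATORY, False, ei_rule) > 0
        # anti-phase: dkappa < 0, i.e. towards -1 (inhibition consolidates)
        assert weight_derivative(-0.5, np.pi, INHIBITORY, EXCITATORY, False, ei_rule) < 0

    def test_out_of_bound_weight_rejected(self, ei_rule):
        with pytest.raises(ValueError):
            weight_derivative(1.5, 0.0, EXCITATORY, EXCITATORY, False, ei_rule)
        with pytest.raises(ValueError):
            weight_derivative(0.5, 0.0, INHIBITORY, EXCITATORY, False, ei_rule)

    def test_unlabelled_relaxation_matches_closed_form(self):
        # dkappa/dt = eps * (Lambda_0 - kappa) at fixed phase difference has the
        # exponential solution kappa(t) = L + (k0 - L) exp(-eps t)
        rule = PlasticityRule(kernel="cosine", eps_slow=0.01, eps_fast=0.1,
                              dale_mode="unlabelled")
        dtheta, k0, dt = 0.8, -0.4, 0.01
        lam = kernel_lambda0(dtheta)
        k = k0
        for _ in range(5000):
            k += weight_derivative(k, dtheta, 0, 0, False, rule) * dt
        t = 5000 * dt
        expected = lam + (k0 - lam) * np.exp(-rule.eps_slow * t)
        assert k == pytest.approx(expected, abs=1e-4)

    def test_rate_ordering_enforced(self):
        with pytest.raises(ValueError):
            PlasticityRule(eps_slow=0.2, eps_fast=0.1)
        with pytest.raises(ValueError):
            PlasticityRule(eps_slow=0.0, eps_fast=0.1)


def make_pair_state(phases, types):
    n = len(phases)
    w = np.full((n, n), 0.5)
    np.fill_diagonal(w, 0.0)
    sgn = np.where(np.asarray(types) == INHIBITORY, -1.0, 1.0)
    return NetworkState(
        phases=np.asarray(phases, dtype=float),
        weights=w * sgn[None, :],
        types=np.asarray(types, dtype=np.int8),
        excitabilities=np.full(n, 1.5),
    )


class TestUpdateWeights:
    def test_in_phase_excitatory_weights_increase(self, ei_rule):
        state = make_pair_state([0.2, 0.2, 0.2], [EXCITATORY] * 3)
        before = state.weights.copy()
        update_weights(state, np.zeros(3), ei_rule, 0.01)
        off = ~np.eye(3, dtype=bool)
        assert np.all(state.weights[off] > before[off])

    def test_anti_phase_excitatory_weights_decrease(self, ei_rule):
        state = make_pair_state([0.0, -np.pi], [EXCITATORY] * 2)
        before = state.weights.copy()
        update_weights(state, np.zeros(2), ei_rule, 0.01)
        off = ~np.eye(2, dtype=bool)
        assert np.all(state.weights[off] < before[off])

    def test_unstimulated_step_size_bound(self, ei_rule, config, rng):
        from thetanet import init_network

        state = init_network(30, 6, "ei", config, rng)
        before = state.weights.copy()
        update_weights(state, np.zeros(30), ei_rule, 0.01)
        bound = ei_rule.eps_slow * 0.01 * 0.25 * 1.0 + 1e-15
        assert np.max(np.abs(state.weights - before)) <= bound

    def test_diagonal_untouched(self, ei_rule, small_ei_state):
        update_weights(small_ei_state, np.zeros(20), ei_rule, 0.01)
        assert np.all(np.diag(small_ei_state.weights) == 0.0)

    def test_dale_signs_preserved_under_stimulated_noisy_evolution(self, rng):
        # several hundred joint phase/weight steps with strong stimulation:
        # excitatory columns must never go negative, inhibitory never positive
        from thetanet import SimulationConfig, init_network, step

        cfg = SimulationConfig()
        rule = PlasticityRule(eps_slow=1e-3, eps_fast=0.3)  # exaggerated rates
        state = init_network(12, 3, "ei", cfg, rng)
        currents = np.zeros(12)
        currents[:4] = 3.0
        for _ in range(300):
            step(state, currents, cfg, rng)
            update_weights(state, currents, rule, cfg.dt)
        exc = state.types == EXCITATORY
        assert np.all(state.weights[:, exc] >= 0.0)
        assert np.all(state.weights[:, ~exc] <= 0.0)
        assert np.all(np.abs(state.weights) <= 1.0)

    def test_weights_stay_in_unit_interval_unlabelled(self, rng):
        from thetanet import SimulationConfig, init_network, step

        cfg = SimulationConfig()
        rule = PlasticityRule(kernel="cosine", eps_slow=0.05, eps_fast=0.5,
                              dale_mode="unlabelled")
        state = init_network(10, 0, "unlabelled", cfg, rng)
        currents = np.zeros(10)
        currents[:5] = 3.0
        for _ in range(300):
            step(state, currents, cfg, rng)
            update_weights(state, currents, rule, cfg.dt)
        assert np.all(np.abs(state.weights) <= 1.0)

    def test_reciprocal_weights_equalise_in_the_long_run(self):
        # an unstimulated E-E pair at fixed anti-phase: both weights decay to
        # the lower soft bound and their difference vanishes
        rule = PlasticityRule(eps_slow=0.05, eps_fast=0.5)
        state = make_pair_state([0.0, -np.pi], [EXCITATORY] * 2)
        state.weights[0, 1], state.weights[1, 0] = 0.9, 0.7
        initial_gap = 0.2
        for _ in range(10000):
            update_weights(state, np.zeros(2), rule, 0.01)
        gap = abs(state.weights[0, 1] - state.weights[1, 0])
        assert gap < 0.25 * initial_gap
        assert max(state.weights[0, 1], state.weights[1, 0]) < 0.1

    def test_interior_clamp_reactivates_saturated_weights(self, ei_rule):
        # exact 0/1 weights sit on absorbing bounds; one update nudges them
        # into the interior so pre-trained matrices stay adaptable
        state = make_pair_state([0.0, 0.1], [EXCITATORY] * 2)
        state.weights[0, 1], state.weights[1, 0] = 0.0, 1.0
        update_weights(state, np.zeros(2), ei_rule, 0.01)
        assert state.weights[0, 1] >= EPS_NUM
        assert state.weights[1, 0] <= 1.0 - EPS_NUM
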