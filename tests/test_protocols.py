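"""Stimulation schedules and pre-trained matrix construction."""

import numpy as np
import pytest

from thetanet import (
    EXCITATORY,
    INHIBITORY,
    ModuleLayout,
    SimulationConfig,
    StimulusSchedule,
    StimulusBlock,
    build_learning_schedule,
    build_pretrained_matrix,
    init_network,
    modular_layout,
    pretrained_state,
    scramble_excitatory_weights,
)


class TestLearningSchedule:
    def test_default_entrainment_shape(self, rng):
        groups = [np.arange(0, 40), np.arange(40, 80)]
        sched = build_learning_schedule(groups, rng=rng)
        assert len(sched.blocks) == 50
        assert sched.blocks[0].t_start == 200.0
        assert all(b.t_end - b.t_start == 20.0 for b in sched.blocks)
        assert all(b.amplitude == 3.0 for b in sched.blocks)
        # contiguous blocks, no gap
        assert sched.total_duration == 200.0 + 50 * 20.0
        # every block targets exactly one of the two groups
        for b in sched.blocks:
            assert any(np.array_equal(b.targets, g) for g in groups)

    def test_random_order_covers_all_groups(self, rng):
        groups = [np.arange(10), np.arange(10, 20), np.arange(20, 30)]
        sched = build_learning_schedule(groups, n_blocks=60, rng=rng)
        firsts = {int(b.targets[0]) for b in sched.blocks}
        assert firsts == {0, 10, 20}

    def test_strict_alternation_round_robin(self):
        groups = [np.arange(5), np.arange(5, 10)]
        sched = build_learning_schedule(
            groups, n_blocks=4, strict_alternation=True, gap=5.0
        )
        order = [int(b.targets[0]) for b in sched.blocks]
        assert order == [0, 5, 0, 5]
        # inter-block gap respected
        assert sched.blocks[1].t_start - sched.blocks[0].t_end == 5.0

    def test_zero_blocks_is_pure_rest(self):
        sched = build_learning_schedule([np.arange(5)], n_blocks=0,
                                        rest_before=30.0, rest_after=20.0)
        assert sched.blocks == []
        assert sched.total_duration == 50.0

    def test_empty_group_rejected(self, rng):
        with pytest.raises(ValueError):
            build_learning_schedule([np.empty(0, dtype=int)], rng=rng)

    def test_currents_and_segments_consistent(self, rng):
        groups = [np.arange(3)]
        sched = build_learning_schedule(
            groups, block_len=2.0, n_blocks=2, rest_before=1.0, gap=1.0, rng=rng
        )
        cur = sched.currents_at(1.5, 6)
        assert cur[0] == 3.0 and cur[5] == 0.0
        assert np.all(sched.currents_at(0.5, 6) == 0.0)
        cover = list(sched.segments(6))
        assert cover[0][0] == 0.0
        assert cover[-1][1] == sched.total_duration
        # segments tile the timeline without holes
        for (a, b, _), (c, d, _) in zip(cover, cover[1:]):
            assert b == c

    def test_schedule_never_targets_inhibitory(self, config, rng):
        state = init_network(10, 2, "ei", config, rng)
        bad = StimulusSchedule(
            blocks=[StimulusBlock(0.0, 1.0, np.array([9]), 3.0)], total_duration=2.0
        )
        with pytest.raises(ValueError):
            bad.validate_against(state)

    def test_schedule_round_trips_through_plain_data(self, rng):
        groups = [np.arange(3), np.arange(3, 6)]
        sched = build_learning_schedule(groups, block_len=2.0, n_blocks=3,
                                        rest_before=1.0, rng=rng)
        back = StimulusSchedule.from_dict(sched.to_dict())
        assert back.total_duration == sched.total_duration
        assert len(back.blocks) == len(sched.blocks)
        for a, b in zip(sched.blocks, back.blocks):
            assert (a.t_start, a.t_end, a.amplitude) == (b.t_start, b.t_end, b.amplitude)
            np.testing.assert_array_equal(a.targets, b.targets)

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError):
            StimulusSchedule(
                blocks=[
                    StimulusBlock(0.0, 2.0, np.array([0]), 3.0),
                    StimulusBlock(1.0, 3.0, np.array([1]), 3.0),
                ]
            )


class TestPretrainedMatrix:
    def test_two_module_block_structure(self):
        layout = modular_layout(100, 2, 20)
        w = build_pretrained_matrix(100, layout)
        types = layout.types()
        c1, c2 = layout.clusters
        # saturated intra-cluster, pruned inter-cluster excitation
        assert np.all(w[np.ix_(c1, c1)][~np.eye(40, dtype=bool)] == 1.0)
        assert np.all(w[np.ix_(c1, c2)] == 0.0)
        # feedforward E->I from own cluster only
        inh = np.flatnonzero(types == INHIBITORY)
        own = [i for i in inh if layout.inhibitory_assignment[int(i)] == 0]
        other = [i for i in inh if layout.inhibitory_assignment[int(i)] == 1]
        assert np.all(w[np.ix_(own, c1)] == 1.0)
        assert np.all(w[np.ix_(own, c2)] == 0.0)
        # I->E onto the opposite cluster only
        assert np.all(w[np.ix_(c2, own)] == -1.0)
        assert np.all(w[np.ix_(c1, own)] == 0.0)
        # I->I across clusters
        assert np.all(w[np.ix_(other, own)] == -1.0)

    def test_output_is_ternary_and_dale_consistent(self):
        layout = modular_layout(60, 3, 9, n_hubs=3)
        w = build_pretrained_matrix(60, layout)
        types = layout.types()
        assert set(np.unique(w)) <= {-1.0, 0.0, 1.0}
        assert np.all(w[:, types == EXCITATORY] >= 0)
        assert np.all(w[:, types == INHIBITORY] <= 0)
        assert np.all(np.diag(w) == 0)

    def test_single_module_has_no_inhibition_targets(self):
        layout = modular_layout(20, 1, 4)
        w = build_pretrained_matrix(20, layout)
        inh = np.arange(16, 20)
        assert np.all(w[:, inh] == 0.0)  # nothing to repel
        assert np.all(w[np.ix_(np.arange(16), np.arange(16))][~np.eye(16, dtype=bool)] == 1.0)

    def test_hubs_excite_every_module_and_receive_no_inhibition(self):
        layout = modular_layout(30, 2, 4, n_hubs=4)
        w = build_pretrained_matrix(30, layout)
        hubs = layout.hubs
        for cluster in layout.clusters:
            assert np.all(w[np.ix_(cluster, hubs)] == 1.0)
        inh = np.arange(26, 30)
        assert np.all(w[np.ix_(hubs, inh)] == 0.0)

    def test_splay_construction_one_pair_per_module(self):
        # N/2 modules, each a single excitatory + single inhibitory neuron
        N = 12
        layout = modular_layout(N, N // 2, N // 2)
        w = build_pretrained_matrix(N, layout)
        types = layout.types()
        assert np.sum(types == INHIBITORY) == N // 2
        from thetanet import count_structural_modules

        assert count_structural_modules(w, types) == N // 2

    def test_inconsistent_layout_rejected(self):
        with pytest.raises(ValueError):
            ModuleLayout(
                clusters=[np.arange(4)], inhibitory_assignment={4: 3}
            )
        layout = modular_layout(20, 2, 4)
        with pytest.raises(ValueError):
            build_pretrained_matrix(21, layout)

    def test_round_robin_assignment_when_fewer_inhibitory_than_modules(self):
        layout = modular_layout(20, 3, 2)
        assigned = set(layout.inhibitory_assignment.values())
        assert assigned == {0, 1}  # third module simply has none


class TestScramble:
    def test_inhibitory_connections_preserved_and_ee_redrawn(self, rng):
        cfg = SimulationConfig()
        layout = modular_layout(100, 2, 20)
        state = pretrained_state(100, layout, cfg, rng)
        before = state.weights.copy()
        scramble_excitatory_weights(state, rng)
        inh = np.arange(80, 100)
        np.testing.assert_array_equal(state.weights[:, inh], before[:, inh])
        np.testing.assert_array_equal(state.weights[inh, :], before[inh, :])
        ee = state.weights[np.ix_(np.arange(80), np.arange(80))]
        off = ~np.eye(80, dtype=bool)
        # uniform redraw: empirical mean within 3 standard errors of 1/2
        se = np.sqrt(1.0 / 12.0 / off.sum())
        assert abs(ee[off].mean() - 0.5) < 3 * se
        assert np.all(np.diag(state.weights) == 0.0)

    def test_same_seed_reproducible(self, config):
        layout = modular_layout(30, 2, 6)
        a = pretrained_state(30, layout, config, np.random.default_rng(3))
        b = pretrained_state(30, layout, config, np.random.default_rng(3))
        scramble_excitatory_weights(a, np.random.default_rng(11))
        scramble_excitatory_weights(b, np.random.default_rng(11))
        np.testing.assert_array_equal(a.weights, b.weights)
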