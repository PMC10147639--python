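"""Experiment orchestration: entrainment, capacity sweeps and memory recall.

The experiments mirror a common arc: (i) a network is entrained by
temporally alternating stimuli and then left to evolve spontaneously so
that the learned modules consolidate; (ii) idealised pre-trained modular
networks are evolved spontaneously to map out how many modules survive as
a function of the number of inhibitory neurons; (iii) a consolidated
network whose excitatory weights have been scrambled is probed with brief
stimulus pulses to test memory recall.

Desk-scale consolidation
------------------------
With the literal slow rate ``eps_slow = 1e-5`` the consolidation phase
spans on the order of ``1e5`` time units.  For desk-scale runs the slow
rate is multiplied by a factor ``rho`` (default 100) and the duration
divided accordingly (default 2000 time units), preserving the separation
``eps_slow << eps_fast`` and the nominal number of plasticity e-folds
(rate x duration).  Full-fidelity settings are available by passing
``ConsolidationParams(rho=1, duration=...)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from . import _fastloop
from .core import (
    INHIBITORY,
    NetworkState,
    SimulationConfig,
    SpikeRaster,
    init_network,
)
from .observables import (
    OrderParameterSeries,
    count_phase_clusters,
    count_structural_modules,
    order_parameter_series,
    recall_score,
    summarize_state,
)
from .plasticity import EPS_NUM, PlasticityRule, default_rule, kernel_table
from .protocols import (
    ModuleLayout,
    StimulusSchedule,
    build_learning_schedule,
    modular_layout,
    pretrained_state,
    split_into_groups,
)

logger = logging.getLogger("thetanet")

_TABLE_CACHE: dict[str, np.ndarray] = {}


def _lam_table(kernel: str) -> np.ndarray:
    if kernel not in _TABLE_CACHE:
        _TABLE_CACHE[kernel] = kernel_table(kernel)
    return _TABLE_CACHE[kernel]


@dataclass
class SegmentResult:
    """Sampled output of one piecewise-constant simulation segment."""

    times: np.ndarray
    phase_samples: np.ndarray
    raster: SpikeRaster


def simulate_segment(
    state: NetworkState,
    currents: np.ndarray,
    duration: float,
    rule: PlasticityRule,
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_every: float = 0.5,
    record_raster: bool = True,
    max_chunk: int = 20000,
) -> SegmentResult:
    """Advance ``state`` (in place) under constant currents.

    Runs the compiled loop in chunks, drawing the per-step noise
    increments from ``rng`` chunk by chunk (row = step), and sampling the
    phase vector every ``sample_every`` time units.
    """
    currents = np.asarray(currents, dtype=float)
    n_steps = int(round(duration / config.dt))
    # sample_every <= 0 disables phase sampling
    stride = 0 if sample_every <= 0 else max(1, int(round(sample_every / config.dt)))
    gate = np.abs(currents) > rule.gate_threshold
    mode = (
        _fastloop.MODE_UNLABELLED
        if rule.dale_mode == "unlabelled"
        else _fastloop.MODE_DALE
    )
    table = _lam_table(rule.kernel)
    col_sign = state.column_signs()
    is_exc = state.types == 1
    sigma = config.noise_std

    all_times, all_samples, rasters = [], [], []
    t_seg0 = state.time
    done = 0
    theta = np.ascontiguousarray(state.phases)
    kappa = np.ascontiguousarray(state.weights)
    eta = np.ascontiguousarray(state.excitabilities)
    while done < n_steps:
        chunk = min(max_chunk, n_steps - done)
        if sigma > 0.0:
            noise = rng.standard_normal((chunk, state.n))
        else:
            noise = np.zeros((chunk, state.n))
        cap = int(chunk * config.dt * state.n * 1.2) + 64
        spike_step = np.empty(cap, dtype=np.int64)
        spike_neuron = np.empty(cap, dtype=np.int64)
        n_sample_cap = (chunk // stride + 1) if stride else 1
        samples = np.empty((n_sample_cap, state.n))
        n_spk, n_smp = _fastloop.advance(
            theta,
            kappa,
            col_sign,
            is_exc,
            eta,
            currents,
            gate,
            config.g,
            config.dt,
            sigma,
            rule.eps_slow,
            rule.eps_fast,
            EPS_NUM,
            mode,
            table,
            noise,
            done,
            stride,
            samples,
            spike_step,
            spike_neuron,
        )
        t0 = state.time + done * config.dt
        if n_smp:
            # samples were taken at global steps that are multiples of stride
            first = (done // stride + 1) * stride
            ts = t_seg0 + np.arange(first, first + n_smp * stride, stride) * config.dt
            all_times.append(ts)
            all_samples.append(samples[:n_smp].copy())
        if record_raster and n_spk:
            n_rec = min(n_spk, cap)
            rasters.append(
                SpikeRaster(
                    t0 + (spike_step[:n_rec] + 1) * config.dt,
                    spike_neuron[:n_rec].copy(),
                )
            )
        done += chunk

    state.phases = theta
    state.weights = kappa
    state.time += n_steps * config.dt
    return SegmentResult(
        times=np.concatenate(all_times) if all_times else np.empty(0),
        phase_samples=(
            np.concatenate(all_samples) if all_samples else np.empty((0, state.n))
        ),
        raster=SpikeRaster.concatenate(rasters),
    )


def run_schedule(
    state: NetworkState,
    schedule: StimulusSchedule,
    rule: PlasticityRule,
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_every: float = 0.5,
    record_raster: bool = True,
) -> SegmentResult:
    """Run an entire stimulation schedule (in place on ``state``)."""
    schedule.validate_against(state)
    parts = []
    for t_start, t_end, currents in schedule.segments(state.n):
        parts.append(
            simulate_segment(
                state,
                currents,
                t_end - t_start,
                rule,
                config,
                rng,
                sample_every=sample_every,
                record_raster=record_raster,
            )
        )
    return SegmentResult(
        times=np.concatenate([p.times for p in parts]) if parts else np.empty(0),
        phase_samples=(
            np.concatenate([p.phase_samples for p in parts])
            if parts
            else np.empty((0, state.n))
        ),
        raster=SpikeRaster.concatenate([p.raster for p in parts]),
    )


@dataclass(frozen=True)
class ConsolidationParams:
    """Desk-scale rescaling of the post-learning consolidation phase.

    The slow rate is multiplied by ``rho`` and the spontaneous-evolution
    duration is ``duration`` time units (already on the rescaled clock).
    """

    rho: float = 100.0
    duration: float = 2000.0

    def effective_rule(self, rule: PlasticityRule) -> PlasticityRule:
        eps = rule.eps_slow * self.rho
        if eps >= rule.eps_fast:
            raise ValueError(
                "consolidation rescaling must preserve eps_slow < eps_fast"
            )
        return replace(rule, eps_slow=eps)


@dataclass
class MainExperimentResult:
    """Artifacts of one entrainment + consolidation run."""

    mode: str
    snapshots: dict[str, np.ndarray]
    snapshot_times: dict[str, float]
    series: OrderParameterSeries
    raster: SpikeRaster
    state: NetworkState
    summary: dict


DEFAULT_SCHEDULE_PARAMS = dict(
    rest_before=200.0,
    block_len=20.0,
    n_blocks=50,
    amplitude=3.0,
    gap=0.0,
    strict_alternation=False,
)


def run_main_experiment(
    mode: str,
    n_stimuli: int = 2,
    *,
    N: int = 100,
    n_inhibitory: int | None = None,
    config: SimulationConfig | None = None,
    rule: PlasticityRule | None = None,
    schedule_params: dict | None = None,
    consolidation: ConsolidationParams | None = None,
    rng: np.random.Generator | None = None,
    sample_every: float = 0.1,
    record_raster: bool = False,
) -> MainExperimentResult:
    """Entrainment protocol: rest -> alternating stimuli -> consolidation.

    Weight snapshots are taken at the phase boundaries T0 (end of the
    initial rest), T1 (early in the learning phase), T2 (end of learning)
    and T3 (end of consolidation).
    """
    if rng is None:
        raise ValueError("an explicit numpy Generator is required")
    config = config or SimulationConfig()
    rule = rule or default_rule(mode)
    if rule.dale_mode != mode:
        raise ValueError(f"rule.dale_mode={rule.dale_mode!r} does not match {mode!r}")
    if n_inhibitory is None:
        n_inhibitory = 20 if mode == "ei" else 0
    consolidation = consolidation or ConsolidationParams()
    params = dict(DEFAULT_SCHEDULE_PARAMS)
    params.update(schedule_params or {})

    state = init_network(N, n_inhibitory, mode, config, rng)
    exc = state.excitatory_indices
    groups = split_into_groups(exc, n_stimuli)
    schedule = build_learning_schedule(
        groups,
        block_len=params["block_len"],
        n_blocks=params["n_blocks"],
        rest_before=params["rest_before"],
        rest_after=0.0,
        amplitude=params["amplitude"],
        gap=params["gap"],
        strict_alternation=params["strict_alternation"],
        rng=rng,
    )
    schedule.validate_against(state)

    orders = tuple(range(1, max(3, n_stimuli) + 1))
    snapshots: dict[str, np.ndarray] = {}
    snapshot_times: dict[str, float] = {}
    parts: list[SegmentResult] = []
    rasters: list[SpikeRaster] = []

    def snap(label: str) -> None:
        snapshots[label] = state.weights.copy()
        snapshot_times[label] = state.time
        s = summarize_state(state)
        logger.info(
            "%s @ t=%.1f: R1=%.3f R2=%.3f modules=%d",
            label,
            state.time,
            s["R1"],
            s["R2"],
            s["structural_modules"],
        )

    def run(seg_schedule_parts) -> None:
        for seg in seg_schedule_parts:
            parts.append(seg)
            if record_raster:
                rasters.append(seg.raster)

    # --- rest phase ---
    segs = [
        simulate_segment(
            state,
            np.zeros(N),
            params["rest_before"],
            rule,
            config,
            rng,
            sample_every=sample_every,
            record_raster=record_raster,
        )
    ]
    run(segs)
    snap("T0")

    # --- learning phase ---
    t1_time = None
    n_blocks = params["n_blocks"]
    t1_after = max(1, n_blocks // 5)  # "early during learning"
    for k, (t_start, t_end, currents) in enumerate(
        b
        for b in schedule.segments(N)
        if b[0] >= params["rest_before"] - 1e-9
    ):
        run(
            [
                simulate_segment(
                    state,
                    currents,
                    t_end - t_start,
                    rule,
                    config,
                    rng,
                    sample_every=sample_every,
                    record_raster=record_raster,
                )
            ]
        )
        if t1_time is None and np.any(currents) and k + 1 >= t1_after:
            snap("T1")
            t1_time = state.time
    if "T1" not in snapshots:
        snap("T1")
    snap("T2")

    # --- consolidation phase ---
    slow_rule = consolidation.effective_rule(rule)
    run(
        [
            simulate_segment(
                state,
                np.zeros(N),
                consolidation.duration,
                slow_rule,
                config,
                rng,
                sample_every=sample_every,
                record_raster=record_raster,
            )
        ]
    )
    snap("T3")

    times = np.concatenate([p.times for p in parts])
    phases = np.concatenate([p.phase_samples for p in parts])
    series = order_parameter_series(times, phases, orders=orders)
    t_end = state.time
    summary = summarize_state(state)
    summary.update(
        {
            f"final_R{n}": series.mean_over(t_end - 10.0, t_end, n) for n in orders
        }
    )
    summary["phase_clusters"] = count_phase_clusters(state.phases)
    return MainExperimentResult(
        mode=mode,
        snapshots=snapshots,
        snapshot_times=snapshot_times,
        series=series,
        raster=SpikeRaster.concatenate(rasters),
        state=state,
        summary=summary,
    )


# ---------------------------------------------------------------------------
# stability analysis of pre-trained modular networks
# ---------------------------------------------------------------------------


@dataclass
class StabilityMap:
    """Grid of surviving-module counts over (M or N_H) x N_I.

    ``outcome`` holds the surviving-cluster count per cell (-1 for
    non-accessible parameter combinations), ``stable`` whether the count
    equals the intended number of modules.
    """

    axis1: np.ndarray
    axis2: np.ndarray
    outcome: np.ndarray
    stable: np.ndarray
    intended: np.ndarray
    accessible: np.ndarray


def run_stability_trial(
    layout: ModuleLayout,
    config: SimulationConfig,
    rule: PlasticityRule,
    consolidation: ConsolidationParams,
    rng: np.random.Generator,
    return_detail: bool = False,
    eval_window: float = 500.0,
):
    """Spontaneous evolution of a pre-trained network; surviving modules.

    The surviving-module count combines a structural and a dynamical
    verdict, both restricted to the modules' exclusive members (hub
    neurons are shared between modules by construction and carry no
    information about segregation): the number of connected components of
    the strong E--E weight graph of the final matrix, and the modal
    number of phase clusters over snapshots spanning the run's final
    ``eval_window`` time units.  The smaller of the two is reported -- a
    module that has lost its independent dynamics is merged for good even
    when a desk-scale run is too short for the weights themselves to
    cross the counting threshold, and conversely.
    """
    N = layout.n
    state = pretrained_state(N, layout, config, rng)
    slow_rule = consolidation.effective_rule(rule)
    tail = min(eval_window, consolidation.duration)
    head = consolidation.duration - tail
    if head > 0:
        simulate_segment(
            state,
            np.zeros(N),
            head,
            slow_rule,
            config,
            rng,
            sample_every=0.0,
            record_raster=False,
        )
    seg = simulate_segment(
        state,
        np.zeros(N),
        tail,
        slow_rule,
        config,
        rng,
        sample_every=2.0,
        record_raster=False,
    )
    exclusive = np.concatenate(layout.clusters)
    structural = count_structural_modules(
        state.weights, state.types, include=exclusive
    )
    counts = [
        count_phase_clusters(ph, include=exclusive) for ph in seg.phase_samples
    ]
    vals, freq = np.unique(counts, return_counts=True)
    dynamical = int(vals[np.argmax(freq)])
    surviving = min(structural, dynamical)
    if return_detail:
        return surviving, {
            "structural": structural,
            "dynamical": dynamical,
            "counts": counts,
            "state": state,
        }
    return surviving


def _modal_outcome(trial_fn, n_seeds: int, rng: np.random.Generator) -> int:
    outcomes = []
    for _ in range(n_seeds):
        child = np.random.default_rng(int(rng.integers(2**31)))
        outcomes.append(trial_fn(child))
    vals, freq = np.unique(outcomes, return_counts=True)
    return int(vals[np.argmax(freq)])


def stability_map_modules(
    M_values,
    NI_values,
    config: SimulationConfig,
    rule: PlasticityRule,
    consolidation: ConsolidationParams,
    rng: np.random.Generator,
    *,
    N: int = 100,
    n_seeds: int = 3,
) -> StabilityMap:
    """Surviving-module counts over a (M, N_I) grid of pre-trained networks."""
    M_values = np.asarray(M_values, dtype=int)
    NI_values = np.asarray(NI_values, dtype=int)
    if M_values.size == 0 or NI_values.size == 0:
        raise ValueError("grids must be non-empty")
    outcome = np.full((M_values.size, NI_values.size), -1, dtype=int)
    accessible = np.zeros_like(outcome, dtype=bool)
    for a, M in enumerate(M_values):
        for b, NI in enumerate(NI_values):
            if M > N - NI:  # fewer excitatory neurons than modules
                continue
            accessible[a, b] = True
            layout = modular_layout(N, int(M), int(NI))
            outcome[a, b] = _modal_outcome(
                lambda child: run_stability_trial(
                    layout, config, rule, consolidation, child
                ),
                n_seeds,
                rng,
            )
            logger.info("modules map M=%d NI=%d -> %d", M, NI, outcome[a, b])
    intended = np.broadcast_to(M_values[:, None], outcome.shape).copy()
    stable = accessible & (outcome == intended)
    return StabilityMap(
        axis1=M_values,
        axis2=NI_values,
        outcome=outcome,
        stable=stable,
        intended=intended,
        accessible=accessible,
    )


def stability_map_hubs(
    NH_values,
    NI_values,
    N: int,
    config: SimulationConfig,
    rule: PlasticityRule,
    consolidation: ConsolidationParams,
    rng: np.random.Generator,
    *,
    n_seeds: int = 3,
) -> StabilityMap:
    """Survival of two modules sharing ``N_H`` hubs, over a (N_H, N_I) grid.

    Cells whose exclusive cluster size would drop below the number of
    hubs are unstable by construction (the hubs would dominate and pull
    the modules into global synchrony); cells without at least one
    exclusive excitatory neuron per module are not accessible.
    """
    NH_values = np.asarray(NH_values, dtype=int)
    NI_values = np.asarray(NI_values, dtype=int)
    if NH_values.size == 0 or NI_values.size == 0:
        raise ValueError("grids must be non-empty")
    outcome = np.full((NH_values.size, NI_values.size), -1, dtype=int)
    accessible = np.zeros_like(outcome, dtype=bool)
    for a, NH in enumerate(NH_values):
        for b, NI in enumerate(NI_values):
            n_exclusive = N - NI - NH
            if n_exclusive < 2:
                continue
            accessible[a, b] = True
            if n_exclusive // 2 < NH:
                outcome[a, b] = 1  # hubs dominate: merged by construction
                continue
            layout = modular_layout(N, 2, int(NI), n_hubs=int(NH))
            outcome[a, b] = _modal_outcome(
                lambda child: run_stability_trial(
                    layout, config, rule, consolidation, child
                ),
                n_seeds,
                rng,
            )
            logger.info("hub map NH=%d NI=%d -> %d", NH, NI, outcome[a, b])
    intended = np.full_like(outcome, 2)
    stable = accessible & (outcome == intended)
    return StabilityMap(
        axis1=NH_values,
        axis2=NI_values,
        outcome=outcome,
        stable=stable,
        intended=intended,
        accessible=accessible,
    )


# ---------------------------------------------------------------------------
# memory recall
# ---------------------------------------------------------------------------


@dataclass
class RecallResult:
    """Artifacts of a memory-recall probe run."""

    times: np.ndarray
    scores: np.ndarray  # (n_patterns, T) anti-phase score pattern vs rest
    raster: SpikeRaster
    pulses: list[tuple[float, float, int]]  # (t_start, t_end, pattern index)
    baselines: np.ndarray  # (n_patterns,) pre-pulse mean score
    peaks: np.ndarray  # (n_patterns,) post-pulse max score
    state: NetworkState


def run_recall_experiment(
    trained_state: NetworkState,
    patterns: list[np.ndarray],
    pulse_len: float = 5.0,
    pulse_amplitude: float = 3.0,
    *,
    config: SimulationConfig | None = None,
    rule: PlasticityRule | None = None,
    rng: np.random.Generator | None = None,
    rest: float = 200.0,
    inter_pulse: float = 200.0,
    sample_every: float = 0.1,
    record_raster: bool = False,
) -> RecallResult:
    """Brief pattern pulses probing a network with scrambled E--E weights.

    After an initial rest each stored pattern is stimulated for
    ``pulse_len`` time units (default amplitude 3, as during learning);
    the anti-phase score between the pulsed pattern's excitatory neurons
    and the remaining patterns' neurons is tracked throughout.  The
    baseline for each pattern is its mean score over the 50 time units
    preceding its pulse; the peak is the maximum within 50 units after
    pulse onset.
    """
    if rng is None:
        raise ValueError("an explicit numpy Generator is required")
    config = config or SimulationConfig()
    rule = rule or default_rule("ei")
    state = trained_state
    N = state.n
    inh = np.flatnonzero(state.types == INHIBITORY)
    patterns = [np.asarray(p, dtype=np.int64) for p in patterns]
    for p in patterns:
        if np.intersect1d(p, inh).size:
            raise ValueError("recall patterns must not include inhibitory neurons")

    parts: list[SegmentResult] = []
    pulses: list[tuple[float, float, int]] = []

    def seg(currents, duration):
        parts.append(
            simulate_segment(
                state,
                currents,
                duration,
                rule,
                config,
                rng,
                sample_every=sample_every,
                record_raster=record_raster,
            )
        )

    seg(np.zeros(N), rest)
    for k, p in enumerate(patterns):
        t0 = state.time
        currents = np.zeros(N)
        currents[p] = pulse_amplitude
        seg(currents, pulse_len)
        pulses.append((t0, t0 + pulse_len, k))
        seg(np.zeros(N), inter_pulse - pulse_len)

    times = np.concatenate([s.times for s in parts])
    phases = np.concatenate([s.phase_samples for s in parts])
    scores = np.empty((len(patterns), times.size))
    for k, p in enumerate(patterns):
        others = np.concatenate([q for j, q in enumerate(patterns) if j != k])
        for t in range(times.size):
            scores[k, t] = recall_score(phases[t], p, others)

    baselines = np.empty(len(patterns))
    peaks = np.empty(len(patterns))
    for k, (t_start, _t_end, _) in enumerate(pulses):
        pre = (times >= t_start - 50.0) & (times < t_start)
        post = (times >= t_start) & (times <= t_start + 50.0)
        baselines[k] = float(np.mean(scores[k, pre]))
        peaks[k] = float(np.max(scores[k, post]))

    return RecallResult(
        times=times,
        scores=scores,
        raster=SpikeRaster.concatenate([s.raster for s in parts]),
        pulses=pulses,
        baselines=baselines,
        peaks=peaks,
        state=state,
    )
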