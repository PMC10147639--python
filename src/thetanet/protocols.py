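"""Stimulation schedules and programmatically constructed trained networks.

This module generates every input the experiments need: timed stimulus
blocks targeting subsets of excitatory neurons (the entrainment protocol),
and idealised "already trained" weight matrices for stability sweeps --
``M`` saturated excitatory clusters, each feeding a group of inhibitory
neurons in a feedforward manner, with each inhibitory neuron inhibiting
everything outside its own cluster.  Optionally a set of *hub* excitatory
neurons belongs to every cluster at once (mixed selectivity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EXCITATORY, INHIBITORY, NetworkState


@dataclass(frozen=True)
class StimulusBlock:
    """A constant-current stimulation window for a set of target neurons."""

    t_start: float
    t_end: float
    targets: np.ndarray
    amplitude: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "targets", np.asarray(self.targets, dtype=np.int64)
        )
        if self.t_start >= self.t_end:
            raise ValueError(
                f"block must satisfy t_start < t_end, got [{self.t_start}, {self.t_end}]"
            )
        if self.targets.size == 0:
            raise ValueError("stimulus block must target at least one neuron")


@dataclass
class StimulusSchedule:
    """Ordered, non-overlapping stimulation blocks over ``[0, total_duration]``."""

    blocks: list[StimulusBlock] = field(default_factory=list)
    total_duration: float = 0.0

    def __post_init__(self) -> None:
        self.blocks = sorted(self.blocks, key=lambda b: b.t_start)
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.t_start < a.t_end:
                raise ValueError("stimulus blocks must not overlap in time")
        if self.blocks and self.blocks[-1].t_end > self.total_duration:
            self.total_duration = self.blocks[-1].t_end

    def currents_at(self, t: float, N: int) -> np.ndarray:
        """Current vector at time ``t``."""
        out = np.zeros(N)
        for b in self.blocks:
            if b.t_start <= t < b.t_end:
                out[b.targets] = b.amplitude
        return out

    def segments(self, N: int):
        """Piecewise-constant cover of ``[0, total_duration]``.

        Yields ``(t_start, t_end, currents)`` with silent gaps filled in.
        """
        t = 0.0
        for b in self.blocks:
            if b.t_start > t:
                yield t, b.t_start, np.zeros(N)
            cur = np.zeros(N)
            cur[b.targets] = b.amplitude
            yield b.t_start, b.t_end, cur
            t = b.t_end
        if t < self.total_duration:
            yield t, self.total_duration, np.zeros(N)

    def validate_against(self, state: NetworkState) -> None:
        """Raise if any block targets an inhibitory neuron."""
        inh = np.flatnonzero(state.types == INHIBITORY)
        for b in self.blocks:
            if np.intersect1d(b.targets, inh).size:
                raise ValueError("stimulation must never target inhibitory neurons")

    def to_dict(self) -> dict:
        """Plain-data form for serialisation to a structured text config."""
        return {
            "total_duration": float(self.total_duration),
            "blocks": [
                {
                    "t_start": float(b.t_start),
                    "t_end": float(b.t_end),
                    "targets": [int(i) for i in b.targets],
                    "amplitude": float(b.amplitude),
                }
                for b in self.blocks
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "StimulusSchedule":
        return cls(
            blocks=[StimulusBlock(**b) for b in data.get("blocks", [])],
            total_duration=float(data.get("total_duration", 0.0)),
        )


def build_learning_schedule(
    groups: list[np.ndarray],
    block_len: float = 20.0,
    n_blocks: int = 50,
    rest_before: float = 200.0,
    rest_after: float = 0.0,
    amplitude: float = 3.0,
    gap: float = 0.0,
    strict_alternation: bool = False,
    rng: np.random.Generator | None = None,
) -> StimulusSchedule:
    """Entrainment schedule: rest, then stimulus blocks, then rest.

    Each block targets one of ``groups`` for ``block_len`` time units at
    the given amplitude.  The group sequence is drawn uniformly at random
    per block (requires ``rng``) or cycles round-robin when
    ``strict_alternation`` is set -- the latter, combined with a short
    inter-block ``gap``, is used for the overlapping-stimuli protocol.
    """
    if block_len <= 0:
        raise ValueError("block_len must be positive")
    groups = [np.asarray(g, dtype=np.int64) for g in groups]
    for g in groups:
        if g.size == 0:
            raise ValueError("stimulus groups must be non-empty")
    if n_blocks > 0 and not groups:
        raise ValueError("at least one stimulus group is required")
    if n_blocks > 0 and not strict_alternation and rng is None:
        raise ValueError("rng is required for randomised block order")

    if strict_alternation:
        order = [k % len(groups) for k in range(n_blocks)]
    else:
        order = [int(rng.integers(len(groups))) for _ in range(n_blocks)]

    blocks = []
    t = rest_before
    for k in order:
        blocks.append(
            StimulusBlock(
                t_start=t, t_end=t + block_len, targets=groups[k], amplitude=amplitude
            )
        )
        t += block_len + gap
    if blocks:
        t = blocks[-1].t_end  # no trailing gap
    total = t + rest_after
    return StimulusSchedule(blocks=blocks, total_duration=max(total, rest_before))


def split_into_groups(indices: np.ndarray, n_groups: int) -> list[np.ndarray]:
    """Partition an index vector into ``n_groups`` contiguous, near-equal sets."""
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    return [np.asarray(g, dtype=np.int64) for g in np.array_split(indices, n_groups)]


@dataclass
class ModuleLayout:
    """Partition of a network into structural modules.

    ``clusters`` lists the *exclusive* excitatory members of each module,
    ``hubs`` are excitatory neurons belonging to every module at once
    (there must be at least two modules when hubs are present), and
    ``inhibitory_assignment`` maps each inhibitory neuron index to the id
    of the single module it serves.  Excitatory indices must come first
    (0..N_E-1) and the union of clusters and hubs must cover them exactly.
    """

    clusters: list[np.ndarray]
    hubs: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    inhibitory_assignment: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.clusters = [np.asarray(c, dtype=np.int64) for c in self.clusters]
        self.hubs = np.asarray(self.hubs, dtype=np.int64)
        if self.hubs.size and len(self.clusters) < 2:
            raise ValueError("hub neurons require at least two modules")
        all_exc = np.concatenate(self.clusters + [self.hubs]) if self.clusters else self.hubs
        if np.unique(all_exc).size != all_exc.size:
            raise ValueError("clusters and hubs must not share exclusive indices")
        expected = np.arange(all_exc.size)
        if not np.array_equal(np.sort(all_exc), expected):
            raise ValueError("excitatory indices must be 0..N_E-1 with no gaps")
        M = len(self.clusters)
        for idx, cid in self.inhibitory_assignment.items():
            if not 0 <= cid < M:
                raise ValueError(
                    f"inhibitory neuron {idx} assigned to nonexistent cluster {cid}"
                )

    @property
    def n_excitatory(self) -> int:
        return int(sum(c.size for c in self.clusters) + self.hubs.size)

    @property
    def n_inhibitory(self) -> int:
        return len(self.inhibitory_assignment)

    @property
    def n(self) -> int:
        return self.n_excitatory + self.n_inhibitory

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def types(self) -> np.ndarray:
        t = np.full(self.n, EXCITATORY, dtype=np.int8)
        t[list(self.inhibitory_assignment.keys())] = INHIBITORY
        return t


def modular_layout(
    N: int,
    n_clusters: int,
    n_inhibitory: int,
    n_hubs: int = 0,
) -> ModuleLayout:
    """Standard layout: M near-equal exclusive clusters (+ optional hubs).

    Excitatory neurons occupy indices ``0..N_E-1`` (hubs take the last
    ``n_hubs`` of them), inhibitory neurons the remaining indices and are
    assigned to clusters round-robin; with ``n_inhibitory < n_clusters``
    some clusters simply have no inhibitory neuron.
    """
    n_exc = N - n_inhibitory
    n_exclusive = n_exc - n_hubs
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_exclusive < n_clusters:
        raise ValueError(
            f"cannot split {n_exclusive} exclusive excitatory neurons into "
            f"{n_clusters} non-empty clusters"
        )
    clusters = split_into_groups(np.arange(n_exclusive), n_clusters)
    hubs = np.arange(n_exclusive, n_exc)
    assignment = {n_exc + k: k % n_clusters for k in range(n_inhibitory)}
    return ModuleLayout(clusters=clusters, hubs=hubs, inhibitory_assignment=assignment)


def build_pretrained_matrix(N: int, layout: ModuleLayout) -> np.ndarray:
    """Idealised consolidated weight matrix for a module layout.

    Excitatory weights are saturated (1) within each module -- including
    every hub's links to all modules it belongs to -- and pruned (0)
    across modules.  Each inhibitory neuron receives feedforward
    excitation (1) from the excitatory members (and hubs) of its assigned
    module and projects inhibition (-1) onto the exclusive excitatory
    members and the inhibitory neurons of every *other* module; hubs and
    same-module neurons receive no inhibition.  The diagonal is zero.
    """
    if layout.n != N:
        raise ValueError(f"layout describes {layout.n} neurons, expected {N}")
    K = np.zeros((N, N))
    M = layout.n_clusters
    member = [np.concatenate([layout.clusters[m], layout.hubs]) for m in range(M)]

    for m in range(M):
        # intra-module excitatory weights saturate (hub links included)
        K[np.ix_(member[m], member[m])] = 1.0

    for inh, m in layout.inhibitory_assignment.items():
        # feedforward excitation from the assigned module
        K[inh, member[m]] = 1.0
        # inhibition of all other modules' exclusive members
        for other in range(M):
            if other != m:
                K[layout.clusters[other], inh] = -1.0
        # inhibition of other modules' inhibitory neurons
        for inh2, m2 in layout.inhibitory_assignment.items():
            if m2 != m:
                K[inh2, inh] = -1.0

    np.fill_diagonal(K, 0.0)
    return K


def pretrained_state(
    N: int,
    layout: ModuleLayout,
    config,
    rng: np.random.Generator,
) -> NetworkState:
    """Network state carrying a pre-trained matrix with random phases.

    Draw order from ``rng``: phases, then excitabilities.
    """
    from .core import SimulationConfig, wrap_phase  # cycle-free local import

    assert isinstance(config, SimulationConfig)
    phases = wrap_phase(rng.uniform(-np.pi, np.pi, size=N))
    eta = rng.normal(config.eta_mean, np.sqrt(config.eta_variance), size=N)
    return NetworkState(
        phases=phases,
        weights=build_pretrained_matrix(N, layout),
        types=layout.types(),
        excitabilities=eta,
        time=0.0,
    )


def scramble_excitatory_weights(
    state: NetworkState,
    rng: np.random.Generator,
) -> NetworkState:
    """Redraw every E->E weight uniformly on [0, 1] (in place).

    Models the volatility of excitatory synapses: the memory trace
    survives only in the connections involving inhibitory neurons, which
    are left untouched, as is the zero diagonal.
    """
    exc = np.flatnonzero(state.types != INHIBITORY)
    block = rng.uniform(0.0, 1.0, size=(exc.size, exc.size))
    state.weights[np.ix_(exc, exc)] = block
    np.fill_diagonal(state.weights, 0.0)
    return state
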