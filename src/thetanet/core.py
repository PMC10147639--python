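"""Network state and stochastic integration of theta-neuron phase dynamics.

The membrane dynamics of each neuron are represented by a single phase
``theta_i`` on the circle, evolving according to the canonical class-I
(theta-neuron) normal form with diffusive sinusoidal coupling::

    dtheta_i/dt = (1 - cos theta_i)
                + (1 + cos theta_i) * [eta_i + (g/N) * sum_j kappa_ij sin(theta_j - theta_i)
                                       + I_i(t) + xi_i(t)]

where ``eta_i`` is the excitability (bifurcation parameter), ``g`` a global
coupling strength, ``kappa_ij`` the plastic synaptic weight from pre-synaptic
neuron ``j`` to post-synaptic neuron ``i``, ``I_i(t)`` an external stimulus
current and ``xi_i(t)`` Gaussian white noise.  A spike is emitted whenever a
phase crosses ``+pi`` from below.  The multiplicative noise term is
interpreted in the Stratonovich sense and integrated with an Euler--Heun
predictor--corrector scheme (Euler--Maruyama predictor; the corrector
averages the diffusion coefficient between current and predicted state),
which converges to the Stratonovich solution for scalar multiplicative
noise.

Conventions
-----------
* Phases live in ``[-pi, pi)``.
* ``weights[i, j]`` is the weight *from* pre-synaptic ``j`` *onto*
  post-synaptic ``i``.  Columns therefore carry the pre-synaptic sign
  constraint (Dale's principle): excitatory columns in ``[0, 1]``,
  inhibitory columns in ``[-1, 0]``, unlabelled entries in ``[-1, 1]``.
* Self-weights ``kappa[i, i]`` are fixed at zero and excluded from
  adaptation; ``sin(theta_i - theta_i) = 0`` so they can never influence
  the dynamics and adapting them would only saturate them meaninglessly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("thetanet")

#: neuron type labels stored in ``NetworkState.types``
EXCITATORY: int = 1
INHIBITORY: int = -1
UNLABELLED: int = 0

#: recognised network construction / plasticity modes
MODES = ("ei", "excitatory_only", "unlabelled")

TWO_PI = 2.0 * np.pi


def wrap_phase(x):
    """Wrap angles to the interval ``[-pi, pi)``."""
    return np.mod(np.asarray(x, dtype=float) + np.pi, TWO_PI) - np.pi


@dataclass
class SimulationConfig:
    """Integration and population parameters.

    Parameters
    ----------
    g : float
        Global synaptic coupling strength.
    dt : float
        Integration time step (dimensionless time units).
    noise_variance : float
        Variance of the Gaussian noise term ``xi``; the increment applied
        per step is ``sqrt(dt) * sqrt(noise_variance) * z`` with ``z``
        standard normal, multiplied by the state-dependent factor
        ``1 + cos(theta)``.
    eta_mean, eta_variance : float
        Mean and variance of the normal distribution from which the
        excitabilities ``eta_i`` are drawn.
    seed : int or None
        Seed recorded for provenance; randomness is always consumed from an
        explicit :class:`numpy.random.Generator` passed to the operations.
    """

    g: float = 1.0
    dt: float = 0.01
    noise_variance: float = 0.01
    eta_mean: float = 1.5
    eta_variance: float = 1e-4
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.noise_variance < 0:
            raise ValueError(f"noise_variance must be >= 0, got {self.noise_variance}")
        if self.g < 0:
            raise ValueError(f"g must be >= 0, got {self.g}")
        if self.eta_variance < 0:
            raise ValueError(f"eta_variance must be >= 0, got {self.eta_variance}")

    @property
    def noise_std(self) -> float:
        return float(np.sqrt(self.noise_variance))


@dataclass
class NetworkState:
    """Instantaneous state of the plastic network.

    Attributes
    ----------
    phases : (N,) float array, radians in ``[-pi, pi)``
    weights : (N, N) float array, ``weights[i, j]`` = weight j -> i
    types : (N,) int array of ``EXCITATORY`` / ``INHIBITORY`` / ``UNLABELLED``
    excitabilities : (N,) float array of bifurcation parameters ``eta_i``
    time : float, simulation clock
    """

    phases: np.ndarray
    weights: np.ndarray
    types: np.ndarray
    excitabilities: np.ndarray
    time: float = 0.0

    @property
    def n(self) -> int:
        return self.phases.shape[0]

    @property
    def n_inhibitory(self) -> int:
        return int(np.sum(self.types == INHIBITORY))

    @property
    def excitatory_indices(self) -> np.ndarray:
        return np.flatnonzero(self.types != INHIBITORY)

    @property
    def inhibitory_indices(self) -> np.ndarray:
        return np.flatnonzero(self.types == INHIBITORY)

    def column_signs(self) -> np.ndarray:
        """Sign carried by each pre-synaptic column (+1 except inhibitory)."""
        return np.where(self.types == INHIBITORY, -1.0, 1.0)

    def copy(self) -> "NetworkState":
        return NetworkState(
            phases=self.phases.copy(),
            weights=self.weights.copy(),
            types=self.types.copy(),
            excitabilities=self.excitabilities.copy(),
            time=self.time,
        )

    def validate(self) -> None:
        """Raise ``ValueError`` if any structural invariant is violated."""
        N = self.n
        for name in ("weights",):
            if self.weights.shape != (N, N):
                raise ValueError(
                    f"{name} has shape {self.weights.shape}, expected {(N, N)}"
                )
        for name, vec in (
            ("types", self.types),
            ("excitabilities", self.excitabilities),
        ):
            if vec.shape != (N,):
                raise ValueError(f"{name} has shape {vec.shape}, expected {(N,)}")
        if np.any(self.phases < -np.pi) or np.any(self.phases >= np.pi):
            raise ValueError("phases must be wrapped to [-pi, pi)")
        if np.any(np.diag(self.weights) != 0.0):
            raise ValueError("self-weights kappa[i, i] must be zero")
        exc = self.types == EXCITATORY
        inh = self.types == INHIBITORY
        if np.any(self.weights[:, exc] < 0) or np.any(self.weights[:, exc] > 1):
            raise ValueError("excitatory columns must lie in [0, 1]")
        if np.any(self.weights[:, inh] > 0) or np.any(self.weights[:, inh] < -1):
            raise ValueError("inhibitory columns must lie in [-1, 0]")
        if np.any(np.abs(self.weights) > 1):
            raise ValueError("all weights must satisfy |kappa| <= 1")


@dataclass
class SpikeRaster:
    """Firing events ``(time, neuron_index)`` from threshold crossings."""

    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    neurons: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.neurons = np.asarray(self.neurons, dtype=np.int64)
        if self.times.shape != self.neurons.shape:
            raise ValueError("times and neurons must have equal length")
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be non-decreasing")

    def __len__(self) -> int:
        return self.times.size

    @staticmethod
    def concatenate(rasters: list["SpikeRaster"]) -> "SpikeRaster":
        if not rasters:
            return SpikeRaster()
        return SpikeRaster(
            np.concatenate([r.times for r in rasters]),
            np.concatenate([r.neurons for r in rasters]),
        )


def init_network(
    N: int,
    n_inhibitory: int,
    mode: str,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> NetworkState:
    """Create a randomly initialised network.

    Draw order from ``rng`` (documented for reproducibility): initial
    phases, then excitabilities, then the weight matrix.

    Phases are uniform on ``[-pi, pi)``; excitabilities are normal with
    mean ``config.eta_mean`` and variance ``config.eta_variance``; weights
    are uniform on ``[0, 1]`` for excitatory (and, columnwise, unlabelled-
    mode draws are uniform on ``[-1, 1]``) pre-synaptic columns and uniform
    on ``[-1, 0]`` for inhibitory columns.  The last ``n_inhibitory``
    indices are labelled inhibitory in ``ei`` mode.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if not 0 <= n_inhibitory <= N:
        raise ValueError(f"n_inhibitory={n_inhibitory} outside [0, {N}]")
    if mode == "excitatory_only" and n_inhibitory > 0:
        raise ValueError("excitatory_only networks cannot contain inhibitory neurons")
    if mode == "unlabelled" and n_inhibitory > 0:
        raise ValueError("unlabelled networks do not label inhibitory neurons")

    phases = rng.uniform(-np.pi, np.pi, size=N)
    eta = rng.normal(config.eta_mean, np.sqrt(config.eta_variance), size=N)

    if mode == "unlabelled":
        types = np.full(N, UNLABELLED, dtype=np.int8)
        weights = rng.uniform(-1.0, 1.0, size=(N, N))
    else:
        types = np.full(N, EXCITATORY, dtype=np.int8)
        if n_inhibitory:
            types[N - n_inhibitory :] = INHIBITORY
        weights = rng.uniform(0.0, 1.0, size=(N, N))
        weights[:, types == INHIBITORY] -= 1.0
    np.fill_diagonal(weights, 0.0)

    return NetworkState(
        phases=wrap_phase(phases),
        weights=weights,
        types=types,
        excitabilities=eta,
        time=0.0,
    )


def _check_currents(state: NetworkState, currents: np.ndarray) -> np.ndarray:
    currents = np.asarray(currents, dtype=float)
    if currents.shape != (state.n,):
        raise ValueError(
            f"currents has shape {currents.shape}, expected ({state.n},)"
        )
    return currents


def phase_drift(
    state: NetworkState,
    currents: np.ndarray,
    config: SimulationConfig,
) -> np.ndarray:
    """Deterministic part of ``dtheta/dt`` (no noise).

    Returns ``(1 - cos theta) + (1 + cos theta) * [eta + (g/N) * sum_j
    kappa_ij sin(theta_j - theta_i) + I_i]``.
    """
    currents = _check_currents(state, currents)
    th = state.phases
    s, c = np.sin(th), np.cos(th)
    # sum_j kappa_ij sin(theta_j - theta_i) = cos(theta_i) * (K s)_i - sin(theta_i) * (K c)_i
    coupling = (config.g / state.n) * (c * (state.weights @ s) - s * (state.weights @ c))
    return (1.0 - c) + (1.0 + c) * (state.excitabilities + coupling + currents)


def step(
    state: NetworkState,
    currents: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[NetworkState, np.ndarray]:
    """Advance the phases by one time step ``dt`` (in place).

    Uses the Euler--Heun scheme: an Euler--Maruyama predictor followed by
    a corrector that averages the diffusion coefficient
    ``sigma * (1 + cos theta)`` between the current and predicted state,
    consistent with the Stratonovich interpretation.  With
    ``noise_variance == 0`` the scheme reduces to the plain Euler method
    and is fully deterministic.

    Returns the advanced state and the indices of neurons whose
    (unwrapped) phase increment carried them across ``+pi`` from below
    this step; phases are wrapped back to ``[-pi, pi)`` afterwards.
    Downward crossings of ``-pi`` (possible transiently under strong
    noise) are not counted as spikes.
    """
    currents = _check_currents(state, currents)
    dt = config.dt
    drift = phase_drift(state, currents, config)
    th = state.phases
    sigma = config.noise_std
    if sigma > 0.0:
        if rng is None:
            raise ValueError("rng is required when noise_variance > 0")
        dw = rng.standard_normal(state.n) * np.sqrt(dt)
        b0 = sigma * (1.0 + np.cos(th))
        predictor = th + drift * dt + b0 * dw
        b1 = sigma * (1.0 + np.cos(predictor))
        new = th + drift * dt + 0.5 * (b0 + b1) * dw
    else:
        new = th + drift * dt
    spiked = np.flatnonzero(new >= np.pi)
    state.phases = wrap_phase(new)
    state.time += dt
    return state, spiked
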