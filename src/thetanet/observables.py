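"""Synchrony and cluster diagnostics.

The central observable is the Kuramoto--Daido order parameter

    Z_n(t) = R_n e^{i Psi_n} = (1/N) * sum_j exp(i n theta_j)

``R_1 ~ 1`` signals global phase synchrony, ``R_1 ~ 0`` with ``R_2 ~ 1``
two clusters in anti-phase, and ``R_M ~ 1`` M evenly spaced clusters.
Order parameters are computed over *all* neurons (the defining sum runs
over the whole population, not only the excitatory neurons).

Structural diagnostics operate on the weight matrix: a *structural module*
is a connected component of the thresholded excitatory-to-excitatory
weight graph.  The default threshold 0.5 sits midway between saturated
(~1) and pruned (~0) weights observed after consolidation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import INHIBITORY, NetworkState


@dataclass
class OrderParameterSeries:
    """Time series of the first ``n`` Kuramoto--Daido order parameters."""

    times: np.ndarray  # (T,)
    R: np.ndarray  # (T, n_orders), moduli in [0, 1]
    Psi: np.ndarray  # (T, n_orders), arguments in [-pi, pi]
    orders: tuple[int, ...] = (1, 2)

    def column(self, n: int) -> np.ndarray:
        """Modulus series of the ``n``-th order parameter."""
        return self.R[:, self.orders.index(n)]

    def mean_over(self, t_start: float, t_end: float, n: int) -> float:
        """Time average of ``R_n`` over the window ``[t_start, t_end]``."""
        mask = (self.times >= t_start) & (self.times <= t_end)
        if not np.any(mask):
            raise ValueError(f"no samples in window [{t_start}, {t_end}]")
        return float(np.mean(self.column(n)[mask]))


def kuramoto_daido(phases: np.ndarray, n: int) -> tuple[float, float]:
    """Modulus ``R_n`` and argument ``Psi_n`` of the n-th order parameter."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("phase vector must be non-empty")
    if n < 1:
        raise ValueError(f"order n must be >= 1, got {n}")
    z = np.mean(np.exp(1j * n * phases))
    return float(np.abs(z)), float(np.angle(z))


def order_parameter_series(
    times: np.ndarray,
    phase_samples: np.ndarray,
    orders: tuple[int, ...] = (1, 2),
) -> OrderParameterSeries:
    """Compute ``R_n(t)``, ``Psi_n(t)`` from sampled phase trajectories."""
    times = np.asarray(times, dtype=float)
    phase_samples = np.asarray(phase_samples, dtype=float)
    if phase_samples.ndim != 2 or phase_samples.shape[0] != times.shape[0]:
        raise ValueError("phase_samples must have shape (len(times), N)")
    R = np.empty((times.size, len(orders)))
    Psi = np.empty_like(R)
    for k, n in enumerate(orders):
        z = np.mean(np.exp(1j * n * phase_samples), axis=1)
        R[:, k] = np.abs(z)
        Psi[:, k] = np.angle(z)
    return OrderParameterSeries(times=times, R=R, Psi=Psi, orders=tuple(orders))


def count_structural_modules(
    weights: np.ndarray,
    types: np.ndarray,
    strong_threshold: float = 0.5,
    include: np.ndarray | None = None,
) -> int:
    """Number of connected components of the strong E--E weight graph.

    The excitatory-to-excitatory block is binarised at
    ``|kappa| >= strong_threshold``, symmetrised by OR, and the number of
    connected components among the (selected) excitatory neurons is
    returned.  ``include`` optionally restricts the count to a subset of
    neuron indices (e.g. to exclude hub neurons whose links are shared by
    several modules).
    """
    types = np.asarray(types)
    exc = np.flatnonzero(types != INHIBITORY)
    if include is not None:
        exc = np.intersect1d(exc, np.asarray(include))
    if exc.size == 0:
        return 0
    block = np.abs(np.asarray(weights)[np.ix_(exc, exc)]) >= strong_threshold
    adj = block | block.T
    n_comp, _ = connected_components(csr_matrix(adj), directed=False)
    return int(n_comp)


def count_phase_clusters(
    phases: np.ndarray,
    gap_tolerance: float = 0.5,
    include: np.ndarray | None = None,
) -> int:
    """Number of phase clusters separated by circular gaps.

    Phases are sorted on the circle; every circular gap larger than
    ``gap_tolerance`` (radians) splits clusters.  If no gap exceeds the
    tolerance the population counts as a single cluster.
    """
    phases = np.asarray(phases, dtype=float)
    if include is not None:
        phases = phases[np.asarray(include)]
    if phases.size == 0:
        raise ValueError("phase vector must be non-empty")
    if phases.size == 1:
        return 1
    srt = np.sort(np.mod(phases, 2.0 * np.pi))
    gaps = np.diff(srt)
    wrap_gap = srt[0] + 2.0 * np.pi - srt[-1]
    n_splits = int(np.sum(gaps > gap_tolerance)) + int(wrap_gap > gap_tolerance)
    return max(n_splits, 1)


def circular_mean(phases: np.ndarray) -> float:
    """Argument of the resultant vector of a set of angles."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("phase vector must be non-empty")
    return float(np.angle(np.mean(np.exp(1j * phases))))


def recall_score(
    phases: np.ndarray,
    cluster_a: np.ndarray,
    cluster_b: np.ndarray,
) -> float:
    """Anti-phase score between two neuron groups, in ``[0, 1]``.

    Returns ``(1 - cos(dpsi)) / 2`` where ``dpsi`` is the difference of
    the circular mean phases of the two groups: 1 for perfect anti-phase
    (the stored pattern is recalled), 0 for identical mean phases.
    """
    a = np.asarray(cluster_a, dtype=np.int64)
    b = np.asarray(cluster_b, dtype=np.int64)
    if a.size == 0 or b.size == 0:
        raise ValueError("cluster index sets must be non-empty")
    if np.intersect1d(a, b).size:
        raise ValueError("cluster index sets must be disjoint")
    phases = np.asarray(phases, dtype=float)
    dpsi = circular_mean(phases[a]) - circular_mean(phases[b])
    return float((1.0 - np.cos(dpsi)) / 2.0)


def summarize_state(state: NetworkState, strong_threshold: float = 0.5) -> dict:
    """Quick scalar summary (R_1, R_2, module count) of a network state."""
    r1, _ = kuramoto_daido(state.phases, 1)
    r2, _ = kuramoto_daido(state.phases, 2)
    return {
        "R1": r1,
        "R2": r2,
        "structural_modules": count_structural_modules(
            state.weights, state.types, strong_threshold
        ),
    }
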