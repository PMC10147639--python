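"""Hebbian phase-difference plasticity kernels and weight dynamics.

Weights adapt as a function of the instantaneous phase difference
``dtheta = theta_j - theta_i`` between pre-synaptic neuron ``j`` and
post-synaptic neuron ``i`` through a plasticity kernel ``Lambda(dtheta)``:
potentiation near ``dtheta = 0`` (cells firing together wire together) and
depression near ``dtheta = +-pi``.

Two kernels are provided:

* ``cosine`` -- ``Lambda_0(dtheta) = cos(dtheta)``, symmetric potentiation
  and depression lobes.
* ``asymmetric_exponential`` -- ``Lambda_1``, a piecewise-exponential kernel
  whose depression lobe decays on an e-fold scale of 0.5 rad, five times
  longer than the 0.1 rad potentiation lobe, mirroring the asymmetric
  potentiation/depression windows of cortical STDP.  Both kernels attain
  (numerically) the same extreme values.

Adaptation runs on two timescales: a slow, always-on rate ``eps_slow``
(consolidation) and a fast rate ``eps_fast`` that is gated on for a synapse
whenever the pre-synaptic neuron receives a sufficiently strong external
stimulus (``|I_j| > gate_threshold``).  Under Dale's principle
(``dale_mode`` "ei" or "excitatory_only") the weight obeys soft-bounded
dynamics::

    dkappa_ij/dt = [eps_slow + eps_fast * gate_j] * |kappa_ij| * (1 - |kappa_ij|) * Lambda(dtheta)

with the fast term present only between two excitatory neurons (synapses
involving an inhibitory neuron always adapt on the slow timescale only,
since inhibitory neurons are never stimulated).  The derivative acts on
the *signed* weight, so a positive kernel value drives every weight
upward within its bound interval: excitatory synapses between in-phase
neurons saturate towards 1, while inhibitory synapses onto in-phase
targets decay towards 0 and those onto anti-phase targets grow towards
-1.  This is what lets the inhibitory wiring self-organise during
consolidation into the feedforward architecture in which each inhibitory
group is driven by its own cluster and suppresses all the others.  In
"unlabelled" mode the weight instead relaxes linearly towards the kernel
value::

    dkappa_ij/dt = [eps_slow + eps_fast * gate_j] * (-kappa_ij + Lambda(dtheta))

The soft bounds make 0 and +-1 absorbing; a forward-Euler step can overshoot
onto the bounds and freeze a weight spuriously, so update results are clamped
to the bound interval shrunk by ``EPS_NUM`` on each side, which preserves the
soft-bound character while keeping every weight (numerically) adaptable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import (
    EXCITATORY,
    INHIBITORY,
    MODES,
    NetworkState,
    _check_currents,
    wrap_phase,
)

#: interior clamp keeping soft-bounded weights off the absorbing bounds
EPS_NUM: float = 1e-6

#: e-fold decay constants (radians) of the asymmetric kernel's lobes
POTENTIATION_SCALE: float = 0.1
DEPRESSION_SCALE: float = 0.5

KERNELS = ("cosine", "asymmetric_exponential")


def potentiation_half_width(kernel: str) -> float:
    """Phase difference at which the kernel's potentiation lobe ends.

    Zero crossing of the kernel for positive phase differences: pi/2 for
    the cosine kernel; for the asymmetric kernel, solving
    ``exp(-x/0.1) = exp((x - pi)/0.5)`` gives exactly ``pi/6``.  Neuron
    pairs closer in phase than this are being potentiated; pairs further
    apart are being depressed.
    """
    if kernel == "cosine":
        return np.pi / 2.0
    return np.pi / 6.0


def kernel_lambda0(dtheta):
    """Symmetric cosine kernel ``Lambda_0(dtheta) = cos(dtheta)``."""
    return np.cos(dtheta)


def kernel_lambda1(dtheta):
    """Asymmetric piecewise-exponential kernel ``Lambda_1`` (2*pi periodic).

    For ``-pi <= d < 0``:  ``exp(d/0.1) - exp(-(d + pi)/0.5)``
    For ``0 <= d < pi``:   ``exp(-d/0.1) - exp((d - pi)/0.5)``

    The function is even in ``dtheta`` and continuous at the branch joins
    ``0`` and ``+-pi``.
    """
    d = wrap_phase(dtheta)
    neg = d < 0
    out = np.where(
        neg,
        np.exp(d / POTENTIATION_SCALE) - np.exp(-(d + np.pi) / DEPRESSION_SCALE),
        np.exp(-d / POTENTIATION_SCALE) - np.exp((d - np.pi) / DEPRESSION_SCALE),
    )
    if np.ndim(dtheta) == 0:
        return float(out)
    return out


_KERNEL_FUNCS = {
    "cosine": kernel_lambda0,
    "asymmetric_exponential": kernel_lambda1,
}


def get_kernel(name: str):
    """Return the kernel function registered under ``name``."""
    try:
        return _KERNEL_FUNCS[name]
    except KeyError:
        raise ValueError(f"unknown kernel {name!r}; expected one of {KERNELS}")


def kernel_table(name: str, size: int = 65536) -> np.ndarray:
    """Tabulate a kernel on a uniform grid over ``[-pi, pi]``.

    Returns ``size + 1`` samples (both endpoints included) for linear
    interpolation; used by the compiled simulation loop and for writing
    the kernel shapes to delimited text.
    """
    grid = np.linspace(-np.pi, np.pi, size + 1)
    return np.asarray(get_kernel(name)(grid), dtype=float)


def tabulate_kernels(path, size: int = 1024) -> None:
    """Write ``(dtheta, Lambda_0, Lambda_1)`` rows as tab-delimited text."""
    grid = np.linspace(-np.pi, np.pi, size + 1)
    data = np.column_stack([grid, kernel_lambda0(grid), kernel_lambda1(grid)])
    np.savetxt(path, data, delimiter="\t", header="dtheta\tlambda0\tlambda1")


@dataclass(frozen=True)
class PlasticityRule:
    """Kernel choice, learning rates and Dale mode for the weight dynamics."""

    kernel: str = "asymmetric_exponential"
    eps_slow: float = 1e-5
    eps_fast: float = 0.1
    gate_threshold: float = 0.1
    dale_mode: str = "ei"

    def __post_init__(self) -> None:
        if self.kernel not in KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.dale_mode not in MODES:
            raise ValueError(f"unknown dale_mode {self.dale_mode!r}")
        if not 0.0 < self.eps_slow < self.eps_fast < 1.0:
            raise ValueError(
                "learning rates must satisfy 0 < eps_slow < eps_fast < 1, got "
                f"eps_slow={self.eps_slow}, eps_fast={self.eps_fast}"
            )

    def kernel_func(self):
        return get_kernel(self.kernel)

    def with_slow_rate(self, eps_slow: float) -> "PlasticityRule":
        return replace(self, eps_slow=eps_slow)


def default_rule(mode: str) -> PlasticityRule:
    """Default plasticity rule for a network mode.

    The unlabelled variant uses the cosine kernel with the linear
    relaxation dynamics; Dale-constrained variants use the asymmetric
    exponential kernel with soft-bounded logistic dynamics.
    """
    kernel = "cosine" if mode == "unlabelled" else "asymmetric_exponential"
    return PlasticityRule(kernel=kernel, dale_mode=mode)


def weight_derivative(
    kappa: float,
    dtheta: float,
    pre_type: int,
    post_type: int,
    pre_stimulated: bool,
    rule: PlasticityRule,
) -> float:
    """Time derivative ``dkappa/dt`` of a single synaptic weight.

    ``pre_stimulated`` is true iff the external current at the pre-synaptic
    neuron exceeds the gate threshold in magnitude.
    """
    lam = float(rule.kernel_func()(dtheta))
    if rule.dale_mode == "unlabelled":
        if not -1.0 <= kappa <= 1.0:
            raise ValueError(f"kappa={kappa} outside [-1, 1]")
        eps = rule.eps_slow + (rule.eps_fast if pre_stimulated else 0.0)
        return eps * (-kappa + lam)

    if pre_type == INHIBITORY:
        if not -1.0 <= kappa <= 0.0:
            raise ValueError(f"kappa={kappa} outside [-1, 0] for inhibitory column")
    else:
        if not 0.0 <= kappa <= 1.0:
            raise ValueError(f"kappa={kappa} outside [0, 1] for excitatory column")
    m = abs(kappa)
    both_excitatory = pre_type == EXCITATORY and post_type == EXCITATORY
    eps = rule.eps_slow
    if pre_stimulated and both_excitatory:
        eps += rule.eps_fast
    # soft-bound factor on |kappa|; the derivative acts on the signed weight
    return eps * m * (1.0 - m) * lam


def update_weights(
    state: NetworkState,
    currents: np.ndarray,
    rule: PlasticityRule,
    dt: float,
) -> NetworkState:
    """Advance every off-diagonal weight by one Euler step (in place).

    Phase differences use ``dtheta[i, j] = theta_j - theta_i``.  Results
    are clamped to the closed bound interval shrunk by ``EPS_NUM``; the
    diagonal is untouched.
    """
    currents = _check_currents(state, currents)
    th = state.phases
    lam = rule.kernel_func()(th[None, :] - th[:, None])
    gate = np.abs(currents) > rule.gate_threshold
    k = state.weights

    if rule.dale_mode == "unlabelled":
        eps = rule.eps_slow + rule.eps_fast * gate[None, :]
        k += eps * (-k + lam) * dt
        np.clip(k, -1.0 + EPS_NUM, 1.0 - EPS_NUM, out=k)
    else:
        sgn = state.column_signs()[None, :]
        exc = state.types == EXCITATORY
        ee = exc[:, None] & exc[None, :]
        eps = rule.eps_slow + rule.eps_fast * (gate[None, :] & ee)
        a = np.abs(k)
        k += eps * a * (1.0 - a) * lam * dt
        m = np.clip(k * sgn, EPS_NUM, 1.0 - EPS_NUM)
        state.weights = k = m * sgn
    np.fill_diagonal(k, 0.0)
    return state
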