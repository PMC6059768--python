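"""Plasticity primitives shared by all network models and the offline evaluator.

This module collects the synaptic machinery of the model family:

* Tsodyks-Markram short-term plasticity (STP), expressed through two
  per-neuron variables: the fraction of available resources ``D`` and the
  utilization (release probability) ``F``.  Between spikes both relax
  exponentially toward their resting values ``(1, U)``; at a spike the
  synapse releases ``D * F`` and the variables jump.
* Pair-based STDP windows (asymmetric exponential, symmetric
  difference-of-exponentials, symmetric Gaussian) and spike-pairing
  schemes (all-to-all, nearest-neighbor).
* The low-pass eligibility trace that turns an instantaneous Hebbian/STDP
  drive into slow weight changes.
* Weight normalization rules used for homeostasis.

All functions are pure and vectorized over numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "STPParams",
    "STPState",
    "stp_decay",
    "stp_on_spike",
    "stp_release_train",
    "STDPWindow",
    "AsymmetricExpWindow",
    "SymmetricExpDiffWindow",
    "GaussianWindow",
    "stdp_kernel",
    "pair_spikes",
    "EligibilityParams",
    "eligibility_step",
    "normalize_weights",
]


@dataclass(frozen=True)
class STPParams:
    """Short-term plasticity parameters.

    Parameters
    ----------
    U : float
        Initial release probability (resting utilization), in (0, 1].
    tau_std : float
        Recovery time constant of short-term depression, ms.
    tau_stf : float
        Decay time constant of short-term facilitation, ms.
    """

    U: float
    tau_std: float
    tau_stf: float

    def __post_init__(self) -> None:
        if not (0.0 < self.U <= 1.0):
            raise ValueError(f"U must be in (0, 1], got {self.U}")
        if self.tau_std <= 0 or self.tau_stf <= 0:
            raise ValueError("STP time constants must be positive")


@dataclass
class STPState:
    """Per-synapse (or per-neuron) STP variables.

    ``D`` is the fraction of available neurotransmitter resources and ``F``
    the utilization.  At rest ``(D, F) = (1, U)``.  Both can be scalars or
    arrays of identical shape.
    """

    D: np.ndarray
    F: np.ndarray

    @classmethod
    def resting(cls, params: STPParams, shape: tuple[int, ...] | int = ()) -> "STPState":
        return cls(D=np.ones(shape), F=np.full(shape, params.U, dtype=float))


def stp_decay(state: STPState, dt: float, params: STPParams) -> STPState:
    """Relax (D, F) toward (1, U) for a spike-free interval of ``dt`` ms.

    Uses the closed-form solution of the linear relaxation ODEs, so it is
    exact for any ``dt >= 0``.
    """
    if dt < 0:
        raise ValueError("dt must be nonnegative")
    ed = np.exp(-dt / params.tau_std)
    ef = np.exp(-dt / params.tau_stf)
    D = 1.0 - (1.0 - state.D) * ed
    F = params.U + (state.F - params.U) * ef
    return STPState(D=np.asarray(D, dtype=float), F=np.asarray(F, dtype=float))


def stp_on_spike(
    state: STPState, params: STPParams, facilitation_first: bool = False
) -> tuple[np.ndarray, STPState]:
    """Apply the spike-triggered jumps and return the released amount.

    The default convention computes the release ``D * F`` with the pre-jump
    values, then applies both jumps (``D -= D*F``, ``F += U*(1-F)``).  With
    ``facilitation_first=True`` the facilitation jump is applied before the
    release is computed (the classical Tsodyks-Markram reading); the default
    makes the first release of a resting synapse exactly ``U``, which
    matches the unit initial amplitude ratio of a regular pulse train.
    """
    D, F = np.asarray(state.D, dtype=float), np.asarray(state.F, dtype=float)
    if facilitation_first:
        F = F + params.U * (1.0 - F)
        release = D * F
        D = D - release
    else:
        release = D * F
        D = D - release
        F = F + params.U * (1.0 - F)
    return release, STPState(D=D, F=F)


def stp_release_train(
    spike_times: np.ndarray,
    params: STPParams,
    facilitation_first: bool = False,
) -> np.ndarray:
    """Release amounts ``D*F`` for each spike of a train, event-based.

    ``spike_times`` may carry leading batch axes; spikes run along the last
    axis and must be sorted ascending along it.  The state starts at the
    resting point ``(1, U)`` and evolves by exact inter-spike decay plus the
    spike jumps of :func:`stp_on_spike`.

    Returns an array of released amounts with the same shape.
    """
    t = np.asarray(spike_times, dtype=float)
    n = t.shape[-1]
    out = np.empty_like(t)
    state = STPState.resting(params, t.shape[:-1])
    prev = None
    for k in range(n):
        tk = t[..., k]
        if prev is not None:
            # exact decay over the inter-spike interval, elementwise dt
            dt = tk - prev
            ed = np.exp(-dt / params.tau_std)
            ef = np.exp(-dt / params.tau_stf)
            state = STPState(
                D=1.0 - (1.0 - state.D) * ed,
                F=params.U + (state.F - params.U) * ef,
            )
        release, state = stp_on_spike(state, params, facilitation_first)
        out[..., k] = release
        prev = tk
    return out


# ---------------------------------------------------------------------------
# STDP windows
# ---------------------------------------------------------------------------


class STDPWindow:
    """Base class for pair-based STDP kernels f(dt), dt = t_post - t_pre."""

    def __call__(self, delta_t: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class AsymmetricExpWindow(STDPWindow):
    """Classical asymmetric STDP: potentiation for post-after-pre, depression
    otherwise.  ``f(dt) = A+ exp(-dt/tau+)`` for dt >= 0, ``-A- exp(dt/tau-)``
    for dt < 0.  Simultaneous spikes fall on the potentiation branch."""

    a_plus: float = 1.0
    a_minus: float = 0.5
    tau_plus: float = 20.0
    tau_minus: float = 40.0

    def __call__(self, delta_t: np.ndarray) -> np.ndarray:
        dt = np.asarray(delta_t, dtype=float)
        pos = self.a_plus * np.exp(-dt / self.tau_plus)
        neg = -self.a_minus * np.exp(dt / self.tau_minus)
        return np.where(dt >= 0, pos, neg)


@dataclass(frozen=True)
class SymmetricExpDiffWindow(STDPWindow):
    """Symmetric STDP as a difference of exponentials in |dt|: potentiation
    for temporally close spikes, depression for distant ones."""

    a_plus: float = 1.0
    a_minus: float = 0.5
    tau_plus: float = 20.0
    tau_minus: float = 40.0

    def __call__(self, delta_t: np.ndarray) -> np.ndarray:
        adt = np.abs(np.asarray(delta_t, dtype=float))
        return self.a_plus * np.exp(-adt / self.tau_plus) - self.a_minus * np.exp(
            -adt / self.tau_minus
        )


@dataclass(frozen=True)
class GaussianWindow(STDPWindow):
    """Symmetric Gaussian STDP window (CA3 recurrent synapses); the default
    width of 70 ms is the experimentally reported broad window."""

    a: float = 1.0
    tau: float = 70.0

    def __call__(self, delta_t: np.ndarray) -> np.ndarray:
        dt = np.asarray(delta_t, dtype=float)
        return self.a * np.exp(-0.5 * (dt / self.tau) ** 2)


def stdp_kernel(window: STDPWindow, t_post: np.ndarray, t_pre: np.ndarray) -> np.ndarray:
    """Evaluate a window at ``t_post - t_pre`` (broadcasting)."""
    return window(np.asarray(t_post, dtype=float) - np.asarray(t_pre, dtype=float))


def pair_spikes(
    mode: Literal["all_to_all", "nearest_neighbor"],
    pre_times: Sequence[float],
    post_times: Sequence[float],
) -> list[tuple[float, float]]:
    """Enumerate (t_post, t_pre) spike pairs under a pairing scheme.

    ``all_to_all`` returns the Cartesian product.  ``nearest_neighbor``
    returns, for each presynaptic spike, the latest postsynaptic spike at or
    before it and the earliest one strictly after it (each if it exists).
    Inputs must be sorted ascending.
    """
    pre = np.asarray(pre_times, dtype=float)
    post = np.asarray(post_times, dtype=float)
    if pre.size == 0 or post.size == 0:
        return []
    if mode == "all_to_all":
        return [(tp, tq) for tq in pre for tp in post]
    if mode != "nearest_neighbor":
        raise ValueError(f"unknown pairing mode {mode!r}")
    pairs: list[tuple[float, float]] = []
    for tq in pre:
        idx = np.searchsorted(post, tq, side="right")
        if idx > 0:
            pairs.append((float(post[idx - 1]), float(tq)))
        if idx < post.size:
            pairs.append((float(post[idx]), float(tq)))
    return pairs


# ---------------------------------------------------------------------------
# Eligibility trace and normalization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EligibilityParams:
    """Parameters of the low-pass plasticity stage: learning-rate gain
    ``eta`` and time constant ``tau_w`` (ms) shared by the eligibility trace
    and the weight integration."""

    eta: float
    tau_w: float

    def __post_init__(self) -> None:
        if self.tau_w <= 0:
            raise ValueError("tau_w must be positive")


def eligibility_step(
    w: np.ndarray,
    delta: np.ndarray,
    drive: np.ndarray,
    dt: float,
    params: EligibilityParams,
) -> tuple[np.ndarray, np.ndarray]:
    """One forward-Euler step of the coupled slow-plasticity pair.

    dw/dt = delta,  tau_w * d(delta)/dt = -delta + eta * drive.

    The weight moves by the current eligibility before the trace itself is
    updated; for an impulse of drive with area G the eventual total weight
    change is ``eta * G`` (the eligibility trace integrates to ``eta*G``
    regardless of ``tau_w``, which only sets how slowly it is paid out).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    w_new = w + dt * delta
    delta_new = delta + dt * (-delta + params.eta * np.asarray(drive)) / params.tau_w
    return w_new, delta_new


def normalize_weights(
    weights: np.ndarray,
    reference_sums: np.ndarray | float,
    mode: Literal["rescale_to_initial", "cap_at_one"],
    axis: int = 1,
) -> np.ndarray:
    """Homeostatic renormalization of incoming weights.

    ``weights[i, j]`` is the weight from j onto i, so incoming sums run over
    ``axis=1`` by default.  ``rescale_to_initial`` forces each incoming sum
    back to its reference value exactly (rows with zero current sum are left
    unchanged); ``cap_at_one`` rescales only rows whose sum exceeds the
    reference (the cap), and never increases a weight.
    """
    w = np.asarray(weights, dtype=float)
    sums = w.sum(axis=axis, keepdims=True)
    ref = np.asarray(reference_sums, dtype=float)
    if ref.ndim == w.ndim - 1:
        ref = np.expand_dims(ref, axis)
    if mode == "rescale_to_initial":
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(sums > 0, ref / np.where(sums > 0, sums, 1.0), 1.0)
        return w * scale
    if mode == "cap_at_one":
        scale = np.where(sums > ref, ref / np.where(sums > 0, sums, 1.0), 1.0)
        return w * scale
    raise ValueError(f"unknown normalization mode {mode!r}")
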