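"""One-dimensional recurrent rate network with STP-modulated Hebbian plasticity.

A chain of 500 threshold-linear rate units with distance-dependent symmetric
excitatory weights, a single global inhibitory feedback variable, and
Tsodyks-Markram short-term plasticity on every presynaptic terminal.  A brief
external pulse at one end launches a traveling activity packet (a model
firing sequence).  Long-term weights evolve through a low-pass Hebbian rule
whose drive is either

* ``standard``:       r_post * r_pre
* ``stp_modulated``:  r_post * r_pre * D_pre * F_pre  (release-gated)
* ``adp``:            p_post * r_pre, with p a low-pass of the postsynaptic
  rate emulating accumulating afterdepolarization.

The release-gated and ADP rules both potentiate connections from the head to
the tail of the packet, i.e. opposite to the propagation direction, which is
the mechanism behind reverse-replay-based learning studied here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .plasticity import EligibilityParams, STPParams

__all__ = [
    "RateNetParams",
    "StimulusEvent",
    "RateNet1D",
    "init_weights_1d",
    "classify_direction",
    "run_fig1_protocol",
    "run_fig6_protocol",
    "FIG6_CONDITIONS",
]


@dataclass(frozen=True)
class RateNetParams:
    """Parameters of the 1-D rate network (defaults follow the reference
    parameter set of the replay model)."""

    n: int = 500
    rho: float = 0.0025  # gain of the threshold-linear transfer, 1/input-unit
    epsilon: float = 0.5  # firing threshold, input units
    tau_exc: float = 10.0  # ms
    tau_inh: float = 10.0  # ms
    w_inh: float = 1.0
    w_max: float = 27.0  # peak initial weight
    d: float = 5.0  # weight length scale, neuron indices
    stp: STPParams = field(default_factory=lambda: STPParams(U=0.6, tau_std=500.0, tau_stf=200.0))
    elig: EligibilityParams = field(default_factory=lambda: EligibilityParams(eta=20.0, tau_w=1000.0))
    hebbian_mode: Literal["standard", "stp_modulated", "adp"] = "stp_modulated"
    tau_adp: float = 80.0  # ms, adp mode only
    normalization: Literal["none", "rescale_to_initial"] = "none"
    dt: float = 1.0  # ms

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least two neurons")
        for name in ("rho", "tau_exc", "tau_inh", "w_max", "d", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class StimulusEvent:
    """External input pulse: ``amplitude`` input units to ``targets`` (an
    index slice) for ``duration`` ms starting at ``t_on``."""

    t_on: float
    duration: float = 10.0
    amplitude: float = 5.0
    targets: tuple[int, int] = (0, 11)  # half-open index range

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def init_weights_1d(n: int, w_max: float, d: float) -> np.ndarray:
    """Distance-dependent symmetric weights w_ij = w_max exp(-|i-j|/d) with a
    zero diagonal (no self-connections); truncated at the array edges."""
    if n < 2:
        raise ValueError("need at least two neurons")
    idx = np.arange(n)
    w = w_max * np.exp(-np.abs(idx[:, None] - idx[None, :]) / d)
    np.fill_diagonal(w, 0.0)
    return w


class RateNet1D:
    """Stateful Euler simulator of the 1-D rate network.

    ``W[i, j]`` is the weight from presynaptic j onto postsynaptic i.
    """

    def __init__(self, params: RateNetParams, rng: np.random.Generator | int | None = None):
        self.params = params
        self.rng = np.random.default_rng(rng)
        n = params.n
        self.W = init_weights_1d(n, params.w_max, params.d)
        self._init_insum = self.W.sum(axis=1)
        self.Delta = np.zeros((n, n))
        self.I_exc = np.zeros(n)
        self.I_inh = 0.0
        self.D = np.ones(n)
        self.F = np.full(n, params.stp.U)
        self.p = np.zeros(n)
        self.t = 0.0

    @property
    def r(self) -> np.ndarray:
        """Instantaneous firing rates from the current input currents."""
        return self._rates(0.0)

    def _rates(self, i_ext: np.ndarray | float) -> np.ndarray:
        p = self.params
        return np.maximum(0.0, p.rho * (self.I_exc - self.I_inh + i_ext - p.epsilon))

    def step(self, i_ext: np.ndarray | float = 0.0) -> np.ndarray:
        """Advance one Euler step of ``dt`` ms; returns the rates used."""
        p = self.params
        dt = p.dt
        r = self._rates(i_ext)
        if not np.all(np.isfinite(r)):
            raise FloatingPointError(f"non-finite rates at t={self.t} ms")
        rdf = r * self.D * self.F

        # Hebbian drive (sparse outer product over active units)
        post = self.p if p.hebbian_mode == "adp" else r
        pre = r if p.hebbian_mode in ("standard", "adp") else rdf
        rows = np.flatnonzero(post)
        cols = np.flatnonzero(pre)
        self.Delta *= 1.0 - dt / p.elig.tau_w
        if rows.size and cols.size:
            self.Delta[np.ix_(rows, cols)] += (dt * p.elig.eta / p.elig.tau_w) * np.outer(
                post[rows], pre[cols]
            )
        self.W += dt * self.Delta
        np.fill_diagonal(self.W, 0.0)

        if p.normalization == "rescale_to_initial":
            s = self.W.sum(axis=1)
            scale = np.where(s > 0, self._init_insum / np.where(s > 0, s, 1.0), 1.0)
            self.W *= scale[:, None]

        # currents, inhibition, STP (forward Euler)
        self.I_exc += dt * (-self.I_exc / p.tau_exc + self.W @ rdf)
        self.I_inh += dt * (-self.I_inh / p.tau_inh + p.w_inh * rdf.sum())
        U = p.stp.U
        self.D += dt * ((1.0 - self.D) / p.stp.tau_std - rdf)
        self.F += dt * ((U - self.F) / p.stp.tau_stf + U * (1.0 - self.F) * r)
        if p.hebbian_mode == "adp":
            self.p += dt * (-self.p + r) / p.tau_adp
        self.t += dt
        return r

    def run(
        self,
        t_total: float,
        stimuli: list[StimulusEvent] = (),
        record_every: float = 10.0,
        callback=None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Run for ``t_total`` ms applying the stimulus schedule.

        Returns ``(times, rates)`` sampled every ``record_every`` ms.
        ``callback(t, net)`` is invoked at each recording sample.
        """
        p = self.params
        n_steps = int(round(t_total / p.dt))
        stride = max(1, int(round(record_every / p.dt)))
        times, recs = [], []
        i_ext = np.zeros(p.n)
        for k in range(n_steps):
            i_ext[:] = 0.0
            for s in stimuli:
                if s.t_on <= self.t < s.t_on + s.duration:
                    i_ext[s.targets[0] : s.targets[1]] = s.amplitude
            r = self.step(i_ext)
            if k % stride == 0:
                times.append(self.t - p.dt)
                recs.append(r.copy())
                if callback is not None:
                    callback(self.t, self)
        return np.asarray(times), np.asarray(recs)


def classify_direction(
    times: np.ndarray,
    rates: np.ndarray,
    center: int,
    left_mark: int,
    right_mark: int,
    active_thresh: float = 1e-6,
) -> str:
    """Classify sequence propagation from a rate recording.

    A recording (samples x neurons) following a center stimulus is scanned
    for suprathreshold activity reaching beyond ``left_mark`` (toward lower
    indices) or ``right_mark``.  Returns one of ``bidirectional``,
    ``reverse_only``, ``forward_only``, ``none`` where forward = increasing
    indices.
    """
    went_left = went_right = False
    for r in np.asarray(rates):
        m = r.max()
        if m <= active_thresh:
            continue
        active = np.flatnonzero(r > 0.1 * m)
        if active.size == 0:
            continue
        if active.min() < left_mark:
            went_left = True
        if active.max() > right_mark:
            went_right = True
    if went_left and went_right:
        return "bidirectional"
    if went_left:
        return "reverse_only"
    if went_right:
        return "forward_only"
    return "none"


def _mode_params(hebbian_mode: str) -> RateNetParams:
    base = RateNetParams()
    if hebbian_mode == "standard":
        return replace(base, hebbian_mode="standard",
                       elig=EligibilityParams(eta=4.0, tau_w=1000.0))
    if hebbian_mode == "stp_modulated":
        return base
    if hebbian_mode == "adp":
        return replace(base, hebbian_mode="adp", tau_adp=80.0,
                       elig=EligibilityParams(eta=4.0, tau_w=1000.0))
    raise ValueError(f"unknown hebbian mode {hebbian_mode!r}")


def run_fig1_protocol(
    hebbian_mode: Literal["standard", "stp_modulated", "adp"] = "stp_modulated",
    seed: int = 0,
    params: RateNetParams | None = None,
    t_total: float = 6000.0,
) -> dict:
    """Sequence-direction experiment: launch a forward sequence from one end
    at t = 0, probe with a center stimulus at t = 3 s, and classify how the
    second sequence propagates.

    Returns a dict with the rate recording, weight snapshots at 0 and 3 s,
    the outgoing-weight profile changes of the center neuron, and the
    direction verdict for the second sequence.
    """
    p = params if params is not None else _mode_params(hebbian_mode)
    net = RateNet1D(p, rng=seed)
    w0 = net.W.copy()
    stimuli = [
        StimulusEvent(t_on=0.0, targets=(0, 11)),
        StimulusEvent(t_on=3000.0, targets=(245, 256)),
    ]
    snap = {}

    def cb(t, n):
        if 2999.0 <= t <= 3001.0 and "w3s" not in snap:
            snap["w3s"] = n.W.copy()

    times, rates = net.run(t_total, stimuli, callback=cb)
    w3 = snap.get("w3s", net.W.copy())
    post = times >= 3000.0
    verdict = classify_direction(times[post], rates[post], 250, 150, 350)
    center = 250
    return {
        "times": times,
        "rates": rates,
        "w_initial": w0,
        "w_3s": w3,
        "center_outgoing_change": w3[:, center] - w0[:, center],
        "verdict": verdict,
    }


def weight_bias(W: np.ndarray, j: int) -> float:
    """Outgoing-weight direction bias of neuron j: summed weights onto
    lower-index targets minus higher-index ones (positive = reverse of the
    increasing-index direction)."""
    return float(W[:j, j].sum() - W[j + 1 :, j].sum())


#: Parameter overrides of the three replay-consolidation conditions:
#: (tau_w, STPParams, w_max).
FIG6_CONDITIONS = {
    1: (5000.0, STPParams(U=0.6, tau_std=500.0, tau_stf=200.0), 27.0),
    2: (500.0, STPParams(U=0.6, tau_std=500.0, tau_stf=200.0), 27.0),
    3: (500.0, STPParams(U=0.3, tau_std=200.0, tau_stf=200.0), 30.0),
}


def run_fig6_protocol(
    condition: int,
    seed: int = 0,
    t_total: float = 30000.0,
    bias_every: float = 100.0,
) -> dict:
    """Replay-consolidation experiment: five forward sequences from the end
    (one per second for 5 s), then repeated center stimulation (every second
    from 10 s) evokes reverse replay that gradually overwrites the weight
    bias at a neuron on the replayed path (#100) while a neuron off the path
    (#400) keeps its initial reverse-side bias.

    Homeostatic rescaling keeps each neuron's incoming weight sum at its
    initial value.  Returns bias time series at neurons 100 and 400.
    """
    tau_w, stp, w_max = FIG6_CONDITIONS[condition]
    p = replace(
        RateNetParams(),
        stp=stp,
        w_max=w_max,
        elig=EligibilityParams(eta=20.0, tau_w=tau_w),
        normalization="rescale_to_initial",
    )
    net = RateNet1D(p, rng=seed)
    stimuli = [StimulusEvent(t_on=1000.0 * k, targets=(0, 11)) for k in range(5)]
    stimuli += [
        StimulusEvent(t_on=1000.0 * k, targets=(245, 256)) for k in range(10, int(t_total / 1000))
    ]
    bias_t, bias_100, bias_400 = [], [], []

    def cb(t, n):
        bias_t.append(t)
        bias_100.append(weight_bias(n.W, 100))
        bias_400.append(weight_bias(n.W, 400))

    times, rates = net.run(t_total, stimuli, record_every=bias_every, callback=cb)
    return {
        "times": times,
        "rates": rates,
        "bias_times": np.asarray(bias_t),
        "bias_100": np.asarray(bias_100),
        "bias_400": np.asarray(bias_400),
        "final_W": net.W.copy(),
    }
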