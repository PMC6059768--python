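"""One-dimensional Izhikevich spiking network with STP-modulated STDP.

Spiking counterpart of the rate chain: 500 Izhikevich neurons (regular
spiking parameters, whose adaptation favors moving activity bumps) coupled by
conductance-based AMPA and NMDA synapses with a 2-ms axonal delay, global
inhibitory feedback, and Tsodyks-Markram short-term plasticity at every
presynaptic terminal.  AMPA weights are plastic under pair-based STDP with
all-to-all spike pairing; each pair's contribution is weighted by the
presynaptic release ``D*F`` at the presynaptic spike when the rule is
STP-modulated.

The online implementation uses the standard exact trace scheme: pairs whose
presynaptic spike comes second are applied at the presynaptic spike using
postsynaptic spike-count traces; pairs whose postsynaptic spike comes second
are applied at the postsynaptic spike using presynaptic traces that
accumulated ``D*F`` at the presynaptic spike.  Simultaneous pairs are counted
once with the kernel value at zero lag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .plasticity import EligibilityParams, STPParams
from .rate_net_1d import classify_direction, init_weights_1d

__all__ = [
    "IzhikevichParams",
    "SynapseParams",
    "SpikingNetParams",
    "SpikingNet1D",
    "izhikevich_step",
    "nmda_gate",
    "run_spiking_protocol",
]


@dataclass(frozen=True)
class IzhikevichParams:
    """Standard Izhikevich neuron coefficients (regular spiking defaults)."""

    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 8.0
    v_thresh: float = 30.0  # mV, spike cut


@dataclass(frozen=True)
class SynapseParams:
    tau_ampa: float = 5.0  # ms
    tau_nmda: float = 150.0  # ms
    tau_inh: float = 10.0  # ms
    t_delay: float = 2.0  # ms, axonal delay
    w_max_ampa: float = 0.3
    nmda_ratio: float = 0.2  # w_NMDA / w_AMPA
    nmda_enabled: bool = True

    def __post_init__(self) -> None:
        if self.t_delay < 0:
            raise ValueError("t_delay must be nonnegative")


@dataclass(frozen=True)
class SpikingNetParams:
    n: int = 500
    neuron: IzhikevichParams = field(default_factory=IzhikevichParams)
    syn: SynapseParams = field(default_factory=SynapseParams)
    w_inh: float = 1.0
    d: float = 5.0  # weight length scale
    stp: STPParams = field(default_factory=lambda: STPParams(U=0.6, tau_std=500.0, tau_stf=200.0))
    elig: EligibilityParams = field(default_factory=lambda: EligibilityParams(eta=0.05, tau_w=1000.0))
    stdp_kind: Literal["symmetric", "asymmetric"] = "symmetric"
    stp_modulated: bool = True
    a_plus: float = 1.0
    a_minus: float = 0.5
    tau_plus: float = 20.0
    tau_minus: float = 40.0
    dt: float = 0.5  # ms
    rate_ceiling: float = 0.8  # abort if this fraction of the net spikes in one step


def izhikevich_step(
    v: np.ndarray, u: np.ndarray, i_input: np.ndarray, dt: float, params: IzhikevichParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One Euler step of the Izhikevich model with reset; returns
    (v, u, spiked).  Spikes are recorded at the step where v crossed the
    30-mV cut, then v <- c and u <- u + d."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    v = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + i_input)
    u = u + dt * params.a * (params.b * v - u)
    spiked = v >= params.v_thresh
    v = np.where(spiked, params.c, v)
    u = np.where(spiked, u + params.d, u)
    return v, u, spiked


def nmda_gate(v: np.ndarray) -> np.ndarray:
    """Voltage dependence of the NMDA conductance: ((V+80)/60)^2 / (1 + ...),
    zero at -80 mV and saturating toward 1 with depolarization."""
    x = ((np.asarray(v, dtype=float) + 80.0) / 60.0) ** 2
    return x / (1.0 + x)


class SpikingNet1D:
    """Euler simulator (dt = 0.5 ms) of the spiking chain."""

    def __init__(self, params: SpikingNetParams, rng: np.random.Generator | int | None = None):
        self.params = params
        self.rng = np.random.default_rng(rng)
        n = params.n
        self.W = init_weights_1d(n, params.syn.w_max_ampa, params.d)
        self.W_nmda = (
            params.syn.nmda_ratio * self.W.copy() if params.syn.nmda_enabled else np.zeros((n, n))
        )
        self.Delta = np.zeros((n, n))
        self.v = np.full(n, -65.0)
        self.u = params.neuron.b * self.v
        self.g_ampa = np.zeros(n)
        self.g_nmda = np.zeros(n)
        self.I_inh = 0.0
        self.D = np.ones(n)
        self.F = np.full(n, params.stp.U)
        # STDP traces: postsynaptic spike counts (xp, xm) and presynaptic
        # release-weighted traces (yp, ym)
        self.xp = np.zeros(n)
        self.xm = np.zeros(n)
        self.yp = np.zeros(n)
        self.ym = np.zeros(n)
        self.t = 0.0
        self.spike_times: list[list[float]] = [[] for _ in range(n)]
        delay_steps = max(1, int(round(params.syn.t_delay / params.dt)))
        self._delay_steps = delay_steps
        self._queue: list[tuple[np.ndarray, np.ndarray]] = [
            (np.empty(0, int), np.empty(0)) for _ in range(delay_steps)
        ]
        self._qpos = 0
        self.plasticity_enabled = True

    def _f0(self) -> float:
        p = self.params
        if p.stdp_kind == "asymmetric":
            return p.a_plus
        return p.a_plus - p.a_minus

    def step(self, i_ext: np.ndarray | float = 0.0) -> np.ndarray:
        p = self.params
        dt = p.dt
        n = p.n

        # membrane update
        i_syn = self.g_ampa * (0.0 - self.v)
        if p.syn.nmda_enabled:
            i_syn = i_syn + nmda_gate(self.v) * self.g_nmda * (0.0 - self.v)
        self.v, self.u, spiked = izhikevich_step(
            self.v, self.u, i_syn - self.I_inh + i_ext, dt, p.neuron
        )
        spk = np.flatnonzero(spiked)
        if spk.size > p.rate_ceiling * n:
            raise RuntimeError(
                f"runaway activity: {spk.size}/{n} neurons spiked in one step at t={self.t} ms"
            )

        # conductance and inhibition decay, then delayed arrivals
        self.g_ampa *= 1.0 - dt / p.syn.tau_ampa
        self.g_nmda *= 1.0 - dt / p.syn.tau_nmda
        self.I_inh *= 1.0 - dt / p.syn.tau_inh
        arr_idx, arr_rel = self._queue[self._qpos]
        if arr_idx.size:
            self.g_ampa += self.W[:, arr_idx] @ arr_rel
            if p.syn.nmda_enabled:
                self.g_nmda += self.W_nmda[:, arr_idx] @ arr_rel
            self.I_inh += p.w_inh * arr_rel.sum()

        # STP: continuous relaxation plus spike jumps; release uses pre-jump D, F
        U = p.stp.U
        self.D += dt * (1.0 - self.D) / p.stp.tau_std
        self.F += dt * (U - self.F) / p.stp.tau_stf
        release = self.D[spk] * self.F[spk]
        self.D[spk] -= release
        self.F[spk] += U * (1.0 - self.F[spk])
        self._queue[self._qpos] = (spk, release)
        self._qpos = (self._qpos + 1) % self._delay_steps

        # STDP traces decay
        self.xp *= 1.0 - dt / p.tau_plus
        self.xm *= 1.0 - dt / p.tau_minus
        self.yp *= 1.0 - dt / p.tau_plus
        self.ym *= 1.0 - dt / p.tau_minus

        if self.plasticity_enabled and spk.size:
            gain = p.elig.eta / p.elig.tau_w
            df = release if p.stp_modulated else np.ones_like(release)
            if p.stdp_kind == "symmetric":
                post_term = p.a_plus * self.xp - p.a_minus * self.xm  # at pre spikes
                pre_term = p.a_plus * self.yp - p.a_minus * self.ym  # at post spikes
            else:
                post_term = -p.a_minus * self.xm
                pre_term = p.a_plus * self.yp
            # pairs applied at this presynaptic spike (post fired earlier)
            self.Delta[:, spk] += gain * post_term[:, None] * df[None, :]
            # pairs applied at this postsynaptic spike (pre fired earlier)
            self.Delta[spk, :] += gain * pre_term[None, :]
            # simultaneous pairs, counted once at zero lag
            self.Delta[np.ix_(spk, spk)] += gain * self._f0() * df[None, :]
            np.fill_diagonal(self.Delta, 0.0)
            # trace increments after drive so same-step pairs are not doubled
            self.xp[spk] += 1.0
            self.xm[spk] += 1.0
            trace_df = release if p.stp_modulated else np.ones_like(release)
            self.yp[spk] += trace_df
            self.ym[spk] += trace_df

        if self.plasticity_enabled:
            self.W += dt * self.Delta
            self.Delta *= 1.0 - dt / p.elig.tau_w
            np.fill_diagonal(self.W, 0.0)

        for j in spk:
            self.spike_times[j].append(self.t)
        self.t += dt
        return spiked

    def run(self, t_total: float, stimuli=()) -> None:
        p = self.params
        n_steps = int(round(t_total / p.dt))
        i_ext = np.zeros(p.n)
        for _ in range(n_steps):
            i_ext[:] = 0.0
            for s in stimuli:
                if s.t_on <= self.t < s.t_on + s.duration:
                    i_ext[s.targets[0] : s.targets[1]] = s.amplitude
            self.step(i_ext)

    def raster(self) -> np.ndarray:
        """Spike events as a (time ms, neuron index) array sorted by time."""
        rows = [
            (t, j) for j, ts in enumerate(self.spike_times) for t in ts
        ]
        if not rows:
            return np.empty((0, 2))
        out = np.asarray(rows, dtype=float)
        return out[np.lexsort((out[:, 1], out[:, 0]))]

    def binned_rates(self, t_max: float, bin_ms: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
        """Spike counts per neuron per time bin (bins x neurons)."""
        n_bins = int(np.ceil(t_max / bin_ms))
        counts = np.zeros((n_bins, self.params.n))
        for j, ts in enumerate(self.spike_times):
            if ts:
                b = np.minimum((np.asarray(ts) / bin_ms).astype(int), n_bins - 1)
                np.add.at(counts[:, j], b, 1.0)
        times = np.arange(n_bins) * bin_ms
        return times, counts


def run_spiking_protocol(
    stdp_kind: Literal["symmetric", "asymmetric"] = "symmetric",
    stp_modulated: bool = True,
    short_tau_variant: bool = False,
    seed: int = 0,
    t_total: float = 6000.0,
) -> dict:
    """Spiking sequence-direction experiment mirroring the rate-model one.

    Launch a sequence from one end at t = 0, probe from the center at 3 s,
    classify the second sequence's direction, and return the AMPA weight
    snapshots.  ``short_tau_variant`` switches to the fast-synapse
    configuration (tau_AMPA = 2.5 ms, tau_inh = 5 ms, w_max = 0.35, NMDA
    off).
    """
    from .rate_net_1d import StimulusEvent

    syn = SynapseParams()
    if short_tau_variant:
        syn = replace(syn, tau_ampa=2.5, tau_inh=5.0, w_max_ampa=0.35, nmda_enabled=False)
    eta = 0.05 if stp_modulated else 0.01
    params = SpikingNetParams(
        syn=syn,
        stdp_kind=stdp_kind,
        stp_modulated=stp_modulated,
        elig=EligibilityParams(eta=eta, tau_w=1000.0),
    )
    net = SpikingNet1D(params, rng=seed)
    w0 = net.W.copy()
    net.run(3000.0, [StimulusEvent(t_on=0.0, targets=(0, 11))])
    w3 = net.W.copy()
    net.run(t_total - 3000.0, [StimulusEvent(t_on=3000.0, targets=(245, 256))])
    times, counts = net.binned_rates(t_total)
    post = times >= 3000.0
    verdict = classify_direction(times[post], counts[post], 250, 150, 350, active_thresh=0.0)
    center = 250
    return {
        "raster": net.raster(),
        "times": times,
        "binned": counts,
        "w_initial": w0,
        "w_3s": w3,
        "center_outgoing_change": w3[:, center] - w0[:, center],
        "verdict": verdict,
    }
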