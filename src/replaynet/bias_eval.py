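"""Offline evaluation of direction biases in STP-gated STDP weight changes.

The question addressed here: when a firing sequence sweeps across a chain of
neurons, which way does pair-based STDP push the outgoing weights of a neuron
in the middle of the chain?  Short-term depression exhausts the presynaptic
resources of neurons that have already fired, so the release-gated plasticity
drive is stronger for spike pairs involving neurons that fire *earlier* than
the center neuron.  With a symmetric STDP window this biases the weight
changes toward the reverse direction of propagation.

Two spike-train generators emulate the relevant regimes:

* sequential Poisson trains over 21 neurons (replay-like bursts), with the
  first spike of neuron ``n`` at ``n * lag`` and subsequent inter-spike
  intervals exponential with a 1-ms absolute refractory period;
* theta-modulated place-cell trains over 81 neurons (run-like activity),
  with Gaussian place fields, von Mises theta phase locking and phase
  precession, sampled per 1-ms bin.

For each realization the weight change from the center neuron onto every
other neuron is the sum over spike pairs of the STDP kernel times the
neurotransmitter release ``D*F`` of the presynaptic (center) spike, and the
bias statistic is the summed change toward earlier-firing minus later-firing
neurons (positive = reverse direction).  Parameter sweeps aggregate the mean
bias and the fraction of positive biases per setting, with Wilcoxon
signed-rank and binomial significance tests and Pearson correlations between
sampled parameters and the bias statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .plasticity import (
    AsymmetricExpWindow,
    GaussianWindow,
    STDPWindow,
    STPParams,
    stp_release_train,
)

__all__ = [
    "SequenceTrainParams",
    "ThetaTrainParams",
    "BiasResult",
    "SweepTable",
    "REPLAY_STP",
    "GUZMAN_ASYMMETRIC_WINDOW",
    "gen_sequence_trains",
    "gen_theta_trains",
    "compute_weight_changes",
    "compute_bias",
    "evaluate_setting",
    "run_sweep",
]

#: STP parameters fitted to hippocampal EPSC amplitude ratios, used for all
#: replay-regime evaluations.
REPLAY_STP = STPParams(U=0.37, tau_std=150.0, tau_stf=40.0)

#: Asymmetric STDP window with experimentally derived CA1 parameters.
GUZMAN_ASYMMETRIC_WINDOW = AsymmetricExpWindow(
    a_plus=0.777, a_minus=0.273, tau_plus=16.8, tau_minus=33.7
)


@dataclass(frozen=True)
class SequenceTrainParams:
    """Sequential Poisson spike-train parameters (replay-like regime)."""

    n_neurons: int = 21
    n_spikes: int = 5
    mean_isi: float = 20.0  # ms
    lag: float = 10.0  # ms between first spikes of adjacent neurons
    refractory: float = 1.0  # ms, absolute

    def __post_init__(self) -> None:
        if self.mean_isi <= 0 or self.lag < 0 or self.n_spikes < 1:
            raise ValueError("invalid sequence-train parameters")


@dataclass(frozen=True)
class ThetaTrainParams:
    """Theta-modulated place-cell spike-train parameters (run regime).

    ``alpha`` scales the firing rate (kHz); ``beta`` is the von Mises
    concentration controlling phase selectivity.  Place-field centers of the
    81 neurons are equidistant on [-0.5, 1.5] in track units (= seconds at
    the assumed constant running speed), so the center neuron (#41, 0-based
    40) peaks at t = 0.5 s.
    """

    n_neurons: int = 81
    duration_ms: int = 1000
    alpha: float = 0.05  # rate gain, kHz
    beta: float = 1.0  # phase concentration
    sigma_pf: float = 0.2  # place-field width, track units
    theta_freq: float = 8.0  # Hz


@dataclass
class BiasResult:
    """Bias statistics over realizations of one parameter setting."""

    mean_bias: float
    p_pos: float
    wilcoxon_p: float
    binomial_p: float
    n_realizations: int
    degenerate: bool = False  # all biases exactly zero; tests not meaningful


@dataclass
class SweepTable:
    """Result of a parameter sweep: one row per setting plus correlations."""

    settings: pd.DataFrame
    correlations: pd.DataFrame

    def to_csv(self, settings_path, correlations_path) -> None:
        self.settings.to_csv(settings_path, sep="\t", index=False)
        self.correlations.to_csv(correlations_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def _gen_sequence_batch(
    n_real: int,
    n_spikes: int,
    mean_isi: np.ndarray | float,
    lag: np.ndarray | float,
    rng: np.random.Generator,
    n_neurons: int = 21,
    refractory: float = 1.0,
) -> np.ndarray:
    """Batched sequential Poisson trains, shape (n_real, n_neurons, n_spikes).

    ``mean_isi`` and ``lag`` may be scalars or per-realization arrays.  The
    refractory period is enforced by sampling ISIs from the conditional
    distribution ``refractory + Exp(mean_isi)``, which by memorylessness is
    identical to resampling until the ISI clears the refractory period.
    """
    isi = np.broadcast_to(np.asarray(mean_isi, dtype=float), (n_real,))
    lg = np.broadcast_to(np.asarray(lag, dtype=float), (n_real,))
    first = np.arange(n_neurons)[None, :, None] * lg[:, None, None]
    if n_spikes == 1:
        return first.copy()
    gaps = refractory + rng.exponential(1.0, size=(n_real, n_neurons, n_spikes - 1)) * isi[
        :, None, None
    ]
    t = np.concatenate(
        [np.zeros((n_real, n_neurons, 1)), np.cumsum(gaps, axis=-1)], axis=-1
    )
    return t + first


def gen_sequence_trains(
    params: SequenceTrainParams, rng: np.random.Generator | int
) -> list[np.ndarray]:
    """One realization of sequential Poisson trains: a list of per-neuron
    sorted spike-time arrays (ms)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    t = _gen_sequence_batch(
        1, params.n_spikes, params.mean_isi, params.lag, rng, params.n_neurons, params.refractory
    )[0]
    return [t[i] for i in range(params.n_neurons)]


def _theta_geometry(params: ThetaTrainParams):
    """Per-bin place-field and phase matrices shared across realizations."""
    t_sec = (np.arange(params.duration_ms) + 0.5) / 1000.0
    mu = 2.0 * np.arange(params.n_neurons) / (params.n_neurons - 1) - 0.5
    pf = (
        1.0
        / (np.sqrt(2.0 * np.pi) * params.sigma_pf)
        * np.exp(-0.5 * ((t_sec[None, :] - mu[:, None]) / params.sigma_pf) ** 2)
    )
    # theta phase minus preferred phase, up to the per-realization offset c:
    # theta(t) = 2*pi*f*t + c, preferred p_i(t) = pi*(mu_i - t)
    ang = (
        2.0 * np.pi * params.theta_freq * t_sec[None, :]
        - np.pi * (mu[:, None] - t_sec[None, :])
    )
    return pf, np.cos(ang), np.sin(ang)


def _theta_prob_batch(
    n_real: int,
    params: ThetaTrainParams,
    rng: np.random.Generator,
    geometry=None,
) -> np.ndarray:
    """Per-bin firing probabilities, shape (n_real, n_neurons, n_bins)."""
    pf, cos_a, sin_a = geometry if geometry is not None else _theta_geometry(params)
    c = rng.uniform(0.0, 2.0 * np.pi, size=n_real)
    cos_arg = cos_a[None] * np.cos(c)[:, None, None] - sin_a[None] * np.sin(c)[:, None, None]
    pl = np.exp(params.beta * cos_arg) / (2.0 * np.pi * float(np.i0(params.beta)))
    prob = params.alpha * pf[None] * pl
    return np.minimum(prob, 1.0)


def gen_theta_trains(
    params: ThetaTrainParams, rng: np.random.Generator | int
) -> list[np.ndarray]:
    """One realization of theta-modulated place-cell trains (spike times, ms).

    Spikes are Bernoulli-sampled per 1-ms bin at probability
    ``min(1, rate * 1 ms)`` with rate ``alpha * PF_i(t) * PL_i(t)`` in kHz.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    prob = _theta_prob_batch(1, params, rng)[0]
    spikes = rng.random(prob.shape) < prob
    times = np.arange(params.duration_ms, dtype=float) + 0.5
    return [times[spikes[i]] for i in range(params.n_neurons)]


# ---------------------------------------------------------------------------
# Weight changes and bias
# ---------------------------------------------------------------------------


def _nearest_neighbor_mask(dt: np.ndarray) -> np.ndarray:
    """Mask over axis -2 (postsynaptic spikes) keeping, per presynaptic spike
    (axis -1), the nearest postsynaptic spike at-or-before and after."""
    neg = np.where(dt <= 0, dt, -np.inf)
    pos = np.where(dt > 0, dt, np.inf)
    kb = np.expand_dims(neg.argmax(axis=-2), -2)
    ka = np.expand_dims(pos.argmin(axis=-2), -2)
    has_b = np.take_along_axis(neg, kb, axis=-2) > -np.inf
    has_a = np.take_along_axis(pos, ka, axis=-2) < np.inf
    mask = np.zeros(dt.shape, dtype=bool)
    np.put_along_axis(mask, kb, has_b, axis=-2)
    maska = np.zeros(dt.shape, dtype=bool)
    np.put_along_axis(maska, ka, has_a, axis=-2)
    return mask | maska


def compute_weight_changes(
    trains: Sequence[np.ndarray],
    window: STDPWindow,
    scheme: Literal["all_to_all", "nearest_neighbor"],
    stp_params: STPParams | None,
    center: int,
    facilitation_first: bool = False,
) -> np.ndarray:
    """STP-gated STDP weight changes from the center neuron onto every other.

    For each presynaptic spike ``l`` of the center neuron, its release
    ``D*F`` (event-based STP along the center train) multiplies the summed
    kernel values over the paired postsynaptic spikes of each target neuron;
    contributions are summed over ``l``.  The self-term is zero.  With
    ``stp_params=None`` the gating is removed (``D*F = 1`` for every spike),
    which restores exact time-reversal symmetry for symmetric windows.
    """
    tc = np.asarray(trains[center], dtype=float)
    n = len(trains)
    delta = np.zeros(n)
    if tc.size == 0:
        return delta
    if stp_params is None:
        rel = np.ones_like(tc)
    else:
        rel = stp_release_train(tc, stp_params, facilitation_first)
    for i, ti in enumerate(trains):
        ti = np.asarray(ti, dtype=float)
        if i == center or ti.size == 0:
            continue
        dt = ti[:, None] - tc[None, :]
        k = window(dt)
        if scheme == "nearest_neighbor":
            k = k * _nearest_neighbor_mask(dt)
        elif scheme != "all_to_all":
            raise ValueError(f"unknown pairing scheme {scheme!r}")
        delta[i] = k.sum(axis=0) @ rel
    return delta


def compute_bias(delta_vector: np.ndarray, center: int) -> float:
    """Reverse-direction bias: summed changes onto earlier-firing neurons
    (indices below center) minus later-firing ones.  Positive = reverse."""
    d = np.asarray(delta_vector, dtype=float)
    return float(d[:center].sum() - d[center + 1 :].sum())


def _poisson_bias_batch(
    n_real: int,
    n_spikes: int,
    mean_isi: np.ndarray | float,
    lag: np.ndarray | float,
    window: STDPWindow,
    stp_params: STPParams,
    rng: np.random.Generator,
    scheme: str = "all_to_all",
    n_neurons: int = 21,
) -> np.ndarray:
    """Biases for a batch of realizations of the sequential-Poisson regime."""
    center = n_neurons // 2
    t = _gen_sequence_batch(n_real, n_spikes, mean_isi, lag, rng, n_neurons)
    tc = t[:, center, :]
    rel = stp_release_train(tc, stp_params)
    dt = t[:, :, :, None] - tc[:, None, None, :]
    k = window(dt)
    if scheme == "nearest_neighbor":
        k = k * _nearest_neighbor_mask(dt)
    delta = np.einsum("rnkl,rl->rn", k, rel)
    return delta[:, :center].sum(axis=1) - delta[:, center + 1 :].sum(axis=1)


def _theta_bias_batch(
    n_real: int,
    params: ThetaTrainParams,
    window: STDPWindow,
    stp_params: STPParams,
    rng: np.random.Generator,
    n_center_cells: int = 1,
    geometry=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Biases and smoothed peak rates (Hz) for a batch of theta realizations.

    With ``n_center_cells > 1``, additional independent trains are drawn for
    the center neuron and the resulting biases are summed, emulating the
    summation of synaptic inputs from overlapping place cells.
    """
    center = params.n_neurons // 2
    prob = _theta_prob_batch(n_real, params, rng, geometry)
    spikes = rng.random(prob.shape) < prob
    extra = None
    if n_center_cells > 1:
        pc = np.broadcast_to(prob[:, center, :][:, None, :], (n_real, n_center_cells - 1, prob.shape[2]))
        extra = rng.random(pc.shape) < pc
    times = np.arange(params.duration_ms, dtype=float) + 0.5
    biases = np.zeros(n_real)
    peaks = np.zeros(n_real)
    for r in range(n_real):
        post_id, post_bin = np.nonzero(spikes[r])
        post_t = times[post_bin]
        center_trains = [times[spikes[r, center]]]
        if extra is not None:
            center_trains += [times[extra[r, j]] for j in range(n_center_cells - 1)]
        b = 0.0
        for tc in center_trains:
            if tc.size == 0:
                continue
            rel = stp_release_train(tc, stp_params)
            kmat = window(post_t[:, None] - tc[None, :])
            if kmat.size:
                wsum = kmat @ rel
                delta = np.bincount(post_id, weights=wsum, minlength=params.n_neurons)
                delta[center] = 0.0
                b += delta[:center].sum() - delta[center + 1 :].sum()
        biases[r] = b
        smoothed = gaussian_filter1d(
            spikes[r, center].astype(float), sigma=50.0, mode="constant"
        )
        peaks[r] = smoothed.max() * 1000.0  # kHz -> Hz
    return biases, peaks


# ---------------------------------------------------------------------------
# Per-setting evaluation and sweeps
# ---------------------------------------------------------------------------


def _bias_result(biases: np.ndarray) -> BiasResult:
    n = biases.size
    n_pos = int((biases > 0).sum())
    degenerate = bool(np.all(biases == 0.0))
    if degenerate:
        wp = 1.0
    else:
        wp = float(stats.wilcoxon(biases).pvalue)
    bp = float(stats.binomtest(n_pos, n, 0.5).pvalue)
    return BiasResult(
        mean_bias=float(biases.mean()),
        p_pos=n_pos / n,
        wilcoxon_p=wp,
        binomial_p=bp,
        n_realizations=n,
        degenerate=degenerate,
    )


def evaluate_setting(
    train_params: SequenceTrainParams | ThetaTrainParams,
    window: STDPWindow,
    scheme: str = "all_to_all",
    stp_params: STPParams = REPLAY_STP,
    n_realizations: int = 100,
    seed: int | np.random.Generator = 0,
) -> BiasResult:
    """Bias statistics over ``n_realizations`` of one parameter setting."""
    if n_realizations < 2:
        raise ValueError("need at least 2 realizations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(train_params, SequenceTrainParams):
        biases = _poisson_bias_batch(
            n_realizations,
            train_params.n_spikes,
            train_params.mean_isi,
            train_params.lag,
            window,
            stp_params,
            rng,
            scheme,
            train_params.n_neurons,
        )
    else:
        biases, _ = _theta_bias_batch(n_realizations, train_params, window, stp_params, rng)
    return _bias_result(biases)


def _correlate(
    df: pd.DataFrame,
    params: Sequence[str],
    stats_cols: Sequence[str] = ("mean_bias", "p_pos"),
    method: str = "pearson",
    extra_keys: dict | None = None,
) -> list[dict]:
    rows = []
    for p in params:
        for s in stats_cols:
            if method == "pearson":
                r, pv = stats.pearsonr(df[p], df[s])
            else:
                r, pv = stats.spearmanr(df[p], df[s])
            row = dict(extra_keys or {})
            row.update(parameter=p, statistic=s, r=float(r), p=float(pv))
            rows.append(row)
    return rows


def run_sweep(
    which: Literal["fig3", "fig4", "fig5", "fig5_narrow", "fig4s1"],
    n_settings: int = 1000,
    n_realizations: int = 100,
    seed: int = 0,
    n_spikes: Sequence[int] | None = None,
    scheme: str = "all_to_all",
    corr_method: str = "pearson",
    n_center_cells: int = 1,
) -> SweepTable:
    """Run one of the predefined parameter sweeps.

    ``fig3``: (mean ISI, lag) uniform on [5, 50] ms per setting, symmetric
    Gaussian window (70 ms), fitted STP constants, spike counts 2-5.
    ``fig4``: (U, tau_STD, tau_STF) uniform on [0.1, 0.6] x [50, 500] x
    [10, 300]; 5 spikes; ISI and lag resampled uniformly from [5, 20] ms per
    realization.
    ``fig4s1``: as fig4 but with the asymmetric CA1 window (all-to-all or
    nearest-neighbor pairing; 5 or 15 spikes).
    ``fig5`` / ``fig5_narrow``: theta-train sweep over (alpha, beta) uniform
    on [0.01, 0.15] x [0.1, 10] with the 70-ms / 10-ms Gaussian window;
    records the estimated peak firing rate per setting and supports the
    summed 10-cell variant.
    """
    seeds = np.random.SeedSequence(seed).spawn(n_settings)
    top = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    rows: list[dict] = []
    corr_rows: list[dict] = []

    if which in ("fig3", "fig4s1"):
        window: STDPWindow = (
            GaussianWindow(a=1.0, tau=70.0) if which == "fig3" else GUZMAN_ASYMMETRIC_WINDOW
        )
        counts = list(n_spikes) if n_spikes is not None else (
            [2, 3, 4, 5] if which == "fig3" else [5, 15]
        )
        for ns in counts:
            isi = top.uniform(5.0, 50.0, size=n_settings)
            lag = top.uniform(5.0, 50.0, size=n_settings)
            sub = []
            for j in range(n_settings):
                rng = np.random.default_rng(seeds[j])
                biases = _poisson_bias_batch(
                    n_realizations, ns, isi[j], lag[j], window, REPLAY_STP, rng, scheme
                )
                res = _bias_result(biases)
                sub.append(
                    dict(
                        n_spikes=ns,
                        mean_isi=isi[j],
                        lag=lag[j],
                        mean_bias=res.mean_bias,
                        p_pos=res.p_pos,
                        wilcoxon_p=res.wilcoxon_p,
                        binomial_p=res.binomial_p,
                    )
                )
            sdf = pd.DataFrame(sub)
            rows.extend(sub)
            corr_rows += _correlate(
                sdf, ["mean_isi", "lag"], method=corr_method, extra_keys={"n_spikes": ns}
            )
    elif which == "fig4":
        window = GaussianWindow(a=1.0, tau=70.0)
        ns = n_spikes[0] if n_spikes else 5
        u = top.uniform(0.1, 0.6, size=n_settings)
        tau_std = top.uniform(50.0, 500.0, size=n_settings)
        tau_stf = top.uniform(10.0, 300.0, size=n_settings)
        for j in range(n_settings):
            rng = np.random.default_rng(seeds[j])
            isi = rng.uniform(5.0, 20.0, size=n_realizations)
            lag = rng.uniform(5.0, 20.0, size=n_realizations)
            stp = STPParams(U=u[j], tau_std=tau_std[j], tau_stf=tau_stf[j])
            biases = _poisson_bias_batch(
                n_realizations, ns, isi, lag, window, stp, rng, scheme
            )
            res = _bias_result(biases)
            rows.append(
                dict(
                    n_spikes=ns,
                    U=u[j],
                    tau_std=tau_std[j],
                    tau_stf=tau_stf[j],
                    mean_bias=res.mean_bias,
                    p_pos=res.p_pos,
                    wilcoxon_p=res.wilcoxon_p,
                    binomial_p=res.binomial_p,
                )
            )
        df = pd.DataFrame(rows)
        corr_rows += _correlate(df, ["U", "tau_std", "tau_stf"], method=corr_method,
                                extra_keys={"n_spikes": ns})
    elif which in ("fig5", "fig5_narrow"):
        tau = 70.0 if which == "fig5" else 10.0
        window = GaussianWindow(a=1.0, tau=tau)
        alpha = top.uniform(0.01, 0.15, size=n_settings)
        beta = top.uniform(0.1, 10.0, size=n_settings)
        geometry = _theta_geometry(ThetaTrainParams())
        for j in range(n_settings):
            rng = np.random.default_rng(seeds[j])
            tp = ThetaTrainParams(alpha=alpha[j], beta=beta[j])
            biases, peaks = _theta_bias_batch(
                n_realizations, tp, window, REPLAY_STP, rng,
                n_center_cells=n_center_cells, geometry=geometry,
            )
            res = _bias_result(biases)
            rows.append(
                dict(
                    alpha=alpha[j],
                    beta=beta[j],
                    peak_rate_hz=float(peaks.mean()),
                    mean_bias=res.mean_bias,
                    p_pos=res.p_pos,
                    wilcoxon_p=res.wilcoxon_p,
                    binomial_p=res.binomial_p,
                )
            )
        df = pd.DataFrame(rows)
        corr_rows += _correlate(df, ["peak_rate_hz", "beta"], method=corr_method)
    else:
        raise ValueError(f"unknown sweep {which!r}")

    return SweepTable(settings=pd.DataFrame(rows), correlations=pd.DataFrame(corr_rows))
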