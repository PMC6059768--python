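"""Closed-loop foraging in an open arena steered by network activity.

The 50x50 place-cell lattice (open-field configuration) runs concurrently
with a moving agent.  At every step the network's *activity vector* -- the
vector from the agent's position to the rate-weighted center of mass of
network activity -- rotates the agent's unit heading vector, so replay
sequences (during immobility) and theta sequences (during run) bias the
direction of movement.  Reward-triggered replay carves convergent synaptic
pathways toward the rewarded site, which shortens search latency on repeat
trials and drags the agent toward the previous reward site after the reward
is relocated.

A simulation set is 20 trials with the reward site switched among four
candidates every 5 trials; trials 2-5, 7-10, 12-15, 17-20 are REPEAT trials
and 6, 11, 16 are SWITCH trials.  Control sets disable learning (eta = 0)
but are otherwise identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import stats

from .place_net_2d import OFFSETS, Lattice2DParams, PlaceCellLattice, _seed_numba
from .plasticity import STPParams

__all__ = [
    "ForagingConfig",
    "activity_vector",
    "motion_step",
    "run_foraging",
    "angular_analysis",
    "open_field_params",
]

REWARD_SITES = np.array([[15.0, 15.0], [15.0, 35.0], [35.0, 15.0], [35.0, 35.0]])


@dataclass(frozen=True)
class ForagingConfig:
    arena_min: float = 5.0
    arena_max: float = 45.0
    reach_radius: float = 3.0
    min_start_distance: float = 10.0
    start_rest_ms: float = 3000.0
    reward_rest_ms: float = 15000.0
    trial_timeout_ms: float = 300000.0
    trials_per_set: int = 20
    switch_every: int = 5
    gamma_v: float = 0.01  # units/ms
    gamma_a: float = 0.01
    gamma_noise: float = 0.05
    sample_stride: int = 20  # ms between angular/trajectory samples


def open_field_params(eta: float = 0.1, tau_w: float = 10000.0) -> Lattice2DParams:
    """Lattice parameters for the open-field tasks: strong initial wiring
    (incoming sums 1.0) and fast plasticity."""
    return Lattice2DParams(init_sum=1.0, eta=eta, tau_w=tau_w)


def activity_vector(
    rates: np.ndarray, z_pos: tuple[float, float]
) -> np.ndarray:
    """Vector from the agent position to the rate-weighted center of mass of
    lattice activity (lattice cell (x, y) sits at coordinates (x, y))."""
    total = rates.sum()
    if total <= 0:
        raise ValueError("activity vector undefined for zero total rate")
    n = rates.shape[0]
    xs = np.arange(n)
    cx = (rates.sum(axis=1) * xs).sum() / total
    cy = (rates.sum(axis=0) * xs).sum() / total
    return np.array([cx - z_pos[0], cy - z_pos[1]])


def motion_step(
    pos: np.ndarray,
    v: np.ndarray,
    a: np.ndarray,
    dt: float,
    config: ForagingConfig,
    noise: np.ndarray,
    moving: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """One Euler step of the agent: rotate the unit heading toward the
    activity vector (plus noise), renormalize, and advance the position when
    moving, clamping to the arena and zeroing the outward component at the
    walls."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    na = np.hypot(a[0], a[1])
    drift = config.gamma_a * a / na if na > 0 else np.zeros(2)
    v = v + dt * drift + config.gamma_noise * noise
    nv = np.hypot(v[0], v[1])
    if nv > 0:
        v = v / nv
    pos = pos.copy()
    if moving:
        pos = pos + dt * config.gamma_v * v
        for k in range(2):
            if pos[k] < config.arena_min:
                pos[k] = config.arena_min
                if v[k] < 0:
                    v[k] = 0.0
            elif pos[k] > config.arena_max:
                pos[k] = config.arena_max
                if v[k] > 0:
                    v[k] = 0.0
        nv = np.hypot(v[0], v[1])
        if nv > 0:
            v = v / nv
    return pos, v


@njit(cache=True)
def _forage_phase(
    I,
    Iinh,
    D,
    F,
    W,
    Delta,
    valid,
    pos,
    v,
    # phase control
    moving,
    c_gain,
    theta_flag,
    extinh_cycling,
    max_steps,
    reward_x,
    reward_y,
    reach_radius,
    ref_x,
    ref_y,
    ref_is_point,
    # network params
    dt,
    rho,
    eps,
    tau,
    w_inh,
    tau_inh,
    U,
    tau_std,
    tau_stf,
    theta_b,
    t_theta,
    noise_sd,
    place_d,
    eta,
    tau_w,
    learn_on,
    t0,
    # agent params
    gamma_v,
    gamma_a,
    gamma_noise,
    arena_min,
    arena_max,
    sample_stride,
):
    """Advance one behavioral phase; state arrays and pos/v updated in place.

    Returns (steps_done, reached, cos_samples, valid_samples, traj) where
    ``cos_samples`` holds the cosine between the activity vector and the
    reference direction every ``sample_stride`` steps (reference = toward
    the point (ref_x, ref_y) if ref_is_point, else the fixed vector
    (ref_x, ref_y)), ``valid_samples`` flags samples passing the activity
    criteria, and ``traj`` records the agent position at the same stride.
    """
    n = I.shape[0]
    n_off = OFFSETS.shape[0]
    n_samp = (max_steps + sample_stride - 1) // sample_stride
    cos_s = np.zeros(n_samp)
    ok_s = np.zeros(n_samp, dtype=np.bool_)
    traj = np.zeros((n_samp, 2))
    r = np.zeros((n, n))
    rdf = np.zeros((n, n))
    rec = np.zeros((n, n))
    gx = np.zeros(n)
    gy = np.zeros(n)
    reached = False
    steps = 0
    for s in range(max_steps):
        t = t0 + s * dt
        # rates and activity statistics
        mx = 0.0
        tot = 0.0
        cx = 0.0
        cy = 0.0
        for x in range(n):
            for y in range(n):
                val = rho * (I[x, y] - eps)
                rv = val if val > 0.0 else 0.0
                r[x, y] = rv
                rdf[x, y] = rv * D[x, y] * F[x, y]
                tot += rv
                cx += rv * x
                cy += rv * y
                if rv > mx:
                    mx = rv

        # activity vector and sampling
        ax = 0.0
        ay = 0.0
        have_a = tot > 0.0
        if have_a:
            ax = cx / tot - pos[0]
            ay = cy / tot - pos[1]
        if s % sample_stride == 0:
            k = s // sample_stride
            traj[k, 0] = pos[0]
            traj[k, 1] = pos[1]
            la = np.sqrt(ax * ax + ay * ay)
            if have_a and mx >= 0.01 and la >= 1.0:
                if ref_is_point:
                    rx = ref_x - pos[0]
                    ry = ref_y - pos[1]
                else:
                    rx = ref_x
                    ry = ref_y
                lr = np.sqrt(rx * rx + ry * ry)
                if lr > 0.0:
                    cos_s[k] = (ax * rx + ay * ry) / (la * lr)
                    ok_s[k] = True

        # agent heading (updated also during immobility) and motion
        la = np.sqrt(ax * ax + ay * ay)
        dvx = gamma_noise * np.random.normal(0.0, 1.0)
        dvy = gamma_noise * np.random.normal(0.0, 1.0)
        if la > 0.0:
            dvx += dt * gamma_a * ax / la
            dvy += dt * gamma_a * ay / la
        v[0] += dvx
        v[1] += dvy
        nv = np.sqrt(v[0] * v[0] + v[1] * v[1])
        if nv > 0.0:
            v[0] /= nv
            v[1] /= nv
        if moving:
            pos[0] += dt * gamma_v * v[0]
            pos[1] += dt * gamma_v * v[1]
            for k2 in range(2):
                if pos[k2] < arena_min:
                    pos[k2] = arena_min
                    if v[k2] < 0.0:
                        v[k2] = 0.0
                elif pos[k2] > arena_max:
                    pos[k2] = arena_max
                    if v[k2] > 0.0:
                        v[k2] = 0.0
            nv = np.sqrt(v[0] * v[0] + v[1] * v[1])
            if nv > 0.0:
                v[0] /= nv
                v[1] /= nv

        # network update (same dynamics as the lattice kernel)
        sum_rdf = 0.0
        for x in range(n):
            for y in range(n):
                sum_rdf += rdf[x, y]
                acc = 0.0
                for o in range(n_off):
                    if valid[o, x, y]:
                        acc += W[o, x, y] * rdf[x - OFFSETS[o, 0], y - OFFSETS[o, 1]]
                rec[x, y] = acc
        i_theta = 0.0
        if theta_flag:
            i_theta = 0.5 * theta_b * (np.sin(2.0 * np.pi * t / t_theta) + 1.0)
        ext_inh = 0.0
        if extinh_cycling:
            phase_ms = (s * dt) % 1000.0
            if phase_ms >= 800.0:
                ext_inh = 0.1
        for x in range(n):
            dxx = (x - pos[0]) / place_d
            gx[x] = np.exp(-0.5 * dxx * dxx)
            dyy = (x - pos[1]) / place_d
            gy[x] = np.exp(-0.5 * dyy * dyy)
        for x in range(n):
            for y in range(n):
                ipl = c_gain * gx[x] * gy[y]
                nz = np.random.normal(0.0, noise_sd)
                I[x, y] += dt * (
                    -I[x, y] / tau + rec[x, y] - Iinh[0] - i_theta - ext_inh + ipl + nz
                )
                D[x, y] += dt * ((1.0 - D[x, y]) / tau_std - rdf[x, y])
                F[x, y] += dt * ((U - F[x, y]) / tau_stf + U * (1.0 - F[x, y]) * r[x, y])
        Iinh[0] += dt * (-Iinh[0] / tau_inh + w_inh * sum_rdf)
        if learn_on:
            decay = 1.0 - dt / tau_w
            g = dt * eta / tau_w
            for x in range(n):
                for y in range(n):
                    ssum = 0.0
                    for o in range(n_off):
                        if valid[o, x, y]:
                            pre = rdf[x - OFFSETS[o, 0], y - OFFSETS[o, 1]]
                            Delta[o, x, y] = Delta[o, x, y] * decay + g * r[x, y] * pre
                            W[o, x, y] += dt * Delta[o, x, y]
                            ssum += W[o, x, y]
                    if ssum > 1.0:
                        for o in range(n_off):
                            W[o, x, y] /= ssum

        steps = s + 1
        if moving:
            dxr = pos[0] - reward_x
            dyr = pos[1] - reward_y
            if np.sqrt(dxr * dxr + dyr * dyr) <= reach_radius:
                reached = True
                break
    n_done = (steps + sample_stride - 1) // sample_stride
    return steps, reached, cos_s[:n_done], ok_s[:n_done], traj[:n_done]


def _quadrant(site: np.ndarray) -> int:
    return int(site[0] > 25.0) * 2 + int(site[1] > 25.0)


def run_foraging(
    n_sets: int = 10,
    learning_on: bool = True,
    seed: int = 0,
    config: ForagingConfig | None = None,
    params: Lattice2DParams | None = None,
) -> dict:
    """Run foraging simulation sets and collect behavioral statistics.

    Returns a dict with per-trial records (set, trial, label, latency_s,
    timeout, previous-reward-quadrant occupancy for SWITCH trials) and
    per-set per-state angular-displacement samples split by trial label.
    """
    cfg = config if config is not None else ForagingConfig()
    p = params if params is not None else open_field_params()
    rng = np.random.default_rng(seed)
    trials = []
    angular: list[dict] = []
    for s_idx in range(n_sets):
        net = PlaceCellLattice(p, seed=int(rng.integers(0, 2**31 - 1)))
        _seed_numba(int(rng.integers(0, 2**31 - 1)))
        site_idx = int(rng.integers(0, 4))
        prev_site_idx = None
        pos = np.zeros(2)
        v = np.array([1.0, 0.0])
        set_ang = {"REPEAT": {0: [], 1: [], 2: []}, "SWITCH": {0: [], 1: [], 2: []}}
        for tr in range(1, cfg.trials_per_set + 1):
            if tr > 1 and (tr - 1) % cfg.switch_every == 0:
                prev_site_idx = site_idx
                choices = [k for k in range(4) if k != site_idx]
                site_idx = int(choices[rng.integers(0, 3)])
            site = REWARD_SITES[site_idx]
            label = "SWITCH" if (tr - 1) % cfg.switch_every == 0 and tr > 1 else (
                "FIRST" if tr == 1 else "REPEAT"
            )
            while True:
                cand = rng.uniform(cfg.arena_min, cfg.arena_max, size=2)
                if np.hypot(*(cand - site)) > cfg.min_start_distance:
                    break
            pos[:] = cand
            net_args = (
                p.dt, p.rho, p.epsilon, p.tau, p.w_inh, p.tau_inh,
                p.stp.U, p.stp.tau_std, p.stp.tau_stf,
                p.theta_b, p.t_theta, p.noise_sd, p.place_d,
                p.eta, p.tau_w, learning_on,
            )
            agent_args = (
                cfg.gamma_v, cfg.gamma_a, cfg.gamma_noise,
                cfg.arena_min, cfg.arena_max, cfg.sample_stride,
            )
            # start rest: immobile, weak place input, replay triggers
            _, _, cs, ok, _ = _forage_phase(
                net.I, net.Iinh, net.D, net.F, net.W, net.Delta, net.valid,
                pos, v, False, 0.001, False, True,
                int(cfg.start_rest_ms / p.dt),
                site[0], site[1], cfg.reach_radius, site[0], site[1], True,
                *net_args, net.t, *agent_args,
            )
            net.t += cfg.start_rest_ms
            start_samples = cs[ok]
            # run: theta sequences, motion on
            steps, reached, cs, ok, traj = _forage_phase(
                net.I, net.Iinh, net.D, net.F, net.W, net.Delta, net.valid,
                pos, v, True, 0.005, True, False,
                int(cfg.trial_timeout_ms / p.dt),
                site[0], site[1], cfg.reach_radius, site[0], site[1], True,
                *net_args, net.t, *agent_args,
            )
            net.t += steps * p.dt
            latency_s = steps * p.dt / 1000.0
            if label in set_ang and reached:
                # timeout trials are excluded from the angular analysis
                set_ang[label][0].extend(start_samples)
                set_ang[label][1].extend(cs[ok])
            occupancy = np.nan
            if label == "SWITCH" and prev_site_idx is not None:
                prev_site = REWARD_SITES[prev_site_idx]
                q = _quadrant(prev_site)
                in_q = (
                    ((traj[:, 0] > 25.0).astype(int) * 2 + (traj[:, 1] > 25.0).astype(int)) == q
                )
                occupancy = float(in_q.mean())
            # goal rest (only if reached): reference = recent path
            if reached:
                n_back = min(len(traj), int(3000 / (p.dt * cfg.sample_stride)))
                recent = traj[-n_back:].mean(axis=0)
                ref = recent - pos
                _, _, cs, ok, _ = _forage_phase(
                    net.I, net.Iinh, net.D, net.F, net.W, net.Delta, net.valid,
                    pos, v, False, 0.001, False, True,
                    int(cfg.reward_rest_ms / p.dt),
                    site[0], site[1], cfg.reach_radius, ref[0], ref[1], False,
                    *net_args, net.t, *agent_args,
                )
                net.t += cfg.reward_rest_ms
                if label in set_ang:
                    set_ang[label][2].extend(cs[ok])
            trials.append(
                dict(
                    set=s_idx,
                    trial=tr,
                    label=label,
                    latency_s=min(latency_s, cfg.trial_timeout_ms / 1000.0),
                    timeout=not reached,
                    prev_quadrant_occupancy=occupancy,
                )
            )
        angular.append(set_ang)
    import pandas as pd

    return {"trials": pd.DataFrame(trials), "angular": angular, "config": cfg}


STATE_NAMES = {0: "start", 1: "run", 2: "goal"}


def angular_analysis(records: list[dict], control_records: list[dict]) -> dict:
    """Baseline-subtracted mean angular displacements with paired tests.

    For each trial label (REPEAT / SWITCH) and behavioral state, computes
    per-set mean cosine similarity, subtracts the across-control-sets mean of
    the same state, and compares states across sets with a paired t-test
    after a Shapiro-Wilk normality check (p > 0.05); if normality is
    rejected, falls back to a sign-flip permutation test and flags it.
    """
    out: dict = {}
    for label in ("REPEAT", "SWITCH"):
        baselines = {}
        for st in (0, 1, 2):
            vals = [np.mean(c[label][st]) for c in control_records if len(c[label][st])]
            baselines[st] = float(np.mean(vals)) if vals else 0.0
        per_set = {st: [] for st in (0, 1, 2)}
        for c in records:
            for st in (0, 1, 2):
                if len(c[label][st]):
                    per_set[st].append(float(np.mean(c[label][st])) - baselines[st])
        tests = {}
        for st_a, st_b in ((0, 2), (1, 2)):
            a = np.asarray(per_set[st_a])
            b = np.asarray(per_set[st_b])
            m = min(len(a), len(b))
            if m < 2:
                tests[(STATE_NAMES[st_a], STATE_NAMES[st_b])] = dict(p=np.nan, flagged=True)
                continue
            diff = a[:m] - b[:m]
            normal = True
            if m >= 3:
                normal = stats.shapiro(diff).pvalue > 0.05
            if normal:
                p = float(stats.ttest_rel(a[:m], b[:m]).pvalue)
                flagged = False
            else:
                obs = diff.mean()
                rng = np.random.default_rng(0)
                flips = rng.choice([-1.0, 1.0], size=(5000, m)) * diff
                p = float((np.abs(flips.mean(axis=1)) >= abs(obs)).mean())
                flagged = True
            tests[(STATE_NAMES[st_a], STATE_NAMES[st_b])] = dict(p=p, flagged=flagged)
        out[label] = {
            "means": {STATE_NAMES[st]: float(np.mean(v)) if v else np.nan for st, v in per_set.items()},
            "per_set": {STATE_NAMES[st]: v for st, v in per_set.items()},
            "tests": tests,
        }
    return out
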