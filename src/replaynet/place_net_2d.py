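"""50x50 place-cell lattice network: W-maze learning and divergent replay.

Each of the 2500 threshold-linear place cells sits on a square lattice and
receives plastic excitatory input from its eight neighbors, global inhibitory
feedback, a theta-band oscillatory inhibition, position-dependent place
input, and independent Gaussian noise.  Short-term plasticity gates both
transmission and (optionally) the Hebbian learning rule, so firing sequences
traveling across the sheet potentiate the synaptic pathway *opposite* to
their direction of travel.  Reverse replay triggered at a rewarded location
therefore carves synaptic pathways that lead toward the reward.

The heavy per-step loop is compiled with numba; schedules (animal position,
place-input gain, theta gating, external inhibition) are passed as per-step
arrays and activity summaries (peak rate, center of mass) are recorded every
10 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numba import njit

from .plasticity import STPParams

__all__ = [
    "Lattice2DParams",
    "WMazeSchedule",
    "PlaceCellLattice",
    "wmaze_position",
    "place_input",
    "connection_vectors",
    "detect_sequence_events",
    "run_wmaze",
    "run_divergence_protocol",
    "track_direction_to_goal",
    "WMAZE_CORNERS",
]

# lattice neighbor offsets (dx, dy); W[o, x, y] is the weight from the neuron
# at (x - dx, y - dy) onto the neuron at (x, y)
OFFSETS = np.array(
    [[1, 1], [1, 0], [1, -1], [0, 1], [0, -1], [-1, 1], [-1, 0], [-1, -1]], dtype=np.int64
)

WMAZE_CORNERS = {
    "A": (25.0, 15.0),
    "B": (25.0, 35.0),
    "C1": (45.0, 35.0),
    "D1": (45.0, 15.0),
    "C2": (5.0, 35.0),
    "D2": (5.0, 15.0),
}


@dataclass(frozen=True)
class Lattice2DParams:
    """Lattice network parameters (W-maze defaults)."""

    n_side: int = 50
    rho: float = 1.0
    epsilon: float = 0.002
    tau: float = 10.0  # ms
    w_inh: float = 0.0005
    tau_inh: float = 10.0  # ms
    stp: STPParams = field(default_factory=lambda: STPParams(U=0.4, tau_std=300.0, tau_stf=200.0))
    theta_b: float = 0.005  # kHz, theta amplitude
    t_theta: float = 1000.0 / 7.0  # ms, theta period
    noise_sd: float = 0.0005  # kHz, per-step Gaussian input noise
    place_d: float = 2.0  # place-input width, lattice units
    eta: float = 1.0
    tau_w: float = 30000.0  # ms
    init_sum: float = 0.5  # initial incoming-weight sum per neuron
    dt: float = 1.0  # ms


@dataclass(frozen=True)
class WMazeSchedule:
    """Alternating W-maze traversal schedule.

    Each 15-s trial: rest at A for 2 s, run A->B, B->X, X->Y at constant
    speed (2 s per 20-unit segment), rest at Y for 7 s, with (X, Y) =
    (C1, D1) on odd trials and (C2, D2) on even trials (or the reverse).
    """

    trial_length: float = 15000.0  # ms
    order: Literal["D1_first", "D2_first"] = "D1_first"
    reward: Literal["D2", "none"] = "D2"


def wmaze_position(t: float, trial_index: int, order: str = "D1_first") -> tuple[float, float]:
    """Animal position (x, y) at time ``t`` ms within trial ``trial_index``
    (1-based).  Constant-speed linear interpolation completes each 2-s
    segment exactly at its endpoint."""
    c = WMAZE_CORNERS
    odd = trial_index % 2 == 1
    if order == "D1_first":
        x_key, y_key = ("C1", "D1") if odd else ("C2", "D2")
    else:
        x_key, y_key = ("C2", "D2") if odd else ("C1", "D1")
    za, zb = np.array(c["A"]), np.array(c["B"])
    zx, zy = np.array(c[x_key]), np.array(c[y_key])
    tp = t % 15000.0
    if tp < 2000.0:
        p = za
    elif tp < 4000.0:
        p = za + (tp - 2000.0) / 2000.0 * (zb - za)
    elif tp < 6000.0:
        p = zb + (tp - 4000.0) / 2000.0 * (zx - zb)
    elif tp < 8000.0:
        p = zx + (tp - 6000.0) / 2000.0 * (zy - zx)
    else:
        p = zy
    return float(p[0]), float(p[1])


def place_input(z_pos: tuple[float, float], c_gain: float, d: float, n_side: int = 50) -> np.ndarray:
    """Gaussian place-input field C * exp(-||z - z_ij||^2 / (2 d^2)) over the
    lattice; returns an (n_side, n_side) array indexed [x, y]."""
    if c_gain < 0:
        raise ValueError("place-input gain must be nonnegative")
    xs = np.arange(n_side, dtype=float)
    gx = np.exp(-0.5 * ((xs - z_pos[0]) / d) ** 2)
    gy = np.exp(-0.5 * ((xs - z_pos[1]) / d) ** 2)
    return c_gain * gx[:, None] * gy[None, :]


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _seed_numba(seed):
    np.random.seed(seed)


@njit(cache=True)
def _run_lattice(
    I,
    Iinh,
    D,
    F,
    W,
    Delta,
    valid,
    pos_x,
    pos_y,
    c_arr,
    theta_on,
    ext_inh,
    t0,
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
    stp_in_rule,
    learn_on,
    record_stride,
):
    """Advance the lattice through a schedule; state arrays updated in place.

    Returns per-sample (max rate, center-of-mass x, y, total rate).
    """
    n = I.shape[0]
    n_steps = pos_x.size
    n_off = OFFSETS.shape[0]
    n_rec = (n_steps + record_stride - 1) // record_stride
    rec_max = np.zeros(n_rec)
    rec_cx = np.zeros(n_rec)
    rec_cy = np.zeros(n_rec)
    rec_sum = np.zeros(n_rec)

    r = np.zeros((n, n))
    rdf = np.zeros((n, n))
    rec = np.zeros((n, n))
    gx = np.zeros(n)
    gy = np.zeros(n)

    for s in range(n_steps):
        t = t0 + s * dt
        # rates
        for x in range(n):
            for y in range(n):
                v = rho * (I[x, y] - eps)
                r[x, y] = v if v > 0.0 else 0.0
                rdf[x, y] = r[x, y] * D[x, y] * F[x, y]

        # recording
        if s % record_stride == 0:
            k = s // record_stride
            mx = 0.0
            tot = 0.0
            cx = 0.0
            cy = 0.0
            for x in range(n):
                for y in range(n):
                    rv = r[x, y]
                    tot += rv
                    cx += rv * x
                    cy += rv * y
                    if rv > mx:
                        mx = rv
            rec_max[k] = mx
            rec_sum[k] = tot
            if tot > 0.0:
                rec_cx[k] = cx / tot
                rec_cy[k] = cy / tot
            else:
                rec_cx[k] = -1.0
                rec_cy[k] = -1.0

        # recurrent input
        sum_rdf = 0.0
        for x in range(n):
            for y in range(n):
                sum_rdf += rdf[x, y]
                acc = 0.0
                for o in range(n_off):
                    if valid[o, x, y]:
                        sx = x - OFFSETS[o, 0]
                        sy = y - OFFSETS[o, 1]
                        acc += W[o, x, y] * rdf[sx, sy]
                rec[x, y] = acc

        # theta and place input
        i_theta = 0.0
        if theta_on[s]:
            i_theta = 0.5 * theta_b * (np.sin(2.0 * np.pi * t / t_theta) + 1.0)
        cg = c_arr[s]
        if cg > 0.0:
            px = pos_x[s]
            py = pos_y[s]
            for x in range(n):
                dx = (x - px) / place_d
                gx[x] = np.exp(-0.5 * dx * dx)
                dy = (x - py) / place_d
                gy[x] = np.exp(-0.5 * dy * dy)

        # current, inhibition, STP updates
        for x in range(n):
            for y in range(n):
                ipl = cg * gx[x] * gy[y] if cg > 0.0 else 0.0
                noise = np.random.normal(0.0, noise_sd)
                I[x, y] += dt * (
                    -I[x, y] / tau + rec[x, y] - Iinh[0] - i_theta - ext_inh[s] + ipl + noise
                )
                D[x, y] += dt * ((1.0 - D[x, y]) / tau_std - rdf[x, y])
                F[x, y] += dt * ((U - F[x, y]) / tau_stf + U * (1.0 - F[x, y]) * r[x, y])
        Iinh[0] += dt * (-Iinh[0] / tau_inh + w_inh * sum_rdf)

        # plasticity with incoming-sum cap
        if learn_on:
            decay = 1.0 - dt / tau_w
            g = dt * eta / tau_w
            for x in range(n):
                for y in range(n):
                    ssum = 0.0
                    for o in range(n_off):
                        if valid[o, x, y]:
                            sx = x - OFFSETS[o, 0]
                            sy = y - OFFSETS[o, 1]
                            pre = rdf[sx, sy] if stp_in_rule else r[sx, sy]
                            Delta[o, x, y] = Delta[o, x, y] * decay + g * r[x, y] * pre
                            W[o, x, y] += dt * Delta[o, x, y]
                            ssum += W[o, x, y]
                    if ssum > 1.0:
                        for o in range(n_off):
                            W[o, x, y] /= ssum
    return rec_max, rec_cx, rec_cy, rec_sum


class PlaceCellLattice:
    """Stateful wrapper over the jitted lattice integrator."""

    def __init__(self, params: Lattice2DParams, seed: int = 0):
        self.params = params
        n = params.n_side
        self.valid = np.zeros((8, n, n), dtype=np.bool_)
        for o, (dx, dy) in enumerate(OFFSETS):
            xs = np.arange(n) - dx
            ys = np.arange(n) - dy
            okx = (xs >= 0) & (xs < n)
            oky = (ys >= 0) & (ys < n)
            self.valid[o] = okx[:, None] & oky[None, :]
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.0, 1.0, size=(8, n, n)) * self.valid
        sums = w.sum(axis=0)
        self.W = w * (params.init_sum / sums)[None, :, :]
        self.Delta = np.zeros((8, n, n))
        self.I = np.zeros((n, n))
        self.Iinh = np.zeros(1)
        self.D = np.ones((n, n))
        self.F = np.full((n, n), params.stp.U)
        self.t = 0.0
        _seed_numba(int(rng.integers(0, 2**31 - 1)))

    def run_schedule(
        self,
        pos_x: np.ndarray,
        pos_y: np.ndarray,
        c_arr: np.ndarray,
        theta_on: np.ndarray,
        ext_inh: np.ndarray | None = None,
        learn_on: bool = True,
        stp_in_rule: bool = True,
        record_stride: int = 10,
    ) -> dict:
        p = self.params
        n_steps = pos_x.size
        if ext_inh is None:
            ext_inh = np.zeros(n_steps)
        rec_max, rec_cx, rec_cy, rec_sum = _run_lattice(
            self.I,
            self.Iinh,
            self.D,
            self.F,
            self.W,
            self.Delta,
            self.valid,
            np.asarray(pos_x, dtype=np.float64),
            np.asarray(pos_y, dtype=np.float64),
            np.asarray(c_arr, dtype=np.float64),
            np.asarray(theta_on, dtype=np.bool_),
            np.asarray(ext_inh, dtype=np.float64),
            self.t,
            p.dt,
            p.rho,
            p.epsilon,
            p.tau,
            p.w_inh,
            p.tau_inh,
            p.stp.U,
            p.stp.tau_std,
            p.stp.tau_stf,
            p.theta_b,
            p.t_theta,
            p.noise_sd,
            p.place_d,
            p.eta,
            p.tau_w,
            stp_in_rule,
            learn_on,
            record_stride,
        )
        times = self.t + np.arange(rec_max.size) * p.dt * record_stride
        self.t += n_steps * p.dt
        return {
            "times": times,
            "max_rate": rec_max,
            "com_x": rec_cx,
            "com_y": rec_cy,
            "total_rate": rec_sum,
        }


def connection_vectors(W: np.ndarray, valid: np.ndarray | None = None) -> np.ndarray:
    """Per-neuron outgoing connection vector field, shape (n, n, 2).

    ``u[x, y]`` sums, over the eight offsets, the outgoing weight from
    (x, y) to (x+dx, y+dy) times the unit vector toward that neighbor.
    """
    n = W.shape[1]
    u = np.zeros((n, n, 2))
    for o, (dx, dy) in enumerate(OFFSETS):
        norm = np.hypot(dx, dy)
        # outgoing weight of (x, y) through offset o lives at W[o, x+dx, y+dy]
        shifted = np.zeros((n, n))
        xs0, xs1 = max(0, -dx), min(n, n - dx)
        ys0, ys1 = max(0, -dy), min(n, n - dy)
        shifted[xs0:xs1, ys0:ys1] = W[o, xs0 + dx : xs1 + dx, ys0 + dy : ys1 + dy]
        u[:, :, 0] += shifted * dx / norm
        u[:, :, 1] += shifted * dy / norm
    return u


# ---------------------------------------------------------------------------
# W-maze experiment
# ---------------------------------------------------------------------------

_TRACK_EDGES = [("A", "B"), ("B", "C1"), ("C1", "D1"), ("B", "C2"), ("C2", "D2")]


from functools import lru_cache


@lru_cache(maxsize=None)
def _node_distances(goal: str) -> dict[str, float]:
    """Shortest along-track distance from each corner to the goal."""
    import heapq

    adj: dict[str, list[tuple[str, float]]] = {k: [] for k in WMAZE_CORNERS}
    for a, b in _TRACK_EDGES:
        d = float(np.hypot(*(np.subtract(WMAZE_CORNERS[a], WMAZE_CORNERS[b]))))
        adj[a].append((b, d))
        adj[b].append((a, d))
    dist = {k: np.inf for k in WMAZE_CORNERS}
    dist[goal] = 0.0
    heap = [(0.0, goal)]
    while heap:
        dv, v = heapq.heappop(heap)
        if dv > dist[v]:
            continue
        for w, d in adj[v]:
            if dv + d < dist[w]:
                dist[w] = dv + d
                heapq.heappush(heap, (dist[w], w))
    return dist


def track_direction_to_goal(
    point: tuple[float, float], goal: str = "D2", max_off_track: float = 2.0
) -> tuple[float, float] | None:
    """Unit vector along the track toward ``goal`` at an on-track point, or
    None if the point is farther than ``max_off_track`` from the track."""
    p = np.asarray(point, dtype=float)
    nd = _node_distances(goal)
    best = None
    for a, b in _TRACK_EDGES:
        za, zb = np.asarray(WMAZE_CORNERS[a]), np.asarray(WMAZE_CORNERS[b])
        seg = zb - za
        L = np.hypot(*seg)
        s = float(np.clip(np.dot(p - za, seg) / (L * L), 0.0, 1.0))
        foot = za + s * seg
        d = float(np.hypot(*(p - foot)))
        if best is None or d < best[0]:
            best = (d, a, b, s, L, seg)
    d, a, b, s, L, seg = best
    if d > max_off_track:
        return None
    via_a = s * L + nd[a]
    via_b = (1.0 - s) * L + nd[b]
    direction = -seg / L if via_a <= via_b else seg / L
    return float(direction[0]), float(direction[1])


def _nearest_landmark(x: float, y: float, radius: float = 5.0) -> str | None:
    best, bd = None, np.inf
    for name in ("A", "D1", "D2"):
        zx, zy = WMAZE_CORNERS[name]
        d = np.hypot(x - zx, y - zy)
        if d < bd:
            best, bd = name, d
    return best if bd <= radius else None


def detect_sequence_events(
    times: np.ndarray,
    max_rate: np.ndarray,
    com_x: np.ndarray,
    com_y: np.ndarray,
    immobile: np.ndarray,
    threshold: float = 0.01,
    landmark_radius: float = 5.0,
) -> list[dict]:
    """Segment the activity recording into sequence events.

    An event starts when the peak rate crosses ``threshold`` upward during
    immobility and ends when it falls back below; origin and destination are
    the landmarks nearest to the center of mass at onset and offset (within
    ``landmark_radius``; None otherwise).
    """
    events = []
    above = max_rate > threshold
    i = 0
    n = len(times)
    while i < n:
        if above[i] and immobile[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            events.append(
                {
                    "t_on": float(times[i]),
                    "t_off": float(times[j]),
                    "origin": _nearest_landmark(com_x[i], com_y[i], landmark_radius),
                    "dest": _nearest_landmark(com_x[j], com_y[j], landmark_radius),
                }
            )
            i = j + 1
        else:
            i += 1
    return events


def _wmaze_schedule_arrays(
    n_trials: int,
    schedule: WMazeSchedule,
    rng: np.random.Generator,
    dt: float = 1.0,
    theta: bool = True,
):
    """Per-step position / place-gain / theta arrays for a full W-maze run."""
    steps_per_trial = int(round(schedule.trial_length / dt))
    n_steps = n_trials * steps_per_trial
    pos_x = np.zeros(n_steps)
    pos_y = np.zeros(n_steps)
    c_arr = np.zeros(n_steps)
    immobile = np.zeros(n_steps, dtype=bool)
    for tr in range(1, n_trials + 1):
        base = (tr - 1) * steps_per_trial
        # Poisson-triggered brief activations (0.1 Hz, 200 ms) during rests
        # at non-rewarded positions, plus a guaranteed trigger at t' = 1 s
        activation = np.zeros(steps_per_trial, dtype=bool)
        hits = np.flatnonzero(rng.random(steps_per_trial) < 0.1e-3 * dt)
        for h in hits:
            activation[h : h + 200] = True
        activation[1000:1200] = True
        for s in range(steps_per_trial):
            tp = s * dt
            x, y = wmaze_position(tp, tr, schedule.order)
            pos_x[base + s] = x
            pos_y[base + s] = y
            moving = 2000.0 <= tp < 8000.0
            immobile[base + s] = not moving
            if moving:
                c_arr[base + s] = 0.005
            else:
                at_reward = (
                    schedule.reward == "D2"
                    and np.hypot(x - WMAZE_CORNERS["D2"][0], y - WMAZE_CORNERS["D2"][1]) < 1e-6
                )
                if at_reward:
                    c_arr[base + s] = 0.001
                elif activation[s]:
                    c_arr[base + s] = 0.001
    # theta is a locomotion rhythm: on during run, absent during immobility
    # (replay events during rests are free-running and terminated by
    # short-term depression rather than by theta hyperpolarization)
    theta_on = (~immobile) if theta else np.zeros(n_steps, dtype=bool)
    return pos_x, pos_y, c_arr, theta_on, immobile


def run_wmaze(
    n_trials: int = 12,
    reward: Literal["D2", "none"] = "D2",
    order: Literal["D1_first", "D2_first"] = "D1_first",
    stp_in_rule: bool = True,
    theta_on: bool = True,
    seed: int = 0,
    params: Lattice2DParams | None = None,
) -> dict:
    """Run the alternating W-maze experiment and count sequence events.

    Returns the activity recording, the final weights, the connection-vector
    field, and sequence-event counts keyed by (origin, destination).
    """
    from dataclasses import replace as _replace

    p = params if params is not None else Lattice2DParams()
    if not stp_in_rule:
        p = _replace(p, eta=0.1)
    rng = np.random.default_rng(seed)
    schedule = WMazeSchedule(order=order, reward=reward)
    pos_x, pos_y, c_arr, theta_arr, immobile = _wmaze_schedule_arrays(
        n_trials, schedule, rng, p.dt, theta_on
    )
    net = PlaceCellLattice(p, seed=int(rng.integers(0, 2**31 - 1)))
    recs = net.run_schedule(pos_x, pos_y, c_arr, theta_arr, stp_in_rule=stp_in_rule)
    stride = 10
    events = detect_sequence_events(
        recs["times"], recs["max_rate"], recs["com_x"], recs["com_y"], immobile[::stride]
    )
    counts: dict[tuple[str, str], int] = {}
    for e in events:
        if e["origin"] and e["dest"] and e["origin"] != e["dest"]:
            key = (e["origin"], e["dest"])
            counts[key] = counts.get(key, 0) + 1
    return {
        "recording": recs,
        "events": events,
        "counts": counts,
        "final_W": net.W.copy(),
        "valid": net.valid,
        "connection_vectors": connection_vectors(net.W),
    }


def run_divergence_protocol(
    seed: int = 0,
    duration_ms: float = 30000.0,
    trigger: tuple[float, float] = (25.0, 25.0),
    learn_on: bool = True,
    params: Lattice2DParams | None = None,
) -> dict:
    """Divergent-sequence experiment in the open-field configuration.

    Initial incoming sums are 1.0 (strong topological wiring), plasticity is
    fast (eta = 0.5, tau_w = 10 s), theta is off, and sequences are triggered
    at the center every second by an 800-ms disinhibition window (external
    inhibition 0.1 otherwise) with constant weak place input at the trigger.
    Returns per-trigger center-of-mass trajectories and the final
    connection-vector field.
    """
    if params is None:
        params = Lattice2DParams(init_sum=1.0, eta=0.5, tau_w=10000.0)
    n_steps = int(round(duration_ms / params.dt))
    pos_x = np.full(n_steps, trigger[0])
    pos_y = np.full(n_steps, trigger[1])
    c_arr = np.full(n_steps, 0.001)
    theta_arr = np.zeros(n_steps, dtype=bool)
    ext_inh = np.full(n_steps, 0.1)
    step_ms = params.dt
    for k in range(int(duration_ms // 1000)):
        a = int(k * 1000 / step_ms)
        ext_inh[a : a + int(800 / step_ms)] = 0.0
    net = PlaceCellLattice(params, seed=seed)
    recs = net.run_schedule(pos_x, pos_y, c_arr, theta_arr, ext_inh=ext_inh, learn_on=learn_on)
    # carve per-trigger trajectories from the 10-ms samples
    trajectories = []
    times = recs["times"]
    for k in range(int(duration_ms // 1000)):
        sel = (times >= k * 1000) & (times < k * 1000 + 800) & (recs["max_rate"] > 0.01)
        if sel.any():
            trajectories.append(np.column_stack([recs["com_x"][sel], recs["com_y"][sel]]))
    return {
        "recording": recs,
        "trajectories": trajectories,
        "final_W": net.W.copy(),
        "connection_vectors": connection_vectors(net.W),
    }


def convergence_cosine(
    u: np.ndarray, target: tuple[float, float] = (25.0, 25.0), radius: float = 20.0
) -> float:
    """Mean cosine between connection vectors and the direction from each
    cell toward ``target``, over cells within ``radius`` of it (excluding
    cells at the target itself and zero vectors)."""
    n = u.shape[0]
    xs, ys = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    dx = target[0] - xs
    dy = target[1] - ys
    dist = np.hypot(dx, dy)
    norm_u = np.hypot(u[:, :, 0], u[:, :, 1])
    sel = (dist > 1e-9) & (dist <= radius) & (norm_u > 1e-12)
    cosv = (u[:, :, 0] * dx + u[:, :, 1] * dy) / (norm_u * dist + 1e-300)
    return float(cosv[sel].mean())


def on_track_goal_cosine(u: np.ndarray, goal: str = "D2") -> float:
    """Mean cosine between connection vectors and the along-track direction
    to the goal, over on-track cells."""
    n = u.shape[0]
    vals = []
    for x in range(n):
        for y in range(n):
            direction = track_direction_to_goal((float(x), float(y)), goal)
            if direction is None:
                continue
            ux, uy = u[x, y]
            nu = np.hypot(ux, uy)
            if nu < 1e-12:
                continue
            vals.append((ux * direction[0] + uy * direction[1]) / nu)
    return float(np.mean(vals))
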