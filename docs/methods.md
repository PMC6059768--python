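# Methods

This note documents the models implemented in `replaynet`, the parameters
that matter, the synthetic protocols the package runs, and the numerical and
design choices behind them.

## The learning principle

All models share one mechanism.  Synaptic transmission is gated by
Tsodyks–Markram short-term plasticity (STP): each presynaptic terminal
carries a resource fraction `D` (depression) and a utilization `F`
(facilitation), at rest `(D, F) = (1, U)`.  Between spikes

    dD/dt = (1 - D)/tau_STD,      dF/dt = (U - F)/tau_STF,

and at a presynaptic spike the terminal releases `D*F`, after which
`D -= D*F` and `F += U*(1 - F)`.  (In the rate models the spike train is
replaced by the rate, giving `dD/dt = (1-D)/tau_STD - r*D*F` and
`dF/dt = (U-F)/tau_STF + U*(1-F)*r`.)

When a firing sequence travels across a population, neurons at the *tail* of
the activity packet have exhausted their resources while neurons at the
*head* still release strongly.  A Hebbian or STDP rule whose drive is
multiplied by the presynaptic release `D*F` therefore potentiates
connections from the head back to the tail — i.e. **opposite** to the
direction of propagation.  Forward experience builds reverse-replay
pathways; reverse replay from a rewarded site builds goal-directed forward
pathways.  That loop is what every experiment in this package probes.

Long-term plasticity is a low-pass eligibility pair

    dw/dt = Delta,      tau_w * dDelta/dt = -Delta + eta * drive,

so a drive impulse of area `G` eventually changes the weight by `eta*G`,
paid out over `tau_w`.  `tau_w` controls how many replay events can act
before the weight bias is overwritten (the replay-consolidation experiment
varies exactly this).

## Offline bias evaluator (`bias_eval`)

The evaluator asks the question in its cleanest form: sample spike trains
with a controlled sequential structure, compute the STP-gated STDP weight
changes from the center neuron, and quantify the direction bias.

* **Sequential Poisson trains** (replay regime): 21 neurons; neuron *n*'s
  first spike at `(n-1)*lag`; subsequent inter-spike intervals drawn as
  `1 ms + Exp(mean_isi)`.  The 1-ms offset implements the absolute
  refractory period exactly: resampling an exponential until it clears 1 ms
  is, by memorylessness, the same distribution.
* **Theta-modulated place-cell trains** (run regime): 81 neurons with
  normalized Gaussian place fields (sigma 0.2) centered equidistantly on
  [-0.5, 1.5] track units, von Mises theta phase locking (concentration
  `beta`) with phase precession `p_i(t) = pi*(mu_i - t)`, theta at 8 Hz with
  a random phase offset per realization, rate `alpha * PF_i(t) * PL_i(t)` in
  kHz, and Bernoulli sampling per 1-ms bin with the probability clamped at
  1.  Peak firing rate is estimated by smoothing the center neuron's train
  with a 50-ms-SD Gaussian kernel and averaging the maximum over
  realizations.
* **Weight change**: for each presynaptic (center) spike, its event-based
  release `D*F` multiplies the summed STDP kernel values over paired
  postsynaptic spikes; pairing is all-to-all or nearest-neighbor.  The bias
  is the summed change onto earlier-firing minus later-firing neurons
  (positive = reverse direction).
* **Statistics per setting**: mean bias and fraction of positive biases
  over (by default) 100 realizations, a two-sided Wilcoxon signed-rank test
  against zero and a two-sided binomial test against 1/2, and Pearson
  correlations (two-sided t p-values) between each swept parameter and both
  statistics.  Spearman is available by configuration; Pearson is the
  default reading of an unqualified "correlation".

Windows: symmetric Gaussian (amplitude 1, width 70 ms; 10 ms in the
narrow-window variant), symmetric difference-of-exponentials, and the
asymmetric exponential window with experimentally derived CA1 parameters
(A+ = 0.777, A- = 0.273, tau+ = 16.8 ms, tau- = 33.7 ms).  The fitted STP
constants for the replay regime are `U = 0.37`, `tau_STD = 150 ms`,
`tau_STF = 40 ms`, taken as given.

An exact-symmetry caveat worth knowing: the bias is *not* antisymmetric
under plain time reversal of the trains once STP gating is active —
breaking time-reversal symmetry is precisely what the gating does.  The
exact invariants (tested) are that reflecting neuron indices about the
center negates the bias, and that with gating removed (`stp_params=None`) a
symmetric window makes every weight change invariant under time reversal.

## 1-D rate network (`rate_net_1d`)

500 threshold-linear units, `r = max(0, rho*(I_exc - I_inh + I_ext - eps))`
with `rho = 0.0025`, `eps = 0.5`; exponential-distance initial weights
`w_max * exp(-|i-j|/d)` (`w_max = 27`, `d = 5`, zero diagonal, truncated at
the array edges — no wraparound); global inhibition `w_inh = 1`; synaptic
and inhibitory time constants 10 ms; STP with `U = 0.6`, `tau_STD = 500 ms`,
`tau_STF = 200 ms`.  Hebbian drive variants: `standard` (`r_i r_j`,
eta = 4), `stp_modulated` (`r_i r_j D_j F_j`, eta = 20), and `adp`
(`p_i r_j` with `tau_ADP * dp/dt = -p + r`, tau_ADP = 80 ms, eta = 4),
each with `tau_w = 1000 ms`.  Forward Euler at dt = 1 ms; every time
constant is >= 10 ms so this is comfortably stable.

Protocols: a 10-ms, amplitude-5 pulse to neurons 0–10 at t = 0 launches a
forward sequence; a second pulse to 245–255 at t = 3 s probes direction.
The verdict (bidirectional / reverse_only / forward_only / none) is decided
from the recorded rates (10-ms stride): during suprathreshold samples, the
neurons above 10 % of the momentary peak are tracked, and propagation to
below index 150 / above 350 marks reverse / forward travel.  The
replay-consolidation protocol adds per-step rescaling of every neuron's
incoming weight sum to its initial value, five forward sequences (one per
second for 5 s), then center stimulation every second from 10 s to 30 s; the
weight bias at neuron j is the outgoing sum toward lower minus higher
indices.  The three conditions vary `(tau_w, U, tau_STD, w_max)` =
(5000, 0.6, 500, 27), (500, 0.6, 500, 27), (500, 0.3, 200, 30).

## 1-D spiking network (`spiking_net_1d`)

500 Izhikevich neurons (a = 0.02, b = 0.2, c = -65, d = 8; spike cut at
30 mV), conductance-based AMPA (tau 5 ms) and NMDA (tau 150 ms, voltage
gate `((V+80)/60)^2 / (1 + ((V+80)/60)^2)`, weights fixed at 0.2x the
initial AMPA weights) synapses with a 2-ms delay, global inhibitory
feedback, and the same STP.  Initial AMPA weights follow the exponential
profile with `w_max = 0.3` (0.35 with NMDA off, tau_AMPA = 2.5 ms,
tau_inh = 5 ms in the fast-synapse variant).  dt = 0.5 ms; spikes are
timestamped at the step where the threshold was crossed; delayed deliveries
use a ring buffer and carry the release `D*F` recorded at the presynaptic
spike.

STDP (all-to-all pairing, eta = 0.05 with STP modulation, 0.01 without,
tau_w = 1000 ms; A+ = 1, A- = 0.5, tau+ = 20 ms, tau- = 40 ms) is
implemented with the standard exact trace scheme: postsynaptic spike-count
traces apply post-before-pre pairs at the presynaptic spike (gated by that
spike's `D*F`), presynaptic traces that accumulated `D*F` apply
pre-before-post pairs at the postsynaptic spike, and simultaneous pairs are
counted once at the zero-lag kernel value.  Every pair therefore contributes
exactly `f_STDP(dt) * D*F(presynaptic spike)`, which is the intended pair
sum; only the time at which the pre-before-post half is credited differs
from a strictly presynaptic-time bookkeeping (unavoidable in an online
simulation, and immaterial at tau_w = 1000 ms).

## 2-D place-cell lattice (`place_net_2d`)

2500 threshold-linear place cells on a 50x50 lattice (`rho = 1`,
`eps = 0.002`, tau = 10 ms), each receiving plastic excitatory input from
its eight neighbors (edge neurons simply lack the missing offsets, which are
excluded from sums and normalization), global inhibition
(`w_inh = 0.0005`), a theta drive `B/2 * (sin(2*pi*t/t_theta) + 1)` with
`B = 0.005 kHz` and `t_theta = 1000/7 ms`, a Gaussian place input of width
`d = 2` centered on the animal, and fresh Gaussian input noise
(SD 0.0005 kHz) per neuron per 1-ms step.  STP uses `U = 0.4`,
`tau_STD = 300 ms`, `tau_STF = 200 ms`.  The Hebbian rule
(`eta = 1`, `tau_w = 30 s`; `eta = 0.1` without the STP factor) runs
through the eligibility pair, and incoming weight sums are capped at 1 by
divisive renormalization checked after every plasticity step.  Initial
incoming weights are i.i.d. uniform, rescaled to sum 0.5 (W-maze) or 1.0
(open field).  The per-step loop is numba-compiled; activity summaries
(peak rate, center of mass, total rate) are recorded every 10 ms.

**Theta gating.** Theta is applied during locomotion only.  This is a
deliberate interpretive choice: theta is a locomotion rhythm, and the
no-theta control's defining feature — long replay-like sequences appearing
*also* during run — presupposes that long free-running replays already occur
during immobility in the normal condition.  With theta applied during rest
as well, replay events die within ~1.5 theta cycles and never complete the
track, and none of the goal-directed sequence phenomenology emerges; with
motion-gated theta all of it does.  During runs, theta's periodic
hyperpolarization localizes place-cell activity and terminates theta
sequences within a cycle.

**W-maze protocol.**  Corners A(25,15), B(25,35), C1(45,35), D1(45,15),
C2(5,35), D2(5,15).  Each 15-s trial: rest at A for 2 s, then constant-speed
traversal A->B, B->X, X->Y (2 s per 20-unit segment, i.e. 10 units/s), rest
at Y for 7 s; (X, Y) alternates between (C1, D1) and (C2, D2).  The printed
interpolation coefficients for the moving segments overshoot the segment
endpoints by a factor of two (and shift the later segments); constant-speed
interpolation that completes each segment exactly on schedule is used
instead, matching the stated timeline and corner coordinates.  Place-input
gain: 0.005 kHz while moving; 0.001 kHz while resting at the rewarded
position (D2 by default); zero at other rests except brief 200-ms
activations at 0.001 kHz following a 0.1-Hz Poisson process, plus one
guaranteed activation 1 s after trial onset (both trigger types coexist
during the same rest).

**Sequence-event counting.**  From the 10-ms activity samples, an event
starts when the peak rate crosses 0.01 kHz during immobility and ends when
it falls below; origin and destination are the landmarks in {A, D1, D2}
nearest to the activity center of mass at onset and offset, accepted within
distance 5 and left unclassified otherwise.  The counting rule and both
thresholds are package choices (exposed as arguments); the source figures do
not state one.

**Connection vectors.**  Each neuron's outgoing weights times the unit
offset vectors (diagonals scaled by 1/sqrt(2)), summed over the eight
neighbors.  Goal convergence is summarized as the mean cosine between these
vectors and the along-track direction to the goal (on-track cells within
distance 2 of the track polyline; the track route to the goal is resolved on
the corner graph), or, in the open field, the direction toward a target
point over cells within a given radius.

**Open-field variants.**  Initial incoming sums 1.0.  Finite-length replay
is enforced by an external inhibition term: during immobility the network is
disinhibited (ext. inhibition 0) for 800 ms out of every 1 s and inhibited
(0.1) otherwise, with constant 0.001-kHz place input at the resting
position.  The divergence experiment triggers sequences at (25, 25) for
30 s with `eta = 0.5`, `tau_w = 10 s`.

## Foraging task (`foraging`)

Arena [5, 45]^2 inside the lattice; four candidate reward sites at
(15/35, 15/35); reach radius 3; random start at distance > 10 from the
reward; 3-s start rest, 15-s reward rest, 300-s timeout (timeout trials
score 300 s and are excluded from the angular analysis); 20 trials per set
with the reward moved to a different site every 5 trials.  The agent's unit
heading `v` turns toward the activity vector
`a = (sum r*z)/(sum r) - z_pos` at rate `gamma_a = 0.01` plus Gaussian
noise (`gamma_noise = 0.05`, added per step, then renormalized); position
advances at `gamma_v = 0.01` units/ms during runs only (heading keeps
updating during immobility, setting the next departure direction).  At the
walls the position is clamped and the outward velocity component zeroed.
The network uses the open-field configuration with `eta = 0.1`,
`tau_w = 10 s`; the control condition disables learning with everything
else identical.

Angular displacement: every 20 ms, the cosine between `a` and a reference
vector (toward the reward at start/run; toward the mean position over the
3 s before goal arrival, at the goal), with samples excluded when the peak
rate is below 0.01 kHz or `|a| < 1`.  Per-set per-state means are
baseline-subtracted using the control sets' state means; states are compared
across sets with a paired t-test after a Shapiro–Wilk normality check
(p > 0.05), falling back to a flagged sign-flip permutation test.

## Problem sizes and runtimes

The package's default experiment sizes follow the stated protocols (1000
settings x 100 realizations for the sweeps; 10 simulation sets for the maze
and foraging experiments).  The test suite exercises reduced sizes chosen
for statistical adequacy: sweeps at 200–300 settings (the correlation
estimates' sampling error is then well below the tolerances tested), five
12-trial W-maze sets, one 30-s divergence run, and two 12-trial foraging
sets per condition.  `scripts/acceptance.py` runs the sweeps at full scale
(the theta sweep's setting count is configurable; its default of 1000
matches the printed protocol).

## Known limitations

* The synthetic protocols probe the model family's internal consistency;
  none of the generators emulate real spike-train irregularities (bursting
  statistics, behavioral variability, non-Poisson ISI structure), so
  passing tests demonstrate the mechanism, not a fit to recordings.
* Sequence-event counting and the direction-verdict classifier are
  package-defined rules; absolute event counts depend on their thresholds,
  though the ordinal comparisons reported are robust to them.
* The spiking model's runaway guard aborts rather than rescues pathological
  parameter choices; no automatic re-balancing is attempted.
* Weight changes in the 1-D spiking model may drive individual weights
  negative under strong depression; no clipping is applied, matching the
  printed rule.
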