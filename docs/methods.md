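# Methods

## Model

Driver behavior on a signalized intersection approach is modeled as a
discrete hidden Markov model.  The hidden state q_t ∈ {accelerate,
decelerate, maintain, stop} (coded 0–3) is the driver's instantaneous
stop/go decision; it evolves as a first-order Markov chain with
transition matrix A (4×4).  The observation O_t is one of M = 81
symbols encoding the discretized tuple (speed, headway, queue
condition, signal phase), emitted with probability b_j(k) from state j
(B is 4×81); π is the initial-state distribution.  The model is fit
separately for each of three approach zones — [0, 40) m from the stop
line, the [40, 100) m dilemma zone, and [100, 135] m — and for the
whole road, because the behavioral mix differs by zone.

Key assumptions: the decision process is first-order Markov at the
observation cadence; drivers are exchangeable (one pooled model per
zone, no per-driver heterogeneity); emissions depend only on the
current state; and the 3-level binning of each observed variable
preserves the behaviorally relevant contrasts.

## Observation alphabet

Speed bins at 8 and 16 m/s (≤8 → 1, (8,16) → 2, ≥16 → 3); headway:
no predecessor in the cycle ("head car") → 1, (0,6) s → 2, ≥6 s → 3;
queue: head car → 1, no stopped vehicle ahead → 2, stopped vehicle
ahead → 3; signal green/red/yellow → 1/2/3.  The enumeration of the 81
tuples runs signal-fastest: index = 27(speed−1) + 9(headway−1) +
3(queue−1) + signal, a bijection with exact round-trip.  The six
dangerous symbols — medium-or-fast speed, short headway, stopped
vehicle ahead, any signal — are (2,2,3,·) → 43,44,45 and (3,2,3,·) →
70,71,72.  Boundary conventions (8 m/s in the slow bin, 16 m/s in the
fast bin, 6 s in the long-headway bin) follow the bin definitions
above; the alphabet is exactly 3⁴ = 81 symbols, 1-based.

## Kinematics from detection lines

With lines spaced s = 2.92 m and video at N = 30 frames/s, a crossing
gap of n frames gives a travel time n/N (a zero-frame gap is rejected
as degenerate), and the speed at an interior line b flanked by
intervals t_ab, t_bc is v_b = 2s/(t_ab + t_bc).  First and last lines
of a track carry no speed; vehicles with fewer than three crossings
are dropped with a warning.  Accelerations are finite differences of
interior-line speeds over their time gaps (one-sided at the ends of
the interior run, via `numpy.gradient`).  Motion-state labels use a
stop-speed threshold of 0.5 m/s (checked first) and a ±0.3 m/s² dead
band around zero acceleration for "maintain"; both configurable.
Headways are computed per (lane, line) with the first vehicle of each
signal cycle flagged as head car; how queue dissipation across cycle
boundaries should interact with the head-car rule is genuinely open,
and the cycle-reset rule is a configurable choice.

## Estimation

Forward/backward use per-step sum normalization; log P(O|λ) is the sum
of log scale factors, and a symbol impossible in every state yields
−∞ rather than an exception.  Viterbi runs in log space with ties
broken toward the lowest state index.  Baum-Welch pools numerators and
denominators across sequences before dividing (the standard
multi-sequence extension; π is the mean first-step posterior), smooths
A and B with an additive ε = 1e-10 and renormalizes, resets
never-visited rows to uniform with a warning, and stops when the
relative log-likelihood improvement falls below 1e-6 or after 500
iterations.  Initialization is seeded Dirichlet-uniform with 5 random
restarts, best final likelihood kept; a caller-supplied initialization
replaces the restarts.  Internally sequences of equal length are
batched so each EM iteration is a handful of small dense matrix
products; results are identical to the per-sequence recursion.
Supervised MLE is closed-form row-normalized counting of labeled
sequences.

Because unsupervised estimation identifies states only up to
relabeling, fitted models are aligned to a reference by the best of
the 24 permutations (minimum total absolute emission difference)
before any entrywise comparison.

Validation uses a held-out design:
sequences are split at the vehicle level (whole sequences, never
within one) at a fraction 7480/11264 ≈ 0.664 of vehicles, and the
Baum-Welch estimates are compared against supervised MLE on the
held-out labeled vehicles by mean absolute percentage error over all
entries of π, A and B with reference value ≥ 0.01 (near-zero
references are masked to avoid division blow-ups).  MAPE on the
default synthetic run is large (≈45–85%): a zone receives only ~1,200
held-out records, so reference emission probabilities of order
0.01–0.05 carry relative sampling noise of the same magnitude; the
statistic is reported for inspection, not asserted against a target.

## Behavior metrics

Stability is the matrix 2-norm (largest singular value) of B, the
standard reading of "2-norm"; a Frobenius variant is provided behind a
flag.  For a row-stochastic 4×81 matrix it ranges from 2/9 (uniform
rows; fully indecisive) toward 1 (orthogonal one-hot rows; fully
decisive).  Risk is α = Σₖ log₁₀ x_k over the six dangerous symbols
with x_k = maxⱼ b_j(k), the emission probability under the symbol's
most likely state — six summands, the reading consistent with
typical magnitudes of such indices; the alternative summing all 24
(state, symbol) pairs is implemented behind a flag and is
systematically more negative.  Probabilities are floored at the
smoothing ε before the log.  Larger (less negative) α = riskier.

## Danger prediction

For each occurrence of a dangerous symbol, the current state is the
argmax of that symbol's emission column (over all four states; "stop"
is effectively excluded at high-speed symbols by its near-zero
emission), the predicted next state is the argmax of the current
state's transition row, and the warning is severe when the predicted
action is not decelerate or stop.  Warnings are a pure function of
(parameters, sequence): one warning per occurrence, no deduplication.
When a vehicle crosses a zone boundary mid-sequence, the zone of the
current observation selects the matrices.

## Synthetic data

The generator emulates a specific large urban data-collection setting: a 190 s cycle with 35 s
green (yellow set to 3 s, a typical urban value, since only green and
cycle length are given), 60 km/h posted limit, detection lines every
2.92 m over the outer 135 m, 30 frames/s, zone boundaries at
40/100/135 m, and 256 vehicles × 44 observations = 11,264 records
(44 = 12 + 20 + 12 interior lines per zone on this geometry).

Two paths: (a) exact HMM sampling per zone from a fixed ground truth —
the data-generating process the estimator assumes, used for estimator
tests and the default pipeline source, because the metric-ordering
claims concern the ground-truth emission structure; (b) a kinematic
simulation — Poisson arrivals (950 veh/h over 2 simulated lanes, half
the 1,900 veh/h through volume of the four-lane setting), entry speeds
uniform on (8 m/s, speed limit), hidden state updated once per second
from the current zone's transition matrix, state-conditional
accelerations +1.5 / −2.5 / 0 m/s² and braking to rest at −3 m/s²
(ordinary urban values), no overtaking (followers cap speed at a 2 m
gap behind their leader), frame-rounded detection records — whose
observations are recovered through the real kinematics and
discretization stages.

The default ground truth is deterministic and documented in code:
per-state emission factors over the four observed variables combined
by outer product, mixed toward uniform with zone-specific diffuseness
(0.90 / 0.50 / 0.85 for zones 1/2/3 — the dilemma zone is flattest),
and with extra mass on the six dangerous symbols for the non-slowing
states (0.04 / 0.20 / 0.01).  This encodes the qualitative behavioral
claim — dilemma-zone drivers are the least decisive and the most
dangerous — so that the pipeline's metric ordering (zone 2 lowest
2-norm, highest risk index) is a reproducible consequence, not an
assertion.

What the generator does *not* emulate: lane changes, turning
movements, pedestrian interactions, per-driver heterogeneity,
signal-responsive behavior beyond what the state chain encodes, and
measurement noise other than frame rounding.  Passing tests on
synthetic data therefore demonstrate the correctness of the
computations and the internal consistency of the model, not the
empirical magnitudes any field deployment would produce.

## Numerical and design notes

- Sequence symbols are 1-based everywhere (0 marks "not yet observed"
  in simulator traces); states are 0-based.
- Zero-probability handling: scaling collapse at a step marks the
  sequence impossible (−∞ log-likelihood) and the trellis row is set
  uniform so downstream code stays finite.
- The EM trace is the likelihood of the *pre-update* parameters each
  iteration plus a final evaluation, so monotonicity (up to 1e-9
  relative) is checked on every fit.
- Transition-matrix recovery is only as good as state identifiability:
  with near-uniform emission rows (as in the dilemma-zone truth, by
  design) the likelihood is flat in A and the unsupervised estimate
  has high variance — verified to match an independent EM
  implementation to the same optimum.  The recovery test therefore
  uses a well-identified truth with sparse emission rows.
- Viterbi path comparisons against enumeration allow for exact
  mathematical ties between distinct paths (same factor multiset);
  on ties any optimal path is accepted.
- Problem sizes in the test suite (e.g. 256 vehicles in the full run,
  200×50 sequences in the recovery experiment, 1,000 enumeration
  instances at T ≤ 6) were chosen to make every statistical check
  well-powered at desk scale while the whole suite completes in about
  a minute.
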