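# Methods

## The explicit-duration hidden semi-Markov model

`gazehsmm.hsmm` implements the standard explicit-duration HSMM over a
discrete observation alphabet. The generative story: the chain enters a
macro-state `i` (initially `i ~ π`), draws a residence duration
`d ~ P_i(·)` supported on `1..D`, emits `d` observations i.i.d. from the
categorical row `b_i(·)` — one observation per time step of residence — and
then jumps to a different state `j ≠ i` with probability `a_ij`. The
transition matrix has a structurally zero diagonal: `A` describes
*macro*-transitions, and all within-segment persistence is carried by the
duration pmf, which is exactly the expressiveness a plain HMM lacks (its
implicit dwell time is geometric through `a_ii`).

Two formulation details deserve explicit statement because variants exist in
the literature:

* **Duration variable.** The trellis arrays are indexed by the *elapsed*
  residence time `τ_t` (how long the current segment has been active up to
  and including `t`), not by the remaining time. The forward variable is
  `α_t(i, d) = P(o_1..o_t, q_t = s_i, τ_t = d)`, which at `t < T` carries
  the survival mass `S_i(d) = Σ_{δ≥d} P_i(δ)`; the backward variable
  conditions on the same event, so `Σ_{i,d} α_t(i,d)β_t(i,d) = P(O)` holds
  for every `t` and the posteriors `r_t(i,d) = α_tβ_t / P(O)` sum to one at
  each time step.
* **End-of-sequence handling.** The likelihood requires the final segment to
  complete exactly at `T`: at the last step the survival factor is replaced
  by the pmf value, so `Σ_{i,d} α_T(i,d) = P(O)` ranges over completed
  durations only while `β_T(i,d) = 1` remains the natural initialization. A
  right-censored variant (survival weight on the last segment) would be a
  small change to the same boundary factor; exact completion was chosen
  because it is directly checkable against exhaustive enumeration, and the
  enumeration oracle — not any particular recursion layout — is what defines
  correctness in the test suite (all instances with N ≤ 3, M ≤ 3, D ≤ 4,
  T ≤ 8 agree to 1e-9).

### Numerics

Public trellis functions (`forward`, `backward`, `posteriors`) work in log
space. The EM E-step instead uses per-time-step scaled linear recursions
(the classical scaling trick extended to segment windows), which is an order
of magnitude faster because it avoids per-cell `log`/`exp`; the two paths
agree to ~1e-13 and both are exercised by tests. Emission rows that lose all
posterior support during EM are floored at a configurable ε (default 1e-10)
and renormalized with a warning. Viterbi ties are broken deterministically
front-to-back (smallest initial state, then smallest segment duration, then
smallest successor state); exact ties are structural — permutations of the
same factor multiset — so determinism, not a canonical order, is the goal.

### Re-estimation

EM uses the exact sufficient statistics of the complete-data likelihood:
initial-state posteriors for `π`, expected macro-transition counts
(summed segment-end × transition × continuation posteriors) for `A`,
expected per-step state occupancies for `B`, and **one count per segment**
(the posterior probability that a segment of state `i` with total duration
`d` occurs) for `P_i(d)`. The last point matters: re-estimating durations
from the per-step occupancy `r_t(i,d)` would count a duration-`d` segment
`d` times, biasing the pmf toward long durations, and would not be an exact
M-step; with segment-level counts the log-likelihood trace is provably
non-decreasing, which the tests assert (tolerance −1e-8, 20 starts × 5
datasets). When `duration_family="discretized_normal"`, the M-step projects
the posterior duration moments back onto normals discretized over `1..D`
(mass of `(d−½, d+½]`, renormalized); the default is the free
`"table"` family.

`simulate` truncates the final segment at `T` (a recording simply ends),
which is mildly inconsistent with the exact-completion likelihood; the
effect is confined to one segment per sequence and shows up only as a
percent-level shrinkage of the longest fitted duration mean in the recovery
experiment (well inside its 10 % acceptance band).

## Fixation detection and the dwell threshold

Fixations are maximal runs of consecutive valid, on-screen samples inside
one AOI rectangle, kept when the run's time span reaches the minimum
fixation duration (default 200 ms). This is deliberately AOI-run-based
rather than dispersion- or velocity-based: the downstream representation
only needs AOI dwells, and the rule is exactly testable against a run-length
oracle. Rectangles are half-open `[x_min, x_max) × [y_min, y_max)` with a
top-left pixel origin, so shared edges cannot double-assign; overlapping
AOIs resolve by configuration order (first match wins). "Outliers" are
defined operationally as samples outside the configured screen bounds.

As an alternative to the global 200 ms threshold, per-AOI thresholds can be
derived from non-dwell-time (NDT) statistics: Φ = μ_NDT + σ_NDT, where the
non-dwell times of an AOI are the gaps between successive fixations on it
and σ is the population (n-denominator) standard deviation. Both thresholds
are computed; the global 200 ms is the default detector parameter, Φ is
stored per AOI in the visual-behavior table for reporting or opt-in use.

## Pattern mining

`cspade` mines frequent ordered patterns of single AOI symbols under gap
constraints (event-index difference between consecutive matched items in
`[min_gap, max_gap]`), a window constraint (total event-index span) and a
maximum length. Support is sequence-level: the number of distinct sequences
containing at least one constrained embedding. Supports of lengths 1 and 2
come from a horizontal scan; longer patterns grow depth-first by temporally
joining the parent's occurrence list with the ID-lists of frequent
2-sequences starting at its last item. The 2-sequence join (rather than the
classic equivalence-class sibling join) is required for completeness under a
`max_gap` constraint and is verified against a brute-force enumerator on
random databases. Items-per-element is fixed at one (gaze events are
atomic); an `accuracy ≠ 100 %` pruning rule that belongs to
classification-rule mining is intentionally not part of plain frequent
mining, though an optional per-class minimum support is available when
sequences carry phase labels. `min_len_report` only filters the returned
list (the CLI defaults it to 6, one per AOI region); mining itself always
starts from single symbols, as the anti-monotone pruning requires.

## The recognition pipeline

A single 3-state model is fitted with states identified with the classes
HP/MP/LP (the alternative — one model per class — is out of scope).
`fit_state_model` initializes the emission rows from per-class empirical
symbol frequencies (add-one smoothed), durations from a broad discretized
normal, transitions uniform off-diagonal, then runs a **short** EM
refinement (default 5 iterations). The brevity is a deliberate regularizer:
the class meaning of each state lives only in the supervised initialization,
and unsupervised EM optimizes marginal likelihood with no incentive to
preserve it — on synthetic data, classification accuracy falls monotonically
with refinement length (from ~1.00 at 1–5 iterations to ~0.90 at
convergence) as the emission rows blur into each other. Early stopping keeps
the states anchored while still letting the durations and transitions adapt.

`classify_sequence` Viterbi-decodes a sequence and aggregates the
segmentation to one label; the default is the duration-weighted modal
decoded state (ties to the lowest state index), with `"final"` (last
segment's state) and `"posterior-mean"` (largest mean posterior occupancy)
as alternatives. The maximum duration `D` defaults to 40 steps; when
observed run lengths are available, `choose_max_duration` implements a
99th-percentile rule with a cap. Evaluation reports per-class and pooled
(micro-averaged) confusion counts N₁/N₂/N₃ and percentage P/R/F with
β = 1 by default; with one label per sample the pooled N₂ and N₃ are
necessarily equal.

## Synthetic data: what it does and does not emulate

The scenario generator reproduces the *structure* of a cockpit eye-tracking
study: six 300 × 300 px instrument AOIs on a 1920 × 1080 screen, 100 Hz
sampling, isotropic Gaussian jitter (default sd 3 px), i.i.d. dropout
(default 2 %), and scan paths driven by a ground-truth 3-state HSMM whose
emission rows concentrate each perceptual level on different instruments
(means of the discretized-normal residence times: 8 / 12 / 18 steps for
HP / MP / LP). Class-conditional sequences come from per-class variants of
the base model (transitions biased back to the class state with return
probability 0.8 and a 2.5× boosted class-state residence), so the class
state dominates roughly three quarters of each path; the ground-truth label
is the duration-weighted modal true state. Per-step dwell times are uniform
on 300–800 ms, all above the detection threshold.

What this does **not** emulate: saccade kinematics and smooth pursuit,
calibration drift or systematic (non-isotropic, non-stationary) tracker
error, correlated dropout bursts, and the fact that real AOI sequences are
produced by a task-driven, non-stationary scanning policy rather than a
time-homogeneous semi-Markov chain. Passing tests therefore demonstrate
correctness of the algorithms and honest recoverability under the stated
noise model — not field performance on real recordings.

## Problem sizes used in tests and the acceptance script

Oracle-equivalence checks run on 200 random instances small enough to
enumerate exhaustively (N ≤ 3, M ≤ 3, D ≤ 4, T ≤ 8). The recovery
experiment uses 300 sequences of length 200 (≈ 5 000 segments), enough to
pin A and B to within a few hundredths. The classification experiment uses
150 sequences of 120–240 steps, split 90 train / 60 test. These sizes were
chosen so the entire suite runs in a few minutes on one CPU while leaving
the statistical margins comfortable.
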