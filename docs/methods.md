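# Methods

## The measurement chain

The package models the full measurement chain of a rodent
ischemia–reperfusion (IR) ventilation experiment. A ventilator delivers
either a fixed tidal volume (VCV) or a pre-computed variable pattern (VV);
airway pressure, flow and volume are sampled at 200 Hz; respiratory-system
mechanics are estimated breath by breath from the equation of motion; lung
injury is read out by stereological morphometry, ultrastructural grading
and relative gene expression. Each stage is an independent module, and a
synthetic-experiment generator wires them into a closed generator →
estimator loop with known ground truth.

## Tidal-volume patterns

VV patterns are i.i.d. Gaussian draws with mean `m` (default 6 mL/kg) and
SD `m·CV/100` (default CV 30%). Draws outside `m ± 3 SD` (or ≤ 0) are
rejected and redrawn: at 30% CV an untruncated Gaussian would produce
non-positive volumes with probability ≈ 4×10⁻⁴, and ±3 SD keeps every
delivered volume positive and physiological. Truncation shrinks the
realized SD by the truncated-normal factor ≈ 0.9866, so a raw pattern
realizes ≈ 29.6% CV.

By default (`normalize=True`) the finished pattern is affinely rescaled so
its sample mean and sample CV (n−1 convention) equal the nominals exactly
— the behaviour of a ventilator replaying a stored, calibrated pattern.
The truncation bounds are mapped through the same affine map, so the
in-bounds invariant is preserved exactly. Raw mode is kept for statistical
studies of the generator itself. A single integer seed governs the whole
sequence; there is no global RNG state. If a run needs more breaths than
the pattern holds, the pattern cycles from the start.

## Waveform simulation

One compartment with resistance `R_RS`, volume-independent elastance
`E1_RS`, volume-dependent elastance `E2_RS` (units cmH₂O/mL²) and
end-expiratory pressure `P0` (absorbing PEEP; volume is counted from the
end-expiratory level, so PEEP-level lung volume lives in `P0`):

    Paw = R_RS·V̇ + (E1_RS + E2_RS·V)·V + P0

* **Inspiration**: square (constant) flow — the standard for rodent VCV;
  the inspiratory time comes from the rate (default 40/min, the
  physiological mid-range for rats when no blood-gas titration model
  exists) and the I:E ratio (default 1:2).
* **Expiration**: passive relaxation, `V̇ = −(E1·V + E2·V²)/R`, stepped at
  the sampling interval with an *implicit trapezoidal* update (each step
  solves a scalar quadratic). The implicit trapezoid was chosen over
  explicit stepping so that the stored volume equals the discrete
  trapezoidal integral of the stored flow to machine precision — the
  invariant the fitting stage relies on — while remaining A-stable for
  stiff time constants. A single zero-flow sample marks the
  inspiration/expiration switch, and the inspiratory flow amplitude is
  chosen so the discrete integral delivers the commanded volume exactly.
* **Noise**: additive Gaussian on pressure only (transducer-like, default
  SD 0.2 cmH₂O); flow and volume are treated as ventilator-commanded.
  Delivery imperfection is modelled as multiplicative Gaussian noise on
  each breath's V_T (default CV 1.5%, the magnitude ventilators realize in
  constant-V_T mode); independence makes the realized VV variability
  compose in quadrature, √(30² + 1.5²) ≈ 30.04%.
* A cycle whose end-expiratory volume exceeds 1% of the delivered volume
  is flagged (incomplete exhalation), not rejected.

## Mechanics estimation

Recordings are segmented at inspiratory-flow onsets: an upward crossing of
a positive threshold, re-armed only after flow has gone negative. The
threshold is 5% of the *median* positive flow rather than of the peak
flow: under VV the largest and smallest breaths differ ~20-fold in peak
flow, and a peak-referenced threshold provably misses the smallest
breaths. Candidate cycles shorter than a quarter of the nominal period are
merged; leading samples before the first onset and trailing fragments
shorter than half the median cycle are dropped; volume is re-zeroed per
cycle.

Each cycle is fitted by ordinary least squares over the full cycle
(inspiration + expiration; inspiratory-only is available) to the linear
model `[V̇, V, 1]` and the volume-dependent model `[V̇, V, V², 1]`. The
contract is the least-squares minimum; designs with condition number above
1e8 raise an ill-conditioned-fit error naming the cycle, and cycles whose
volume excursion spans less than half the tidal volume raise an
unidentifiable-fit error (E2 cannot be separated from E1 without volume
range). The nonlinearity index is

    %E2 = 100·E2·V_T / (E1 + E2·V_T),   V_T = max volume of the cycle,

the convention of the volume-dependent-elastance literature. Negative E2
(tidal recruitment) is reported unmodified; window summaries flag windows
where more than 20% of breaths have E2 < 0. Summaries average the last
30 s of each window (configurable) — long enough to suppress noise, short
enough to be stationary within a time point. E2 is carried in cmH₂O/mL²
throughout for dimensional correctness even where reports print cmH₂O/mL.

The estimator's absolute precision for E2 is set by the pressure noise and
the design matrix, so its *relative* error is only meaningful where E2 is
substantive; recovery checks are therefore run at injury-range mechanics
(E2 = 0.6 cmH₂O/mL², %E2 ≈ 45%), where 200 noisy breaths give < 2% bias
and < 5% RMSE per parameter.

## Histology and ultrastructure

Collapse fractions follow the point-counting estimator: per field,
100·(collapsed points)/(denominator); the denominator is all 100 grid
points by default (the literal counting rule), with a parenchyma-only
option since excluding non-parenchymal points (vessels, airways) is also
common — outputs state which was used. The animal-level statistic is the
median across the 10 fields with IQR (means are also emitted). The EM
severity grade maps a declared fraction-of-tissue-changed to 0–4 with bin
edges at 25/50/75 (upper-edge inclusive; grade 0 requires a fraction
rounding to 0%). No pixel-level image analysis is attempted — the package
operates on point labels and declared fractions. Cohen's kappa
(unweighted) quantifies two-observer agreement; the degenerate case
(expected agreement 1) raises rather than returning 0/0.

## Relative expression

Triplicate Ct values are averaged per (animal, gene); replicate SD > 0.5
cycles or missing replicates raise a QC flag but never drop data. ΔCt
normalizes to the 36B4 reference gene per animal and side; ΔΔCt calibrates
to the *mean* ΔCt of the non-ventilated calibrator animals of the same
lung side (left = injured, right = contralateral) — the standard 2^−ΔΔCt
convention; the calibrator defaults to the pooled NV groups. Fold change
is 2^−ΔΔCt; group summaries are median (IQR). Amplification-efficiency
correction (Pfaffl) is out of scope.

## Sample size and tests

The two-sample t-test sample size iterates n upward from 2 and evaluates
exact power from the noncentral t distribution (noncentrality `d·√(n/2)`
at equal allocation, df = 2n−2). For d = 1.85, α = 0.05 two-sided, power
0.8 it returns 6 per group, and a vectorized 10⁵-replicate simulation
oracle agrees with the analytic power to < 1%. Summaries use the linear
interpolation quartile convention. The paired t, mixed two-way
repeated-measures ANOVA with Bonferroni post-hoc (via pingouin) and
Kruskal–Wallis (via scipy) are dispatch plumbing; Dunn's post-hoc z
comparisons (rank-based, tie-corrected, Bonferroni-adjusted) are computed
in-package as no installed library provides them.

## Synthetic experiments

`study_synth` draws 36 animals (body weight ~ N(0.526, 0.117) kg,
truncated positive), randomizes them to Sham-VCV/Sham-VV/IR-VCV/IR-VV
(6 each) plus NV-Sham/NV-IR (6 each), and emits per animal: four
recording windows (Baseline 1, Baseline 2, Initial, Final) with scheduled
ground-truth mechanics, a triplicate Ct table for both lung sides, 10
point-count fields and 20 two-observer EM images per side.

Baseline mechanics default to R = 0.15 cmH₂O·s/mL, E1 = 2.0 cmH₂O/mL,
E2 = 0.15 cmH₂O/mL², P0 = 2 cmH₂O with 15% lognormal between-animal
spread — %E2 ≈ 19% at 6 mL/kg, the healthy-rat range. Effects are
multiplicative knobs chosen for *direction and ordering*, not to mimic any
in-vivo table: IR doubles E2 (and raises E1 by 15%) at Baseline 2; two
hours of VCV doubles E2 again and raises E1 by 20% while VV slightly
lowers both; IL-6 and ICAM-1 carry +2 and +1.5 log2 fold in the IR-VCV
injured lung; SP-D carries +1.2 log2 fold under VV; collapse probabilities
order IR-VCV > Sham-VCV > IR-VV > Sham-VV per side. Observers share each
image's true fraction-changed and independently slip ±1 grade with
probability 0.10, which places kappa near 0.7 ("good" agreement). Blood
gases and hemodynamics are passthrough observational columns from simple
distributions, explicitly non-mechanistic.

Each time point is represented by a 20-breath recording window (the
summaries use the last 30 s), with the mechanics schedule piecewise
constant across time points; the 2-h course between windows is not
simulated, since the estimators only ever see the windows. Baselines are
ventilated in VCV for all groups; the assigned strategy applies from
Initial onward, mirroring the protocol timeline.

### What the generator does and does not emulate

It reproduces the study's *structure* (groups, time points, sampling rate,
pattern statistics, noise magnitudes, effect directions) but not: real
lungs' viscoelastic stress relaxation, intra-breath parameter changes,
spontaneous effort, blood-gas feedback on the respiratory rate (RR is
fixed at 40/min), mechanistic IR biology, or pixel-level histology.
Passing tests therefore demonstrate that the estimators recover what the
single-compartment generative model puts in — an internal-consistency
claim, not a validation against animal data, whose in-vivo values
(elastances, collapse fractions, fold changes) are measurements no
simulation can reproduce.

## Numerical choices and degenerate inputs

* Least squares via `numpy.linalg.lstsq`; tests cross-check against an
  independent normal-equations solve at 1e-8 relative.
* Implicit trapezoidal expiration step; with E2 = 0 the discrete solution
  tracks the closed-form exponential to < 0.5% at 200 Hz, converging at
  second order under grid refinement.
* CV/SD use the n−1 convention everywhere; quartiles use linear
  interpolation.
* Zero-CV patterns are constant sequences; zero-variance summaries return
  SD 0; single values flag an undefined SD rather than guessing.
* %E2 with zero total tidal elastance, kappa with degenerate marginals,
  missing calibrators and empty vt sources raise typed errors rather than
  returning sentinels.
* All randomness flows from named integer seeds through
  `numpy.random.default_rng`; derived child seeds stay below 2³¹.

## Problem sizes

The default test suite simulates up to a few hundred breaths per
condition, uses 100 seeds for the raw-CV sweep, 10⁵ replicates for the
power oracle, and 12-seed Monte-Carlo for effect-direction checks; the
acceptance script simulates six full 1200-breath runs. These sizes hold
Monte-Carlo error comfortably inside the asserted tolerances while keeping
a full run in tens of seconds on one CPU.

## Known limitations

Single-compartment only (no viscoelasticity, no esophageal-pressure
partitioning, no intrinsic-PEEP estimation beyond P0); constant-flow
inspiration only (no pressure-controlled modes); the qPCR model assumes
ideal amplification efficiency; EM grading consumes declared fractions,
not micrographs; the statistical layer delegates ANOVA internals to
established routines by design.
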