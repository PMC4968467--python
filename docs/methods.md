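# Methods

This note documents the models, parameters and numerical choices behind
`dazzletrack`: a simulation-plus-inference pipeline for a tracking
psychophysics paradigm in which an observer follows one square target
among identical moving distractors whose surface patterns (striped or
noise, at two contrast levels) are candidates for motion dazzle
camouflage interacting with the confusion effect.

## Stimuli

Each moving square is 32 x 32 px and carries a two-level luminance
texture defined in its *object frame* (+x = heading axis, so the pattern
rotates rigidly with the square):

* **parallel** — square-wave grating, wavelength 8 px (4 px dark / 4 px
  light), stripes elongated along the heading;
* **orthogonal** — the same grating rotated 90°, stripes across the
  heading;
* **binary** — 8 x 8 grid of 4 x 4 px blocks, each independently dark or
  light with probability 1/2.

Grating phase is 0° or 180° with probability 1/2, assigned independently
per square; phase 180° is the exact complement image.  Binary noise is
resampled per square by default (`shared_noise` behaviour can be emulated
by reusing one rendered image).  Two fixed luminance pairs are used:
(0.5, 132.5) cd/m² ("high", nominally 100 % contrast) and (38, 103)
cd/m² ("low", nominally 50 %).  The printed pairs imply Michelson
contrasts of ≈0.992 and ≈0.461 — not literally 1.0 and 0.5 — and neither
averages exactly to the 71.4 cd/m² background; the pairs are treated as
ground truth and the percentage labels as nominal.  No display-gamma
model is applied: luminances are carried symbolically.

## Motion model

Squares perform a confined correlated random walk at 200 px/s sampled at
100 Hz (displacement exactly 2 px per frame).  Each frame the heading
changes by a draw from a **wrapped normal** distribution with mean 0 and
SD σ = π/8 rad — sampled as a plain normal and wrapped, which is exact;
a von Mises would be indistinguishable at this concentration but the
wrapped normal is the more literal "circular Gaussian".  Orientation is
locked to heading.

**Confinement.** Square *centres* are confined to the 268 x 268 px arena
(origin at the arena centre, +x right, +y up, angles CCW from +x; all
positions continuous).  A step that would exit triggers up to 20 fresh
increment draws; if all fail, the heading is reflected about each
violated wall, which always yields an inward step from an interior
point.  Whether the bound applies to centres or whole squares is a free
choice (`confine_mode`); centre confinement is the default.  The
boundary rule perturbs only steps that start within one step length
(2 px) of a wall; increments measured over interior steps are exact
wrapped-normal draws, and the simulator diagnostic estimates σ from
those (the all-steps circular SD sits ~5 % above σ by construction of
any confinement rule).  Overlap between squares is permitted — at 60
squares of 32 px in a 268 px arena it is unavoidable — and no collision
rule exists.

Trials last 6000 ms: a 1000 ms highlight cueing the target, then a
5000 ms tracking period.  Initial positions are uniform in the arena,
initial headings uniform on the circle, and the target index uniform.

## Synthetic observer

The human participants are replaced by an explicitly synthetic tracking
mechanism; its parameters are generative knobs, **not** estimates of
human behaviour, and no cognitive realism is claimed.  The observer
maintains a *believed target*, initialized to the true target when the
highlight ends.  Each 10 ms frame:

1. with probability `swap_base x similarity[coloration] x (number of
   distractors within swap_radius of the believed square)`, capped at 1,
   the believed target switches to the nearest other square;
2. the cursor is placed on the believed target's position `lag_ms`
   earlier (clamped at the start of tracking), plus isotropic Gaussian
   noise with SD `motor_sd`.

Defaults: `motor_sd` 6 px (with zero lag this alone yields a Rayleigh
mean error of 6·√(π/2) ≈ 7.5 px, a plausible floor), `lag_ms` 100 ms (a
typical pursuit latency; with the walk's per-frame direction correlation
e^(−σ²/2) ≈ 0.93 it contributes ≈17 px of baseline error), `swap_base`
5·10⁻⁴ per nearby distractor per frame (at 60 squares ≈6 distractors sit
within the 48 px radius, giving roughly one swap per 500-frame tracking
period), `swap_radius` 48 px (1.5 square widths), and
`similarity = {parallel 1.6, orthogonal 1.25, binary 1.0}`, which
injects the condition ordering parallel > orthogonal > binary.  Contrast
never enters the observer, so the generated data contain a true null
contrast effect.  Between-participant heterogeneity multiplies
`motor_sd` and `swap_base` by a shared lognormal factor with log-SD
`participant_sd` = 0.25.

Consequences built in by this mechanism: with `swap_base = 0` the error
distribution is independent of group size; with swaps enabled the mean
error rises monotonically with group size (the confusion effect) because
the local distractor count does; at group size 1 all colorations are
equivalent (no distractor to swap to).  What the generator does **not**
emulate: appearance-based confusability (similarity is a scalar, not a
pattern computation), learning or fatigue across blocks, saccadic
structure in cursor paths, or any real contrast effect — so passing
end-to-end tests demonstrates that the pipeline detects effects of this
kind and size, not that the observer model mirrors human vision.

The distribution of *participant mean* errors per design cell is
right-skewed and approximately lognormal (Shapiro–Wilk on logs passes at
α = 0.01 in ≥95 % of the 42 cells), motivating the log transform the
analysis applies.  Raw trial-level errors within a cell are a
baseline/swap mixture: right-skewed, but not themselves lognormal —
an inevitable feature of any mechanism with rare, large confusion
events.

## Session design and response

A session is 6 blocks — one per coloration x contrast pair — in uniform
random order (no Latin-square constraint), each containing the 7 group
sizes {1, 10, 20, 30, 40, 50, 60} x 8 repetitions in shuffled order:
336 analysed trials.  The repetition count 8 is inferred from
336 / (6 x 7).  Four practice trials precede the first block, flagged
and excluded from analysis; their condition (first block's pair at group
size 20) is a free choice.  No trial-exclusion rules are applied.

The per-trial response is the mean Euclidean cursor-target distance over
the **final 4000 ms** of tracking at the 10 ms recording interval — the
half-open window (1000, 5000] ms, i.e. exactly the last 400 of 500
samples (half-open to avoid double-counting the boundary sample).

For modelling, trial errors are averaged per participant x coloration x
contrast x group-size cell (14 x 42 = 588 cells) and the cell means are
log-transformed (*mean-then-log*, the default reading of "participant
mean errors were log-transformed").  Because mean-then-log and
log-then-mean differ (Jensen), the alternative is exposed
(`log_stage="trial"`), and the ladder can equally be fitted to
trial-level log errors (`metrics.trial_log_table`).

## Mixed-model inference

The response is modelled as y = Xβ + Zb + ε with a random intercept per
participant, b ~ N(0, σ²_b I), ε ~ N(0, σ²_e I), fitted by **maximum
likelihood** (not REML: every reported comparison is a deviance test and
AIC values come from the same fits; AIC = −2ℓ + 2k with k counting fixed
effects plus both variance components).

**Fitting.** The likelihood is profiled over λ = σ²_b/σ²_e: for fixed λ,
GLS gives β̂ and σ̂²_e in closed form via the Woodbury identity on the
grouped covariance (cost O(np²) per evaluation), leaving a 1-D
deterministic search on log λ (bounded scalar minimization on
[−30, 15], xatol 10⁻¹⁰, with the λ = 0 boundary checked explicitly;
λ = 0 fits are allowed and flagged singular).  Fits agree with R's
`lme4::lmer(REML=FALSE)` to 4 decimal places in log-likelihood and AIC
and with a generic-optimizer maximization of the full joint Gaussian
likelihood to <10⁻⁵.

**Fixed-effect structure.** Group size enters as an orthogonal
polynomial (degree 2 by default; R `poly()`-style orthonormal basis via
QR, raw coding available and likelihood-equivalent); coloration and
contrast are treatment-coded with alphabetical reference levels (binary,
high).  LRT results are invariant to these codings.

**The ladder.**  Backward simplification by deviance tests
(χ² with df = parameter-count difference): (1) quadratic vs linear
group-size polynomial in the all-interactions model (df 6); (2) drop the
three-way interaction (df 4); (3) drop coloration x contrast (df 2);
(4) drop contrast x number (df 2); (5) drop coloration x number (df 4);
then from the main-effects model, delete (6) coloration (df 2),
(7) number (df 2), (8) contrast (df 1).  Failed interactions are
discarded as the ladder descends.

**Post hoc contrasts.** All pairwise coloration differences from the
main-effects fit; z = estimate/SE from the fixed-effects covariance;
single-step Tukey-type family adjustment p_i = 1 − P(max_j |Z_j| ≤
|z_i|) under the joint normal law of the three contrast statistics,
evaluated by scipy's quasi-Monte-Carlo multivariate-normal integration
with a fixed seed.  The normal (not t) reference matches z-statistic
reporting; adjusted p-values are floored at the unadjusted value.

**Within-subject CIs.** Cousineau–Morey: recentre each participant on
the grand mean, per-condition SE of the normalized scores, Morey
inflation √(C/(C−1)) for C = 42 conditions, scaled by the two-sided t
quantile with 13 df.

## Calibration results the suite recomputes

* LRT type-I error for a null 3-level factor (14 participants x 10 reps
  per level, 2000 simulations): within [0.04, 0.06].
* Variance-component recovery at the experiment's size (σ²_b = 0.04,
  σ²_e = 0.09, 14 x 42): the residual component is recovered within 25 %
  essentially always; the between-participant component cannot be — with
  14 participants its sampling SD is ≈ σ²_b √(2/13) ≈ 39 % of the truth,
  so the probability of landing within 25 % is ≈ 0.48 for any consistent
  estimator.  This is a design-inherent limit of small-q repeated-
  measures studies, not an estimator defect; the suite asserts the
  tighter joint bound anyway and that assertion documents the limit by
  failing.
* End-to-end: full 14 x 336 synthetic experiments recover a significant
  coloration main effect and the injected ordering of post hoc contrasts
  in every seeded replicate tried.

## Problem sizes used

Simulation-based checks use: 10⁶ motion steps for kinematic fidelity;
10⁴ rendered noise patterns (6.4·10⁵ blocks) for the dark-block rate;
2000 simulations for LRT calibration; 200 replicates for variance
recovery; 5 (test suite) or 3 (reproduction script) full-design
end-to-end replicates for ordering recovery; ≥150 trials per group size
for observer-level Monte-Carlo checks.  These sizes give Monte-Carlo
standard errors comfortably below the asserted tolerances.

## Known limitations

* The observer is a caricature; only the qualitative phenomena listed
  above are calibrated, and nothing about human mechanism should be read
  from its parameters.
* Degree-of-visual-angle conversions are reported nowhere: the display
  geometry's printed pixel quantities are authoritative (the printed
  7.54 deg/s and 2.2 minarc/px are mutually inconsistent by ~3 %).
* The generalized-least-squares re-analysis relaxing compound symmetry
  is out of scope, as are capture/speed-judgement paradigms and any
  display-hardware modelling.
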