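# Methods

This note documents the models, estimators and numerical choices behind
`speedcontours`: a pipeline for analyzing two-alternative forced-choice
(2AFC) auditory speed discrimination with the discrimination-contours
technique, exercised end to end on simulated cue-weighted observers.

## Stimulus model

Every stimulus is a point in the distance–duration Weber plane. Relative
to a reference sound travelling `R_dist = 21.17°` of arc in
`R_dur = 800 ms` (i.e. 26.4625 °/s at full precision; the package never
rounds internally), a target is described by

    w_distance = (T_dist − R_dist) / R_dist
    w_duration = (T_dur − R_dur) / R_dur

with `w_duration` on the horizontal axis and `w_distance` on the vertical
axis. Its physical speed is `ref_speed · (1 + w_distance)/(1 + w_duration)`.
Eight orientations through the origin, 22.5° apart and measured from the
positive distance (vertical) axis, sample the plane; four are the named
conditions: spatial (0°, only distance varies), coherent (45°, speed
constant), temporal (90°, only duration varies) and opposite (135°, speed
varies steeply).

**Level grids.** Nine levels per orientation, middle level = the reference,
are geometric in the target/reference speed-ratio factor over `[1/4, 4]`
(`f = 4^(k/4)`, `k = −4…4`). This reproduces the extreme target speeds of
6.62 and 105.85 °/s on the pure axes. The rule is algebraically infeasible
on two orientation families, so the grid falls back there:

* 45° (coherent): speed never changes; levels are geometric in the shared
  cue factor, `1 + w = f` (the natural degenerate-limit extension).
* 22.5° and 67.5°: the attainable speed ratio is capped near `cot 22.5° ≈
  2.41` by the line's slope, so levels are geometric in the dominant cue
  factor (distance below 45°, duration above).

Within every orientation the target speed remains strictly monotone in the
level magnitude (constant on the coherent line), and no trial leaves the
printed 6.62–105.85 °/s range.

The schedule shuffles all `8 × 9 × 6 = 432` trials with the design seed,
assigns motion direction (left/right) and start-speaker offset uniformly,
and deals trials round-robin into 6 blocks. Loudspeaker-array geometry is
carried as metadata only; no audio is modelled.

## Observer model (synthetic-data generator)

Observers receive noisy internal Weber fractions `ŵ_t = w_duration + ε`,
`ŵ_d = w_distance + ε` (ε i.i.d. Gaussian, sd `noise_sd` in Weber units —
noise proportional to the reference magnitudes, the standard psychophysical
assumption) and a derived speed fraction `ŵ_v = (1+ŵ_d)/(1+ŵ_t) − 1`. The
decision variable is

    D = w_speed·ŵ_v − w_duration·ŵ_t + s·w_distance·ŵ_d

answered "faster" iff `D > 0` (exact ties: fair coin). The negative
duration term encodes the temporal assumption *shorter sound = faster*;
`s = −1` applies the same heuristic to space (*shorter travelled distance =
faster*), `s = +1` is veridical. With probability `lapse` the answer is
replaced by a fair coin. Draws pushing a noisy fraction to −1 or below are
resampled so internal cues stay physical.

Defaults are `noise_sd = 0.3`, `lapse = 0.02`. Presets: `duration_only`
(0,1,0,+1), `distance_only` (0,0,1,+1), `speed_only` (1,0,0,+1), `eb_like`
(0, 1, 0.4, −1) and `sc_like` (0.3, 1, 0.3, +1). Cohort simulations jitter
each subject's weights (sd 0.1, clipped at 0) and noise (sd 0.05, floor
0.05).

What the generator does and does not emulate: it reproduces the
*statistical decision structure* the analysis assumes — graded psychometric
functions, inverted curves exactly where the temporal heuristic misleads
(spatial and coherent conditions), lapses, between-subject heterogeneity.
It does not model binaural acoustics, adaptation, attention or trial-order
effects, and the preset weights are not calibrated to any human cohort; a
passing pipeline shows the analysis machinery recovers the structure it was
built for, not that these parameters describe human listeners. Note a
geometric side effect worth knowing: a weighted observer is near-blind along
the orientation where its decision gradient cancels (157.5° for `eb_like`,
22.5° for `sc_like`), which is what produces whole-cohort fit failures on
single orientations and motivates the substitution fallback below.

## Psychometric estimation

"Faster" proportions per level are fitted with a cumulative Gaussian
`p(x) = Φ((x − pse)/σ)` by count-weighted Bernoulli maximum likelihood
(Nelder–Mead from a moment start, both slope signs tried). σ is allowed
either sign; `jnd_signed = σ`, so inverted curves carry negative JNDs and
|σ| is the JND. No free lapse parameter is fitted.

*Fixed floor.* The analysis pipeline evaluates the fitted curve as
`p_floor + (1 − 2·p_floor)·Φ(·)` with `p_floor = 0.01` — a fixed, symmetric
guess/lapse floor, not a free parameter, set at half the generator's
default lapse rate. Rationale: the level grids put extreme stimuli up to
10σ from threshold; under a no-lapse model a handful of stimulus-
independent errors at those saturated levels exerts enormous leverage and
can more than double the estimated σ. The floor removes that instability
while leaving the two estimated parameters untouched. The bare
`fit_psychometric` defaults to `p_floor = 0` and then recovers
noise-free cumulative-Gaussian data to better than 1e-3.

*Goodness-of-fit gate.* R² is the squared Pearson correlation between
observed and fitted proportions, tested with `F = R²(k−2)/(1−R²)` on
(1, k−2) df at α = 0.05. Fits failing the gate, and flat fits
(|σ| > 10·max|x|, or degenerate input), are replaced by the *worst JND* of
their cohort cell. "Worst" is ordered by converted JND for radial-axis fits
(an inverted curve is always worst on the precision scale) and by absolute
magnitude for contour radii (the contour needs a radius); ties resolve
toward the larger magnitude. A cell can contain no valid fit at all (a
cohort blind along one orientation); the pipeline then widens the donor
pool to the whole cohort rather than aborting, and flags every substituted
fit. Under i.i.d. coin-flip responses the gate fires at ≈ α (measured
0.058 at 1000-replicate scale), and the |JND| estimator has < 10% bias at
60 reps/level.

## Discrimination contours and ellipses

Each orientation's post-substitution JND magnitude `j`, mirrored through
the origin (`±j·(sin φ, cos φ)`), gives the 16-point contour. Ellipses are
fitted with the numerically stable direct least-squares method of
Fitzgibbon/Halir–Flusser (constraint `4AC − B² = 1`, guaranteeing an
ellipse); geometry comes from the eigendecomposition of the quadratic-form
matrix, and the major-axis orientation θ is reported from the vertical
distance axis so that 0° = duration-dominant, 45° = speed-dominant,
90° = distance-dominant. The center is fitted, not pinned at the origin. A
`conic` alternative fits an unconstrained algebraic conic and raises
`NotAnEllipse` on hyperbolic/degenerate JND sets — emulating general-conic
toolbox routines; such subjects are excluded from the orientation
statistics only. Exact 16-point samples are recovered to ~1e−9; under 5%
multiplicative point noise the median orientation error stays below 5°.

θ is axial (defined modulo 180°). Comparisons use the axial distance
`min(|Δ| mod 180, 180 − |Δ| mod 180)`, and orientation-vs-constant tests
operate on differences wrapped into (−90°, 90°]. One caveat is intrinsic to
axial data: against a target 90° away (e.g. a ~0° cohort vs the
distance-dominant 90° axis) wrapped differences straddle ±90° and the mean
difference is diluted — the test is conservative exactly at the antipode.

## Radial speed statistic and JND conversion

Each trial collapses onto `|r| = √(w_duration² + w_distance²)`, signed
positive when the target is veridically faster: `sign(w_distance −
w_duration)`, which on the constant-speed coherent line (where the speed
difference is identically zero) falls back to `sign(w_distance)`. The
literal alternative — signing by the vertical coordinate alone — is kept as
`rule="y"`, but is not the default because applied globally it would invert
the temporal condition for a veridical observer. With the default rule a
noiseless veridical speed observer yields increasing "faster"-vs-r curves
in all four conditions; heuristic observers invert spatial and coherent.

Negative JNDs are converted within each group (min/max over all the
group's signed JNDs, across conditions, after substitution):

    JND_conv = JND_neg − min(JND) + max(JND)

Non-negative JNDs pass through. The most negative JND maps exactly to the
group maximum and every converted value sits at or above it, so after
conversion low JND_conv always means good speed discrimination.

## Permutation statistics

All tests are two-sided with p = (hits + 1)/(n_iter + 1) under random
resampling, switching automatically to exhaustive enumeration (exact p)
when the full permutation set has ≤ 20 000 elements — which covers 2¹⁰
sign-flip patterns and the 12 870 splits of an 8+8 comparison. Fixed seeds
reproduce every p-value. Defaults: 5000 iterations, α = 0.05, Bonferroni
`min(1, p·m)` within each comparison family.

* One-sample / paired: sign flips of the (optionally axially wrapped)
  differences; Student t statistic; Hedges' g with the exact small-sample
  correction `J(df) = Γ(df/2)/(√(df/2)·Γ((df−1)/2))`; t-based 95% CI.
* Two-sample: group-label shuffles of a Welch t; Hedges' g on the pooled
  sd (zero pooled variance is flagged degenerate); Welch-t CI.
* Mixed ANOVA (Group × Condition): classical balanced decomposition —
  Group against subjects-within-groups, Condition and interaction against
  the condition×subject residual; partial η² = SS_eff/(SS_eff+SS_err).
  Permutation respects the exchangeability units: Group by permuting group
  labels across subjects; Condition and interaction by permuting condition
  labels independently within each subject after removing subject means
  (Freedman–Lane-style). Under a Gaussian null the type-I error of every
  effect is within [0.03, 0.07] at α = 0.05 (500 tables × 500 iterations).
  F statistics agree with `pingouin.mixed_anova` to machine precision.
* Corner comparison: 2×2 Pearson χ² (no continuity correction) between the
  two extreme opposite-condition points (shorter-duration/longer-distance
  vs longer-duration/shorter-distance), Cramér's V = √(χ²/N), Wald CI on
  the proportion difference. Zero margins are flagged, not raised.
* Shapiro–Wilk delegates to SciPy (3 ≤ n ≤ 5000, non-constant input).

CIs printed next to permutation tests are t-based and labelled as such.

## Reproducibility and problem sizes

A single global seed fans out through `numpy.random.SeedSequence` spawning
to the design shuffle, each simulated subject and each permutation test;
identical configs give byte-identical report bundles, and every output file
records the config hash and seed. The default cohort run is 20 subjects ×
432 trials; the acceptance recomputation uses single observers at 60
reps/level (4320 trials each) — the size at which the contour-orientation
recovery is stable to a few degrees — and the ANOVA calibration uses 500
null tables × 500 iterations.

## Known limitations

* The observer presets are demonstrative, not fitted to human data;
  group-level effect sizes of the simulated cohorts carry no empirical
  meaning.
* The no-lapse psychometric model (available with `p_floor = 0`) is
  unstable for low-lapse observers on heavily saturated level grids; the
  pipeline's fixed 1% floor trades a small bias for robustness.
* The mixed ANOVA assumes a complete, balanced subject × condition layout
  (guaranteed here by construction; incomplete layouts are rejected).
* Axial orientation tests are conservative against targets near the 90°
  antipode (see above).
* The per-projection contour reconstruction (separate `w_distance` and
  `w_duration` fits per orientation) is geometrically equivalent to the
  implemented magnitude-axis construction on oblique orientations but
  degenerate on the pure axes; the magnitude-axis route is therefore the
  single implemented construction.
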