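# Methods

This note documents the models implemented in `yokedbml`, the choices made
where the design was genuinely open, and what the synthetic-data generator
does and does not emulate.

## Paradigm simulation

The moving-circles session is generated blockwise. Defaults encode the
study conditions: 6 runs of two 180-s blocks (30-s off period between
blocks, 15-s lead and tail blanks, so one run spans 420 s), 25 collisions
in total with 0–3 per block, approach/retreat segments of 2–9 s whose
total durations are equated exactly (retreat durations are a shuffled copy
of the approach durations, in integer frames at 20 Hz), and exactly 7
near-misses per run (a near-miss is a local minimum of the edge-to-edge
distance in (0, 1.5] circle diameters). Stressor durations come from a
frozen 25-value schedule (median 1.37 s, range 0.16–4.27 s, bulk within
0.5–3 s), assigned in ascending order because the escalating press
requirement lengthened stressors as the session progressed. Distances are
edge-to-edge in units of one circle diameter, with a configurable maximum
separation of 10 diameters; "near" is defined as proximity
1 − d/d_max > 1/3, which makes collisions near and maximal separation far.

**Motion texture.** Each segment's backbone is a cosine ramp between
turning points, but a pure ramp makes the labeled direction (±1) and the
proximity derivative (the speed regressor) almost collinear after
hemodynamic convolution, because within a monotone segment the derivative
always carries the label's sign. The experimental motion was smooth only
at the trend scale — the circles frequently altered course within an
approach period — so the generator superimposes (a) slow within-segment
countertrend sinusoids (harmonics 2–4, amplitude-capped per segment) and
(b) heavy-tailed frame-scale kinks (clipped Student-t jitter) that put
label-independent structure into the distance derivative. Both components
vanish at segment endpoints, are soft-clipped above a floor just over the
near-miss threshold (so designated troughs remain the only sub-threshold
minima and collisions are approached monotonically, via a power-law creep
through the deep range), and are bounded by the screen ceiling. Amplitudes
were calibrated once so that the default paradigm reproduces the printed
design diagnostics (maximum task-regressor variance inflation factor at or
below 1.9 and parametric-regressor correlations below 0.5); the cost is
that the synthetic distance trace is rough at the frame scale, which is a
deliberate trade of cosmetic smoothness for the published collinearity
properties. A per-block rejection/retry step guarantees that event counts
are exact for every seed.

**Yoked behavior.** Successful trial k requires min(1 + k, 12) presses of
the controllable member, placed inside the stressor window (the final
press terminates the stressor). The uncontrollable member sees wheel
rotations at exactly the yoked press times with random rotation amounts,
and answers each rotation with probability 0.76, which reproduces the
direction of the published press-total asymmetry (uncontrollable members
pressed less despite instruction). Note that with the escalation rule and
guaranteed success the controllable total over 25 trials is 234 presses,
higher than the observed 173; real participants occasionally failed or
deviated, which the generator does not model.

## Synthetic cohort

Anxiety covariates are drawn at the pair level from a Gaussian over
(state average, state difference, trait average, trait difference) whose
covariance is constructed to reproduce three correlation targets: the
participant-level state–trait correlation (0.5), the state average–
difference correlation (0.05), and the trait average–difference
correlation (−0.22). Setting the average–average and difference–
difference correlations both equal to the participant-level target makes
the member-score correlation exact. Scores are on a STAI-like scale
(mean 35, SD 9); only the correlation structure matters downstream. The
target matrix is checked for positive semi-definiteness and infeasible
calibrations raise an error.

BOLD series follow the participant-level forward model: each task
regressor (built by the same design code used for analysis) times its true
amplitude, demeaned per run so that per-run normalization to mean 100 is
exact in the noise-free case and the first-level GLM recovers every
injected amplitude to numerical precision; plus per-run random polynomial
drift (orders 1–4) and AR(1) noise (coefficient 0.3, innovation SD 0.8 %
signal). The stressor amplitude is 0.30 % signal for controllable members
plus the per-region `effect_map` entry for uncontrollable members
(default +0.08 % in left/right BST and left dorsal anterior insula, about
0.5 residual SD of the pair contrast at the default noise level), and
varies trial by trial through a shared latent arousal term (SD 0.08).
TR defaults to 1.25 s — not an acquisition claim, simply a grid fine
enough for the FIR analyses — and 420 s runs give 336 samples per run.

SCR traces (250 Hz by default) superimpose a gamma-shaped response
(peak at 3 s) per stressor on a slowly drifting tonic baseline. Response
heights share a Gaussian-copula correlation with the participant's trial
BOLD amplitudes at the configured per-group coupling (0.2 controllable,
0.6 uncontrollable). The generator and the scorer share the kernel, which
is a documented convention rather than a physiological claim.

The generator does not emulate cardiac/respiratory physiological noise,
scanner artifacts, spatial noise correlations beyond the smoothing
applied, or real STAI item structure; passing tests therefore validate
the statistical machinery under the stated generative model, not
robustness to real-data pathologies.

## Participant-level GLM

Regressors are built at frame resolution (20 Hz), convolved with the
gamma-variate response (peak-normalized, 32-s kernel), and averaged
within TR bins. Direction/speed/interaction columns are built separately
for the near and far zones and set to zero during stressor
administration; the interaction is mean-centered over its support run by
run, and the parametric press regressor is mean-centered across events
run by run (the required press count escalates over the session, so
session-level centering would leak trend). Motion derivatives are
backward differences reset at run boundaries; drift uses per-run Legendre
polynomials to fourth order. OLS is solved by SVD-based least squares
with rank checking (singular values below 1e-10 of the maximum treated as
zero; dependent columns are named in the error). VIF for a column is
computed against all other columns plus an implicit intercept. FIR
estimation uses TR-spaced stick functions over a 15-s post-onset window
alongside the drift model. Trial-by-trial amplitudes use
least-squares-separate (target trial vs. all-others-pooled); exact
recovery holds for trials whose regressors do not overlap (one per run),
while dense 25-trial sessions incur a small pooling bias (< 0.1 % signal
in the noise-free check), which is inherent to the estimator.

## Group-level Bayesian multilevel models

All group models share one linear-Gaussian hierarchical form and one
sampler. Priors: Student-t(3, 0, 10·sd(y)) on fixed effects (the
intercept's scale additionally covers |mean(y)| so location is never
shrunk through an accident of scaling), half-t(3, sd(y)) on every scale
including the residual, and — for the robust location tests — a
Student-t observation model whose degrees of freedom get a Gamma(2, 0.1)
prior. The blocked Gibbs sampler draws all location parameters (fixed
effects and every varying-effect batch) as one joint multivariate normal
per iteration, then updates scales from conjugate inverse-gamma
conditionals (half-t priors via the inverse-gamma/inverse-gamma
expansion, t priors and likelihood via per-coefficient /
per-observation mixing variables, the likelihood degrees of freedom by a
log-scale Metropolis step). Each varying-effect scale is then re-updated
in the non-centred parameterization (effects held fixed as u/σ) with a
short Metropolis walk — the standard interweaving remedy for the funnel
that otherwise slows the centred Gibbs step when a scale approaches
zero. Defaults are 4 chains × 1000 post-warmup draws after 1000 warmup
iterations; any sampler achieving split-R̂ ≤ 1.1 and ESS ≥ 400 on the
reported parameters satisfies the downstream contract. Split-R̂ is
implemented in-package (and cross-checked against arviz in the tests);
ESS is delegated to arviz.

The region model includes varying slopes for all five covariates
(independent scales per covariate, no correlation structure across
slopes — a tractability choice with negligible impact under the
weakly-informative priors). Region evidence is reported for
θ_r = b₀ + τ_r with covariates mean-centered, i.e. marginal at the mean;
P+ is the fraction of pooled post-warmup draws strictly greater than
zero. The three-level voxel model replaces the region term with sub-ROI
plus voxel terms (a single shared voxel scale, configurable) and emits a
per-voxel P+ map from θ_v = b₀ + s_{j(v)} + u_v.

**Calibration checks.** Recovery simulations (61 pairs, +0.5 SD in 3 of
24 regions) must give P+ > 0.95 for the injected regions with all
split-R̂ ≤ 1.1, with partial pooling pulling region estimates toward the
grand mean. Null calibration uses 200 reduced-size simulations (20 pairs
× 8 regions, short chains — sized so the whole check runs in about two
minutes); one randomly selected region's P+ per simulation is compared
against the uniform distribution, because P+ values within one fit are
strongly dependent under partial pooling and pooling them would violate
the independence assumption of the Kolmogorov–Smirnov test.

## Voxelwise path and SCR coupling

Sub-ROIs are plain k-means on millimeter voxel coordinates (20 restarts,
seeded, clusters relabeled by centroid order so partitions are
deterministic). The standard map is a closed-form paired t test per voxel
(two-sided p, NaN with a warning at zero-variance voxels), thresholded at
a voxel-level alpha and filtered by connected-component extent (face
connectivity by default; edge and corner connectivity available); extent
thresholds are user inputs, since their Monte-Carlo calibration is out of
scope. Smoothing is mask-renormalized Gaussian convolution (per-axis
sigma from the voxel size, so constants are preserved and nothing bleeds
across the mask edge). SNR erosion keeps voxels whose temporal mean/SD
ratio meets a minimum, the generic form of excluding aqueduct-adjacent
voxels from a periaqueductal-gray mask.

SCR trials are scored as the within-window peak (1–6 s post-onset) minus
a 1-s pre-onset baseline, floored at zero; the window is a documented
convention. Per participant, trial SCR amplitudes are Spearman-correlated
with trial brain amplitudes (least-squares-separate betas) and
Fisher-z-transformed; the group comparison models the per-pair z
difference (uncontrollable minus controllable) with the robust location
model, covariates mean-centered, the intercept carrying the
controllability effect.

## Numerical conventions and limitations

- All randomness flows through one seeded generator with tagged
  substreams; identical seeds give byte-identical deterministic outputs,
  and the pipeline manifest records per-file digests.
- Event durations written to events tables are the schedule values; the
  frame timeline holds their nearest-frame rendering.
- Rank deficiency tolerance 1e-10 (relative); Spearman ties get average
  ranks; Fisher z clips |ρ| away from 1 by 1e-15 before atanh.
- The sampler is exact-conditional Gibbs, not HMC; for the model sizes
  used here (≤ ~300 location parameters) a fit takes seconds. Very short
  chains on null data can leave scale parameters above the R̂ ≤ 1.1
  contract — runs attach a convergence warning rather than failing
  silently.
- Prewhitening of first-level residuals is deliberately not implemented
  (the reference program's default OLS behavior is reproduced); AR(1)
  noise therefore slightly inflates first-level standard errors, which
  the pair-level analysis absorbs.
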