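# Methods

`headingflow` simulates a classic psychophysics protocol — judging one's
direction of self-motion (heading) from a radial optic-flow field — and runs
four heading-estimation models through it so their performance profiles can
be compared against human-like reference profiles. This note records the
models as implemented, the parameters that matter, the numerical choices,
and what the synthetic data do and do not establish.

## Stimulus model

The observer translates forward at 1 m/s through a cloud of dots at depths
drawn uniformly from 0.5–4.5 m, viewed through a 40° × 32° window. Dot
*image* positions are sampled uniformly over the field of view and then
back-projected to 3D (image-first sampling fixes on-screen dot density; a
uniform 3D volume would not). Flow is the instantaneous pinhole field in
tangent coordinates (x, y) = (X/Z, Y/Z):

    dx/dt = (x·Tz − Tx)/Z + x·y·Ωx − (1 + x²)·Ωy + y·Ωz
    dy/dt = (y·Tz − Ty)/Z + (1 + y²)·Ωx − x·y·Ωy − x·Ωz

All model computation stays in tangent coordinates, where a pure-translation
field is *exactly* radial about the focus of expansion (FoE) at
(Tx/Tz, Ty/Tz); positions and velocities are converted to degrees (atan per
axis) only for reporting, which is exact projective geometry at the 20°
eccentricities of this display (small-angle treatment would err by ~2%).

Heading offsets are realized by rotating the translation vector in the
horizontal plane, so a requested offset of d° puts the FoE at exactly
(d, 0)° with the target at the image origin. Directional noise rotates each
velocity vector by an independent zero-mean Gaussian angle (sd 0°, 7.5° or
15°), leaving speed and position untouched.

Velocities are analytic instantaneous flow rather than two-frame
displacements; the 270 ms estimate interval enters only as the independence
spacing of successive estimates within a trial. Limited dot lifetime
(250 ms) combined with ~100 ms visual persistence is modeled by giving every
model 40% more dots than the nominal dots-per-frame level (5 → 7, …,
200 → 280).

## The four models

**Motion-parallax differencing (lhp80).** Velocity differences of
image-coincident dots at different depths cancel rotation and leave a vector
along a line through the FoE. Random displays have no exactly coincident
dots, so the model greedily pairs the globally closest unused dots (each dot
used once, deterministic), forms one difference line per pair (pairs with
velocity-difference norm < 1e−9 are dropped), and returns the point
minimizing summed squared perpendicular distance to the lines (2 × 2 normal
equations). Near-parallel line sets raise a degenerate-geometry error that
the simulated observer converts into a coin flip — a forced-choice observer
must answer. With truly coincident pairs recovery is exact to machine
precision; on random clouds the pairs are only *nearly* coincident, so the
lines are biased off the FoE and errors of a degree or more occur even
without noise. Lines are unweighted (weighting by separation would help but
is deliberately not done). `max_pairs` defaults to ⌊n/2⌋.

**Template matching (p92).** A bank of radial-flow templates on a
41 × 41 grid of candidate headings (±20°, 1° steps; 81 × 81 at the 0.5°
resolution variant). Each template predicts, at each dot, motion directly
away from its heading; a local unit responds with Gaussian direction tuning
g(Δθ) = exp(−Δθ²/2σ²), σ = 30° (direction-only: speed tuning is flattened,
which keeps the activation scale-invariant over the 9× speed range the
depth interval produces). Activation sums local responses; the most active
template wins, ties broken toward the center. Noiseless recovery is exact
up to grid quantization (error ≤ (resolution/2)·√2).

**Subspace method (hj92).** For each candidate translation T the flows
consistent with T over all depths and rotations form an (n+3)-dimensional
subspace of the 2n-dimensional stacked flow space (n per-dot translational
columns A(xᵢ)T, three rotational columns B(xᵢ)). The residual is the
squared norm of the observed flow's component orthogonal to that subspace,
normalized by total flow energy (∈ [0, 1], scale-invariant); the candidate
grid (same as p92's) is scanned and the minimizer returned. Depths and
rotation are implicitly least-squares-eliminated — nothing is ever solved
for explicitly. Because the translational columns have disjoint two-row
support, the projection is computed blockwise (per-dot perpendiculars plus a
3-column closed-form fit), which makes the grid scan a set of BLAS matmuls
(~25 ms per 280-dot field at 1° resolution) and is verified in tests against
a dense SVD projection and an explicit depth+rotation least squares. Rank
decisions use a 1e−10 relative tolerance; the batched 3 × 3 solves carry a
ridge of 1e−10 × trace. With n < 5 the subspace generically spans
everything, every residual is ~0, and the estimate is flagged
low-confidence but still returned (the 2AFC observer must answer).

**Pairwise convergence (wc99).** The visual field is split into 1°-wide
heading columns spanning ±20°. For each dot pair the model asks whether the
pair's *horizontal* separation is shrinking: for rigid translation the
horizontal tangent velocity is u = c·(x − f) with c > 0, so a horizontally
converging pair can never straddle the heading azimuth f — this exclusion
is exact and is property-tested over 1000 random fields. (Full 2D
image-distance shrinkage does not support the exclusion: vertical motion
components let 2D-converging pairs straddle the heading, which is why
convergence is defined azimuthally here.) Each verdict multiplies the
column posterior (log-space, renormalized on read-out): converging pairs
multiply in-span columns by 0.1 (out-span 1.0); diverging pairs multiply
in-span columns by 0.55 vs 0.5 out-span. The diverging boost
(ratio 1.1 ≈ (1−ε)/(1−q) with ε ≈ 0.01 the chance of a false convergence
across the heading and q ≈ 0.1 the chance of convergence elsewhere) is
deliberate: with diverging pairs uninformative, grid-edge columns — outside
nearly every pair span, hence almost never penalized — become spurious MAP
winners once noise produces scattered false convergences (mean error ~15°
at noise sd 15°; with the boost, ~1.6–1.8°). Sensitivity: ratios 1.05–1.25
behave similarly (noisy error 1.5–1.8°), ratio 1.0 reproduces the edge
pathology, ratios ≥ 1.25 begin to bias noiseless estimates centerward.
All pairs are enumerated up to `max_pairs` = 50 000 (seeded uniform
subsample beyond); capping at a few thousand pairs equalizes the
information available at 100 vs 200 dots and suppresses the model's
characteristic continued improvement past 100 dots per frame. The MAP
column center is the (azimuth-only) estimate; ties go to the most central
column, which leaves a deliberate, documented centerward quantization: in
noiseless fields, columns adjacent to the FoE are often excluded by no
converging pair (the required same-side depth-inverted pair may be absent
from the sample), so the estimate lands 1–2 columns centerward in roughly
half the fields (mean error ≈ 0.7°). This shrinks estimate magnitude but
rarely flips its sign, which is what the forced-choice task measures.

## Simulated observer protocol

One trial = 7 independent flow fields (2 s of stimulus at ~270 ms per
estimate), each with a fresh cloud and fresh noise; the horizontal estimates
are averaged and the observer answers "right" iff the mean exceeds the
target position (0 for model runs). A model degenerate on all 7 fields
answers by seeded coin flip. A psychometric run presents the five unsigned
offsets (0.2°, 0.5°, 1°, 2°, 4°), signs balanced within each level; the
%correct curve is fitted and the 75% threshold extracted. Threshold
replicates accumulate until their standard error falls below 0.2° (or
`max_reps`); the SEM rule is applied to replicate thresholds — the quantity
plotted and compared — rather than raw estimates. Estimate variability is
the SD of per-trial mean estimates over 1000 trials at a fixed +1° offset
(mid-range; the offset at which variability is probed is config-exposed).

Design arithmetic: the human factorial design (4 dot levels × 3 noise
levels × 4 target locations × 10 signed offsets) gives 480 conditions,
collapsing signed offsets and targets gives 60 cells with 16 repetitions
over two sessions. Model runs fix the target at the image center, so only
the (dots × noise) grid and unsigned offsets remain.

## Psychometric fitting and aggregation

Cumulative Gaussians are fitted to %correct vs unsigned offset by least
squares (not binomial likelihood: downstream weighting is defined through
the RMS error of the fit). Two parameterizations ship: the default plain
P(x) = Φ((x − μ)/σ) with threshold75 = μ + 0.6745σ, and a chance-floored
P(x) = 0.5 + 0.5·Φ((x − μ)/σ) whose 75% point is μ. μ is constrained ≥ 0
(a zero-offset judgment is chance), which pins saturated cells — correct at
every offset — to thresholds near 0 instead of letting the fit drift to
arbitrary negative values. Non-convergent fits are flagged with RMSE = ∞
and receive zero downstream weight; no imputation.

Observer thresholds are normalized by each observer's grand mean over the
12 (dots × noise) cells, averaged per cell with weights ∝ 1/RMSE
(normalized to sum 1, RMSE floored at 1e−6), and rescaled by the grand mean
over observers. Weighted paired t-tests use the effective-sample-size
formulation: Var(d̄) = σ̂²·Σw² with σ̂² = Σw(d − d̄)²/(1 − Σw²) and
df = 1/Σw² − 1, which reduces exactly to the classical paired t-test at
uniform weights and loses all inferential power (p → 1) as the weight mass
concentrates on one pair. p-values are reported uncorrected.

## Model-vs-human comparison

Ordinary least squares with the human value as response: t_H = α + β·t_M
(and likewise for estimate SDs). R² measures shared profile shape; β is the
gain (1 = matched magnitudes). Fits are reported for three dot-level
subsets — the low range (≤ 50), the primary levels {5, 50, 100, 200}, and
all — and at both grid resolutions (1° and 0.5°; the parallax model has no
resolution parameter and is identical across the two by construction).

## Synthetic human data

No human data ship with the package; a generator produces per-observer
threshold tables with the qualitative structure that human heading
thresholds show: plateaus of 0.5°/0.75°/1.0° at noise 0/7.5/15° for dense
fields (noise roughly doubles the threshold), a smooth ~3× inflation as the
field thins from the ~25-dot knee down to 5 dots, noise sensitivity fading
in sparse fields, lognormal between-observer scatter (log-sd 0.2 across 19
observers), small per-cell jitter (log-sd 0.05), SDs at 0.6× the threshold,
and positive fit-RMSE draws for weighting. Every generated table is
validated against the orderings it must carry (noise ordering at ≥ 50 dots,
5 > 50 dots within noise level) before being returned.

These fixtures make the *pipeline* testable — normalization, weighting,
regression, gain recovery — but a green end-to-end test establishes only
that the machinery recovers constructed relationships; it says nothing
about numerical fidelity to any real observer population.

## Known limitations and scaled-down checks

- The template model's direction-only reading makes it nearly noise-proof
  at high dot counts: directional noise dithers its grid-quantized
  estimates, and the 7-estimate average then resolves sub-grid offsets, so
  its simulated thresholds can *fall* slightly when noise is added at 100+
  dots (noiseless thresholds are quantization-limited at ~0.25°). A
  speed-tuned variant might restore noise sensitivity; it is out of scope.
- The convergence model is azimuth-only by construction (no elevation
  posterior), and its noiseless precision is limited by exclusion coverage,
  not by column width.
- Test-suite simulations use reduced replicate/trial counts (typically 10
  replicates × 8 trials per offset instead of SEM-stopped runs with 16);
  the qualitative contrasts they check are several times larger than the
  resulting uncertainty.
- No frame-by-frame animation, eye rotations, lapse rates, or reaction
  times are modeled.
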