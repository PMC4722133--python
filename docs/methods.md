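# Methods

## The phenomenon and the model

When a seated subject is spun up in a swing-out gondola centrifuge, the
gondola rolls outward to align with the gravitoinertial resultant. The
semicircular canals register this roll as an angular displacement, while
the otolith organs keep signalling "upright" — the resultant stays
aligned with the body's long axis. The induced sensation of lateral tilt
is read out as the subjective visual horizontal (SVH): in darkness the
subject repeatedly sets a luminous line to what feels Earth-horizontal,
and the deviation (degrees, right tilt positive) decays over the minutes
that follow. That decay is a short-term forgetting curve for a canal-borne
angular-displacement memory, and the package's central question is its
functional form.

Two three-parameter candidates are compared by unweighted least squares
on each run:

- exponential: `SVH(t) = A·exp(−b·t) + C`, time constant `T = 1/b`;
- power: `SVH(t) = A·t^(−b) + C`.

The asymptote `C` is included in both families because individuals have a
persistent idiosyncratic SVH offset even when upright; for the power
family it is kept for comparability, although the unconstrained fit
routinely drives it to physiologically meaningless values (thousands of
degrees negative) — that behaviour is reproduced deliberately, not
clamped. Goodness of fit is RMS error only; we take RMS = sqrt(SSE/n)
(the plain reading of "root-mean-square error"; n, not n−p). A third
family, the single-trace fragility function
`m(t) = λ(1+βt)^(−ψ)·exp(−πt)`, is supported for evaluation but not
fitted.

Because the power function diverges as t → 0+, all model comparison is
confined to the observation interval [4, 360] s after the G plateau is
reached: no line settings occur before 4 s, and recording stops at 6 min.
Fitted curves are summarized by their endpoint values F(4) and F(360),
which for these monotone families are the extremes on the interval.

## Fitting: variable projection with a deterministic multistart

Both families are linear in (A, C) once b is fixed, so the
three-parameter problem is profiled down to one dimension: for each
candidate b the linear subproblem is solved exactly (least squares on the
design [basis(b, t), 1]), and the global search runs over b alone. The
search is a deterministic multistart: 64 log-spaced values of b
(default range [1e−4, 2] s⁻¹ for the exponential, [1e−4, 4] for the power
exponent), bounded Brent refinement in log b around every grid-local
minimum, followed by a fixed 60-iteration golden-section polish that
tracks the best evaluated point (Brent's stopping rule floors its
x-precision at ~sqrt(eps)·|x|, which leaves the last digits of b on the
table for noiseless data). Among candidates within 1e−9 relative SSE of
the best, the smallest b (flattest curve) is reported — an arbitrary but
deterministic tie-break. A constant series has b unidentified (the
profiled SSE is flat); it is detected by SSE flatness across the grid and
reported as A = 0, C = mean(SVH) at the smallest grid b rather than
chasing the b → ∞ ridge.

b > 0 is enforced in both families (decay orientation; the sign of the
tilt is carried by A); A and C are unconstrained, matching the original
unconstrained-fit behaviour. Fits refuse series with fewer than 4 points
or non-finite values. Everything is deterministic given the multistart
configuration; no randomness enters the fitter.

The test suite cross-checks the fitter against an independent oracle —
a 2000-point exhaustive grid over b with a closed-form 2×2
normal-equations linear solve and its own golden-section polish — and
the two routes agree to better than 1e−6 relative SSE on
study-conformant noisy series.

## Aggregation levels

Run-level fits are averaged into individual summaries (arithmetic mean
of A, b, C, F(4), F(360) and RMS over a subject's one or two runs)
before any group statistics; the individual time constant is
T = 1/(run-averaged b). Group tables report mean, median and sample SD
(ddof 1) over subjects. Note mean(1/b) ≠ 1/mean(b): the group-mean rate
0.018 s⁻¹ corresponds to 55 s, while the mean individual time constant
is ~85 s.

The model contest counts per-run power wins (power RMS < exponential
RMS), computes the percent excess of the group-mean power RMS over the
exponential one, and runs a two-sided paired t-test across subjects on
run-averaged RMS (df = n_subjects − 1). Identical inputs yield a defined
null result (t = 0, p = 1).

Group pooling follows three schemes. For binned pooling, the [0, 360] s
recording window is cut into k equal intervals (15 or 5 by default; the
first bin is simply sparse since no datum precedes 4 s); each subject's
settings — both runs pooled — are averaged within a bin, then bins are
averaged over contributing subjects; empty bins are dropped; both
families are fitted to the k pooled points. The all-points scheme fits
every raw setting from every run at once (tied times across runs are
allowed there). The quantity of interest is the gap ratio
RMS_power/RMS_exponential at each level: with heterogeneous individual
rates it collapses toward 1 as pooling coarsens — the averaging artifact
by which a mixture of exponentials masquerades as a power law.

One subtlety: with perfectly homogeneous noiseless exponentials the
all-points fit is exact, but the binned points are not on any
exponential — the within-bin mean of a convex function exceeds the curve
at the mean time (Jensen), bounded to second order by A·b²·w²/8 for bin
width w. The homogeneity control asserts exactness where it is exact and
this curvature bound where it is not.

A six-point discriminability report checks whether a data set can in
principle tell retention functions apart: ≥9 distinct measurement times
per run, precise times, large spans in both the measured quantity and in
time (the last/first time ratio is 90 for a full-window run), single
stimulus presentation, constant filler activity, and feasibility of
per-individual fitting.

## Synthetic cohorts

The raw setting series of the original cohort were never deposited, so
the generator emulates the study conditions and serves as the substrate
for all property-level checks. Defaults: 27 subjects, 17 with two runs;
per-run parameters drawn as A ~ lognormal(mean 27.8°, SD 15.2°),
b ~ lognormal(mean 0.018 s⁻¹, SD 0.0147 s⁻¹), C ~ normal(0.5°, 6.1°);
per-run setting noise is i.i.d. Gaussian with SD itself drawn
lognormal(mean 2.4°, SD 1.0°) and floored at 0.3°. Lognormal families
are a modeling choice: A and b must be positive, and b's SD ≈ 0.8×mean
demands right skew; only the first two moments are matched to the group
statistics. Two-run subjects share a subject-level standard-normal
component with intra-subject correlation 0.7 — a plausibility choice
(runs of one subject resemble each other more than runs across
subjects), not an estimate from data. Setting times draw the first
setting uniformly in [4, 20] s and inter-setting gaps uniformly in
[12, 20] s out to 360 s, i.e. 3–5 settings per minute and ~15–30 per
run. All randomness flows from one integer seed through
`numpy.random.default_rng`; identical configs give byte-identical
cohorts.

What the generator does not emulate: serial correlation of setting
errors within a run, drift of the asymptote during a run, the ramp-phase
dynamics before the plateau (series start at the plateau), asymmetries
between leftward/rightward tilt, or any departure of the true individual
decay from a single exponential. Passing recovery and artifact tests
therefore shows that the pipeline behaves correctly when the
single-exponential model is true at the individual level — it cannot
show that real SVH decay is exponential.

A multi-trace generator produces sums of exponentials
`Σ wᵢ·exp(−rᵢ t)`: with rates spread over about two decades the compound
decay of a single individual is better fit by the power family, the
mechanism by which multiple underlying traces could produce power-law
forgetting without any power-law process.

Decay-rate recovery under the default conditions is honest but marginal:
with noise SD ~2.4° on amplitudes ~28° and a rate CV of 0.8, flat
low-rate runs are weakly identified, and the median relative error of
recovered b over 200 runs hovers around 0.13–0.17 depending on the seed.

## Centrifuge kinematics

A small analytic utility connects the protocol numbers: at constant
rotation the centripetal acceleration is a = ω²r, the resultant is
G = sqrt(1 + (a/g)²), and the freely swinging gondola aligns with the
resultant at tilt = atan(a/g). Solving for a target G gives
a/g = sqrt(G² − 1); with r = 7.25 m and G = 2.5 this yields a 66.4°
swing-out and ω = 100.9°/s, and ramp times ω/α of 6.7 s and 14.4 s at
α = 15 and 7°/s². g is fixed at 9.81 m/s²; rounding to the protocol's
integers happens only at reporting.

## Reference tables and printed precision

The published per-run results (both families' A, b, C, F(4), F(360);
per-run RMS and setting counts) are embedded in `svhdecay.study` and
drive two reproduction suites: re-evaluating every row at t = 4 and
t = 360, and running the run-averaging → group-summary → contest
pipeline on the printed values. Printed constants are rounded (A, C, F
to 0.1°, b to 1e−4, a handful of very large power-family magnitudes to
whole degrees), so re-evaluation is compared within a first-order
propagated rounding bound: half a printed quantum per constant times the
corresponding sensitivity (∂F/∂b is ~A·ln t·t^(−b), which is large when
A ~ 10⁴), plus the half-quantum of the printed F itself, floored at
0.3°. Wherever constants carry full printed resolution the bound is
below 0.3° and the plain 0.3° band governs.

Known reconciliation limits: the per-run setting counts sum to 917 while
the all-points fit is described with 921 points, and some summary
medians differ in the last digit from medians of the rounded table
entries; neither is resolvable without the raw data, and neither is used
as a computed target.

## Problem sizes and tolerances

Reproduction suites run on the 44 published runs. Seeded synthetic
checks use: 50 series for fitter-vs-oracle agreement (1e−6 relative
SSE), 200 single-run subjects for rate recovery (median relative error
< 0.15), a 27-subject default cohort for the averaging-artifact
properties (per-individual exponential win fraction > 0.8; all-points
gap ratio below the mean per-individual ratio and below 1.10), and 500
subjects for generator moment checks (2 SE). Local refinement stops at
1e−10 relative SSE change; ties at 1e−9.
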