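# Methods

This note records the scientific and numerical decisions behind
`spherestim`: what the generator assumes, which parameters matter, what the
synthetic stimuli do and do not emulate, and where the design was genuinely
open.

## Stimulus space

A sphere is the parameter vector `(x, y, z, size, hue, sat, val)`. Scene
coordinates are dimensionless; random base stimuli are sampled inside the
symmetric box `[-1, 1]` per axis, which renders comfortably and makes
polar-shift distances easy to reason about. Derived stimuli may leave the
box — position is unbounded by design; only the following legality rules
are enforced, always by post-hoc clamping:

- `size >= 0.01`. Smaller spheres are barely visible; any operation that
  proposes a smaller radius stores exactly 0.01.
- `sat, val ∈ [0, 1]`, clamped.
- `hue ∈ [0, 1)`, wrapped modulo 1. The hue circle has no edge, so wrapping
  is not a clamp and is never recorded as one.

Clamping after sampling (rather than resampling until valid) keeps the
stated deviation distributions intact everywhere the bounds are inactive;
censoring only occurs at the bounds themselves. Each clamp event is
recorded in the derived stimulus's `lineage` string for auditability.

Default base-sampling ranges: positions `U[-1, 1]` per axis, size
`U[0.05, 0.25]`, hue `U[0, 1)` (the full circle), saturation and value
`U[0.6, 1.0]`. The color floor of 0.6 avoids colorless, pale or black
spheres, which would collapse the color dimension perceptually; a
reference base with saturation 0.9 and value 0.84 sits comfortably inside
this window. All ranges are overridable via `BaseRanges`.

## Category derivation

Uniform mode draws a magnitude `m ~ U[δ_lo, δ_hi]` and an independent fair
sign per parameter per sphere, giving symmetric deviation bands on both
sides of the base value with hard edges. Gauss mode draws
`N(base, σ)` directly. The two modes intentionally produce different
category geometry: bounded, flat-density membership versus unbounded,
center-weighted membership with a vague boundary.

Position is special-cased: the X–Z pair moves together as one polar shift
(`θ ~ U[0, 2π)`, distance `U[δ_lo, δ_hi]` or half-normal `|N(0, σ)|`),
while Y is perturbed independently like the scalar parameters. The
half-normal choice for Gaussian distances keeps distances nonnegative
without rejection; its mean is `σ·√(2/π)`, which the tests verify by
simulation. The X–Z displacement equals the drawn distance exactly for
every angle — a property the test suite asserts to float tolerance.

Every sphere and every parameter is perturbed independently; no
cross-sphere or cross-parameter coupling is modeled. Member `i` of a
category with master seed `s` uses `SeedSequence((s, i))`, so categories
are reproducible from one integer while members stay statistically
independent.

Preview exemplars visualize a spec's extremes: uniform mode places every
parameter at deviation `δ_hi` (both signs); gauss mode at the two-sided
tail quantiles of `N(base, σ)` with default total tail mass 5 % (the
2.5th/97.5th percentiles). Whether a quoted "5 % tail" means 5 % total or
per tail is ambiguous in common usage, so the tail mass is an explicit
parameter.

## Morphing

Continua interpolate linearly in parameter space: step `j` of `k`
in-betweens is `p1 + j/(k+1)·(p2 − p1)`. Linear interpolation is the
minimal rule that yields exactly equal adjacent-step differences, which is
the property categorical-perception designs require (equal physical steps,
so any sharp behavioral boundary is perceptual). Hue follows the shortest
circular arc; exact antipodes (circular distance 0.5) are a genuine tie and
break toward increasing hue, deterministically. Endpoints are copies of the
parents, not `t = 0, 1` evaluations, so they are bit-exact. Spheres pair by
index; a greedy nearest-position pairing is available behind a flag but off
by default, since stored sphere order is the declared correspondence.
Parents must have equal sphere counts — there is no rule for interpolating
a sphere into nothing.

## Exceptions

`exceptions_from_limits` first computes per-sphere, per-parameter min/max
over the category's members (the base is not included unless it is a
member). Per parameter, a fair coin picks a side and a magnitude
`U[δ_lo, δ_hi]` is added above the upper or subtracted below the lower
limit. With `δ_lo = δ_hi = 0` the exception parameters sit exactly on the
category extremes — already far from the base for a well-spread category.
Limits are per sphere index by default (exceptions stay structurally
comparable to members); pooled limits across spheres are available via a
flag. Hue limits are computed on deviations unwrapped around the base hue
(smallest signed circular difference) and re-wrapped afterwards, because
min/max is meaningless on a circle.

`exceptions_from_base` reuses the uniform derivation machinery on a
dedicated exception base, which is the route to exceptions with a
*different* sphere count from the category.

Exceptions are parametric outliers only; nothing here guarantees they are
perceptual outliers.

## Similarity

`stimulus_deviation` reports, per sphere: Euclidean distance (both X–Z and
X–Y–Z variants, since the default display ignores Y for placement),
absolute size difference, circular hue distance `min(|Δh|, 1 − |Δh|)`, and
absolute saturation/value differences, plus mean/max aggregates. No single
scalar similarity is produced by default — numeric deviations need not
track perception, and keeping parameters separate supports downstream
regression on behavior. Where code needs an ordering (scheduler set growth,
the simulated observer), `deviation_score` is an explicit equal-weight sum
of the mean components; its units are mixed and it is documented as an
ordering device only.

## Rendering

Orthographic projection after azimuth (about Z) and elevation (about X)
rotation; the default view maps X to the horizontal and Z to the vertical
image axis, with rotated Y as depth. Orthographic (not perspective)
projection is required by the display convention: depth must affect only
occlusion order, never apparent position or size. Larger rotated Y is
nearer by default (flag to invert). Discs are drawn back-to-front with a
stable sort (ties keep sphere order), filled with the HSV color converted
to RGB and shaded by a fixed radial highlight (offset 0.35 r toward the
upper-left, smooth falloff) for a 3D appearance. All shading constants are
module-level constants; angles are reduced modulo 360° before conversion to
radians so a full turn is bit-identical to no turn. The rasterizer is plain
numpy and the output a pure function of (stimulus, view): identical inputs
give byte-identical PNGs. Sphere radii below half a pixel are drawn at half
a pixel so no sphere silently disappears.

## Training protocols

The prototype scheduler starts each session with only the two prototypes
(set size 1 per category) and multiplies the per-category set size by
`growth_factor` (default 2) whenever rolling accuracy over the last
`window` responses (default 20) is at or above `criterion` (default 0.80).
The window resets on each advancement, so each block is judged on its own
trials; accuracy is computed as `n_correct / window` and compared `>=
criterion` directly (multiplying the criterion by the window first would
misclassify exact boundary cases in floating point). Stimuli added on
advancement come from the pool in order of increasing `deviation_score`
from the prototype, so later blocks are progressively less prototypical;
random order is a flag. The rolling-window estimator itself is a design
choice — any performance estimator could drive advancement — and both the
window and the criterion are configuration.

The exemplar scheduler draws every trial uniformly from the full pool with
the category bases excluded (a base found in a pool is removed with a
warning). The continuum scheduler draws uniformly from the morph steps and
labels by the side of a movable boundary; moving the boundary relabels
subsequent trials without touching the stimuli.

The simulated observer classifies by smaller composite deviation to each
category's prototype (or to the nearest stored exemplar) and responds
through a softmax with temperature `noise`: zero noise is the deterministic
argmin, large noise approaches chance. It exists to make the schedulers
testable end-to-end and to check the qualitative prediction that a
prototype-first protocol yields higher early-session accuracy than an
exemplar protocol for the same observer. That comparison is only
informative when the observer is off ceiling, so the test constructs
categories whose within-category spread is comparable to the
between-category offset (shared base geometry, bases offset by 0.5 scene
units in x and 0.15 in hue, polar shifts up to 0.45) with observer noise
0.25.

## What the synthetic stimuli do and do not show

The generator *is* the product here — the stimuli are synthetic by
definition — but the simulated observer is not a model of any real
subject: it sees parameter vectors, not images, and weighs all parameters
equally. Passing protocol tests therefore demonstrates scheduler
correctness and the internal consistency of the similarity measure, not
predictions about animal or human learning curves. Likewise, parametric
deviations (and exceptions built from them) say nothing about perceptual
similarity: large parameter changes can be nearly invisible and small ones
salient. Rendering aims at geometric correctness and determinism, not
visual parity with any particular display pipeline; colors are HSV→sRGB
without calibration, which matters for non-human subjects.

## Problem sizes and tolerances

Distribution-recovery tests use n = 2000 derived members with 3-standard-
error tolerances (and Kolmogorov–Smirnov / chi-square checks at α = 0.01);
sampling-uniformity checks use 10 000 trials over 50–60 item pools; the
learning-curve comparison averages 100-trial sessions over three seeded
replicates. These sizes make the statistical assertions stable under the
fixed seeds while keeping the whole suite fast. Float comparisons are
bit-exact where the contract is exactness (serialization round-trip,
endpoints, clamps at the floor) and use absolute tolerances of 1e-9–1e-12
where a chain of float arithmetic is involved (equal morph spacing, polar
displacement).
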