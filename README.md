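# spherestim

Parametric sphere-cloud stimuli for visual category-learning experiments.

Category-learning studies need large sets of unique, controllable stimuli:
natural images confound the category-defining feature with background cues,
and many artificial sets are slow to produce or hard to parameterize.
`spherestim` generates abstract stimuli composed of an arbitrary number of
colored spheres in 3D space, where every stimulus parameter — per-sphere
position (x, y, z), radius, and HSV color — is explicit, independently
perturbable, and recorded, so whole categories can be synthesized, morphed,
and audited numerically.

## The model

A stimulus is an ordered list of spheres, each a parameter vector
`(x, y, z, size, h, s, v)`. Hue lives on the chromatic circle (red ≡ 0 ≡ 1),
so all hue arithmetic is modulo 1; sizes have a hard floor of 0.01 (smaller
spheres are barely visible); saturation and value are clamped to [0, 1].

A **category** is defined by a *base stimulus* (its prototype) plus a
perturbation spec applied per parameter:

- **uniform** mode: a member's parameter is `base ± m` with magnitude
  `m ~ U[δ_lo, δ_hi]` and a fair random sign — members fill symmetric bands
  with sharp parametric boundaries;
- **gauss** mode: the parameter is drawn from `N(base, σ)` — most members
  resemble the base and the category boundary is fuzzy.

Sphere position is perturbed as a polar shift in the X–Z display plane:
angle `θ ~ U[0, 2π)`, distance per the spec (half-normal `|N(0, σ)|` in
gauss mode), converted back to Cartesian offsets. The depth coordinate Y is
perturbed independently like size and color, because the default display
projects along X–Z and Y only sets occlusion order.

On top of this the package provides morph **continua** (linear
interpolation in parameter space with `k` equally spaced in-between steps;
hue follows the shortest circular arc), **category exceptions** (stimuli
placed beyond the per-sphere parameter extremes of a category, or derived
from a dedicated exception base), per-member **deviation tables**
(Euclidean sphere distances, absolute size/color deviations, circular hue
distance), a **deterministic renderer** (orthographic projection,
painter's-algorithm shaded discs, byte-identical PNGs), and the three
**training schedulers** (prototype-based with performance-dependent
set-size doubling at an 80 % rolling-accuracy criterion, exemplar-based
uniform pool sampling with the prototypes excluded, and continuum training
with a movable category boundary), plus a simulated observer for end-to-end
session testing.

## Worked example

```sh
$ spherestim generate base --n-spheres 8 --seed 11 --out base.json
wrote base.json (8 spheres, seed 11)
$ spherestim generate category --base base.json --mode uniform \
    --position-dev 0.05:0.25 --size-dev 0.01:0.04 --hue-dev 0:0.08 \
    --members 40 --seed 3 --out cat.json
wrote cat.json (40 members, mode uniform, seed 3)
$ spherestim similarity --category cat.json --out table.csv
wrote table.csv (40 rows)
```

The deviation table quantifies how far each member sits from the prototype:

```text
  member  mean_xz_distance  mean_size_abs_dev  mean_hue_circ_dev
member-0          0.169734           0.023683           0.048481
member-1          0.169412           0.026944           0.028245
member-2          0.173290           0.020409           0.044228
max size dev over category: 0.04
```

Every mean X–Z distance lies in the requested polar-shift band
[0.05, 0.25], every size deviation within [0.01, 0.04] (the maximum over
the whole category is 0.04), and hue deviations stay below the 0.08 bound —
the uniform bands are hard limits, which is what gives uniform-mode
categories their sharp parametric boundaries.

The same operations are available as library calls (`make_base`,
`generate_category`, `morph_pair`, `exceptions_from_limits`,
`category_deviation_table`, `render`, `PrototypeScheduler`, ...); see the
module docstrings and `docs/methods.md`.

## File formats

Stimuli and categories are stored as JSON (`format_version` 1). A stimulus
file is `{format_version, label, seed, lineage, spheres: [{x, y, z, size,
hue, sat, val}, ...]}` with spheres in meaningful order (morphing maps by
index); a category file embeds `base`, `members` and the generating `spec`.
Floats are written at full round-trip precision, so `load(save(s))`
reproduces every parameter bit-identically. Renders are PNG (lossless) or
JPEG; trial logs are CSV with a JSON summary; every CLI run writes a
manifest recording the command, parameters and seed.
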