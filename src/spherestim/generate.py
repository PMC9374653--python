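"""Random base-stimulus creation and category-member derivation.

Two perturbation regimes produce category members from a base stimulus:

* **uniform**: each scalar parameter gets ``base +/- m`` with magnitude
  ``m ~ U[lo, hi]`` and a fair random sign — members fill symmetric bands
  with hard edges, so the category has clear parametric boundaries;
* **gauss**: each scalar parameter is drawn from ``Normal(base, sigma)`` —
  most members resemble the base, the boundary is fuzzy.

Sphere position is special: the X–Z position moves by a polar shift (angle
uniform on ``[0, 2pi)``, distance per the spec), while the depth coordinate
Y is perturbed independently like size and color, because stimuli are
displayed along the X–Z axes and Y only sets drawing order.

Post-processing keeps every generated sphere legal: sizes are floored at
0.01, saturation/value clamped to [0, 1], hue wrapped modulo 1 (red is both
0 and 1).  Clamping happens after sampling — rejection sampling would
distort the stated distributions — and clamp events are recorded in the
member's lineage string.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import stats

from .model import (
    SIZE_FLOOR,
    Category,
    CategorySpec,
    DeltaRange,
    DevSpec,
    GaussSpec,
    Sphere,
    Stimulus,
    wrap_hue,
)

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]

#: Scalar parameters perturbed independently, in draw order.
SCALAR_PARAMS = ("y", "size", "hue", "sat", "val")


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class BaseRanges:
    """Sampling intervals for random base stimuli.

    Positions default to ``U[-1, 1]`` per axis (a symmetric, rendering-
    friendly box); sizes to ``U[0.05, 0.25]``; saturation and value to
    ``U[0.6, 1.0]`` so base spheres are never colorless, pale or black.
    Hue is always uniform on the full circle ``[0, 1)``.
    """

    x: tuple[float, float] = (-1.0, 1.0)
    y: tuple[float, float] = (-1.0, 1.0)
    z: tuple[float, float] = (-1.0, 1.0)
    size: tuple[float, float] = (0.05, 0.25)
    sat: tuple[float, float] = (0.6, 1.0)
    val: tuple[float, float] = (0.6, 1.0)

    def __post_init__(self) -> None:
        for name in ("x", "y", "z", "size", "sat", "val"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range has lo > hi: ({lo}, {hi})")
        if self.size[0] < SIZE_FLOOR:
            raise ValueError(f"size range must start at or above {SIZE_FLOOR}")
        for name in ("sat", "val"):
            lo, hi = getattr(self, name)
            if lo < 0.0 or hi > 1.0:
                raise ValueError(f"{name} range must lie within [0, 1]")


def make_base(
    n_spheres: int,
    seed: SeedLike,
    ranges: BaseRanges | None = None,
    label: str = "",
) -> Stimulus:
    """Generate a random base stimulus with exactly ``n_spheres`` spheres.

    The sphere count is the only mandatory choice; every other parameter is
    sampled independently and uniformly within ``ranges``.  Deterministic
    given ``seed``.
    """
    if n_spheres < 1:
        raise ValueError(f"n_spheres must be >= 1, got {n_spheres}")
    ranges = ranges or BaseRanges()
    rng = _rng(seed)
    spheres = []
    for _ in range(n_spheres):
        spheres.append(
            Sphere(
                x=rng.uniform(*ranges.x),
                y=rng.uniform(*ranges.y),
                z=rng.uniform(*ranges.z),
                size=rng.uniform(*ranges.size),
                hue=rng.uniform(0.0, 1.0),
                sat=rng.uniform(*ranges.sat),
                val=rng.uniform(*ranges.val),
            )
        )
    return Stimulus(
        spheres=spheres,
        label=label,
        seed=seed if isinstance(seed, int) else None,
        lineage="base",
    )


# ---------------------------------------------------------------------------
# Perturbation primitives
# ---------------------------------------------------------------------------

def _raw_perturb(base_value: float, dev: DevSpec, rng: np.random.Generator) -> float:
    """Unclamped perturbed value: base +/- U[lo,hi] (fair sign) or
    Normal(base, sigma)."""
    if isinstance(dev, DeltaRange):
        m = rng.uniform(dev.lo, dev.hi)
        sign = -1.0 if rng.random() < 0.5 else 1.0
        return base_value + sign * m
    return float(rng.normal(base_value, dev.sigma))


def finalize_param(value: float, param: str) -> tuple[float, bool]:
    """Apply the field's legality rule; returns (value, clamped?).

    size: floored at 0.01.  sat/val: clamped to [0, 1].  hue: wrapped
    modulo 1 (never counts as a clamp — the circle has no edge).  Any other
    field is passed through.
    """
    if param == "size":
        if value < SIZE_FLOOR:
            return SIZE_FLOOR, True
        return value, False
    if param in ("sat", "val"):
        if value < 0.0:
            return 0.0, True
        if value > 1.0:
            return 1.0, True
        return value, False
    if param == "hue":
        return wrap_hue(value), False
    return value, False


def perturb_scalar(
    base_value: float,
    dev: DevSpec,
    rng: np.random.Generator,
    param: str = "y",
    clamp: bool = True,
) -> float:
    """Perturb one scalar parameter of one sphere.

    ``param`` selects the post-processing rule (see :func:`finalize_param`);
    ``clamp=False`` skips it and returns the raw draw (a test hook for
    checking the distributional contract without floor/clamp censoring).
    """
    raw = _raw_perturb(base_value, dev, rng)
    if not clamp:
        return raw
    value, _ = finalize_param(raw, param)
    return value


def shift_position(
    sphere: Sphere, dist_dev: DevSpec, rng: np.random.Generator
) -> tuple[float, float]:
    """Polar shift of a sphere's X–Z position; returns the new ``(x, z)``.

    The angle theta is uniform on ``[0, 2pi)``; the distance is
    ``U[lo, hi]`` in uniform mode or half-normal ``|Normal(0, sigma)|`` in
    Gaussian mode (distances are nonnegative by construction).  The polar
    displacement is converted back to Cartesian offsets and added to the
    sphere's coordinates.  Y is untouched.
    """
    theta = rng.uniform(0.0, 2.0 * math.pi)
    if isinstance(dist_dev, DeltaRange):
        d = rng.uniform(dist_dev.lo, dist_dev.hi)
    else:
        d = abs(float(rng.normal(0.0, dist_dev.sigma)))
    return sphere.x + d * math.cos(theta), sphere.z + d * math.sin(theta)


def derive_member(
    base: Stimulus,
    spec: CategorySpec,
    seed: SeedLike,
    label: str = "",
    clamp: bool = True,
) -> Stimulus:
    """Derive one category member from a base stimulus.

    For each sphere, in a fixed draw order (theta, distance, y, size, hue,
    sat, val), the X–Z position is polar-shifted and every scalar parameter
    perturbed independently per ``spec``.  Sphere count is preserved.
    Deterministic given ``seed``.
    """
    rng = _rng(seed)
    spheres = []
    n_clamped = 0
    for sp in base.spheres:
        x, z = shift_position(sp, spec.position_shift, rng)
        vals = {}
        for param in SCALAR_PARAMS:
            raw = _raw_perturb(getattr(sp, param), spec.dev_for(param), rng)
            if clamp:
                v, was_clamped = finalize_param(raw, param)
                n_clamped += was_clamped
            else:
                v = raw
            vals[param] = v
        spheres.append(Sphere(x=x, y=vals["y"], z=z, size=vals["size"],
                              hue=vals["hue"], sat=vals["sat"], val=vals["val"]))
    lineage = f"derived:{spec.mode}"
    if n_clamped:
        lineage += f";clamped={n_clamped}"
    return Stimulus(
        spheres=spheres,
        label=label,
        seed=seed if isinstance(seed, int) else None,
        lineage=lineage,
    )


def member_seed(master_seed: int, i: int) -> np.random.SeedSequence:
    """Documented seed fan-out: member ``i`` of a category seeded with
    ``master_seed`` uses ``SeedSequence((master_seed, i))``."""
    return np.random.SeedSequence((master_seed, i))


def generate_category(
    base: Stimulus,
    spec: CategorySpec,
    n_members: int,
    seed: int,
    label_prefix: str = "member",
) -> Category:
    """Generate a full category: ``n_members`` independent derivatives of
    ``base``, each seeded via :func:`member_seed` so the whole category is
    reproducible from one master seed."""
    if n_members < 1:
        raise ValueError(f"n_members must be >= 1, got {n_members}")
    members = [
        derive_member(base, spec, member_seed(seed, i), label=f"{label_prefix}-{i}")
        for i in range(n_members)
    ]
    return Category(base=base, members=members, spec=spec)


# ---------------------------------------------------------------------------
# Preview exemplars
# ---------------------------------------------------------------------------

def preview_exemplars(
    base: Stimulus, spec: CategorySpec, tail_mass: float = 0.05
) -> list[Stimulus]:
    """Two illustrative stimuli at the extremes of a category spec.

    Uniform mode: every scalar deviates by exactly ``hi`` (one exemplar
    subtracting, one adding); the position shifts by ``hi`` along -x / +x.
    Gaussian mode: deviations sit at the two-sided ``tail_mass`` tail
    quantiles of ``Normal(base, sigma)`` — with the default 5% total tail
    mass, the 2.5th and 97.5th percentiles.  (Whether the quoted tail mass
    is per tail or total is ambiguous; ``tail_mass`` is exposed so either
    reading is available.)  Clamps still apply, so the preview shows what
    would actually be generated.
    """
    if not (0.0 < tail_mass < 1.0):
        raise ValueError("tail_mass must be in (0, 1)")
    if spec.mode == "uniform":
        def extreme(dev: DevSpec) -> float:
            assert isinstance(dev, DeltaRange)
            return dev.hi
    else:
        q = float(stats.norm.ppf(1.0 - tail_mass / 2.0))

        def extreme(dev: DevSpec) -> float:
            assert isinstance(dev, GaussSpec)
            return q * dev.sigma

    out = []
    for sign, tag, theta in ((-1.0, "low", math.pi), (1.0, "high", 0.0)):
        spheres = []
        for sp in base.spheres:
            d = extreme(spec.position_shift)
            x = sp.x + d * math.cos(theta)
            z = sp.z + d * math.sin(theta)
            vals = {}
            for param in SCALAR_PARAMS:
                raw = getattr(sp, param) + sign * extreme(spec.dev_for(param))
                vals[param], _ = finalize_param(raw, param)
            spheres.append(Sphere(x=x, y=vals["y"], z=z, size=vals["size"],
                                  hue=vals["hue"], sat=vals["sat"], val=vals["val"]))
        out.append(Stimulus(spheres=spheres, label=f"preview-{tag}",
                            lineage=f"preview:{spec.mode}:{tag}"))
    return out
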