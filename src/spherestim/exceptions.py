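"""Category exceptions: stimuli that lie outside a category's parametric extent.

An exception is a stimulus deliberately constructed *outside* the parameter
range spanned by a category's members, so it can be assigned to the category
while violating its statistics.  Two constructions are provided:

* :func:`exceptions_from_limits` — compute the per-parameter upper/lower
  limits actually realized by the category's members, then place each
  exception parameter beyond a limit: ``upper + m`` or ``lower - m`` with
  ``m ~ U[lo, hi]`` and a fair coin choosing the side.  With deviation
  ranges of (0, 0) the exception sits exactly on the category extremes —
  which can still differ profoundly from the base stimulus.
* :func:`exceptions_from_base` — perturb a dedicated *exception base*
  stimulus with uniform min/max ranges, exactly like ordinary uniform-mode
  category generation.  This variant allows a different sphere count from
  the category's.

Hue needs care: min/max on a circle is meaningless, so hue limits are
computed on deviations unwrapped around the category base's hue (smallest
signed circular difference) and the resulting exception hues are re-wrapped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .generate import SeedLike, _rng, derive_member, finalize_param
from .model import (
    Category,
    CategorySpec,
    DeltaRange,
    Sphere,
    Stimulus,
    signed_hue_diff,
    wrap_hue,
)

#: Per-sphere parameters over which limits are computed, in column order.
LIMIT_PARAMS = ("x", "y", "z", "size", "hue", "sat", "val")


@dataclass
class CategoryLimits:
    """Per-sphere, per-parameter (lower, upper) extremes over a category's
    members.

    Arrays have shape ``(n_spheres, 7)`` with columns in :data:`LIMIT_PARAMS`
    order.  The hue column holds *unwrapped* values ``base_hue + d`` where
    ``d`` is the signed circular deviation from the base hue, so hue limits
    may lie outside [0, 1) and must be re-wrapped on use.
    """

    lower: np.ndarray
    upper: np.ndarray
    base_hue: np.ndarray
    pooled: bool = False

    def param_index(self, param: str) -> int:
        return LIMIT_PARAMS.index(param)


def category_limits(cat: Category, pooled: bool = False) -> CategoryLimits:
    """Exact min/max of every parameter of every sphere over the members.

    Limits are computed over the members only (the base is excluded unless
    it happens to be a member).  With ``pooled=True`` the extremes are taken
    across spheres as well, so every sphere shares one limit pair per
    parameter.
    """
    if cat.n_members < 1:
        raise ValueError("category has no members; limits are undefined")
    n = cat.base.n_spheres
    base_hue = np.array([sp.hue for sp in cat.base.spheres])
    vals = np.empty((cat.n_members, n, len(LIMIT_PARAMS)))
    for mi, m in enumerate(cat.members):
        for si, sp in enumerate(m.spheres):
            for pi, param in enumerate(LIMIT_PARAMS):
                v = getattr(sp, param)
                if param == "hue":
                    v = base_hue[si] + signed_hue_diff(v, base_hue[si])
                vals[mi, si, pi] = v
    lower = vals.min(axis=0)
    upper = vals.max(axis=0)
    if pooled:
        lower = np.broadcast_to(lower.min(axis=0), lower.shape).copy()
        upper = np.broadcast_to(upper.max(axis=0), upper.shape).copy()
    return CategoryLimits(lower=lower, upper=upper, base_hue=base_hue, pooled=pooled)


def _as_dev_map(dev) -> dict[str, DeltaRange]:
    if isinstance(dev, DeltaRange):
        return {p: dev for p in LIMIT_PARAMS}
    out = {p: DeltaRange(0.0, 0.0) for p in LIMIT_PARAMS}
    for key, dr in dev.items():
        if key not in LIMIT_PARAMS:
            raise ValueError(f"unknown parameter {key!r}; expected one of {LIMIT_PARAMS}")
        if not isinstance(dr, DeltaRange):
            raise TypeError(f"deviation for {key!r} must be a DeltaRange")
        out[key] = dr
    return out


def exceptions_from_limits(
    cat: Category,
    dev,
    m: int,
    seed: SeedLike,
    limits: CategoryLimits | None = None,
    clamp: bool = True,
) -> list[Stimulus]:
    """Generate ``m`` exception stimuli beyond a category's parameter limits.

    ``dev`` maps parameter names (x, y, z, size, hue, sat, val) to
    :class:`~spherestim.model.DeltaRange` deviation magnitudes (a single
    DeltaRange applies to all parameters; omitted parameters get (0, 0)).
    For every parameter of every sphere, an independent fair coin picks the
    side and a magnitude ``U[lo, hi]`` is added above the upper limit or
    subtracted below the lower one.  Exceptions keep the category's sphere
    count.  Size floor and sat/val clamps still apply; hue is re-wrapped
    onto the circle.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    dev_map = _as_dev_map(dev)
    lim = limits if limits is not None else category_limits(cat)
    rng = _rng(seed)
    n = cat.base.n_spheres
    out = []
    for ei in range(m):
        spheres = []
        for si in range(n):
            vals = {}
            for pi, param in enumerate(LIMIT_PARAMS):
                dr = dev_map[param]
                mag = rng.uniform(dr.lo, dr.hi)
                above = rng.random() < 0.5
                v = lim.upper[si, pi] + mag if above else lim.lower[si, pi] - mag
                if param == "hue":
                    v = wrap_hue(v)
                elif clamp:
                    v, _ = finalize_param(v, param)
                vals[param] = v
            spheres.append(Sphere(**vals))
        out.append(Stimulus(spheres=spheres, label=f"exception-{ei}",
                            lineage="exception:from-limits"))
    return out


def exceptions_from_base(
    exception_base: Stimulus,
    ranges,
    m: int,
    seed: SeedLike,
) -> list[Stimulus]:
    """Generate ``m`` exceptions as uniform-mode derivatives of a dedicated
    exception base stimulus.

    ``ranges`` maps {position, y, size, hue, sat, val} to
    :class:`~spherestim.model.DeltaRange` (a single DeltaRange applies to
    all; omitted keys get (0, 0)); ``position`` is the polar shift distance
    range, exactly as in category generation.  The exceptions inherit the
    exception base's sphere count, which may differ from the category's.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    keys = ("position", "y", "size", "hue", "sat", "val")
    if isinstance(ranges, DeltaRange):
        rmap = {k: ranges for k in keys}
    else:
        rmap = {k: DeltaRange(0.0, 0.0) for k in keys}
        for key, dr in ranges.items():
            if key not in keys:
                raise ValueError(f"unknown parameter {key!r}; expected one of {keys}")
            rmap[key] = dr
    spec = CategorySpec(
        "uniform",
        position_shift=rmap["position"],
        y_dev=rmap["y"],
        size_dev=rmap["size"],
        hue_dev=rmap["hue"],
        sat_dev=rmap["sat"],
        val_dev=rmap["val"],
    )
    seq = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    children = seq.spawn(m)
    out = []
    for ei in range(m):
        s = derive_member(exception_base, spec, children[ei], label=f"exception-{ei}")
        s.lineage = "exception:from-base"
        out.append(s)
    return out
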