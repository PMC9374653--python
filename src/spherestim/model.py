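"""Core data types, validation and JSON (de)serialization for sphere-cloud stimuli.

A stimulus is an ordered list of colored spheres in 3D scene space.  Each
sphere carries a position (x, y, z), a radius (``size``) and an HSV color.
The hue lives on the chromatic circle: red is both 0 and 1, so hue is stored
in canonical ``[0, 1)`` form and all hue arithmetic is modulo 1.  Scene
coordinates are dimensionless; base stimuli are sampled inside ``[-1, 1]``
per axis, but derived stimuli may leave that box — only the size floor and
the saturation/value bounds are ever enforced by clamping.

Categories are defined relative to a *base stimulus* (the category
prototype): a :class:`CategorySpec` says, per parameter, how far members may
deviate from the base, either as a uniform min–max magnitude range
(:class:`DeltaRange`, the ``delta`` of the uniform method) or as a Gaussian
standard deviation (:class:`GaussSpec`, the ``sigma`` of the Gaussian
method).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

FORMAT_VERSION = "1"

#: Hard lower bound on sphere radius; smaller spheres are barely visible and
#: are clamped up to this value wherever sizes are produced.
SIZE_FLOOR = 0.01

#: Canonical per-sphere scalar parameter names, in serialization order.
SPHERE_FIELDS = ("x", "y", "z", "size", "hue", "sat", "val")


class StimulusFormatError(ValueError):
    """A stimulus/category file is malformed (missing or ill-typed field)."""


class StimulusVersionError(StimulusFormatError):
    """A stimulus/category file declares an unknown format version."""


def wrap_hue(h: float) -> float:
    """Wrap a hue onto the chromatic circle, returning a value in ``[0, 1)``.

    Red is defined as both 0 and 1, so the wrap has period 1 and 1.0 maps
    to 0.0.  Values already in ``[0, 1)`` are returned unchanged (bit-exact).
    """
    if 0.0 <= h < 1.0:
        return h
    r = h % 1.0
    # x % 1.0 can round up to exactly 1.0 for tiny negative x.
    if r == 1.0:
        r = 0.0
    return r


def hue_distance(h1: float, h2: float) -> float:
    """Shortest distance between two hues on the unit circle, in ``[0, 0.5]``."""
    d = abs(wrap_hue(h1) - wrap_hue(h2))
    return min(d, 1.0 - d)


def signed_hue_diff(h: float, ref: float) -> float:
    """Signed circular difference ``h - ref`` folded into ``[-0.5, 0.5)``."""
    d = (h - ref + 0.5) % 1.0 - 0.5
    return d


@dataclass
class Sphere:
    """One colored ball: 3D position, radius and HSV color.

    ``y`` is the depth axis in the default view (it only affects drawing
    order).  A hue of exactly 1.0 is normalized to 0.0 on construction; no
    other normalization happens here so that :func:`validate_stimulus` can
    report out-of-domain values instead of silently fixing them.
    """

    x: float
    y: float
    z: float
    size: float
    hue: float
    sat: float
    val: float

    def __post_init__(self) -> None:
        for name in SPHERE_FIELDS:
            setattr(self, name, float(getattr(self, name)))
        if self.hue == 1.0:
            self.hue = 0.0

    def copy(self) -> "Sphere":
        return Sphere(self.x, self.y, self.z, self.size, self.hue, self.sat, self.val)


@dataclass
class Stimulus:
    """An ordered list of spheres plus provenance metadata.

    Sphere order is meaningful: morphing and deviation reports map spheres
    by index.  ``lineage`` is free-text provenance such as ``"base"``,
    ``"derived:uniform"`` or ``"morph step 3/7"``.
    """

    spheres: list[Sphere]
    label: str = ""
    seed: int | None = None
    lineage: str = "base"

    @property
    def n_spheres(self) -> int:
        return len(self.spheres)

    def copy(self) -> "Stimulus":
        return Stimulus([s.copy() for s in self.spheres], self.label, self.seed, self.lineage)


@dataclass(frozen=True)
class DeltaRange:
    """Uniform-mode deviation magnitude range ``[lo, hi]`` (the delta).

    A drawn deviation has magnitude uniform on ``[lo, hi]`` and a fair
    random sign, so members sit in symmetric bands on both sides of the
    base value.
    """

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo <= self.hi):
            raise ValueError(f"DeltaRange requires 0 <= lo <= hi, got ({self.lo}, {self.hi})")


@dataclass(frozen=True)
class GaussSpec:
    """Gaussian-mode deviation spec: draws come from Normal(base, sigma)."""

    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0.0:
            raise ValueError(f"GaussSpec requires sigma >= 0, got {self.sigma}")


DevSpec = Union[DeltaRange, GaussSpec]


@dataclass
class CategorySpec:
    """Per-parameter perturbation specification relative to a category base.

    ``position_shift`` is the polar movement *distance* applied in the X–Z
    plane (the shift angle is always uniform on ``[0, 2pi)`` and is not part
    of the spec); ``y_dev`` perturbs the depth coordinate independently, the
    same way as size and color.  All sub-specs must match ``mode``.
    """

    mode: str
    position_shift: DevSpec
    y_dev: DevSpec
    size_dev: DevSpec
    hue_dev: DevSpec
    sat_dev: DevSpec
    val_dev: DevSpec

    def __post_init__(self) -> None:
        if self.mode not in ("uniform", "gauss"):
            raise ValueError(f"mode must be 'uniform' or 'gauss', got {self.mode!r}")
        want = DeltaRange if self.mode == "uniform" else GaussSpec
        for name in ("position_shift", "y_dev", "size_dev", "hue_dev", "sat_dev", "val_dev"):
            if not isinstance(getattr(self, name), want):
                raise ValueError(
                    f"{name} must be a {want.__name__} in {self.mode!r} mode"
                )

    @classmethod
    def uniform(
        cls,
        position_shift: tuple[float, float] = (0.0, 0.0),
        y_dev: tuple[float, float] = (0.0, 0.0),
        size_dev: tuple[float, float] = (0.0, 0.0),
        hue_dev: tuple[float, float] = (0.0, 0.0),
        sat_dev: tuple[float, float] = (0.0, 0.0),
        val_dev: tuple[float, float] = (0.0, 0.0),
    ) -> "CategorySpec":
        return cls(
            "uniform",
            DeltaRange(*position_shift),
            DeltaRange(*y_dev),
            DeltaRange(*size_dev),
            DeltaRange(*hue_dev),
            DeltaRange(*sat_dev),
            DeltaRange(*val_dev),
        )

    @classmethod
    def gauss(
        cls,
        position_shift: float = 0.0,
        y_dev: float = 0.0,
        size_dev: float = 0.0,
        hue_dev: float = 0.0,
        sat_dev: float = 0.0,
        val_dev: float = 0.0,
    ) -> "CategorySpec":
        return cls(
            "gauss",
            GaussSpec(position_shift),
            GaussSpec(y_dev),
            GaussSpec(size_dev),
            GaussSpec(hue_dev),
            GaussSpec(sat_dev),
            GaussSpec(val_dev),
        )

    def dev_for(self, param: str) -> DevSpec:
        """Deviation spec for a scalar parameter name (y/size/hue/sat/val)."""
        return getattr(self, f"{param}_dev")


@dataclass
class Category:
    """A base stimulus plus members derived from it under one spec.

    All members share the base's sphere count — the invariant that makes
    per-sphere-index comparisons (limits, deviations, morphs) meaningful.
    """

    base: Stimulus
    members: list[Stimulus]
    spec: CategorySpec

    def __post_init__(self) -> None:
        n = self.base.n_spheres
        for i, m in enumerate(self.members):
            if m.n_spheres != n:
                raise ValueError(
                    f"member {i} has {m.n_spheres} spheres, base has {n}; "
                    "the sphere count must be constant within a category"
                )

    @property
    def n_members(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    """One invariant violation: which sphere (None = stimulus-level), which
    field, and a human-readable message."""

    sphere: int | None
    field: str
    message: str


def validate_stimulus(s: Stimulus) -> list[Violation]:
    """Check every stimulus invariant and report all violations.

    Returns an empty list iff the stimulus is valid.  Checks: at least one
    sphere; per sphere, finite coordinates, ``size >= 0.01``, ``hue`` in
    ``[0, 1)`` and ``sat``/``val`` in ``[0, 1]``.
    """
    out: list[Violation] = []
    if s.n_spheres < 1:
        out.append(Violation(None, "spheres", "stimulus must contain at least one sphere"))
    for i, sp in enumerate(s.spheres):
        for name in ("x", "y", "z"):
            if not math.isfinite(getattr(sp, name)):
                out.append(Violation(i, name, f"{name} is not finite"))
        if not (sp.size >= SIZE_FLOOR):
            out.append(Violation(i, "size", f"size {sp.size} below floor {SIZE_FLOOR}"))
        if not (0.0 <= sp.hue < 1.0):
            out.append(Violation(i, "hue", f"hue {sp.hue} outside [0, 1)"))
        if not (0.0 <= sp.sat <= 1.0):
            out.append(Violation(i, "sat", f"sat {sp.sat} outside [0, 1]"))
        if not (0.0 <= sp.val <= 1.0):
            out.append(Violation(i, "val", f"val {sp.val} outside [0, 1]"))
    return out


# ---------------------------------------------------------------------------
# JSON serialization
#
# Python's json writes floats with repr (shortest round-trip decimal), so
# save -> load reproduces every numeric field bit-identically.
# ---------------------------------------------------------------------------

def _sphere_to_dict(sp: Sphere) -> dict:
    return {name: getattr(sp, name) for name in SPHERE_FIELDS}


def _sphere_from_dict(d: dict, path: str) -> Sphere:
    if not isinstance(d, dict):
        raise StimulusFormatError(f"{path}: expected an object, got {type(d).__name__}")
    vals = {}
    for name in SPHERE_FIELDS:
        if name not in d:
            raise StimulusFormatError(f"{path}.{name}: missing required field")
        v = d[name]
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            raise StimulusFormatError(f"{path}.{name}: expected a number, got {v!r}")
        vals[name] = float(v)
    return Sphere(**vals)


def stimulus_to_dict(s: Stimulus) -> dict:
    return {
        "format_version": FORMAT_VERSION,
        "label": s.label,
        "seed": s.seed,
        "lineage": s.lineage,
        "spheres": [_sphere_to_dict(sp) for sp in s.spheres],
    }


def stimulus_from_dict(d: dict, path: str = "$", check_version: bool = True) -> Stimulus:
    if not isinstance(d, dict):
        raise StimulusFormatError(f"{path}: expected an object")
    if check_version:
        ver = d.get("format_version")
        if ver != FORMAT_VERSION:
            raise StimulusVersionError(
                f"{path}.format_version: unknown version {ver!r} (expected {FORMAT_VERSION!r})"
            )
    if "spheres" not in d or not isinstance(d["spheres"], list):
        raise StimulusFormatError(f"{path}.spheres: missing or not an array")
    spheres = [
        _sphere_from_dict(sd, f"{path}.spheres[{i}]") for i, sd in enumerate(d["spheres"])
    ]
    seed = d.get("seed")
    if seed is not None and not isinstance(seed, int):
        raise StimulusFormatError(f"{path}.seed: expected an integer or null")
    return Stimulus(
        spheres=spheres,
        label=str(d.get("label", "")),
        seed=seed,
        lineage=str(d.get("lineage", "")),
    )


def _dev_to_dict(dev: DevSpec) -> dict:
    if isinstance(dev, DeltaRange):
        return {"lo": dev.lo, "hi": dev.hi}
    return {"sigma": dev.sigma}


def _dev_from_dict(d: dict, mode: str, path: str) -> DevSpec:
    try:
        if mode == "uniform":
            return DeltaRange(float(d["lo"]), float(d["hi"]))
        return GaussSpec(float(d["sigma"]))
    except (KeyError, TypeError) as e:
        raise StimulusFormatError(f"{path}: malformed deviation spec ({e})") from e


def spec_to_dict(spec: CategorySpec) -> dict:
    return {
        "mode": spec.mode,
        "position_shift": _dev_to_dict(spec.position_shift),
        "y_dev": _dev_to_dict(spec.y_dev),
        "size_dev": _dev_to_dict(spec.size_dev),
        "hue_dev": _dev_to_dict(spec.hue_dev),
        "sat_dev": _dev_to_dict(spec.sat_dev),
        "val_dev": _dev_to_dict(spec.val_dev),
    }


def spec_from_dict(d: dict, path: str = "$.spec") -> CategorySpec:
    mode = d.get("mode")
    if mode not in ("uniform", "gauss"):
        raise StimulusFormatError(f"{path}.mode: expected 'uniform' or 'gauss', got {mode!r}")
    kw = {}
    for name in ("position_shift", "y_dev", "size_dev", "hue_dev", "sat_dev", "val_dev"):
        if name not in d:
            raise StimulusFormatError(f"{path}.{name}: missing required field")
        kw[name] = _dev_from_dict(d[name], mode, f"{path}.{name}")
    return CategorySpec(mode=mode, **kw)


def save_stimulus(s: Stimulus, path: str | Path) -> None:
    """Write a stimulus to JSON; :func:`load_stimulus` reproduces it exactly."""
    Path(path).write_text(json.dumps(stimulus_to_dict(s), indent=1) + "\n")


def load_stimulus(path: str | Path) -> Stimulus:
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise StimulusFormatError(f"{path}: not valid JSON ({e})") from e
    return stimulus_from_dict(d)


def save_category(cat: Category, path: str | Path) -> None:
    d = {
        "format_version": FORMAT_VERSION,
        "kind": "category",
        "base": stimulus_to_dict(cat.base),
        "members": [stimulus_to_dict(m) for m in cat.members],
        "spec": spec_to_dict(cat.spec),
    }
    Path(path).write_text(json.dumps(d, indent=1) + "\n")


def load_category(path: str | Path) -> Category:
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise StimulusFormatError(f"{path}: not valid JSON ({e})") from e
    ver = d.get("format_version")
    if ver != FORMAT_VERSION:
        raise StimulusVersionError(
            f"$.format_version: unknown version {ver!r} (expected {FORMAT_VERSION!r})"
        )
    for key in ("base", "members", "spec"):
        if key not in d:
            raise StimulusFormatError(f"$.{key}: missing required field")
    base = stimulus_from_dict(d["base"], "$.base", check_version=False)
    members = [
        stimulus_from_dict(md, f"$.members[{i}]", check_version=False)
        for i, md in enumerate(d["members"])
    ]
    return Category(base=base, members=members, spec=spec_from_dict(d["spec"]))
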