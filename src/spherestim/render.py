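"""Deterministic rasterization of stimuli as 2D images.

The scene is rotated by the view's azimuth/elevation, orthographically
projected and drawn back-to-front as shaded discs (painter's algorithm).
The default view looks down the Y axis: X maps to the horizontal image
axis, Z to the vertical, and Y only determines the drawing order — nearer
spheres (larger rotated Y by default) occlude farther ones.  Orthographic
projection is deliberate: in the default display depth must not change a
sphere's apparent position or size.

Rendering is bit-deterministic: identical stimulus + view always produce
byte-identical pixel arrays (and PNG files).  The rasterizer is plain numpy
so no backend state can leak into the output; a fixed radial highlight
(offset toward the upper-left of each disc) gives the flat discs a 3D look.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib.colors import hsv_to_rgb
from PIL import Image

from .model import Stimulus

#: Scene half-extent mapped to the image: coordinates in [-EXTENT, EXTENT]
#: fit inside the smaller image dimension.
EXTENT = 1.6

#: Highlight constants (fractions of the disc radius / shading weights);
#: fixed so renders are reproducible.
HIGHLIGHT_OFFSET = 0.35
HIGHLIGHT_FALLOFF = 1.6
SHADE_BASE = 0.62
SHADE_RAMP = 0.38
SPECULAR = 0.55

SUPPORTED_FORMATS = ("png", "jpg", "jpeg")


class UnsupportedFormatError(ValueError):
    """Requested image format is not one of the supported raster formats."""


@dataclass(frozen=True)
class ViewSpec:
    """Viewing parameters: rotation angles (degrees), canvas size, options.

    Azimuth rotates the scene about the vertical (Z) axis, elevation about
    the horizontal (X) axis; both default to 0, the flat X–Z view.
    ``invert_depth`` flips the depth convention (smaller rotated Y drawn
    last instead of larger).
    """

    azimuth: float = 0.0
    elevation: float = 0.0
    show_axes: bool = False
    width: int = 512
    height: int = 512
    background: tuple[int, int, int] = (255, 255, 255)
    invert_depth: bool = False

    def __post_init__(self) -> None:
        if self.width < 16 or self.height < 16:
            raise ValueError("canvas must be at least 16x16 pixels")


def _rotate(xyz: np.ndarray, azimuth_deg: float, elevation_deg: float) -> np.ndarray:
    # reduce mod 360 first so a full turn is bit-identical to no turn
    a = math.radians(azimuth_deg % 360.0)
    e = math.radians(elevation_deg % 360.0)
    ca, sa = math.cos(a), math.sin(a)
    ce, se = math.cos(e), math.sin(e)
    rz = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    rx = np.array([[1.0, 0.0, 0.0], [0.0, ce, -se], [0.0, se, ce]])
    return xyz @ rz.T @ rx.T


def render(s: Stimulus, view: ViewSpec | None = None) -> np.ndarray:
    """Rasterize a stimulus; returns an ``(H, W, 3)`` uint8 RGB array.

    Every sphere produces exactly one disc draw call; occlusion can hide
    pixels but never suppresses a draw.  Output is a pure function of
    (stimulus, view).
    """
    view = view or ViewSpec()
    w, h = view.width, view.height
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.asarray(view.background, dtype=np.float64) / 255.0

    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    scale = min(w, h) / (2.0 * EXTENT)

    if view.show_axes:
        axis_col = 0.78
        img[int(round(cy)), :, :] = axis_col
        img[:, int(round(cx)), :] = axis_col

    xyz = np.array([[sp.x, sp.y, sp.z] for sp in s.spheres], dtype=np.float64)
    rot = _rotate(xyz, view.azimuth, view.elevation)
    depth = rot[:, 1]
    if view.invert_depth:
        depth = -depth
    # painter's algorithm: far (small depth) first; stable sort keeps
    # sphere order deterministic on ties
    order = np.argsort(depth, kind="stable")

    yy, xx = np.mgrid[0:h, 0:w]
    for i in order:
        sp = s.spheres[i]
        u = cx + rot[i, 0] * scale
        v = cy - rot[i, 2] * scale
        r = max(sp.size * scale, 0.5)
        d2 = (xx - u) ** 2 + (yy - v) ** 2
        mask = d2 <= r * r
        if not mask.any():
            continue
        rgb = hsv_to_rgb(np.array([sp.hue, sp.sat, sp.val]))
        # radial highlight toward the upper-left of the disc
        hx, hy = u - HIGHLIGHT_OFFSET * r, v - HIGHLIGHT_OFFSET * r
        dh = np.sqrt((xx[mask] - hx) ** 2 + (yy[mask] - hy) ** 2)
        t = np.clip(dh / (HIGHLIGHT_FALLOFF * r), 0.0, 1.0)
        shade = SHADE_BASE + SHADE_RAMP * (1.0 - t)
        spec = SPECULAR * (1.0 - t) ** 3
        pix = rgb[None, :] * shade[:, None] * (1.0 - spec[:, None]) + spec[:, None]
        img[mask] = pix
    return (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def save_image(image: np.ndarray, path: str | Path, format: str | None = None) -> None:
    """Write a rendered raster to disk as PNG (lossless) or JPEG.

    ``format`` defaults to the file extension.  Unsupported formats raise
    :class:`UnsupportedFormatError`; extend :data:`SUPPORTED_FORMATS` to
    add more.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in SUPPORTED_FORMATS:
        raise UnsupportedFormatError(
            f"unsupported image format {fmt!r}; supported: {', '.join(SUPPORTED_FORMATS)}"
        )
    pil = Image.fromarray(image)
    pil.save(path, format="PNG" if fmt == "png" else "JPEG")


def load_image(path: str | Path) -> np.ndarray:
    """Read an image back as an ``(H, W, 3)`` uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))
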