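"""Parametric deviation of stimuli from a reference stimulus.

After generating a category, the Euclidean distance of each sphere from its
counterpart in the category base, and the absolute deviations in size and
color, quantify a basic mathematical (within- or between-category)
similarity.  Hue deviations use the circular distance on the chromatic
circle (at most 0.5); saturation and value are plain absolute differences.

No single scalar "similarity" is computed by default: numeric parameter
deviations need not track perceptual similarity, so the table keeps the
parameters separate for downstream modeling (e.g., a GLM on performance
data).  :func:`deviation_score` offers an explicit, documented composite
for code that needs an ordering (training schedulers, simulated observers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Category, Stimulus, hue_distance

#: Deviation components, in report column order.
COMPONENTS = ("xz_distance", "xyz_distance", "size_abs_dev",
              "hue_circ_dev", "sat_abs_dev", "val_abs_dev")


@dataclass
class DeviationReport:
    """Per-sphere deviations of a stimulus from a reference, plus aggregates.

    Each array has one entry per sphere (index correspondence).  The default
    2D display projects along the X–Z axes, so both the in-plane
    ``xz_distance`` and the full 3D ``xyz_distance`` are reported.
    """

    xz_distance: np.ndarray
    xyz_distance: np.ndarray
    size_abs_dev: np.ndarray
    hue_circ_dev: np.ndarray
    sat_abs_dev: np.ndarray
    val_abs_dev: np.ndarray

    def aggregates(self) -> dict[str, float]:
        """Mean and max of every component over spheres."""
        out = {}
        for name in COMPONENTS:
            arr = getattr(self, name)
            out[f"mean_{name}"] = float(arr.mean())
            out[f"max_{name}"] = float(arr.max())
        return out

    def to_frame(self) -> pd.DataFrame:
        """Per-sphere deviations as a DataFrame (one row per sphere)."""
        return pd.DataFrame({name: getattr(self, name) for name in COMPONENTS})


def stimulus_deviation(s: Stimulus, ref: Stimulus) -> DeviationReport:
    """Per-sphere parametric deviation of ``s`` from ``ref``.

    Requires equal sphere counts (spheres correspond by index).  Symmetric
    in its arguments and zero iff the stimuli share all parameters.
    """
    if s.n_spheres != ref.n_spheres:
        raise ValueError(
            f"stimuli must have equal sphere counts (got {s.n_spheres} and {ref.n_spheres})"
        )
    a = np.array([[sp.x, sp.y, sp.z, sp.size, sp.hue, sp.sat, sp.val] for sp in s.spheres])
    b = np.array([[sp.x, sp.y, sp.z, sp.size, sp.hue, sp.sat, sp.val] for sp in ref.spheres])
    dx, dy, dz = a[:, 0] - b[:, 0], a[:, 1] - b[:, 1], a[:, 2] - b[:, 2]
    hue = np.array([hue_distance(ha, hb) for ha, hb in zip(a[:, 4], b[:, 4])])
    return DeviationReport(
        xz_distance=np.hypot(dx, dz),
        xyz_distance=np.sqrt(dx * dx + dy * dy + dz * dz),
        size_abs_dev=np.abs(a[:, 3] - b[:, 3]),
        hue_circ_dev=hue,
        sat_abs_dev=np.abs(a[:, 5] - b[:, 5]),
        val_abs_dev=np.abs(a[:, 6] - b[:, 6]),
    )


def category_deviation_table(cat: Category) -> pd.DataFrame:
    """Aggregate deviations of every member from the category base.

    One row per member, columns ``mean_*``/``max_*`` per component, indexed
    by member label.  Export with ``df.to_csv(path)``.
    """
    rows = []
    for m in cat.members:
        rows.append(stimulus_deviation(m, cat.base).aggregates())
    df = pd.DataFrame(rows)
    df.insert(0, "member", [m.label for m in cat.members])
    return df


def deviation_score(s: Stimulus, ref: Stimulus) -> float:
    """Scalar composite deviation: sum of the mean per-sphere components.

    Equal-weight sum of mean xyz distance, size, circular hue, saturation
    and value deviations.  The components have different units, so this is
    an ordering device, not a perceptual metric.
    """
    r = stimulus_deviation(s, ref)
    return float(
        r.xyz_distance.mean()
        + r.size_abs_dev.mean()
        + r.hue_circ_dev.mean()
        + r.sat_abs_dev.mean()
        + r.val_abs_dev.mean()
    )
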