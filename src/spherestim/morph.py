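"""Morph continua between two parent stimuli with equal sphere counts.

A continuum interpolates every stimulus parameter linearly from parent 1 to
parent 2 in ``k + 2`` equally spaced steps (the parents are the endpoints).
Equal physical spacing between adjacent steps is the property categorical-
perception experiments rely on: any sharp behavioral boundary along the
continuum then reflects perception, not the stimuli.

Spheres are paired by index — sphere ``i`` of parent 1 morphs into sphere
``i`` of parent 2 — which is why both parents must have the same sphere
count.  Hue is interpolated along the shortest arc of the chromatic circle
(exact antipodes break ties toward increasing hue); sizes are floored at
0.01 as everywhere else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .generate import finalize_param
from .model import Sphere, Stimulus, wrap_hue


@dataclass
class Continuum:
    """An ordered morph series from ``parents[0]`` to ``parents[1]``.

    ``steps`` has length ``k + 2``: the first and last entries are exact
    copies of the parents, with ``k`` interpolated stimuli in between.
    """

    parents: tuple[Stimulus, Stimulus]
    steps: list[Stimulus]
    k: int

    @property
    def n_steps(self) -> int:
        return len(self.steps)


def hue_arc_delta(h1: float, h2: float) -> float:
    """Signed hue increment taking ``h1`` to ``h2`` along the shortest arc.

    Folded into ``(-0.5, 0.5]``: exact antipodes (circular distance 0.5)
    break the tie toward increasing hue (+0.5).
    """
    d = (wrap_hue(h2) - wrap_hue(h1) + 0.5) % 1.0 - 0.5
    if d == -0.5:
        d = 0.5
    return d


def _lerp(a: float, b: float, t: float) -> float:
    return a + t * (b - a)


def morph_pair(parent1: Stimulus, parent2: Stimulus, k: int,
               pair_by_position: bool = False) -> Continuum:
    """Morph ``parent1`` into ``parent2`` through ``k`` in-between stimuli.

    Step ``j`` (j = 1..k) sets every scalar parameter to
    ``p1 + j/(k+1) * (p2 - p1)``; hue follows the shortest circular arc
    instead of the chord.  Endpoints are the parents themselves.

    ``pair_by_position`` is an extension: instead of pairing spheres by
    index (the default, matching how the stimuli are stored), greedily pair
    each sphere of parent 1 with the nearest unmatched sphere of parent 2
    by 3D position.
    """
    if parent1.n_spheres != parent2.n_spheres:
        raise ValueError(
            f"parents must consist of the same number of spheres "
            f"(got {parent1.n_spheres} and {parent2.n_spheres})"
        )
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")

    p2_order = list(range(parent2.n_spheres))
    if pair_by_position:
        p2_order = _greedy_position_pairing(parent1, parent2)

    steps: list[Stimulus] = [parent1.copy()]
    steps[0].lineage = f"morph step 0/{k + 1}"
    for j in range(1, k + 1):
        t = j / (k + 1)
        spheres = []
        for i, s1 in enumerate(parent1.spheres):
            s2 = parent2.spheres[p2_order[i]]
            size, _ = finalize_param(_lerp(s1.size, s2.size, t), "size")
            hue = wrap_hue(s1.hue + t * hue_arc_delta(s1.hue, s2.hue))
            spheres.append(
                Sphere(
                    x=_lerp(s1.x, s2.x, t),
                    y=_lerp(s1.y, s2.y, t),
                    z=_lerp(s1.z, s2.z, t),
                    size=size,
                    hue=hue,
                    sat=_lerp(s1.sat, s2.sat, t),
                    val=_lerp(s1.val, s2.val, t),
                )
            )
        steps.append(
            Stimulus(spheres=spheres, label=f"morph-{j}",
                     lineage=f"morph step {j}/{k + 1}")
        )
    last = parent2.copy()
    if pair_by_position:
        # keep index correspondence along the continuum
        last = Stimulus([parent2.spheres[i].copy() for i in p2_order],
                        parent2.label, parent2.seed, parent2.lineage)
    last.lineage = f"morph step {k + 1}/{k + 1}"
    steps.append(last)
    return Continuum(parents=(parent1, parent2), steps=steps, k=k)


def _greedy_position_pairing(parent1: Stimulus, parent2: Stimulus) -> list[int]:
    """For each sphere of parent1 (in order), the index of the nearest
    still-unmatched sphere of parent2."""
    p1 = np.array([[s.x, s.y, s.z] for s in parent1.spheres])
    p2 = np.array([[s.x, s.y, s.z] for s in parent2.spheres])
    free = list(range(len(p2)))
    order = []
    for i in range(len(p1)):
        dists = np.linalg.norm(p2[free] - p1[i], axis=1)
        j = free.pop(int(np.argmin(dists)))
        order.append(j)
    return order
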