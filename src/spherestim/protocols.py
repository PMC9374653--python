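"""Trial schedulers for the three categorization-training regimes.

* **Prototype-based** (:class:`PrototypeScheduler`): training starts with
  only the two category prototypes (the bases) — a delayed match-to-sample
  task — and, once rolling accuracy reaches a behavioral criterion
  (default 80% correct over a 20-trial window), the per-category stimulus
  set doubles, turning the task into delayed match-to-category.  Added
  stimuli come from the pool in order of increasing parametric deviation
  from the prototype, so later blocks are progressively less prototypical.
* **Exemplar-based** (:class:`ExemplarScheduler`): every trial draws
  uniformly from the entire pool from the first trial on; there are no
  blocks and the category base stimuli are excluded from the pool.
* **Continuum** (:class:`ContinuumScheduler`): trials draw uniformly from
  the steps of a morph continuum; the true category is the side of a
  movable boundary, and moving the boundary relabels trials without
  changing the stimuli.

A :class:`SimulatedObserver` (prototype- or exemplar-strategy classifier
with softmax response noise) plus :func:`run_session` make whole sessions
testable end-to-end, including the qualitative prediction that the
prototype protocol's learning curve starts steeper than the exemplar
protocol's.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .model import Stimulus
from .morph import Continuum
from .similarity import deviation_score

logger = logging.getLogger(__name__)


@dataclass
class SessionConfig:
    """Configuration shared by the schedulers.

    ``pools`` maps category name -> member stimuli; ``prototypes`` maps
    category name -> base stimulus (required by the prototype protocol).
    ``criterion`` is the rolling-accuracy fraction that triggers set-size
    growth, evaluated over the last ``window`` trials since the previous
    advancement; ``growth_factor`` multiplies the per-category set size on
    each advancement.
    """

    pools: dict[str, list[Stimulus]] = field(default_factory=dict)
    prototypes: dict[str, Stimulus] = field(default_factory=dict)
    criterion: float = 0.80
    window: int = 20
    growth_factor: int = 2
    max_set_size: int | None = None
    seed: int = 0
    order_by_deviation: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.criterion <= 1.0):
            raise ValueError("criterion must be in (0, 1]")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.growth_factor < 2:
            raise ValueError("growth_factor must be >= 2")


@dataclass
class TrialRecord:
    trial: int
    stimulus: str
    true_category: str
    response: str | None
    correct: bool | None
    set_sizes: dict[str, int]


class _SchedulerBase:
    """Common next_trial/record bookkeeping."""

    def __init__(self, config: SessionConfig) -> None:
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.records: list[TrialRecord] = []
        self._pending: tuple[Stimulus, str] | None = None

    def next_trial(self) -> tuple[Stimulus, str]:
        if self._pending is not None:
            raise RuntimeError("previous trial has not been recorded yet")
        self._pending = self._draw()
        return self._pending

    def record(self, response: str) -> TrialRecord:
        if self._pending is None:
            raise RuntimeError("no pending trial; call next_trial() first")
        stim, true_cat = self._pending
        self._pending = None
        rec = TrialRecord(
            trial=len(self.records),
            stimulus=stim.label,
            true_category=true_cat,
            response=response,
            correct=(response == true_cat),
            set_sizes=self.set_sizes(),
        )
        self.records.append(rec)
        self._after_record(rec)
        return rec

    def set_sizes(self) -> dict[str, int]:
        return {}

    def _draw(self) -> tuple[Stimulus, str]:
        raise NotImplementedError

    def _after_record(self, rec: TrialRecord) -> None:
        pass


class PrototypeScheduler(_SchedulerBase):
    """Performance-dependent set-size growth, starting from prototypes only.

    The active set of category ``c`` consists of the prototype plus the
    ``size - 1`` pool members closest to it in parametric deviation (or in
    pool order when ``order_by_deviation`` is off).  Rolling accuracy is
    computed as ``n_correct / window`` over the last ``window`` responses
    since the previous advancement; when it is at or above ``criterion``
    the set size multiplies by ``growth_factor`` and the rolling window is
    reset (a new training block begins).  Set size never decreases and is
    capped at ``1 + len(pool)`` (and ``max_set_size`` if given).
    """

    def __init__(self, config: SessionConfig) -> None:
        super().__init__(config)
        if not config.pools or not config.prototypes:
            raise ValueError("prototype protocol needs nonempty pools and prototypes")
        if set(config.pools) != set(config.prototypes):
            raise ValueError("pools and prototypes must cover the same categories")
        for cat, pool in config.pools.items():
            if not pool:
                raise ValueError(f"pool for category {cat!r} is empty")
        self.categories = sorted(config.pools)
        self.ordered_pools: dict[str, list[Stimulus]] = {}
        for cat in self.categories:
            pool = list(config.pools[cat])
            if config.order_by_deviation:
                proto = config.prototypes[cat]
                pool.sort(key=lambda s: deviation_score(s, proto))
            self.ordered_pools[cat] = pool
        self.size = 1
        self._window: deque[bool] = deque(maxlen=config.window)

    def set_sizes(self) -> dict[str, int]:
        return {cat: self._effective_size(cat) for cat in self.categories}

    def _effective_size(self, cat: str) -> int:
        cap = 1 + len(self.ordered_pools[cat])
        if self.config.max_set_size is not None:
            cap = min(cap, self.config.max_set_size)
        return min(self.size, cap)

    def active_set(self, cat: str) -> list[Stimulus]:
        k = self._effective_size(cat)
        return [self.config.prototypes[cat]] + self.ordered_pools[cat][: k - 1]

    def _draw(self) -> tuple[Stimulus, str]:
        cat = self.categories[self.rng.integers(len(self.categories))]
        active = self.active_set(cat)
        stim = active[self.rng.integers(len(active))]
        return stim, cat

    def _after_record(self, rec: TrialRecord) -> None:
        self._window.append(bool(rec.correct))
        if len(self._window) < self.config.window:
            return
        accuracy = sum(self._window) / self.config.window
        if accuracy >= self.config.criterion:
            self.size *= self.config.growth_factor
            self._window.clear()


class ExemplarScheduler(_SchedulerBase):
    """Uniform draws from the entire pool, ab initio; no blocks.

    The category bases are excluded from the pool: if a base stimulus is
    found among the members (parameter-identical), it is removed with a
    warning.
    """

    def __init__(self, config: SessionConfig) -> None:
        super().__init__(config)
        if not config.pools:
            raise ValueError("exemplar protocol needs nonempty pools")
        self.items: list[tuple[Stimulus, str]] = []
        for cat in sorted(config.pools):
            base = config.prototypes.get(cat)
            for s in config.pools[cat]:
                if base is not None and _same_parameters(s, base):
                    logger.warning(
                        "category base found in pool for %r; removed (bases are "
                        "not part of the exemplar stimulus set)", cat
                    )
                    continue
                self.items.append((s, cat))
        if not self.items:
            raise ValueError("pool is empty after excluding category bases")

    def _draw(self) -> tuple[Stimulus, str]:
        return self.items[self.rng.integers(len(self.items))]


class ContinuumScheduler(_SchedulerBase):
    """Uniform draws from a morph continuum with a movable category boundary.

    Steps ``0..boundary_index`` belong to category A, the rest to B.  The
    boundary sits between two steps, so valid indices are
    ``0..n_steps - 2``; :meth:`set_boundary` relabels subsequent trials
    without touching the stimuli.
    """

    def __init__(self, continuum: Continuum, boundary_index: int,
                 config: SessionConfig, labels: tuple[str, str] = ("A", "B")) -> None:
        super().__init__(config)
        self.continuum = continuum
        self.labels = labels
        self.boundary_index = self._check_boundary(boundary_index)

    def _check_boundary(self, idx: int) -> int:
        if not (0 <= idx < self.continuum.n_steps - 1):
            raise ValueError(
                f"boundary_index must be in [0, {self.continuum.n_steps - 2}], got {idx}"
            )
        return idx

    def set_boundary(self, new_index: int) -> None:
        self.boundary_index = self._check_boundary(new_index)

    def label_of(self, step_index: int) -> str:
        return self.labels[0] if step_index <= self.boundary_index else self.labels[1]

    def _draw(self) -> tuple[Stimulus, str]:
        i = int(self.rng.integers(self.continuum.n_steps))
        return self.continuum.steps[i], self.label_of(i)


def _same_parameters(a: Stimulus, b: Stimulus) -> bool:
    if a.n_spheres != b.n_spheres:
        return False
    for sa, sb in zip(a.spheres, b.spheres):
        if (sa.x, sa.y, sa.z, sa.size, sa.hue, sa.sat, sa.val) != (
                sb.x, sb.y, sb.z, sb.size, sb.hue, sb.sat, sb.val):
            return False
    return True


# ---------------------------------------------------------------------------
# Simulated observer
# ---------------------------------------------------------------------------

class SimulatedObserver:
    """Distance-based classifier with softmax response noise.

    ``kind='prototype'`` scores each category by the composite parametric
    deviation of the stimulus from that category's prototype;
    ``kind='exemplar'`` by the deviation from the nearest stored exemplar.
    Response probabilities are ``softmax(-score / noise)``: ``noise=0``
    responds with the best category deterministically (ties broken by
    category-name order), large noise approaches chance.
    """

    def __init__(
        self,
        kind: str,
        references: dict[str, Stimulus] | dict[str, list[Stimulus]],
        noise: float = 0.0,
        seed: int = 0,
    ) -> None:
        if kind not in ("prototype", "exemplar"):
            raise ValueError("kind must be 'prototype' or 'exemplar'")
        if noise < 0.0:
            raise ValueError("noise must be >= 0")
        self.kind = kind
        self.references = references
        self.noise = noise
        self.rng = np.random.default_rng(seed)
        self.categories = sorted(references)

    def scores(self, stimulus: Stimulus) -> dict[str, float]:
        out = {}
        for cat in self.categories:
            ref = self.references[cat]
            if self.kind == "prototype":
                out[cat] = deviation_score(stimulus, ref)
            else:
                out[cat] = min(deviation_score(stimulus, ex) for ex in ref)
        return out

    def respond(self, stimulus: Stimulus) -> str:
        scores = self.scores(stimulus)
        cats = self.categories
        if self.noise == 0.0:
            return min(cats, key=lambda c: (scores[c], c))
        z = np.array([-scores[c] / self.noise for c in cats])
        z -= z.max()
        with np.errstate(under="ignore"):
            p = np.exp(z)
        p /= p.sum()
        return cats[self.rng.choice(len(cats), p=p)]


def run_session(
    scheduler: _SchedulerBase,
    observer: SimulatedObserver,
    n_trials: int,
) -> tuple[list[TrialRecord], dict]:
    """Run ``n_trials`` of a scheduler against a simulated observer.

    Returns the trial records and a summary with the overall accuracy and a
    rolling learning curve (window = the scheduler's config window).
    Deterministic given the scheduler's and observer's seeds.
    """
    for _ in range(n_trials):
        stim, _true = scheduler.next_trial()
        scheduler.record(observer.respond(stim))
    records = scheduler.records[-n_trials:]
    correct = np.array([r.correct for r in records], dtype=float)
    w = scheduler.config.window
    curve = learning_curve(records, w)
    summary = {
        "n_trials": n_trials,
        "accuracy": float(correct.mean()),
        "window": w,
        "learning_curve": curve.tolist(),
        "final_set_sizes": scheduler.set_sizes(),
    }
    return records, summary


def learning_curve(records: list[TrialRecord], window: int) -> np.ndarray:
    """Rolling accuracy over trials (window truncated at the start)."""
    correct = np.array([float(r.correct) for r in records])
    out = np.empty_like(correct)
    csum = np.concatenate([[0.0], np.cumsum(correct)])
    for i in range(len(correct)):
        lo = max(0, i + 1 - window)
        out[i] = (csum[i + 1] - csum[lo]) / (i + 1 - lo)
    return out
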