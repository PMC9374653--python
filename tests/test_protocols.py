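"""Training schedulers: criterion semantics, set growth, draw distributions,
and the qualitative prototype-vs-exemplar learning-curve prediction."""

import numpy as np
import pytest
from scipy import stats

import spherestim as st


def two_categories(n_members=30, seed=0, sep=1.2):
    """Two well-separated categories: bases offset in x and hue."""
    rng = np.random.default_rng(seed)
    spec = st.CategorySpec.uniform(position_shift=(0.0, 0.35), y_dev=(0.0, 0.2),
                                   size_dev=(0.0, 0.04), hue_dev=(0.0, 0.10))
    base_a = st.make_base(6, seed + 1)
    base_b = st.make_base(6, seed + 2)
    for sp in base_a.spheres:
        sp.x -= sep / 2
        sp.hue = st.wrap_hue(0.0 + 0.05 * rng.random())
    for sp in base_b.spheres:
        sp.x += sep / 2
        sp.hue = st.wrap_hue(0.5 + 0.05 * rng.random())
    cat_a = st.generate_category(base_a, spec, n_members, seed + 3, label_prefix="a")
    cat_b = st.generate_category(base_b, spec, n_members, seed + 4, label_prefix="b")
    return cat_a, cat_b


def overlapping_categories(n_members=30, seed=0, sep=0.5, hue_sep=0.15):
    """Two categories sharing base geometry, offset in x and hue, with
    within-category spread comparable to the offset — genuinely hard items."""
    spec = st.CategorySpec.uniform(position_shift=(0.0, 0.45), y_dev=(0.0, 0.2),
                                   size_dev=(0.0, 0.04), hue_dev=(0.0, 0.12))
    base_a = st.make_base(6, seed + 1)
    base_b = base_a.copy()
    for sp in base_a.spheres:
        sp.x -= sep / 2
    for sp in base_b.spheres:
        sp.x += sep / 2
        sp.hue = st.wrap_hue(sp.hue + hue_sep)
    cat_a = st.generate_category(base_a, spec, n_members, seed + 3, label_prefix="a")
    cat_b = st.generate_category(base_b, spec, n_members, seed + 4, label_prefix="b")
    return cat_a, cat_b


def config_from(cat_a, cat_b, **kw):
    return st.SessionConfig(
        pools={"A": cat_a.members, "B": cat_b.members},
        prototypes={"A": cat_a.base, "B": cat_b.base},
        **kw,
    )


def feed(scheduler, pattern):
    """Run trials answering correctly where pattern is True; returns records."""
    out = []
    for want_correct in pattern:
        stim, true_cat = scheduler.next_trial()
        wrong = "B" if true_cat == "A" else "A"
        out.append(scheduler.record(true_cat if want_correct else wrong))
    return out


class TestPrototypeScheduler:
    def test_first_window_presents_only_prototypes(self):
        cat_a, cat_b = two_categories()
        sched = st.PrototypeScheduler(config_from(cat_a, cat_b, window=20, seed=1))
        protos = {cat_a.base.label, cat_b.base.label}
        for _ in range(20):
            stim, _ = sched.next_trial()
            assert stim.label in protos
            sched.record("A")

    def test_all_correct_doubles_every_window(self):
        cat_a, cat_b = two_categories()
        sched = st.PrototypeScheduler(config_from(cat_a, cat_b, window=10, seed=2))
        sizes = [sched.size]
        for _ in range(4):
            feed(sched, [True] * 10)
            sizes.append(sched.size)
        assert sizes == [1, 2, 4, 8, 16]

    def test_below_criterion_never_advances(self):
        # 79% < 80%: periodic pattern keeps every rolling window below criterion
        cat_a, cat_b = two_categories()
        sched = st.PrototypeScheduler(
            config_from(cat_a, cat_b, window=100, criterion=0.80, seed=3))
        pattern = ([True] * 79 + [False] * 21) * 3
        feed(sched, pattern)
        assert sched.size == 1

    def test_advances_exactly_at_criterion(self):
        # rolling accuracy first hits exactly 16/20 = 0.80 at a known trial
        cat_a, cat_b = two_categories()
        sched = st.PrototypeScheduler(
            config_from(cat_a, cat_b, window=20, criterion=0.80, seed=4))
        feed(sched, [False] * 5 + [True] * 15)   # window full: 15/20 = 0.75
        assert sched.size == 1
        feed(sched, [True])                       # oldest False drops: 16/20 = 0.80
        assert sched.size == 2

    def test_set_size_caps_at_pool(self):
        cat_a, cat_b = two_categories(n_members=5)
        sched = st.PrototypeScheduler(config_from(cat_a, cat_b, window=5, seed=5))
        for _ in range(10):
            feed(sched, [True] * 5)
        assert sched.set_sizes() == {"A": 6, "B": 6}  # prototype + full pool

    def test_set_size_nondecreasing_powers_of_growth(self):
        cat_a, cat_b = two_categories()
        sched = st.PrototypeScheduler(config_from(cat_a, cat_b, window=10, seed=6))
        rng = np.random.default_rng(0)
        seen = [sched.size]
        feed(sched, rng.random(300) < 0.85)
        seen.append(sched.size)
        assert all(b >= a for a, b in zip(seen, seen[1:]))
        assert all((s & (s - 1)) == 0 for s in seen)  # powers of 2

    def test_added_stimuli_ordered_by_deviation(self):
        cat_a, cat_b = two_categories()
        sched = st.PrototypeScheduler(config_from(cat_a, cat_b, seed=7))
        devs = [st.deviation_score(s, cat_a.base) for s in sched.ordered_pools["A"]]
        assert devs == sorted(devs)

    def test_empty_pool_rejected(self):
        cat_a, cat_b = two_categories()
        cfg = config_from(cat_a, cat_b)
        cfg.pools["A"] = []
        with pytest.raises(ValueError):
            st.PrototypeScheduler(cfg)


class TestExemplarScheduler:
    def test_draws_uniform_over_pool(self):
        # 10,000 trials over a 50-stimulus pool; chi-square at alpha = 0.01
        cat_a, cat_b = two_categories(n_members=25)
        sched = st.ExemplarScheduler(config_from(cat_a, cat_b, seed=8))
        counts = {}
        for _ in range(10_000):
            stim, _ = sched.next_trial()
            counts[stim.label] = counts.get(stim.label, 0) + 1
            sched.record("A")
        assert len(counts) == 50
        assert stats.chisquare(list(counts.values())).pvalue > 0.01

    def test_base_never_presented(self):
        cat_a, cat_b = two_categories(n_members=10)
        # plant the base inside the pool; scheduler must remove it
        cfg = config_from(cat_a, cat_b)
        cfg.pools["A"] = cfg.pools["A"] + [cat_a.base.copy()]
        sched = st.ExemplarScheduler(cfg)
        protos = {id(cat_a.base), id(cat_b.base)}
        for _ in range(500):
            stim, _ = sched.next_trial()
            assert stim.spheres != cat_a.base.spheres
            assert stim.spheres != cat_b.base.spheres
            sched.record("A")

    def test_deterministic_replay(self):
        cat_a, cat_b = two_categories()
        labels = []
        for _ in range(2):
            sched = st.ExemplarScheduler(config_from(cat_a, cat_b, seed=9))
            run = []
            for _ in range(50):
                stim, cat = sched.next_trial()
                run.append((stim.label, cat))
                sched.record("A")
            labels.append(run)
        assert labels[0] == labels[1]


class TestContinuumScheduler:
    def make(self, boundary, k=5, seed=10):
        cont = st.morph_pair(st.make_base(6, 1), st.make_base(6, 2), k=k)  # 7 steps
        return st.ContinuumScheduler(cont, boundary, st.SessionConfig(seed=seed))

    def test_boundary_splits_labels(self):
        sched = self.make(boundary=3)
        assert [sched.label_of(i) for i in range(7)] == list("AAAABBB")

    def test_moving_boundary_relabels_only(self):
        sched = self.make(boundary=3)
        sched.set_boundary(1)
        assert [sched.label_of(i) for i in range(7)] == list("AABBBBB")
        # stimuli unchanged
        assert sched.continuum.n_steps == 7

    def test_out_of_range_boundary_rejected(self):
        with pytest.raises(ValueError):
            self.make(boundary=6)   # n_steps - 1 is invalid
        with pytest.raises(ValueError):
            self.make(boundary=-1)
        sched = self.make(boundary=0)
        with pytest.raises(ValueError):
            sched.set_boundary(7)


class TestSimulatedObserver:
    def test_zero_noise_perfect_on_separated_prototypes(self):
        cat_a, cat_b = two_categories()
        obs = st.SimulatedObserver("prototype", {"A": cat_a.base, "B": cat_b.base},
                                   noise=0.0)
        assert obs.respond(cat_a.base) == "A"
        assert obs.respond(cat_b.base) == "B"
        for m in cat_a.members[:10]:
            assert obs.respond(m) == "A"

    def test_zero_noise_prototype_session_doubles_every_window(self):
        cat_a, cat_b = two_categories()
        cfg = config_from(cat_a, cat_b, window=10, seed=11)
        sched = st.PrototypeScheduler(cfg)
        obs = st.SimulatedObserver("prototype", {"A": cat_a.base, "B": cat_b.base},
                                   noise=0.0, seed=12)
        _, summary = st.run_session(sched, obs, 40)
        assert summary["accuracy"] == 1.0
        assert sched.size == 16  # doubled after each of the 4 windows

    def test_huge_noise_is_chance(self):
        cat_a, cat_b = two_categories()
        cfg = config_from(cat_a, cat_b, seed=13)
        sched = st.ExemplarScheduler(cfg)
        obs = st.SimulatedObserver("prototype", {"A": cat_a.base, "B": cat_b.base},
                                   noise=1e9, seed=14)
        _, summary = st.run_session(sched, obs, 4000)
        # binomial(4000, .5): 3 sigma ~ 0.024
        assert abs(summary["accuracy"] - 0.5) < 0.03

    def test_exemplar_observer_uses_nearest_exemplar(self):
        cat_a, cat_b = two_categories()
        obs = st.SimulatedObserver("exemplar",
                                   {"A": cat_a.members, "B": cat_b.members},
                                   noise=0.0)
        assert obs.respond(cat_a.members[0]) == "A"
        assert obs.respond(cat_b.members[0]) == "B"

    def test_prototype_curve_initially_steeper_than_exemplar(self):
        # the prototype protocol starts with only the (easy, maximally
        # representative) prototypes, so early accuracy must exceed the
        # exemplar protocol's, which mixes in hard pool items from trial 1;
        # same observer model and categories in both arms
        accs = {"prototype": [], "exemplar": []}
        for seed in (0, 1, 2):
            cat_a, cat_b = overlapping_categories(seed=100 + seed)
            noise = 0.25
            for proto in (True, False):
                cfg = config_from(cat_a, cat_b, window=20, seed=20 + seed)
                sched = (st.PrototypeScheduler(cfg) if proto
                         else st.ExemplarScheduler(cfg))
                obs = st.SimulatedObserver(
                    "prototype", {"A": cat_a.base, "B": cat_b.base},
                    noise=noise, seed=30 + seed)
                records, _ = st.run_session(sched, obs, 100)
                acc = np.mean([r.correct for r in records])
                accs["prototype" if proto else "exemplar"].append(acc)
        assert np.mean(accs["prototype"]) > np.mean(accs["exemplar"])


def test_learning_curve_rolling_window():
    recs = [st.TrialRecord(i, "s", "A", "A", c, {}) for i, c in
            enumerate([True, True, False, False])]
    curve = st.learning_curve(recs, window=2)
    assert curve.tolist() == [1.0, 1.0, 0.5, 0.0]
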