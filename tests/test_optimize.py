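import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drowsefuse.ground_truth import WindowDataset
from drowsefuse.indicators import OPTIMIZABLE, IndicatorParams, compute_window_value
from drowsefuse.optimize import (
    ConfusionMatrix,
    GAConfig,
    IndicatorEvaluator,
    SplitSpec,
    SubjectScore,
    classify_threshold,
    confusion,
    ga_optimize,
    grid_search_threshold,
    holdout_split,
    largest_remainder_allocation,
    objective_f,
    score_dataset,
    sens_spec,
)
from drowsefuse.synthetic import generate_planted_lanex_dataset


class TestThresholdClassifier:
    def test_strict_inequality(self):
        preds = classify_threshold(np.array([0.1, 0.5, 0.9]), 0.5)
        assert preds.tolist() == [False, False, True]  # value == T -> alert

    def test_below_min_threshold_all_drowsy(self, rng):
        v = rng.uniform(0, 1, 100)
        assert classify_threshold(v, v.min() - 1).all()

    def test_matches_comparison_oracle(self, rng):
        v = rng.standard_normal(1000)
        t = 0.3
        assert classify_threshold(v, t).tolist() == [x > t for x in v]

    def test_monotone_roc(self, rng):
        """Raising T never increases sensitivity, never decreases specificity."""
        v = rng.uniform(0, 1, 500)
        truth = rng.random(500) < 0.3
        prev_sens, prev_spec = 1.0, 0.0
        for t in np.linspace(-0.1, 1.1, 25):
            cm = confusion(classify_threshold(v, t), truth)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                s = sens_spec(cm)
            assert s.sensitivity <= prev_sens + 1e-12
            assert s.specificity >= prev_spec - 1e-12
            prev_sens, prev_spec = s.sensitivity, s.specificity


class TestConfusion:
    def test_perfect_and_inverted(self):
        truth = np.array([True] * 8 + [False] * 12)
        cm = confusion(truth, truth)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (8, 12, 0, 0)
        cm = confusion(~truth, truth)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (0, 0, 12, 8)

    def test_matches_counting_oracle(self, rng):
        pred = rng.random(200) < 0.5
        truth = rng.random(200) < 0.3
        cm = confusion(pred, truth)
        assert cm.tp == sum(1 for p, t in zip(pred, truth) if p and t)
        assert cm.fp == sum(1 for p, t in zip(pred, truth) if p and not t)
        assert cm.tn == sum(1 for p, t in zip(pred, truth) if not p and not t)
        assert cm.fn == sum(1 for p, t in zip(pred, truth) if not p and t)
        assert cm.total == 200

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion(np.array([True]), np.array([True, False]))


class TestScores:
    def test_ratio_arithmetic(self):
        s = sens_spec(ConfusionMatrix(tp=8, fp=1, tn=9, fn=2))
        assert s.sensitivity == pytest.approx(0.8)
        assert s.specificity == pytest.approx(0.9)

    def test_all_correct(self):
        s = sens_spec(ConfusionMatrix(tp=5, fp=0, tn=5, fn=0))
        assert (s.sensitivity, s.specificity) == (1.0, 1.0)

    def test_empty_class_flagged(self):
        with pytest.warns(UserWarning, match="missing one class"):
            s = sens_spec(ConfusionMatrix(tp=0, fp=1, tn=9, fn=0), "U4")
        assert np.isnan(s.sensitivity)
        assert not s.defined

    def test_objective_published_rows(self):
        """f for single-subject scores reproduces the published table rows."""
        assert objective_f([SubjectScore("a", 0.82, 0.90)]) == pytest.approx(0.86)
        assert objective_f([SubjectScore("a", 0.56, 0.94)]) == pytest.approx(0.75)
        assert objective_f([SubjectScore("a", 0.94, 0.98)]) == pytest.approx(0.96)

    def test_objective_perfect_and_excluded(self):
        perfect = [SubjectScore(f"U{i}", 1.0, 1.0) for i in range(9)]
        assert objective_f(perfect) == 1.0
        mixed = perfect + [SubjectScore("U10", float("nan"), 1.0)]
        assert objective_f(mixed) == 1.0  # undefined subject excluded

    @given(
        scores=st.lists(
            st.tuples(st.floats(0, 1), st.floats(0, 1)), min_size=1, max_size=8
        )
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_objective_invariances(self, scores):
        subj = [SubjectScore(str(i), s, p) for i, (s, p) in enumerate(scores)]
        f = objective_f(subj)
        assert 0.0 <= f <= 1.0
        assert objective_f(subj[::-1]) == pytest.approx(f)
        swapped = [SubjectScore(s.subject_id, s.specificity, s.sensitivity) for s in subj]
        assert objective_f(swapped) == pytest.approx(f)

    def test_objective_empty_rejected(self):
        with pytest.raises(ValueError):
            objective_f([])


class TestHoldoutSplit:
    def test_largest_remainder_published_sizes(self):
        assert largest_remainder_allocation(314, (0.6, 0.2, 0.2)) == [188, 63, 63]
        assert sum(largest_remainder_allocation(17, (0.6, 0.2, 0.2))) == 17

    @pytest.fixture
    def dataset(self):
        return generate_planted_lanex_dataset(n_drivers=3, intervals_per_driver=6, seed=11)

    def test_partition(self, dataset):
        splits = holdout_split(dataset, SplitSpec(seed=5))
        idx = np.concatenate([s.interval_ids for s in splits.values()])
        assert len(idx) == len(dataset)
        # intervals are never shared between subsets
        sets = [set(s.interval_ids.tolist()) for s in splits.values()]
        assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])
        assert sets[0] | sets[1] | sets[2] == set(dataset.interval_ids.tolist())

    def test_interval_level_no_leakage(self, dataset):
        """All ten sibling windows of an interval land in one subset."""
        splits = holdout_split(dataset, SplitSpec(seed=5))
        for s in splits.values():
            for iv in np.unique(s.interval_ids):
                assert (dataset.interval_ids == iv).sum() == (s.interval_ids == iv).sum()

    def test_deterministic(self, dataset):
        a = holdout_split(dataset, SplitSpec(seed=9))
        b = holdout_split(dataset, SplitSpec(seed=9))
        for name in a:
            assert np.array_equal(a[name].start_s, b[name].start_s)
            assert np.array_equal(a[name].interval_ids, b[name].interval_ids)

    def test_stratified_by_subject_and_label(self):
        # 5 intervals per (subject, label) group: enough for every subset
        # to receive at least one unit from each group at 60/20/20
        dataset = generate_planted_lanex_dataset(n_drivers=3, intervals_per_driver=10, seed=11)
        splits = holdout_split(dataset, SplitSpec(seed=5))
        for s in splits.values():
            for subj in dataset.subjects:
                m = s.subject_ids == subj
                assert m.any()
                assert s.labels[m].any() and (~s.labels[m]).any()


class TestEvaluator:
    @pytest.mark.parametrize("name", list(OPTIMIZABLE) + ["STD_lp", "TLC_avg", "PERCLOS"])
    def test_matches_scalar_kernels(self, name, default_cohort):
        ds = default_cohort.dataset.subset(np.arange(40))
        params = IndicatorParams.defaults(name)
        ev = IndicatorEvaluator(name, ds, params)
        got = ev.values()
        from drowsefuse.indicators import INDICATOR_CHANNEL
        from drowsefuse.signal_core import derivative

        for i in range(len(ds)):
            w = ds.channels[INDICATOR_CHANNEL[name]][i].astype(float)
            speed = derivative(w, ds.sample_rate) if name in ("TLC_5s", "TLC_avg", "RSWM") else None
            expected = compute_window_value(name, w, params, ds.sample_rate, speed)
            assert got[i] == pytest.approx(expected, rel=1e-8, abs=1e-10)


class TestGA:
    def test_recovers_planted_virtual_lines(self):
        planted_l, planted_r = 2.45, 1.30
        ds = generate_planted_lanex_dataset(planted_l, planted_r, seed=3)
        splits = holdout_split(ds, SplitSpec(seed=3))
        params, val_f = ga_optimize(
            "Lanex", splits["train"], splits["validation"],
            GAConfig(seed=3, population_size=40, generations=60, patience=15),
        )
        assert abs(params.x_L - planted_l) <= 0.10
        assert abs(params.x_R - planted_r) <= 0.10
        assert val_f > 0.9

    def test_deterministic_under_seed(self):
        ds = generate_planted_lanex_dataset(n_drivers=3, intervals_per_driver=4, seed=1)
        splits = holdout_split(ds, SplitSpec(seed=1))
        cfg = GAConfig(seed=42, population_size=20, generations=10, patience=5)
        p1, f1 = ga_optimize("Lanex", splits["train"], splits["validation"], cfg)
        p2, f2 = ga_optimize("Lanex", splits["train"], splits["validation"], cfg)
        assert (p1.x_L, p1.x_R, p1.threshold, f1) == (p2.x_L, p2.x_R, p2.threshold, f2)

    def test_dominates_shipped_preset(self, default_cohort):
        """The GA result never scores below the shipped optimized preset,
        which is injected into the initial population."""
        splits = holdout_split(default_cohort.dataset, SplitSpec(seed=2))
        cfg = GAConfig(seed=2, population_size=20, generations=10, patience=5)
        params, _ = ga_optimize("RSWM", splits["train"], splits["validation"], cfg)
        ev = IndicatorEvaluator("RSWM", splits["train"])
        preset = IndicatorParams.table2_optimized("RSWM")
        t_preset, f_preset = grid_search_threshold(ev.values(d=preset.d), splits["train"])
        f_ga = ev.f_at_threshold(ev.values(d=params.d), params.threshold)
        assert f_ga >= f_preset - 1e-12

    def test_stays_inside_bounds(self):
        ds = generate_planted_lanex_dataset(n_drivers=3, intervals_per_driver=4, seed=5)
        splits = holdout_split(ds, SplitSpec(seed=5))
        cfg = GAConfig(seed=5, population_size=16, generations=8, patience=4)
        params, _ = ga_optimize("Lanex", splits["train"], splits["validation"], cfg)
        lo_l, hi_l = params.bounds["x_L"]
        lo_r, hi_r = params.bounds["x_R"]
        assert lo_l <= params.x_L <= hi_l
        assert lo_r <= params.x_R <= hi_r
        assert params.x_L > params.x_R

    def test_single_class_training_rejected(self):
        ds = generate_planted_lanex_dataset(n_drivers=2, intervals_per_driver=4, seed=6)
        alert_only = ds.subset(np.flatnonzero(~ds.labels))
        with pytest.raises(ValueError, match="both classes"):
            ga_optimize("Lanex", alert_only, alert_only, GAConfig(seed=0))


class TestScoreDataset:
    def test_chance_level_on_random_labels(self, rng):
        """A label-independent classifier scores near 0.5 in expectation."""
        n = 4000
        values = rng.uniform(0, 1, n)
        ds = WindowDataset(
            subject_ids=np.repeat([f"U{i}" for i in range(4)], n // 4),
            session_ids=np.repeat(["S"] * 4, n // 4),
            interval_ids=np.arange(n) // 10,
            start_s=np.zeros(n),
            labels=rng.random(n) < 0.5,
            channels={},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, f = score_dataset(values, 0.5, ds)
        assert 0.45 <= f <= 0.55
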