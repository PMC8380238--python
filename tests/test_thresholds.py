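import numpy as np
import pytest

from cypscreen.thresholds import (
    ClassMetrics,
    DensityAnalysisError,
    ThresholdSet,
    UndefinedMetricError,
    class_metrics,
    density_profile,
    find_allosteric_threshold,
    find_orthosteric_pair,
    orthosteric_binder_threshold,
)


class TestClassMetrics:
    @pytest.mark.parametrize(
        "cm,sens,spec,ba",
        [
            # confusion tables scaled from reported sensitivity/specificity pairs
            (ClassMetrics(tp=910, fn=90, tn=362, fp=638), 0.910, 0.362, 0.636),
            (ClassMetrics(tp=943, fn=57, tn=441, fp=559), 0.943, 0.441, 0.692),
            (ClassMetrics(tp=641, fn=359, tn=665, fp=335), 0.641, 0.665, 0.653),
        ],
    )
    def test_balanced_accuracy_is_mean_of_sens_spec(self, cm, sens, spec, ba):
        assert cm.sensitivity == pytest.approx(sens)
        assert cm.specificity == pytest.approx(spec)
        assert cm.balanced_accuracy == pytest.approx(ba, abs=5e-4)

    def test_perfect_predictions(self):
        m = class_metrics([True, False, True], [True, False, True])
        assert (m.sensitivity, m.specificity, m.balanced_accuracy) == (1.0, 1.0, 1.0)

    def test_single_class_truth_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            class_metrics([True, False], [True, True])

    def test_agrees_with_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(3)
        pred = rng.random(500) < 0.4
        actual = rng.random(500) < 0.3
        m = class_metrics(pred, actual)
        assert m.balanced_accuracy == pytest.approx(
            sklearn_metrics.balanced_accuracy_score(actual, pred)
        )
        assert m.sensitivity == pytest.approx(sklearn_metrics.recall_score(actual, pred))


def _brute_force_1d(scores, labels, grid):
    """Independent re-derivation: plain loops, no shared code path."""
    rows = []
    pos = sum(labels)
    neg = len(labels) - pos
    for t in grid:
        tp = sum(1 for s, y in zip(scores, labels) if s < t and y)
        tn = sum(1 for s, y in zip(scores, labels) if s >= t and not y)
        rows.append((t, tp / pos, tn / neg))
    bas = sorted(0.5 * (se + sp) for _, se, sp in rows)
    # linear-interpolation 95th percentile
    h = 0.95 * (len(bas) - 1)
    lo = int(np.floor(h))
    p95 = bas[lo] + (h - lo) * (bas[min(lo + 1, len(bas) - 1)] - bas[lo])
    best = None
    for t, se, sp in rows:
        if 0.5 * (se + sp) >= p95:
            key = (se, 0.5 * (se + sp), -t)  # max sens, then max BA, then most negative t
            if best is None or key > best[0]:
                best = (key, t)
    return best[1], p95


class TestAllostericThreshold:
    def test_separated_classes_reach_perfect_sensitivity(self):
        scores = [-50, -45, -42, -5, -3, -1, 0]
        labels = [True, True, True, False, False, False, False]
        res = find_allosteric_threshold(scores, labels)
        # any grid value between the classes separates perfectly; the
        # most-conservative tie-break picks the lowest such value
        assert -42 < res.chosen <= -5
        assert res.sensitivity == 1.0
        assert res.balanced_accuracy == 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        n = 20000
        y = rng.random(n) < 0.1
        scores = np.where(y, rng.normal(-28, 7, n), rng.normal(-18, 7, n))
        scores = np.minimum(scores, 0.0)
        grid = list(np.arange(-60.0, 1.0))
        res = find_allosteric_threshold(scores, y, grid=grid)
        t_oracle, p95_oracle = _brute_force_1d(list(scores), list(y), grid)
        assert res.chosen == t_oracle
        assert res.percentile95 == pytest.approx(p95_oracle)

    def test_selection_dominance_over_candidates(self, score_records, labels):
        res = find_allosteric_threshold([r.allo_score for r in score_records], labels)
        ok = res.candidates[res.candidates["balanced_accuracy"] >= res.percentile95]
        assert res.balanced_accuracy >= res.percentile95
        assert (ok["sensitivity"] <= res.sensitivity + 1e-12).all()

    def test_sensitivity_monotone_specificity_antitone_in_threshold(self, score_records, labels):
        res = find_allosteric_threshold([r.allo_score for r in score_records], labels)
        c = res.candidates.sort_values("threshold")
        assert (np.diff(c["sensitivity"]) >= -1e-12).all()
        assert (np.diff(c["specificity"]) <= 1e-12).all()

    def test_record_order_irrelevant(self, score_records, labels):
        allo = [r.allo_score for r in score_records]
        res1 = find_allosteric_threshold(allo, labels)
        perm = np.random.default_rng(0).permutation(len(allo))
        res2 = find_allosteric_threshold(
            [allo[i] for i in perm], [labels[i] for i in perm]
        )
        assert res1.chosen == res2.chosen

    def test_percentile_worked_example(self):
        # five candidates with distinct balanced accuracies
        # {0.5, 2/3, 0.75, 5/6, 1}: the linear-interpolation 95th percentile
        # is 5/6 + 0.8·(1 − 5/6) = 29/30, satisfied only by the T = −30
        # candidate (hand-traced).
        scores = [-45.0, -35.0, -25.0, -15.0, -5.0]
        labels = [True, True, False, False, False]
        grid = [-40.0, -30.0, -20.0, -10.0, 0.0]
        res = find_allosteric_threshold(scores, labels, grid=grid)
        assert sorted(res.candidates["balanced_accuracy"]) == pytest.approx(
            [0.5, 2 / 3, 0.75, 5 / 6, 1.0]
        )
        assert res.percentile95 == pytest.approx(29 / 30)
        assert res.chosen == -30.0
        assert res.balanced_accuracy == 1.0


class TestOrthostericBinderThreshold:
    def test_two_gaussian_valley_near_midpoint(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(-30, 6, 25000), rng.normal(0, 6, 25000)])
        t_ob, prof = orthosteric_binder_threshold(x, bandwidth=3.0)
        assert t_ob == pytest.approx(-15.0, abs=0.5)
        assert prof.bandwidth == 3.0

    def test_unimodal_sample_raises(self):
        rng = np.random.default_rng(8)
        with pytest.raises(DensityAnalysisError):
            orthosteric_binder_threshold(rng.normal(-10, 5, 5000))

    def test_density_integrates_to_one_and_extrema_alternate(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(-25, 4, 3000), rng.normal(-5, 4, 3000)])
        prof = density_profile(x, bandwidth=3.0)
        assert np.trapezoid(prof.density, prof.grid) == pytest.approx(1.0, abs=1e-3)
        kinds = [k for _, k in prof.extrema]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_point_mass_at_cap_shows_in_density(self):
        rng = np.random.default_rng(10)
        x = np.concatenate([rng.normal(-20, 5, 2000), np.full(800, 20.0)])
        t_ob, prof = orthosteric_binder_threshold(x)
        # the capped mass forms its own mode; the valley lies between
        assert -20 < t_ob < 20

    def test_needs_two_distinct_scores(self):
        with pytest.raises(ValueError):
            density_profile([1.0, 1.0, 1.0])


def _brute_force_2d(scores, labels, grid):
    pos = sum(labels)
    neg = len(labels) - pos
    rows = []
    for i, lo in enumerate(grid):
        for hi in grid[i + 1:]:
            tp = sum(1 for s, y in zip(scores, labels) if (s < lo or s >= hi) and y)
            tn = sum(1 for s, y in zip(scores, labels) if (lo <= s < hi) and not y)
            rows.append(((lo, hi), tp / pos, tn / neg))
    bas = sorted(0.5 * (se + sp) for _, se, sp in rows)
    h = 0.95 * (len(bas) - 1)
    k = int(np.floor(h))
    p95 = bas[k] + (h - k) * (bas[min(k + 1, len(bas) - 1)] - bas[k])
    best = None
    for pair, se, sp in rows:
        if 0.5 * (se + sp) >= p95:
            key = (se, 0.5 * (se + sp), -pair[0], -pair[1])
            if best is None or key > best[0]:
                best = (key, pair)
    return best[1], p95


class TestOrthostericPair:
    def test_constructed_gap_is_bracketed(self):
        # inhibitors only at the extremes, non-inhibitors only inside a known gap
        scores = [-40, -38, -36, -8, -7, -6, -25, -24, -23, -22, -21, -20]
        labels = [True] * 6 + [False] * 6
        res = find_orthosteric_pair(scores, labels)
        lo, hi = res.chosen
        assert lo <= -25 and hi > -20
        assert res.balanced_accuracy == 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(31)
        n = 5000
        y = rng.random(n) < 0.15
        low = rng.random(n) < 0.5
        s_inh = np.where(low, rng.normal(-33, 4, n), rng.normal(-11, 4, n))
        s = np.where(y, s_inh, rng.normal(-18, 9, n))
        keep = s < -4  # binders only
        s, y = s[keep], y[keep]
        grid = list(np.arange(-60.0, -3.0))
        res = find_orthosteric_pair(s, y, grid=grid)
        pair_oracle, p95_oracle = _brute_force_2d(list(s), list(y), grid)
        assert res.chosen == pair_oracle
        assert res.percentile95 == pytest.approx(p95_oracle)

    def test_candidates_respect_ordering_constraint(self):
        scores = [-40, -30, -10, -22, -21]
        labels = [True, True, True, False, False]
        res = find_orthosteric_pair(scores, labels)
        assert (res.candidates["t_sob"] < res.candidates["t_wob"]).all()


class TestThresholdSet:
    def test_ordering_invariant(self):
        with pytest.raises(ValueError):
            ThresholdSet(t_sab=-23.0, t_ob=-3.29, t_sob=-19.0, t_wob=-27.0)

    def test_roundtrip(self):
        ts = ThresholdSet(t_sab=-23.0, t_ob=-3.29, t_sob=-27.0, t_wob=-19.0)
        assert ThresholdSet.from_dict(ts.to_dict()) == ts
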