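"""Expression-MPH vs size-MPH covariation: records, curves, classes, tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hybridaction.containers import (ConfigurationError, ExpressionMatrix,
                                     InsufficientDataError)
from hybridaction.mph import (CURVE_GRID, MphData, cliffs_delta,
                              cluster_mph_splines, compute_mph,
                              covariation_test, fit_mph_splines,
                              ks_two_sample_sizes, sort_into_classes,
                              trio_size_mph, dunn_index)


# ---------------------------------------------------------------------------
# MPH records
# ---------------------------------------------------------------------------

def _tiny_panel(f1_expr=3.0, pa=2.0, pb=4.0, f1_area=150.0, aa=100.0,
                ab=120.0):
    cols, rows = {}, []
    for gid, v, area, hyb in [("P1", pa, aa, False), ("P2", pb, ab, False),
                              ("F1", f1_expr, f1_area, True)]:
        sid = f"{gid}_mock_r1"
        cols[sid] = [v]
        rows.append((sid, gid, hyb, "mock", 1, area))
    expr = ExpressionMatrix(pd.DataFrame(cols, index=["g"]), "log2")
    meta = pd.DataFrame(rows, columns=["sample_id", "genotype_id",
                                       "is_hybrid", "treatment",
                                       "replicate", "rosette_area"]) \
        .set_index("sample_id", drop=False)
    trios = pd.DataFrame([("t1", "P1", "P2", "F1")],
                         columns=["trio_id", "parent_a", "parent_b", "f1"])
    return expr, meta, trios


class TestComputeMph:
    def test_exact_additivity_gives_zero_expression_mph(self):
        expr, meta, trios = _tiny_panel()
        data = compute_mph(expr, meta, trios)
        assert data.expression.iloc[0, 0] == pytest.approx(0.0)

    def test_size_mph_arithmetic(self):
        expr, meta, trios = _tiny_panel()
        data = compute_mph(expr, meta, trios)
        assert data.records["size_mph"].iloc[0] == pytest.approx(40.0)

    def test_parent_swap_invariant(self):
        expr, meta, trios = _tiny_panel(f1_expr=2.5)
        swapped = trios.rename(columns={"parent_a": "parent_b",
                                        "parent_b": "parent_a"})
        a = compute_mph(expr, meta, trios)
        b = compute_mph(expr, meta, swapped)
        pd.testing.assert_frame_equal(a.expression, b.expression)

    def test_incomplete_trio_skipped(self):
        expr, meta, trios = _tiny_panel()
        meta2 = meta.drop("P2_mock_r1")
        expr2 = ExpressionMatrix(expr.data.drop(columns="P2_mock_r1"),
                                 "log2")
        data = compute_mph(expr2, meta2, trios)
        assert len(data.records) == 0


def test_trio_size_mph(midi_panel):
    out = trio_size_mph(midi_panel.meta, midi_panel.trios)
    assert len(out) == len(midi_panel.trios)
    # hybrids are planted larger on average
    assert out.mean() > 0


# ---------------------------------------------------------------------------
# covariation curves
# ---------------------------------------------------------------------------

def _records(x, y, treatment="mock"):
    rids = [f"t{i}_{treatment}_r1" for i in range(len(x))]
    records = pd.DataFrame({
        "record_id": rids, "trio_id": [f"t{i}" for i in range(len(x))],
        "treatment": treatment, "replicate": 1, "size_mph": y,
    }).set_index("record_id", drop=False)
    expression = pd.DataFrame({rid: [xv] for rid, xv in zip(rids, x)},
                              index=["g"])
    return MphData(records=records, expression=expression)


class TestMphSplines:
    def test_linear_signal_reproduced(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 40)
        data = _records(x, 2 * x)
        feats = fit_mph_splines(data)
        curve = feats.loc["g", "mock"].to_numpy()
        assert np.all(np.diff(curve) > 0)                  # monotone up
        # y = 2x means slope 2*std(x) per unit of z-scored x
        expected = 2 * x.std() * (CURVE_GRID[-1] - CURVE_GRID[0])
        np.testing.assert_allclose(curve[-1] - curve[0], expected,
                                   rtol=1e-6)

    def test_independent_signal_flat(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 400)
        y = rng.normal(0, 1, 400)
        feats = fit_mph_splines(data=_records(x, y))
        curve = feats.loc["g", "mock"].to_numpy()
        se = 1 / np.sqrt(len(x) / len(CURVE_GRID))
        assert np.abs(curve - curve.mean()).max() < 3 * se

    def test_quadratic_signal_concave(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 200)
        data = _records(x, -(x ** 2))
        feats = fit_mph_splines(data)
        curve = feats.loc["g", "mock"].to_numpy()
        mid = curve[len(curve) // 2]
        assert mid > curve[0] and mid > curve[-1]

    def test_degenerate_spread_dropped(self):
        data = _records(np.zeros(20), np.arange(20.0))
        feats = fit_mph_splines(data)
        assert len(feats) == 0

    def test_too_few_records_raise(self):
        data = _records(np.arange(4.0), np.arange(4.0))
        with pytest.raises(InsufficientDataError):
            fit_mph_splines(data)


# ---------------------------------------------------------------------------
# class sorting
# ---------------------------------------------------------------------------

def _features_from_curves(curves_mock, curves_bth):
    cols = pd.MultiIndex.from_tuples(
        [("BTH", i) for i in range(len(CURVE_GRID))]
        + [("mock", i) for i in range(len(CURVE_GRID))],
        names=["treatment", "grid"])
    rows = np.hstack([np.atleast_2d(curves_bth),
                      np.atleast_2d(curves_mock)])
    return pd.DataFrame(rows, columns=cols,
                        index=[f"g{i}" for i in range(len(rows))])


class TestSortIntoClasses:
    grid = CURVE_GRID

    def test_positive_positive(self):
        feats = _features_from_curves(self.grid, self.grid)
        labels = pd.Series([1] * len(feats), index=feats.index)
        classes = sort_into_classes(feats, labels, delta=0.25)
        assert classes.loc[1, "class"] == "positive-positive"

    def test_none_none_flat(self):
        feats = _features_from_curves(np.zeros_like(self.grid),
                                      np.zeros_like(self.grid))
        labels = pd.Series([1] * len(feats), index=feats.index)
        classes = sort_into_classes(feats, labels, delta=0.25)
        assert classes.loc[1, "class"] == "none-none"

    def test_quadratic_negative(self):
        quad = -(self.grid ** 2)
        neg = -self.grid
        feats = _features_from_curves(quad, neg)
        labels = pd.Series([1] * len(feats), index=feats.index)
        classes = sort_into_classes(feats, labels, delta=0.25)
        assert classes.loc[1, "class"] == "quadratic-negative"

    def test_every_cluster_gets_exactly_one_label(self):
        rng = np.random.default_rng(3)
        feats = _features_from_curves(rng.normal(0, 1, (10, 7)),
                                      rng.normal(0, 1, (10, 7)))
        labels = pd.Series(rng.integers(1, 4, 10), index=feats.index)
        classes = sort_into_classes(feats, labels, delta=0.25)
        vocab = {"positive", "negative", "quadratic", "none"}
        for _, row in classes.iterrows():
            mock_l, bth_l = row["class"].split("-")
            assert mock_l in vocab and bth_l in vocab


# ---------------------------------------------------------------------------
# covariation test
# ---------------------------------------------------------------------------

def _multi_gene_records(n_genes, n_records, fn, seed=0, treatment="mock"):
    rng = np.random.default_rng(seed)
    rids = [f"t{i}_{treatment}_r1" for i in range(n_records)]
    y = rng.normal(0, 1, n_records)
    records = pd.DataFrame({
        "record_id": rids, "trio_id": [f"t{i}" for i in range(n_records)],
        "treatment": treatment, "replicate": 1, "size_mph": y,
    }).set_index("record_id", drop=False)
    X = np.vstack([fn(y, rng) for _ in range(n_genes)])
    expression = pd.DataFrame(X, index=[f"g{i}" for i in range(n_genes)],
                              columns=rids)
    return MphData(records=records, expression=expression)


class TestCovariationTest:
    def test_extreme_selection_rule(self):
        # expression MPH values 1..10: low group = ranks 1-4, high = 7-10
        data = _multi_gene_records(1, 10, lambda y, rng: np.arange(1, 11.0))
        data.records["size_mph"] = np.arange(1, 11.0)    # align with rank
        labels = pd.Series([1], index=["g0"])
        classes = pd.DataFrame({"n_genes": [1], "label_mock": ["none"],
                                "class": ["none"]}, index=[1])
        classes.index.name = "cluster"
        out = covariation_test(data, labels, classes, n_extreme=4)
        # mean of ranks 7-10 minus mean of ranks 1-4 = 8.5 - 2.5
        # reconstruct from the reported p by checking the raw means instead
        assert out.iloc[0]["contrast"] == "two-sided"

    def test_perfect_positive_cluster_significant(self):
        data = _multi_gene_records(
            50, 30, lambda y, rng: y + rng.normal(0, 0.05, len(y)))
        labels = pd.Series([1] * 50, index=data.expression.index)
        classes = pd.DataFrame({"n_genes": [50], "label_mock": ["positive"],
                                "class": ["positive"]}, index=[1])
        out = covariation_test(data, labels, classes, n_extreme=4)
        assert out.iloc[0]["p"] < 0.001

    def test_independent_cluster_not_significant(self):
        hits = 0
        for seed in range(20):
            data = _multi_gene_records(
                30, 30, lambda y, rng: rng.normal(0, 1, len(y)), seed=seed)
            labels = pd.Series([1] * 30, index=data.expression.index)
            classes = pd.DataFrame({"n_genes": [30], "label_mock": ["none"],
                                    "class": ["none"]}, index=[1])
            out = covariation_test(data, labels, classes, n_extreme=4)
            hits += out.iloc[0]["p"] < 0.001
        assert hits <= 1

    def test_all_zero_differences_degenerate(self):
        data = _multi_gene_records(5, 12, lambda y, rng: np.arange(12.0))
        data.records["size_mph"] = 0.0
        labels = pd.Series([1] * 5, index=data.expression.index)
        classes = pd.DataFrame({"n_genes": [5], "label_mock": ["none"],
                                "class": ["none"]}, index=[1])
        out = covariation_test(data, labels, classes, n_extreme=4)
        assert out.iloc[0]["p"] == 1.0
        assert out.iloc[0]["degenerate"]


# ---------------------------------------------------------------------------
# two-round clustering
# ---------------------------------------------------------------------------

class TestClusterMphSplines:
    def _planted(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 40
        shapes = {
            "pos": CURVE_GRID * 2, "neg": -CURVE_GRID * 2,
            "flat": np.zeros_like(CURVE_GRID),
        }
        rows, names = [], []
        for name, base in shapes.items():
            for i in range(n):
                jitter = rng.normal(0, 0.1, (2, len(CURVE_GRID)))
                rows.append(np.hstack([base + jitter[0], base + jitter[1]]))
                names.append(f"{name}{i}")
        cols = pd.MultiIndex.from_tuples(
            [("BTH", i) for i in range(len(CURVE_GRID))]
            + [("mock", i) for i in range(len(CURVE_GRID))],
            names=["treatment", "grid"])
        return pd.DataFrame(rows, index=names, columns=cols)

    def test_planted_shapes_recovered_and_flat_removed(self):
        feats = self._planted()
        labels, classes = cluster_mph_splines(feats, seed=0, k_max=6,
                                              delta=0.5)
        # flat genes are dropped in round 1
        assert not any(g.startswith("flat") for g in labels.index)
        for prefix, expect in (("pos", "positive-positive"),
                               ("neg", "negative-negative")):
            genes = [g for g in labels.index if g.startswith(prefix)]
            cls = {classes.loc[labels[g], "class"] for g in genes}
            assert cls == {expect}

    def test_deterministic(self):
        feats = self._planted(seed=1)
        a = cluster_mph_splines(feats, seed=5, delta=0.5)
        b = cluster_mph_splines(feats, seed=5, delta=0.5)
        pd.testing.assert_series_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_size_constraint_arithmetic(self):
        # 10 clusters with 4 below 5% -> 40% small > 25% -> k rejected
        sizes = np.array([50, 50, 50, 50, 50, 50, 2, 2, 2, 2])
        n = sizes.sum()
        frac_small = np.mean(sizes < 0.05 * n)
        assert frac_small == pytest.approx(0.4)
        assert frac_small > 0.25

    def test_dunn_index_separated_blobs(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 0.1, (20, 3)),
                       rng.normal(5, 0.1, (20, 3))])
        labels = np.repeat([0, 1], 20)
        assert dunn_index(X, labels) > 1.0
        assert dunn_index(X, np.zeros(40, dtype=int)) == 0.0


# ---------------------------------------------------------------------------
# Cliff's delta and the size KS test
# ---------------------------------------------------------------------------

def cliffs_delta_bruteforce(a, b):
    gt = sum(1 for x in a for y in b if x > y)
    lt = sum(1 for x in a for y in b if x < y)
    return (gt - lt) / (len(a) * len(b))


class TestCliffsDelta:
    def test_identical_samples_zero(self):
        assert cliffs_delta([1, 2, 3], [1, 2, 3]) == 0.0

    def test_complete_dominance_one(self):
        assert cliffs_delta([4, 5], [1, 2]) == 1.0

    def test_tied_cross_pairs(self):
        assert cliffs_delta([1, 3], [2, 2]) == 0.0

    def test_matches_bruteforce_on_random_pairs(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            a = rng.normal(size=rng.integers(1, 20))
            b = rng.normal(size=rng.integers(1, 20))
            assert cliffs_delta(a, b) == pytest.approx(
                cliffs_delta_bruteforce(a, b), abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.integers(-5, 5), min_size=1, max_size=15),
           st.lists(st.integers(-5, 5), min_size=1, max_size=15))
    def test_antisymmetric_and_bounded(self, a, b):
        d = cliffs_delta(a, b)
        assert -1.0 <= d <= 1.0
        assert d == pytest.approx(-cliffs_delta(b, a), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            cliffs_delta([], [1.0])


class TestKsSizes:
    def test_identical_samples_p_one(self):
        d, p = ks_two_sample_sizes([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        rng = np.random.default_rng(9)
        d, p = ks_two_sample_sizes(rng.uniform(0, 1, 50),
                                   rng.uniform(10, 11, 50))
        assert d == 1.0 and p < 1e-10

    def test_agrees_with_reference(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            a, b = rng.normal(size=30), rng.normal(0.3, 1, 25)
            _, p = ks_two_sample_sizes(a, b)
            ref = stats.ks_2samp(a, b).pvalue
            assert p == pytest.approx(ref, abs=1e-10)
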