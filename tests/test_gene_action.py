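"""Additive/dominant calling: exact oracles, null behaviour, recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import ks_2samp

from hybridaction.containers import (AlignmentError, ConfigurationError,
                                     ExpressionMatrix,
                                     InsufficientDataError)
from hybridaction.gene_action import (AdditiveModel, DominanceModel, bh_fdr,
                                      build_mpv_null, call_gene_action,
                                      classify_direction, compute_mpv,
                                      dominance_score, genotype_means,
                                      intersect_common_additive)


# ---------------------------------------------------------------------------
# MPV and the pairwise null
# ---------------------------------------------------------------------------

class TestMpv:
    def test_arithmetic_mean(self):
        a = pd.Series([2.0, 1.0, 3.0], index=list("xyz"))
        b = pd.Series([4.0, 3.0, 1.0], index=list("xyz"))
        out = compute_mpv(a, b)
        np.testing.assert_allclose(out, [3.0, 2.0, 2.0])

    def test_symmetric_and_idempotent_on_identical(self):
        a = pd.Series([1.5, -2.0], index=["g1", "g2"])
        b = pd.Series([0.5, 4.0], index=["g1", "g2"])
        pd.testing.assert_series_equal(compute_mpv(a, b), compute_mpv(b, a))
        pd.testing.assert_series_equal(compute_mpv(a, a), a)

    def test_mismatched_genes_raise(self):
        a = pd.Series([1.0], index=["g1"])
        b = pd.Series([1.0], index=["g2"])
        with pytest.raises(AlignmentError):
            compute_mpv(a, b)


class TestMpvNull:
    def test_three_accessions_enumeration(self):
        vals = pd.DataFrame([[0.0, 2.0, 4.0]], index=["g"])
        null = build_mpv_null(vals)
        assert sorted(null.loc["g"]) == [1.0, 2.0, 3.0]

    @pytest.mark.parametrize("n", range(3, 11))
    def test_size_is_n_choose_2(self, n):
        vals = pd.DataFrame(np.random.default_rng(n).normal(size=(2, n)))
        null = build_mpv_null(vals)
        assert null.shape[1] == n * (n - 1) // 2

    def test_adding_one_accession_adds_n_pairs(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.normal(size=(1, 7)))
        bigger = pd.DataFrame(np.hstack([vals, rng.normal(size=(1, 1))]))
        assert build_mpv_null(bigger).shape[1] \
            == build_mpv_null(vals).shape[1] + 7

    def test_constant_gene_constant_null(self):
        null = build_mpv_null(pd.DataFrame([[3.0] * 5], index=["g"]))
        assert (null.loc["g"] == 3.0).all()

    def test_values_within_parent_range(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.normal(size=(10, 8)))
        null = build_mpv_null(vals)
        assert (null.to_numpy().min(axis=1)
                >= vals.to_numpy().min(axis=1)).all()
        assert (null.to_numpy().max(axis=1)
                <= vals.to_numpy().max(axis=1)).all()

    def test_too_few_accessions(self):
        with pytest.raises(InsufficientDataError):
            build_mpv_null(pd.DataFrame([[1.0, 2.0]]))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_reference(p):
    """Brute-force step-up: independent oracle for the BH adjustment."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


class TestBH:
    def test_single_p(self):
        np.testing.assert_allclose(bh_fdr([0.03]), [0.03])

    def test_hand_stepup(self):
        np.testing.assert_allclose(bh_fdr([0.0001, 0.5, 0.9]),
                                   [0.0003, 0.75, 0.9])

    def test_all_equal_fixed_point(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        p = rng.random(200)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all() and (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(12345)
        for _ in range(200):
            p = rng.random(rng.integers(1, 60))
            np.testing.assert_allclose(bh_fdr(p), bh_reference(p),
                                       atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ConfigurationError):
            bh_fdr([0.5, 1.2])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=40))
    def test_property_matches_bruteforce(self, p):
        np.testing.assert_allclose(bh_fdr(p), bh_reference(p), atol=1e-12)


# ---------------------------------------------------------------------------
# direction and dominance score
# ---------------------------------------------------------------------------

class TestDirectionAndScore:
    def test_direction_by_medians(self):
        null = np.array([2.5, 3.0, 3.5])
        assert classify_direction(np.array([2.0, 2.1, 2.2]), null) \
            == "below_mpv"
        assert classify_direction(np.array([3.4, 3.5, 3.6]), null) \
            == "above_mpv"

    def test_tie_goes_below(self):
        assert classify_direction(np.array([3.0]), np.array([3.0])) \
            == "below_mpv"

    def test_identical_samples_score_zero(self):
        x = np.arange(10.0)
        assert dominance_score(x, x) == 0.0

    def test_complete_separation_below_scores_minus_one(self):
        f1 = np.arange(5.0)
        null = np.arange(10.0, 20.0)
        assert dominance_score(f1, null) == -1.0


# ---------------------------------------------------------------------------
# additive model
# ---------------------------------------------------------------------------

def _matrix_from_genotype_values(gvals, reps=2, noise=0.0, seed=0,
                                 treatment_levels=("mock",)):
    """Build an expression matrix + metadata from genotype-level values."""
    rng = np.random.default_rng(seed)
    cols, meta_rows = {}, []
    for gt, v in gvals.items():
        for tr in treatment_levels:
            for r in range(1, reps + 1):
                sid = f"{gt}_{tr}_r{r}"
                cols[sid] = np.asarray(v, dtype=float) \
                    + rng.normal(0, noise, len(v)) if noise else \
                    np.asarray(v, dtype=float)
                meta_rows.append((sid, gt, gt.startswith("f"), tr, "pb1",
                                  "lib1", r))
    genes = [f"g{i}" for i in range(len(next(iter(gvals.values()))))]
    expr = ExpressionMatrix(pd.DataFrame(cols, index=genes), scale="log2")
    meta = pd.DataFrame(meta_rows, columns=[
        "sample_id", "genotype_id", "is_hybrid", "treatment",
        "plant_batch", "library_batch", "replicate"]) \
        .set_index("sample_id", drop=False)
    return expr, meta


def _perfect_trio_panel(n_trios=6, n_genes=5, seed=0, f1_fn=None):
    rng = np.random.default_rng(seed)
    gvals, trios = {}, []
    for t in range(n_trios):
        a, b = rng.normal(3, 1, n_genes), rng.normal(3, 1, n_genes)
        mpv = (a + b) / 2
        f1 = f1_fn(a, b, mpv, rng) if f1_fn else mpv
        gvals[f"p{2 * t}"] = a
        gvals[f"p{2 * t + 1}"] = b
        gvals[f"f{t}"] = f1
        trios.append((f"trio{t}", f"p{2 * t}", f"p{2 * t + 1}", f"f{t}"))
    trios = pd.DataFrame(trios, columns=["trio_id", "parent_a", "parent_b",
                                         "f1"])
    expr, meta = _matrix_from_genotype_values(gvals, seed=seed + 1)
    return expr, meta, trios


class TestAdditive:
    def test_perfect_additivity_called(self):
        expr, meta, trios = _perfect_trio_panel()
        res = AdditiveModel(expr, meta, trios).fit()
        assert res.frame["additive"].all()
        np.testing.assert_allclose(res.frame["slope"], 1.0, atol=1e-9)
        np.testing.assert_allclose(res.frame["r2"], 1.0, atol=1e-9)

    def test_constant_f1_not_additive(self):
        expr, meta, trios = _perfect_trio_panel(
            f1_fn=lambda a, b, mpv, rng: np.zeros_like(mpv))
        res = AdditiveModel(expr, meta, trios).fit()
        assert not res.frame["additive"].any()

    def test_attenuated_slope_recovered(self):
        # F1 = 0.8 MPV + small noise: expected R^2 ~ 0.98 >> 0.4
        expr, meta, trios = _perfect_trio_panel(
            n_trios=60, n_genes=20,
            f1_fn=lambda a, b, mpv, rng: 0.8 * mpv + rng.normal(0, 0.1,
                                                                len(mpv)))
        res = AdditiveModel(expr, meta, trios).fit()
        assert res.frame["additive"].mean() >= 0.95

    def test_too_few_trios_raise(self):
        expr, meta, trios = _perfect_trio_panel(n_trios=2)
        with pytest.raises(InsufficientDataError):
            AdditiveModel(expr, meta, trios).fit()

    def test_shb2_reduces_to_shb1_without_effects(self):
        expr, meta, trios = _perfect_trio_panel(n_trios=8)
        res = AdditiveModel(expr, meta, trios, mode="shb2").fit()
        assert res.frame["additive"].all()
        np.testing.assert_allclose(res.frame["slope"], 1.0, atol=1e-6)
        assert (res.frame["sigma"] < 1e-6).all()

    def test_shb2_corrects_planted_treatment_offset(self):
        expr, meta, trios = _perfect_trio_panel(n_trios=10)
        # add BTH arm with +2 offset on every sample
        expr2, meta2 = _matrix_from_genotype_values(
            {gt: expr.data[f"{gt}_mock_r1"].to_numpy()
             for gt in meta["genotype_id"].unique()},
            treatment_levels=("mock", "BTH"))
        bth_cols = meta2.index[meta2["treatment"] == "BTH"]
        data = expr2.data.copy()
        data[list(bth_cols)] += 2.0
        res = AdditiveModel(ExpressionMatrix(data, "log2"), meta2,
                            trios, mode="shb2").fit()
        assert res.frame["additive"].all()
        np.testing.assert_allclose(res.frame["slope"], 1.0, atol=1e-6)

    def test_pure_noise_not_additive(self):
        rng = np.random.default_rng(9)
        expr, meta, trios = _perfect_trio_panel(
            n_trios=30, n_genes=40,
            f1_fn=lambda a, b, mpv, rng_: rng.normal(3, 1, len(mpv)))
        res = AdditiveModel(expr, meta, trios).fit()
        assert res.frame["additive"].mean() <= 0.05


def test_intersect_common_additive():
    assert intersect_common_additive({"a", "b", "c"}, {"b", "c", "d"}) \
        == ["b", "c"]
    assert intersect_common_additive(set(), {"a"}) == []
    assert intersect_common_additive({"a"}, {"a"}) == ["a"]


# ---------------------------------------------------------------------------
# dominance model
# ---------------------------------------------------------------------------

class TestDominance:
    def test_identical_f1_and_null_never_dominant(self):
        # 10 inbreds whose pairwise means are reproduced verbatim as F1s
        rng = np.random.default_rng(4)
        inbred_vals = {f"p{i}": rng.normal(3, 1, 6) for i in range(10)}
        pairs = [(i, j) for i in range(10) for j in range(i + 1, 10)]
        trios, gvals = [], dict(inbred_vals)
        for t, (i, j) in enumerate(pairs[:20]):
            gvals[f"f{t}"] = (inbred_vals[f"p{i}"] + inbred_vals[f"p{j}"]) / 2
            trios.append((f"trio{t}", f"p{i}", f"p{j}", f"f{t}"))
        trios = pd.DataFrame(trios, columns=["trio_id", "parent_a",
                                             "parent_b", "f1"])
        expr, meta = _matrix_from_genotype_values(gvals)
        res = DominanceModel(expr, meta, trios).fit()
        assert not res.frame["dominant"].any()

    def test_complete_separation_dominant_below(self):
        rng = np.random.default_rng(5)
        gvals = {f"p{i}": rng.normal(10, 0.2, 4) for i in range(8)}
        trios = []
        for t in range(6):
            gvals[f"f{t}"] = np.full(4, 1.0) + 0.01 * t
            trios.append((f"trio{t}", f"p{2 * (t % 4)}",
                          f"p{2 * (t % 4) + 1}", f"f{t}"))
        trios = pd.DataFrame(trios, columns=["trio_id", "parent_a",
                                             "parent_b", "f1"])
        expr, meta = _matrix_from_genotype_values(gvals)
        res = DominanceModel(expr, meta, trios).fit(q_max=0.05)
        assert res.frame["dominant"].all()
        assert (res.frame["direction"] == "below_mpv").all()
        np.testing.assert_allclose(res.frame["D"], 1.0)
        np.testing.assert_allclose(res.frame["dominance_score"], -1.0)

    def test_too_few_f1_raise(self):
        expr, meta, trios = _perfect_trio_panel(n_trios=3)
        with pytest.raises(InsufficientDataError):
            DominanceModel(expr, meta, trios).fit()


# ---------------------------------------------------------------------------
# combined verdict on a simulated panel
# ---------------------------------------------------------------------------

def test_combined_call_recovers_planted_actions(midi_panel):
    calls = call_gene_action(midi_panel.expression, midi_panel.meta,
                             midi_panel.trios)
    merged = calls.join(midi_panel.truth)
    isdom = merged["true_action"].str.startswith("dominant")
    isadd = merged["true_action"] == "additive"
    dom = merged["action"] == "dominant"
    add = merged["action"] == "additive"
    assert (dom & isdom).sum() / isdom.sum() >= 0.75
    assert (dom & isdom).sum() / dom.sum() >= 0.85
    assert (add & isadd).sum() / isadd.sum() >= 0.85
    assert (add & isadd).sum() / add.sum() >= 0.75


def test_additive_genes_rank_low_by_dominance_score(midi_panel):
    res = DominanceModel(midi_panel.expression, midi_panel.meta,
                         midi_panel.trios).fit()
    merged = res.frame.join(midi_panel.truth)
    add_scores = merged.loc[merged["true_action"] == "additive",
                            "dominance_score"].abs()
    dom_scores = merged.loc[
        merged["true_action"].str.startswith("dominant"),
        "dominance_score"].abs()
    assert add_scores.median() < dom_scores.median()
    # nearly all dominant genes out-rank nearly all additive genes
    assert (dom_scores.quantile(0.1) > add_scores.quantile(0.9))
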