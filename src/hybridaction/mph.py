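"""Mid-parent heterosis (MPH) covariation between expression and size.

Per trio, treatment and replicate, expression MPH is the F1's log2 value
minus the mid-parent value and size MPH the F1's rosette area minus the
mid-parent area.  For each gene and treatment a natural-cubic-spline
regression of size MPH on expression MPH summarises the covariation shape;
genes are clustered on these curves (k chosen by the Dunn index subject to
a cluster-size constraint), clusters without covariation are removed, the
survivors are re-clustered, and each final cluster is sorted into a
mock-label x BTH-label covariation class (positive / negative / quadratic /
none per treatment).  Each cluster's class is then validated by the
extreme-sample Wilcoxon procedure: per gene, the mean size MPH of the
``n_extreme`` samples with the lowest and highest expression MPH, compared
across genes by a signed-rank test (one-sided for monotone classes,
extreme-vs-median for quadratic ones), Bonferroni-corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from scipy.spatial.distance import cdist, pdist
from sklearn.cluster import KMeans

from .containers import ConfigurationError, ExpressionMatrix, \
    InsufficientDataError

__all__ = [
    "MphData", "compute_mph", "fit_mph_splines", "dunn_index",
    "cluster_mph_splines", "sort_into_classes", "covariation_test",
    "cliffs_delta", "ks_two_sample_sizes", "MphCovariationModel",
    "MphCovariationResults",
]

logger = logging.getLogger(__name__)

#: z-grid on which fitted covariation curves are evaluated (fixed basis)
CURVE_GRID = np.linspace(-1.2, 1.2, 7)
CLASS_VOCAB = ("positive", "negative", "quadratic", "none")


# ---------------------------------------------------------------------------
# MPH records
# ---------------------------------------------------------------------------

@dataclass
class MphData:
    """Per-record expression and size MPH.

    ``records`` has one row per (trio, treatment, replicate) with the size
    MPH; ``expression`` is genes x records of expression MPH.
    """

    records: pd.DataFrame
    expression: pd.DataFrame

    def for_treatment(self, treatment: str) -> "MphData":
        keep = self.records.index[self.records["treatment"] == treatment]
        return MphData(self.records.loc[keep], self.expression[list(keep)])


def compute_mph(expr: ExpressionMatrix, meta: pd.DataFrame,
                trios: pd.DataFrame) -> MphData:
    """Expression and size MPH per trio, treatment and replicate.

    Members are matched by (genotype, treatment, replicate); replicates
    with any missing member are skipped with a log message.  Size MPH is
    only defined where all three rosette areas are present.
    """
    meta = meta.loc[expr.sample_ids]
    lookup: dict[tuple, list[str]] = {}
    for sid, row in meta.iterrows():
        lookup.setdefault(
            (row["genotype_id"], row["treatment"], row["replicate"]),
            []).append(sid)

    def value_of(key):
        sids = lookup.get(key)
        if not sids:
            return None, None
        vals = expr.data[sids].mean(axis=1)
        area = meta.loc[sids, "rosette_area"].mean()
        return vals, area

    rec_rows = []
    expr_cols = {}
    treatments = sorted(meta["treatment"].unique())
    replicates = sorted(meta["replicate"].unique())
    for _, trio in trios.iterrows():
        for tr in treatments:
            for rep in replicates:
                va, aa = value_of((trio["parent_a"], tr, rep))
                vb, ab = value_of((trio["parent_b"], tr, rep))
                vf, af = value_of((trio["f1"], tr, rep))
                if va is None or vb is None or vf is None:
                    logger.info("trio %s incomplete for %s r%s; skipped",
                                trio["trio_id"], tr, rep)
                    continue
                rid = f"{trio['trio_id']}_{tr}_r{rep}"
                size_mph = np.nan
                if not (pd.isna(aa) or pd.isna(ab) or pd.isna(af)):
                    size_mph = af - (aa + ab) / 2.0
                rec_rows.append((rid, trio["trio_id"], tr, rep, size_mph))
                expr_cols[rid] = vf - (va + vb) / 2.0
    records = pd.DataFrame(rec_rows, columns=[
        "record_id", "trio_id", "treatment", "replicate", "size_mph"]) \
        .set_index("record_id", drop=False)
    return MphData(records=records, expression=pd.DataFrame(expr_cols))


# ---------------------------------------------------------------------------
# per-gene covariation splines
# ---------------------------------------------------------------------------

def _curve_features(x: np.ndarray, y: np.ndarray, df: int) -> np.ndarray | None:
    """Natural-cubic-spline fit of y on z-scored x, evaluated on CURVE_GRID.

    The grid evaluation expresses every gene's curve in one fixed basis so
    curves are directly comparable for clustering.  Returns None for
    degenerate x.
    """
    if np.ptp(x) < 1e-8:
        return None
    z = (x - x.mean()) / x.std()
    design = patsy.dmatrix(f"cr(z, df={df})", {"z": z})
    beta, *_ = np.linalg.lstsq(np.asarray(design), y, rcond=None)
    (grid,) = patsy.build_design_matrices(
        [design.design_info], {"z": np.clip(CURVE_GRID, z.min(), z.max())})
    return np.asarray(grid) @ beta


def fit_mph_splines(data: MphData, genes=None, df: int = 3,
                    min_records: int = 8) -> pd.DataFrame:
    """Per-gene, per-treatment covariation curves on the fixed grid.

    Returns genes x features; columns are (treatment, grid index).  Genes
    with degenerate expression-MPH spread in either treatment are dropped.
    """
    genes = list(data.expression.index if genes is None else genes)
    treatments = sorted(data.records["treatment"].unique())
    blocks = {}
    for tr in treatments:
        sub = data.for_treatment(tr)
        ok = sub.records["size_mph"].notna()
        if ok.sum() < min_records:
            raise InsufficientDataError(
                f"treatment {tr}: {int(ok.sum())} complete records < "
                f"{min_records}")
        rids = list(sub.records.index[ok])
        y = sub.records.loc[rids, "size_mph"].to_numpy(dtype=float)
        X = sub.expression.loc[genes, rids].to_numpy(dtype=float)
        rows = []
        for k, g in enumerate(genes):
            feats = _curve_features(X[k], y, df)
            rows.append(feats if feats is not None
                        else np.full(len(CURVE_GRID), np.nan))
        blocks[tr] = np.vstack(rows)
    cols = pd.MultiIndex.from_tuples(
        [(tr, i) for tr in treatments for i in range(len(CURVE_GRID))],
        names=["treatment", "grid"])
    out = pd.DataFrame(np.hstack([blocks[tr] for tr in treatments]),
                       index=pd.Index(genes, name="gene_id"), columns=cols)
    dropped = out.index[out.isna().any(axis=1)]
    if len(dropped):
        logger.warning("%d genes dropped (degenerate expression MPH)",
                       len(dropped))
    return out.dropna()


# ---------------------------------------------------------------------------
# two-round Dunn-constrained clustering
# ---------------------------------------------------------------------------

def dunn_index(X: np.ndarray, labels: np.ndarray) -> float:
    """Min inter-cluster distance / max intra-cluster diameter."""
    uniq = np.unique(labels)
    if len(uniq) < 2:
        return 0.0
    diam = 0.0
    for u in uniq:
        pts = X[labels == u]
        if len(pts) > 1:
            diam = max(diam, pdist(pts).max())
    if diam == 0:
        return np.inf
    inter = np.inf
    for a in range(len(uniq)):
        for b in range(a + 1, len(uniq)):
            inter = min(inter, cdist(X[labels == uniq[a]],
                                     X[labels == uniq[b]]).min())
    return inter / diam


def _kmeans_scan(X: np.ndarray, seed: int, k_max: int,
                 max_small_frac: float = 0.25, small_size: float = 0.05
                 ) -> np.ndarray:
    """k-means over a k-scan; highest Dunn index subject to the rule that
    at most 25% of clusters hold fewer than 5% of the genes."""
    n = X.shape[0]
    k_hi = min(k_max, n - 1)
    results = {}
    for k in range(2, k_hi + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        labels = km.labels_
        sizes = np.bincount(labels, minlength=k)
        frac_small = np.mean(sizes < small_size * n)
        results[k] = (dunn_index(X, labels), frac_small <= max_small_frac,
                      labels)
    feasible = {k: v for k, v in results.items() if v[1]}
    pool = feasible if feasible else results
    if not feasible:
        logger.warning("no k satisfies the cluster-size constraint; "
                       "using unconstrained Dunn maximum")
    best_k = max(pool, key=lambda k: pool[k][0])
    return pool[best_k][2] + 1


def cluster_mph_splines(features: pd.DataFrame, seed: int = 0,
                        k_max: int = 12, delta: float | None = None,
                        size_mph_sd: float | None = None
                        ) -> tuple[pd.Series, pd.DataFrame]:
    """Two-round clustering of covariation curves.

    Round 1 clusters all genes, drops clusters classified none-none (no
    size-expression covariation under either treatment), and round 2
    re-clusters the survivors with the same criteria.  Curves are centred
    per gene (shape, not offset).  Returns (labels, cluster-class table).
    """
    X = features.to_numpy(dtype=float)
    X = X - X.mean(axis=1, keepdims=True)
    if delta is None:
        if size_mph_sd is None:
            size_mph_sd = float(np.std(X))
        delta = 0.25 * size_mph_sd

    labels1 = _kmeans_scan(X, seed, k_max)
    classes1 = sort_into_classes(features, pd.Series(labels1,
                                                     index=features.index),
                                 delta=delta)
    keep_clusters = classes1.index[classes1["class"] != "none-none"]
    keep = np.isin(labels1, keep_clusters)
    survivors = features.index[keep]
    if keep.sum() < 4 or len(keep_clusters) == 0:
        logger.warning("round-1 removal left too few genes; single round")
        return pd.Series(labels1, index=features.index, name="cluster"), \
            classes1
    labels2 = _kmeans_scan(X[keep], seed + 1, k_max)
    final = pd.Series(labels2, index=survivors, name="cluster")
    classes2 = sort_into_classes(features.loc[survivors], final, delta=delta)
    return final, classes2


# ---------------------------------------------------------------------------
# class sorting and the covariation test
# ---------------------------------------------------------------------------

def _label_curve(curve: np.ndarray, delta: float) -> str:
    """positive / negative / quadratic / none from one mean curve."""
    end_diff = curve[-1] - curve[0]
    mid = curve[len(curve) // 2]
    chord_mid = (curve[0] + curve[-1]) / 2.0
    mid_dev = mid - chord_mid
    steps = np.diff(curve)
    if end_diff > delta and np.all(steps > -delta / 4):
        return "positive"
    if end_diff < -delta and np.all(steps < delta / 4):
        return "negative"
    if abs(mid_dev) > delta and abs(end_diff) <= delta:
        return "quadratic"
    return "none"


def sort_into_classes(features: pd.DataFrame, labels: pd.Series,
                      delta: float) -> pd.DataFrame:
    """Per-cluster covariation class: mock label '-' BTH label.

    A cluster's curve per treatment is the mean over member genes; the
    label rule is monotone beyond +/-delta at the endpoints for positive /
    negative, mid-point chord deviation beyond delta for quadratic.
    """
    treatments = features.columns.get_level_values("treatment").unique()
    rows = []
    for c in sorted(pd.unique(labels)):
        genes = labels.index[labels == c]
        per_tr = {}
        for tr in treatments:
            curve = features.loc[genes, tr].mean(axis=0).to_numpy()
            per_tr[tr] = _label_curve(curve, delta)
        ordered = [per_tr.get("mock"), per_tr.get("BTH")]
        ordered = [x for x in ordered if x is not None] or \
            [per_tr[tr] for tr in treatments]
        rows.append((c, len(genes), *([per_tr[tr] for tr in treatments]),
                     "-".join(ordered)))
    cols = ["cluster", "n_genes"] + [f"label_{tr}" for tr in treatments] \
        + ["class"]
    return pd.DataFrame(rows, columns=cols).set_index("cluster")


def _signed_rank(diffs: np.ndarray, alternative: str) -> float:
    """Wilcoxon signed-rank p; exact for <= 25 nonzero pairs."""
    nz = diffs[diffs != 0]
    if len(nz) == 0:
        return 1.0
    method = "exact" if len(nz) <= 25 else "approx"
    return stats.wilcoxon(nz, alternative=alternative, method=method,
                          correction=(method == "approx")).pvalue


def covariation_test(data: MphData, labels: pd.Series,
                     classes: pd.DataFrame, n_extreme: int = 4,
                     decile_mode: bool = False) -> pd.DataFrame:
    """Extreme-sample Wilcoxon validation of each cluster's class.

    Per gene: mean size MPH of the ``n_extreme`` records with the lowest
    and highest expression MPH (per treatment).  Monotone classes use a
    one-sided signed-rank test across genes in the labelled direction;
    'quadratic' runs two one-sided tests of each extreme against the
    median-expression group; 'none' is two-sided.  Bonferroni over all
    tests performed.
    """
    treatments = sorted(data.records["treatment"].unique())
    tests = []
    for tr in treatments:
        sub = data.for_treatment(tr)
        ok = sub.records["size_mph"].notna()
        rids = list(sub.records.index[ok])
        y = sub.records.loc[rids, "size_mph"].to_numpy(dtype=float)
        n_rec = len(rids)
        k = max(1, int(round(0.1 * n_rec))) if decile_mode else n_extreme
        if n_rec < 2 * k:
            raise InsufficientDataError(
                f"treatment {tr}: {n_rec} records < 2 x {k} extremes")
        X = sub.expression.loc[labels.index, rids].to_numpy(dtype=float)
        order = np.argsort(X, axis=1, kind="stable")
        low_mean = y[order[:, :k]].mean(axis=1)
        high_mean = y[order[:, -k:]].mean(axis=1)
        mid_lo = (n_rec - k) // 2
        mid_mean = y[order[:, mid_lo:mid_lo + k]].mean(axis=1)
        per_gene = pd.DataFrame({"low": low_mean, "high": high_mean,
                                 "mid": mid_mean}, index=labels.index)
        for c in classes.index:
            genes = labels.index[labels == c]
            sub_pg = per_gene.loc[genes]
            label = classes.loc[c, f"label_{tr}"]
            d_hl = (sub_pg["high"] - sub_pg["low"]).to_numpy()
            degenerate = bool(np.all(d_hl == 0))
            if label == "positive":
                tests.append((c, tr, label, "high>low",
                              _signed_rank(d_hl, "greater"), degenerate))
            elif label == "negative":
                tests.append((c, tr, label, "high<low",
                              _signed_rank(d_hl, "less"), degenerate))
            elif label == "quadratic":
                # test direction follows the sign of the mid deviation
                mdev = (sub_pg["mid"]
                        - (sub_pg["low"] + sub_pg["high"]) / 2).mean()
                side = "less" if mdev > 0 else "greater"
                for arm, extreme in (("low_vs_mid", "low"),
                                     ("high_vs_mid", "high")):
                    d = (sub_pg[extreme] - sub_pg["mid"]).to_numpy()
                    tests.append((c, tr, label, arm,
                                  _signed_rank(d, side),
                                  bool(np.all(d == 0))))
            else:
                tests.append((c, tr, label, "two-sided",
                              _signed_rank(d_hl, "two-sided"), degenerate))
    out = pd.DataFrame(tests, columns=["cluster", "treatment", "label",
                                       "contrast", "p", "degenerate"])
    out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out


def trio_size_mph(meta: pd.DataFrame, trios: pd.DataFrame,
                  treatment: str = "mock") -> pd.Series:
    """Per-trio size MPH: mean F1 area minus mid-parent mean area."""
    sel = meta[meta["treatment"] == treatment]
    geno_area = sel.groupby("genotype_id")["rosette_area"].mean()
    out = {}
    for _, row in trios.iterrows():
        try:
            out[row["trio_id"]] = geno_area[row["f1"]] - (
                geno_area[row["parent_a"]] + geno_area[row["parent_b"]]) / 2.0
        except KeyError:
            logger.info("trio %s lacks size data; skipped", row["trio_id"])
    return pd.Series(out, name="size_mph")


# ---------------------------------------------------------------------------
# effect sizes and distribution tests
# ---------------------------------------------------------------------------

def cliffs_delta(a, b) -> float:
    """Cliff's delta: P(a > b) - P(a < b) over all cross pairs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ConfigurationError("cliffs_delta requires nonempty samples")
    bs = np.sort(b)
    greater = np.searchsorted(bs, a, side="left").sum()
    less = (len(bs) - np.searchsorted(bs, a, side="right")).sum()
    return (greater - less) / (a.size * b.size)


def ks_two_sample_sizes(f1_sizes, parent_sizes) -> tuple[float, float]:
    """Two-sided two-sample KS on rosette areas; returns (D, p)."""
    res = stats.ks_2samp(np.asarray(f1_sizes, dtype=float),
                         np.asarray(parent_sizes, dtype=float))
    return res.statistic, res.pvalue


# ---------------------------------------------------------------------------
# model-style facade
# ---------------------------------------------------------------------------

@dataclass
class MphCovariationResults:
    data: MphData
    features: pd.DataFrame
    labels: pd.Series
    classes: pd.DataFrame
    tests: pd.DataFrame

    def genes_in_class(self, pattern: str) -> list[str]:
        """Genes whose final cluster carries the given class label."""
        clusters = self.classes.index[self.classes["class"] == pattern]
        return list(self.labels.index[self.labels.isin(clusters)])

    def summary(self) -> str:
        counts = self.classes.groupby("class")["n_genes"].sum()
        lines = ["MPH covariation classes (genes per class):"]
        lines += [f"  {cls:<22} {n}" for cls, n in counts.items()]
        sig = self.tests[self.tests["p_bonferroni"] < 0.001]
        lines.append(f"  significant cluster tests (Bonferroni p < 0.001): "
                     f"{len(sig)}/{len(self.tests)}")
        return "\n".join(lines)


class MphCovariationModel:
    """End-to-end expression-MPH vs size-MPH covariation analysis."""

    def __init__(self, expr: ExpressionMatrix, meta: pd.DataFrame,
                 trios: pd.DataFrame, genes=None, df: int = 3):
        self.expr, self.meta, self.trios = expr, meta, trios
        self.genes = genes
        self.df = df

    def fit(self, seed: int = 0, k_max: int = 12, n_extreme: int = 4,
            decile_mode: bool = False) -> MphCovariationResults:
        data = compute_mph(self.expr, self.meta, self.trios)
        features = fit_mph_splines(data, genes=self.genes, df=self.df)
        sd = float(np.nanstd(data.records["size_mph"]))
        labels, classes = cluster_mph_splines(features, seed=seed,
                                              k_max=k_max,
                                              size_mph_sd=sd)
        tests = covariation_test(data, labels, classes, n_extreme=n_extreme,
                                 decile_mode=decile_mode)
        return MphCovariationResults(data=data, features=features,
                                     labels=labels, classes=classes,
                                     tests=tests)
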