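"""Additive and dominant gene-action calling across parent-F1 trios.

Two complementary callers classify each gene's mode of inheritance:

* **Additive** (``AdditiveModel``) — per gene, the F1 expression value is
  regressed on the mid-parent value (MPV = arithmetic mean of the parental
  log2 expression) across trios.  Genes tracking the MPV (slope > 0.5 and
  R^2 > 0.4 in the simple design; slope > 0.4 and residual sigma < 0.6 in
  the treatment/batch-corrected mixed-model design) are called additive.
* **Dominant** (``DominanceModel``) — per gene, a population-wide MPV null
  distribution is built from the arithmetic means of all C(n, 2) pairwise
  combinations of inbred accessions, and a two-sided two-sample
  Kolmogorov-Smirnov test asks whether the F1 values were drawn from it.
  Benjamini-Hochberg q < 0.001 calls dominance; the direction (above or
  below MPV) is the sign of the median difference.

``call_gene_action`` combines the two into a single per-gene verdict with
dominance taking precedence: a gene whose F1 values sit at a constant
offset from the MPV satisfies the regression criteria yet is not additive,
and the KS test is the instrument that detects exactly that.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .containers import (AlignmentError, ConfigurationError, ExpressionMatrix,
                         InsufficientDataError)

__all__ = [
    "compute_mpv", "build_mpv_null", "bh_fdr", "genotype_means",
    "classify_direction", "dominance_score",
    "AdditiveModel", "AdditiveResults",
    "DominanceModel", "DominanceResults",
    "intersect_common_additive", "call_gene_action",
]

logger = logging.getLogger(__name__)

#: product n_f1 * n_null below which the exact KS distribution is used
KS_EXACT_LIMIT = 10_000


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def compute_mpv(parent_a: pd.Series, parent_b: pd.Series) -> pd.Series:
    """Elementwise mid-parent value (a + b) / 2; symmetric in its arguments."""
    if not parent_a.index.equals(parent_b.index):
        if set(parent_a.index) != set(parent_b.index):
            raise AlignmentError("parents cover different gene sets")
        parent_b = parent_b.loc[parent_a.index]
    return (parent_a + parent_b) / 2.0


def build_mpv_null(inbred_values: pd.DataFrame) -> pd.DataFrame:
    """All-pairwise-combination MPV null, one multiset per gene.

    ``inbred_values`` is genes x inbred accessions; the result is genes x
    C(n, 2) pairwise arithmetic means (self-pairs excluded).
    """
    n = inbred_values.shape[1]
    if n < 3:
        raise InsufficientDataError(
            f"MPV null needs >= 3 inbred accessions, got {n}")
    i, j = np.triu_indices(n, k=1)
    vals = inbred_values.to_numpy(dtype=float)
    null = (vals[:, i] + vals[:, j]) / 2.0
    return pd.DataFrame(null, index=inbred_values.index)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def center_nuisance(expr: ExpressionMatrix, meta: pd.DataFrame,
                    factors=("library_batch", "plant_batch", "treatment")
                    ) -> ExpressionMatrix:
    """Remove per-gene mean offsets of nuisance factors.

    For each factor level, the gene's mean over samples in that level is
    shifted back to the gene's grand mean.  This strips library-batch,
    plant-batch and treatment main effects before gene-action calling so
    that genotype means compare F1s and inbreds on a common footing; it
    deliberately leaves genotype-level signal untouched.
    """
    X = expr.data.to_numpy(dtype=float).copy()
    meta = meta.loc[expr.sample_ids]
    grand = X.mean(axis=1, keepdims=True)
    for col in factors:
        if col not in meta.columns:
            continue
        codes, levels = pd.factorize(meta[col])
        if len(levels) < 2:
            continue
        for b in range(len(levels)):
            mask = codes == b
            X[:, mask] -= X[:, mask].mean(axis=1, keepdims=True) - grand
    return ExpressionMatrix(
        pd.DataFrame(X, index=expr.gene_ids, columns=expr.sample_ids),
        scale="log2", pseudocount=expr.pseudocount)


def genotype_means(expr: ExpressionMatrix, meta: pd.DataFrame,
                   treatment: str | None = "mock") -> pd.DataFrame:
    """Genes x genotypes matrix of replicate-mean log2 expression.

    ``treatment`` restricts to one arm (None pools all samples); genotypes
    without samples in the stratum are absent from the result.
    """
    meta = meta.loc[expr.sample_ids]
    if treatment is not None:
        if treatment not in set(meta["treatment"]):
            raise ConfigurationError(
                f"no samples with treatment {treatment!r}")
        meta = meta[meta["treatment"] == treatment]
    groups = meta.groupby("genotype_id").groups
    cols = {gt: expr.data[list(samples)].mean(axis=1)
            for gt, samples in groups.items()}
    return pd.DataFrame(cols)


def classify_direction(f1_values: np.ndarray, null_values: np.ndarray
                       ) -> str:
    """'below_mpv' iff median(F1) < median(null); ties resolve below."""
    m_f1, m_null = np.median(f1_values), np.median(null_values)
    if m_f1 == m_null:
        logger.warning("direction tie (medians equal); classified below_mpv")
        return "below_mpv"
    return "below_mpv" if m_f1 < m_null else "above_mpv"


def dominance_score(f1_values: np.ndarray, null_values: np.ndarray) -> float:
    """Signed KS statistic: -D for below-MPV genes, +D above.

    A perfectly additive gene (F1 values drawn from the null) scores 0 in
    expectation; ranking genes by |score| descending puts additive genes
    at the bottom.
    """
    d = ks_2samp(f1_values, null_values).statistic
    sign = -1.0 if classify_direction(f1_values, null_values) == "below_mpv" \
        else 1.0
    return sign * d


def intersect_common_additive(calls_a, calls_b) -> list[str]:
    """Genes called additive in both experiments (sorted)."""
    set_a = set(calls_a.additive_genes if hasattr(calls_a, "additive_genes")
                else calls_a)
    set_b = set(calls_b.additive_genes if hasattr(calls_b, "additive_genes")
                else calls_b)
    return sorted(set_a & set_b)


# ---------------------------------------------------------------------------
# additive calling
# ---------------------------------------------------------------------------

@dataclass
class AdditiveResults:
    """Per-gene F1-on-MPV regression results and the additive call."""

    frame: pd.DataFrame
    mode: str
    slope_min: float
    stat_name: str
    stat_threshold: float

    @property
    def additive_genes(self) -> list[str]:
        return list(self.frame.index[self.frame["additive"]])

    def summary(self) -> str:
        n = len(self.frame)
        called = int(self.frame["additive"].sum())
        lines = [
            f"Additive gene-action calls ({self.mode.upper()} design)",
            f"  genes tested: {n}",
            f"  thresholds:   slope > {self.slope_min}, "
            f"{self.stat_name} {'>' if self.stat_name == 'r2' else '<'} "
            f"{self.stat_threshold}",
            f"  called additive: {called} ({100 * called / max(n, 1):.1f}%)",
        ]
        return "\n".join(lines)


class AdditiveModel:
    """F1-on-MPV regression across trios, per gene.

    mode='shb1': ordinary least squares on one value per trio (replicate
    means within the chosen treatment arm).  mode='shb2': per-sample F1
    values with a fixed treatment effect and a random intercept per plant
    batch (statsmodels MixedLM), degrading to fixed effects when the
    design cannot support the random term.
    """

    def __init__(self, expr: ExpressionMatrix, meta: pd.DataFrame,
                 trios: pd.DataFrame, mode: str = "shb1",
                 treatment: str | None = None):
        if mode not in ("shb1", "shb2"):
            raise ConfigurationError(f"unknown mode {mode!r}")
        self.expr, self.meta, self.trios = expr, meta, trios
        self.mode = mode
        self.treatment = treatment

    # -- shared design -----------------------------------------------------
    def _trio_design(self, treatment):
        gmeans = genotype_means(self.expr, self.meta, treatment=treatment)
        ok = self.trios[
            self.trios["parent_a"].isin(gmeans.columns)
            & self.trios["parent_b"].isin(gmeans.columns)
            & self.trios["f1"].isin(gmeans.columns)]
        dropped = len(self.trios) - len(ok)
        if dropped:
            logger.warning("%d incomplete trios dropped", dropped)
        if len(ok) < 3:
            raise InsufficientDataError(
                f"additive calling needs >= 3 complete trios, got {len(ok)}")
        mpv = (gmeans[list(ok["parent_a"])].to_numpy()
               + gmeans[list(ok["parent_b"])].to_numpy()) / 2.0
        f1 = gmeans[list(ok["f1"])].to_numpy()
        return ok, gmeans.index, mpv, f1

    # -- fitting -----------------------------------------------------------
    def fit(self, slope_min: float | None = None,
            r2_min: float = 0.4, sigma_max: float = 0.6,
            gene_subset=None) -> AdditiveResults:
        if self.mode == "shb1":
            return self._fit_shb1(0.5 if slope_min is None else slope_min,
                                  r2_min)
        return self._fit_shb2(0.4 if slope_min is None else slope_min,
                              sigma_max, gene_subset)

    def _fit_shb1(self, slope_min, r2_min) -> AdditiveResults:
        _, genes, x, y = self._trio_design(self.treatment)
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        sxx = (xc * xc).sum(axis=1)
        syy = (yc * yc).sum(axis=1)
        sxy = (xc * yc).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.where(sxx > 0, sxy / sxx, np.nan)
            r2 = np.where((sxx > 0) & (syy > 0), sxy**2 / (sxx * syy), 0.0)
        additive = (slope > slope_min) & (r2 > r2_min)
        additive &= ~np.isnan(slope)
        frame = pd.DataFrame({"slope": slope, "r2": r2,
                              "additive": additive}, index=genes)
        return AdditiveResults(frame, "shb1", slope_min, "r2", r2_min)

    def _fit_shb2(self, slope_min, sigma_max, gene_subset) -> AdditiveResults:
        meta = self.meta.loc[self.expr.sample_ids]
        gmeans_by_treatment = {
            t: genotype_means(self.expr, self.meta, treatment=t)
            for t in sorted(meta["treatment"].unique())}
        f1_meta = meta[meta["genotype_id"].isin(set(self.trios["f1"]))]
        parents = self.trios.set_index("f1")
        rows = []
        for sid, srow in f1_meta.iterrows():
            gm = gmeans_by_treatment[srow["treatment"]]
            pa, pb = parents.loc[srow["genotype_id"], ["parent_a", "parent_b"]]
            if pa in gm.columns and pb in gm.columns:
                rows.append((sid, srow["treatment"], srow["plant_batch"]))
        if len(rows) < 3:
            raise InsufficientDataError("too few complete F1 observations")
        design = pd.DataFrame(rows, columns=["sample_id", "treatment",
                                             "plant_batch"])
        sample_ids = list(design["sample_id"])
        f1_geno = meta.loc[sample_ids, "genotype_id"]
        mpv_cols = {}
        for t, gm in gmeans_by_treatment.items():
            pa = parents.loc[f1_geno, "parent_a"].to_numpy()
            pb = parents.loc[f1_geno, "parent_b"].to_numpy()
            mpv_cols[t] = (gm[pa].to_numpy() + gm[pb].to_numpy()) / 2.0
        t_idx = design["treatment"].to_numpy()
        mpv = np.stack([mpv_cols[t][:, k] for k, t in enumerate(t_idx)],
                       axis=1)
        y_all = self.expr.data[sample_ids].to_numpy()
        genes = self.expr.gene_ids
        if gene_subset is not None:
            sel = genes.get_indexer(list(gene_subset))
            genes = genes[sel]
            y_all = y_all[sel]
            mpv = mpv[sel]

        treat_codes = pd.get_dummies(design["treatment"], drop_first=True,
                                     dtype=float).to_numpy()
        batches = design["plant_batch"].to_numpy()
        single_batch = len(np.unique(batches)) < 2
        single_treatment = treat_codes.shape[1] == 0
        if single_batch or single_treatment:
            logger.warning("degenerate design (single batch or treatment); "
                           "fitting fixed-effects regression")
        slopes = np.full(len(genes), np.nan)
        sigmas = np.full(len(genes), np.nan)
        for k in range(len(genes)):
            x = mpv[k]
            X = np.column_stack([np.ones_like(x), x, treat_codes]) \
                if not single_treatment else np.column_stack(
                    [np.ones_like(x), x])
            y = y_all[k]
            if single_batch:
                beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
                slopes[k] = beta[1]
                dof = max(len(y) - X.shape[1], 1)
                resid = y - X @ beta
                sigmas[k] = np.sqrt((resid ** 2).sum() / dof)
                continue
            try:
                model = MixedLM(y, X, groups=batches)
                fit = model.fit(reml=True, method="lbfgs")
                slopes[k] = fit.fe_params[1]
                sigmas[k] = np.sqrt(fit.scale)
            except Exception:   # singular fits degrade to OLS
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                resid = y - X @ beta
                slopes[k] = beta[1]
                sigmas[k] = np.sqrt((resid ** 2).sum()
                                    / max(len(y) - X.shape[1], 1))
        additive = (slopes > slope_min) & (sigmas < sigma_max)
        frame = pd.DataFrame({"slope": slopes, "sigma": sigmas,
                              "additive": additive}, index=genes)
        return AdditiveResults(frame, "shb2", slope_min, "sigma", sigma_max)


# ---------------------------------------------------------------------------
# dominance calling
# ---------------------------------------------------------------------------

@dataclass
class DominanceResults:
    """Per-gene KS test against the pairwise-MPV null."""

    frame: pd.DataFrame
    q_max: float
    n_null: int = 0
    n_f1: int = 0

    @property
    def dominant_genes(self) -> list[str]:
        return list(self.frame.index[self.frame["dominant"]])

    def genes_with_direction(self, direction: str) -> list[str]:
        f = self.frame
        return list(f.index[f["dominant"] & (f["direction"] == direction)])

    def summary(self) -> str:
        f = self.frame
        n_dom = int(f["dominant"].sum())
        n_below = len(self.genes_with_direction("below_mpv"))
        lines = [
            "Dominance calls (two-sample KS vs pairwise-MPV null)",
            f"  genes tested: {len(f)}   null size: {self.n_null} pairs, "
            f"{self.n_f1} F1 values per gene",
            f"  dominant (q < {self.q_max}): {n_dom}",
        ]
        if n_dom:
            lines.append(f"  below MPV: {n_below} "
                         f"({100 * n_below / n_dom:.1f}% of dominant)")
        return "\n".join(lines)


class DominanceModel:
    """Two-sample KS test of F1 expression against the pairwise-MPV null."""

    def __init__(self, expr: ExpressionMatrix, meta: pd.DataFrame,
                 trios: pd.DataFrame, treatment: str | None = None,
                 min_f1: int = 5):
        self.expr, self.meta, self.trios = expr, meta, trios
        self.treatment = treatment
        self.min_f1 = min_f1

    def fit(self, q_max: float = 0.001) -> DominanceResults:
        gmeans = genotype_means(self.expr, self.meta,
                                treatment=self.treatment)
        meta = self.meta.loc[self.expr.sample_ids]
        f1_ids = [f for f in self.trios["f1"] if f in gmeans.columns]
        inbred_ids = [g for g in gmeans.columns
                      if g in set(meta.loc[~meta["is_hybrid"],
                                           "genotype_id"])]
        if len(f1_ids) < self.min_f1:
            raise InsufficientDataError(
                f"dominance calling needs >= {self.min_f1} F1 values, "
                f"got {len(f1_ids)}")
        null = build_mpv_null(gmeans[inbred_ids])
        f1 = gmeans[f1_ids].to_numpy()
        null_arr = null.to_numpy()
        n, m = f1.shape[1], null_arr.shape[1]
        method = "exact" if n * m <= KS_EXACT_LIMIT else "asymp"
        stats = np.empty(len(gmeans.index))
        pvals = np.empty(len(gmeans.index))
        direction = np.empty(len(gmeans.index), dtype=object)
        for k in range(len(gmeans.index)):
            res = ks_2samp(f1[k], null_arr[k], method=method)
            stats[k], pvals[k] = res.statistic, res.pvalue
            direction[k] = classify_direction(f1[k], null_arr[k])
        qvals = bh_fdr(pvals)
        dominant = qvals < q_max
        score = np.where(direction == "below_mpv", -stats, stats)
        frame = pd.DataFrame({
            "D": stats, "p": pvals, "q": qvals, "dominant": dominant,
            "direction": np.where(dominant, direction, "none"),
            "dominance_score": score,
        }, index=gmeans.index)
        frame["dominance_rank"] = (-np.abs(score)).argsort().argsort() + 1
        return DominanceResults(frame, q_max, n_null=m, n_f1=n)


# ---------------------------------------------------------------------------
# combined verdict
# ---------------------------------------------------------------------------

def call_gene_action(expr: ExpressionMatrix, meta: pd.DataFrame,
                     trios: pd.DataFrame, treatment: str | None = None,
                     slope_min: float = 0.5, r2_min: float = 0.4,
                     q_max: float = 0.001, adjust: bool = True
                     ) -> pd.DataFrame:
    """One verdict per gene: dominant, else additive, else neither.

    By default nuisance factors (library batch, plant batch, treatment
    main effect) are centred out per gene and genotype means pool all
    replicate samples; pass ``treatment='mock'`` to restrict to one arm.
    Dominance (KS against the MPV null) takes precedence because a
    uniformly shifted F1 passes the slope/R^2 screen while plainly not
    sitting at the MPV.
    """
    if adjust:
        expr = center_nuisance(expr, meta)
    add = AdditiveModel(expr, meta, trios, mode="shb1",
                        treatment=treatment).fit(slope_min=slope_min,
                                                 r2_min=r2_min)
    dom = DominanceModel(expr, meta, trios, treatment=treatment).fit(
        q_max=q_max)
    frame = dom.frame.join(add.frame, how="left")
    action = np.where(frame["dominant"], "dominant",
                      np.where(frame["additive"].fillna(False),
                               "additive", "neither"))
    frame["action"] = action
    return frame
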