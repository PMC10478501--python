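"""Clustering of dominant genes and spline modelling of size covariation.

Dominant genes are grouped by k-means on per-gene z-scaled expression
profiles (k fixed, e.g. the study's k = 13, or chosen by the elbow of the
within-cluster sum of squares).  Each cluster's mean expression is then
modelled as a function of rosette size with a linear mixed model

    GeneExpression ~ IsHybrid + ns(Size) + ns(Size):IsHybrid
                     + (IsHybrid | LibraryBatch)

where GeneExpression is the z-scaled cluster-mean log2 expression, Size the
z-scored rosette area and ns() a natural cubic spline basis.  95% credible
intervals for the coefficients come from simulating the approximate
posterior (multivariate normal at the fitted optimum).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from sklearn.cluster import KMeans
import statsmodels.formula.api as smf

from .containers import ConfigurationError, ExpressionMatrix

__all__ = [
    "kmeans_cluster", "ClusterAssignment",
    "SizeSplineModel", "SizeSplineResults", "fit_size_spline",
    "cluster_size_correlation",
]

logger = logging.getLogger(__name__)

ELBOW_K_RANGE = (2, 25)
KMEANS_RESTARTS = 25


# ---------------------------------------------------------------------------
# k-means clustering of expression profiles
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    """Gene -> cluster labels plus cluster-mean profiles over samples."""

    labels: pd.Series                 # gene_id -> cluster id (1..K)
    k: int
    profiles: pd.DataFrame            # cluster x samples mean profile
    inertia_path: dict[int, float] = field(default_factory=dict)

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def genes_in(self, cluster_id: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster_id])


def _zscale_rows(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (values - mu) / sd


def kmeans_cluster(profiles: pd.DataFrame, k: int | str = "auto",
                   seed: int = 0, zscale: bool = True,
                   n_restarts: int = KMEANS_RESTARTS) -> ClusterAssignment:
    """K-means over per-gene (z-scaled) profiles with a fixed seed.

    ``k='auto'`` scans k in [2, 25] and takes the elbow: the k maximising
    the second difference of the within-cluster sum of squares.
    """
    X = profiles.to_numpy(dtype=float)
    if zscale:
        X = _zscale_rows(X)
    n_genes = X.shape[0]
    inertia_path: dict[int, float] = {}
    if k == "auto":
        lo, hi = ELBOW_K_RANGE
        hi = min(hi, n_genes - 1)
        if hi < lo:
            k = 1
        else:
            ks = list(range(lo, hi + 1))
            for kk in ks:
                km = KMeans(n_clusters=kk, n_init=n_restarts,
                            random_state=seed).fit(X)
                inertia_path[kk] = km.inertia_
            if len(ks) >= 3:
                wss = np.array([inertia_path[kk] for kk in ks])
                second = wss[:-2] - 2 * wss[1:-1] + wss[2:]
                k = ks[1 + int(np.argmax(second))]
            else:
                k = ks[0]
    k = int(k)
    if k > n_genes:
        raise ConfigurationError(f"k={k} exceeds the {n_genes} genes")
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(X)
    labels = pd.Series(km.labels_ + 1, index=profiles.index, name="cluster")
    prof = pd.DataFrame(
        {c: profiles.loc[labels.index[labels == c]].mean(axis=0)
         for c in range(1, k + 1)}).T
    prof.index.name = "cluster"
    return ClusterAssignment(labels=labels, k=k, profiles=prof,
                             inertia_path=inertia_path)


# ---------------------------------------------------------------------------
# size-spline linear mixed model
# ---------------------------------------------------------------------------

@dataclass
class SizeSplineResults:
    """Fixed effects, their covariance and fitted curves of one spline LMM."""

    params: pd.Series                  # fixed-effect point estimates
    cov: pd.DataFrame                  # fixed-effect covariance
    scale: float                       # residual variance
    random_structure: str              # 'hybrid-slope', 'intercept', 'none'
    design_info: object                # patsy design info for prediction
    data: pd.DataFrame                 # model frame (z-scaled)
    intervals: pd.DataFrame | None = None

    def fitted_curves(self, n_points: int = 50) -> pd.DataFrame:
        """Fitted inbred and hybrid curves over the observed size range."""
        grid = np.linspace(self.data["size"].min(), self.data["size"].max(),
                           n_points)
        frames = []
        for hybrid in (0.0, 1.0):
            new = pd.DataFrame({"size": grid, "is_hybrid": hybrid})
            (X,) = patsy.build_design_matrices([self.design_info], new)
            frames.append(pd.DataFrame({
                "size_z": grid, "is_hybrid": bool(hybrid),
                "fitted": np.asarray(X) @ self.params.to_numpy()}))
        return pd.concat(frames, ignore_index=True)

    def hybrid_effect(self) -> float:
        """Average hybrid-minus-inbred fitted difference over the data.

        With a spline-by-hybrid interaction the raw IsHybrid coefficient is
        the offset where the interaction basis vanishes; the mean curve
        difference over the observed size distribution is the identifiable
        hybrid effect (on the z-scale of the response).
        """
        sizes = self.data["size"].to_numpy()
        diffs = []
        for hybrid in (0.0, 1.0):
            new = pd.DataFrame({"size": sizes, "is_hybrid": hybrid})
            (X,) = patsy.build_design_matrices([self.design_info], new)
            diffs.append(np.asarray(X) @ self.params.to_numpy())
        return float(np.mean(diffs[1] - diffs[0]))

    def credible_intervals(self, n_sim: int = 10_000, seed: int = 0,
                           level: float = 0.95) -> pd.DataFrame:
        """Percentile intervals from the normal posterior approximation."""
        rng = np.random.default_rng(seed)
        cov = self.cov.to_numpy()
        try:
            chol = np.linalg.cholesky(cov)
            draws = self.params.to_numpy() \
                + rng.standard_normal((n_sim, len(self.params))) @ chol.T
        except np.linalg.LinAlgError:
            logger.warning("singular coefficient covariance; using "
                           "eigenvalue square root")
            w, v = np.linalg.eigh(cov)
            root = v @ np.diag(np.sqrt(np.clip(w, 0, None)))
            draws = self.params.to_numpy() \
                + rng.standard_normal((n_sim, len(self.params))) @ root.T
        alpha = (1 - level) / 2
        lower = np.percentile(draws, 100 * alpha, axis=0)
        upper = np.percentile(draws, 100 * (1 - alpha), axis=0)
        out = pd.DataFrame({"estimate": self.params,
                            "lower": lower, "upper": upper})
        self.intervals = out
        return out

    def plot(self, ax=None):
        """Fitted inbred/hybrid curves with the observed points."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        curves = self.fitted_curves()
        for hybrid, grp in curves.groupby("is_hybrid"):
            ax.plot(grp["size_z"], grp["fitted"],
                    label="hybrid" if hybrid else "inbred")
        for hybrid, marker in ((False, "o"), (True, "^")):
            sub = self.data[self.data["is_hybrid"] == float(hybrid)]
            ax.scatter(sub["size"], sub["expr"], s=8, alpha=0.4,
                       marker=marker)
        ax.set_xlabel("rosette size (z-score)")
        ax.set_ylabel("expression (z-score)")
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = [f"Size-spline LMM (random structure: "
                 f"{self.random_structure})",
                 f"  residual SD: {np.sqrt(self.scale):.4f}"]
        table = self.intervals if self.intervals is not None else \
            pd.DataFrame({"estimate": self.params})
        lines.append(table.to_string(float_format=lambda v: f"{v: .4f}"))
        return "\n".join(lines)


class SizeSplineModel:
    """Mixed model of (cluster-mean) expression against rosette size.

    ``response`` is one value per sample; expression and size are z-scored
    internally.  The random-effect structure degrades
    (IsHybrid | batch) -> (1 | batch) -> none on convergence failure or
    when only one library batch exists; each degradation is logged.
    """

    def __init__(self, response: pd.Series, meta: pd.DataFrame,
                 df: int = 4):
        meta = meta.loc[response.index]
        if meta["rosette_area"].isna().any():
            raise ConfigurationError("rosette areas required for every sample")
        self.df = df
        self.data = pd.DataFrame({
            "expr": stats.zscore(response.to_numpy(dtype=float)),
            "size": stats.zscore(meta["rosette_area"].to_numpy(dtype=float)),
            "is_hybrid": meta["is_hybrid"].astype(float).to_numpy(),
            "library_batch": meta["library_batch"].to_numpy(),
        }, index=response.index)

    @property
    def formula(self) -> str:
        return (f"expr ~ is_hybrid + cr(size, df={self.df}) "
                f"+ cr(size, df={self.df}):is_hybrid")

    def fit(self) -> SizeSplineResults:
        data = self.data
        n_batches = data["library_batch"].nunique()
        attempts = []
        if n_batches >= 2:
            attempts = [("hybrid-slope", "~is_hybrid"), ("intercept", "1")]
        else:
            logger.warning("single library batch; fitting fixed effects only")
        for name, re_formula in attempts:
            try:
                model = smf.mixedlm(self.formula, data,
                                    groups=data["library_batch"],
                                    re_formula=re_formula)
                res = model.fit(reml=True, method="lbfgs", maxiter=200)
                if not np.all(np.isfinite(res.fe_params)):
                    raise ValueError("non-finite fixed effects")
                if not getattr(res, "converged", True):
                    raise ValueError("optimizer did not converge")
                k = len(res.fe_params)
                cov = np.asarray(res.cov_params())[:k, :k]
                diag = np.diag(cov)
                if (not np.all(np.isfinite(cov)) or np.any(diag < 0)
                        or diag.max() > 1e3):
                    raise ValueError("ill-conditioned coefficient covariance")
                design_info = model.data.design_info
                return SizeSplineResults(
                    params=res.fe_params,
                    cov=pd.DataFrame(cov, index=res.fe_params.index,
                                     columns=res.fe_params.index),
                    scale=res.scale, random_structure=name,
                    design_info=design_info, data=data)
            except Exception as exc:
                logger.warning("random structure %s failed (%s); degrading",
                               name, exc)
        # fixed-effects fallback
        res = smf.ols(self.formula, data).fit()
        return SizeSplineResults(
            params=res.params,
            cov=pd.DataFrame(np.asarray(res.cov_params()),
                             index=res.params.index,
                             columns=res.params.index),
            scale=res.scale if hasattr(res, "scale") else res.mse_resid,
            random_structure="none",
            design_info=res.model.data.design_info,
            data=data)


def fit_size_spline(cluster_mean: pd.Series, meta: pd.DataFrame,
                    df: int = 4) -> SizeSplineResults:
    """Convenience wrapper: fit the size-spline LMM for one cluster mean."""
    return SizeSplineModel(cluster_mean, meta, df=df).fit()


# ---------------------------------------------------------------------------
# cluster/size correlations
# ---------------------------------------------------------------------------

def cluster_size_correlation(assignment: ClusterAssignment,
                             expr: ExpressionMatrix, meta: pd.DataFrame,
                             treatment: str | None = None
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r of each cluster's mean expression with rosette area.

    Returns (per-cluster table, cluster x cluster correlation matrix of
    the cluster averages across samples).  ``treatment`` restricts the
    samples to one arm (recommended: the treatment-driven size reduction
    otherwise dominates the correlation).  Zero-variance cluster means
    yield missing correlations.
    """
    meta = meta.loc[expr.sample_ids]
    if treatment is not None:
        meta = meta[meta["treatment"] == treatment]
        expr = expr.subset_samples(meta.index)
    area = meta["rosette_area"].to_numpy(dtype=float)
    rows = []
    means = {}
    for c in sorted(assignment.labels.unique()):
        genes = assignment.genes_in(c)
        m = expr.data.loc[genes].mean(axis=0).to_numpy()
        means[c] = m
        if np.std(m) == 0 or np.std(area) == 0:
            rows.append((c, len(genes), np.nan, np.nan))
            continue
        r, p = stats.pearsonr(m, area)
        rows.append((c, len(genes), r, p))
    table = pd.DataFrame(rows, columns=["cluster", "n_genes", "r", "p"]) \
        .set_index("cluster")
    mean_frame = pd.DataFrame(means)
    corr = mean_frame.corr()
    return table, corr
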