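"""Upstream rare-allele burden, expression rank and genetic distance.

Rare (MAF < 0.05) biallelic SNPs in the strand-aware 1 kb window upstream
of each gene are counted per accession (site counts: a site contributes 1
when the accession carries at least one alternate allele; an allele-dosage
mode is available).  F1 burdens are the mean of the two parental counts.

Burden is then related to expression rank: within a stratum (inbreds or
F1s, mock or BTH), samples are ranked per gene by expression, the mean
burden of all samples sharing a rank is averaged over a gene list, the
trend is LOWESS-smoothed, and the top and bottom expression-rank deciles
are compared by a Wilcoxon rank-sum test.  Hybrid growth advantage enters
through the rank-wise Pearson correlation of parental burden with rosette
size MPH.  Genetic distances are SNP Hamming distances over common
(MAF > 0.2) sites, optionally restricted to gene-body + 1 kb windows.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import ConfigurationError, ExpressionMatrix, \
    InsufficientDataError
from .synthetic import GenotypePanel, _upstream_interval

__all__ = [
    "load_genotypes_vcf", "count_upstream_rare", "add_f1_burden",
    "rank_burden_profile", "burden_mph_correlation",
    "genetic_distance", "distance_mph_correlation",
]

logger = logging.getLogger(__name__)

STRATA = {
    "inbred-mock": (False, "mock"), "inbred-BTH": (False, "BTH"),
    "F1-mock": (True, "mock"), "F1-BTH": (True, "BTH"),
}


def load_genotypes_vcf(path: str) -> GenotypePanel:
    """Read biallelic SNPs from a VCF into a genotype panel (cyvcf2).

    Missing genotypes are treated as reference (logged).  A MAF INFO field
    is preferred when present; otherwise MAF is computed from the panel.
    """
    from cyvcf2 import VCF
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    rows, dosages = [], []
    n_missing = 0
    for k, var in enumerate(vcf):
        if len(var.ALT) != 1:
            continue
        gt = np.asarray(var.gt_types)        # 0 hom-ref, 1 het, 2 hom-alt, 3 missing
        n_missing += int((gt == 3).sum())
        dos = np.where(gt == 3, 0, np.where(gt == 1, 1, np.where(gt == 2, 2,
                                                                 0)))
        maf = var.INFO.get("MAF")
        if maf is None:
            af = dos.sum() / (2 * len(dos))
            maf = min(af, 1 - af)
        sid = var.ID or f"site{k + 1:07d}"
        rows.append((sid, var.CHROM, var.POS, var.REF, var.ALT[0],
                     var.INFO.get("GENE", ""), "", float(maf), maf < 0.05))
        dosages.append(dos.astype(np.int8))
    if n_missing:
        logger.warning("%d missing genotype calls treated as reference",
                       n_missing)
    sites = pd.DataFrame(rows, columns=[
        "snp_id", "chrom", "pos", "ref", "alt", "gene_id", "region",
        "maf", "is_rare"]).set_index("snp_id", drop=False)
    dosage = pd.DataFrame(np.vstack(dosages).T if dosages
                          else np.empty((len(samples), 0), dtype=np.int8),
                          index=pd.Index(samples, name="accession"),
                          columns=sites.index)
    return GenotypePanel(sites=sites, dosage=dosage)


def _window_table(annotation: pd.DataFrame, window: int) -> pd.DataFrame:
    missing = annotation.index[annotation["tss"].isna()] \
        if annotation["tss"].isna().any() else []
    if len(missing):
        logger.warning("%d genes without TSS excluded", len(missing))
    ann = annotation.dropna(subset=["tss"])
    lo, hi = [], []
    for _, row in ann.iterrows():
        if window == 1000:
            a, b = _upstream_interval(row)
        else:
            if row["strand"] == "+":
                a, b = max(1, row["tss"] - window), row["tss"] - 1
            else:
                a, b = row["tss"] + 1, row["tss"] + window
        lo.append(a)
        hi.append(b)
    return pd.DataFrame({"chrom": ann["chromosome"], "lo": lo, "hi": hi},
                        index=ann.index)


def count_upstream_rare(genotypes: GenotypePanel, annotation: pd.DataFrame,
                        window: int = 1000, maf_max: float = 0.05,
                        dosage_mode: bool = False) -> pd.DataFrame:
    """Accession x gene counts of rare SNP sites in upstream windows.

    The window is strand-aware and excludes the TSS itself: [TSS-1000,
    TSS-1] for '+' genes, [TSS+1, TSS+1000] in genomic coordinates for '-'
    genes.  ``dosage_mode`` sums alternate-allele dosages instead of
    carrier sites.
    """
    sites = genotypes.sites
    rare = sites[sites["maf"] < maf_max]
    windows = _window_table(annotation, window)
    acc = genotypes.dosage.index
    out = pd.DataFrame(0, index=acc, columns=annotation.index, dtype=float)
    by_chrom = {c: g.sort_values("pos") for c, g in rare.groupby("chrom")}
    for gid, w in windows.iterrows():
        chrom_sites = by_chrom.get(w["chrom"])
        if chrom_sites is None:
            continue
        pos = chrom_sites["pos"].to_numpy()
        a = np.searchsorted(pos, w["lo"], side="left")
        b = np.searchsorted(pos, w["hi"], side="right")
        if b <= a:
            continue
        snp_ids = chrom_sites.index[a:b]
        dos = genotypes.dosage[snp_ids].to_numpy()
        out[gid] = dos.sum(axis=1) if dosage_mode \
            else (dos >= 1).sum(axis=1)
    return out


def add_f1_burden(burden: pd.DataFrame, trios: pd.DataFrame) -> pd.DataFrame:
    """Append F1 rows as the exact mean of the two parental rows."""
    f1_rows = {}
    for _, row in trios.iterrows():
        f1_rows[row["f1"]] = (burden.loc[row["parent_a"]]
                              + burden.loc[row["parent_b"]]) / 2.0
    return pd.concat([burden, pd.DataFrame(f1_rows).T])


def rank_burden_profile(expr: ExpressionMatrix, burden: pd.DataFrame,
                        gene_list, meta: pd.DataFrame, stratum: str,
                        lowess_frac: float = 0.5) -> dict:
    """Mean upstream rare-allele count by expression rank within a stratum.

    Per gene, stratum samples are ranked by expression (average ranks for
    ties; constant genes excluded); each sample's burden for the gene is
    its genotype's count (F1s: parental mean).  Per integer rank, burdens
    are averaged over all genes in the list; the trend is
    LOWESS-smoothed.  The top and bottom expression-rank deciles are
    compared by a one-/two-sample-free Wilcoxon rank-sum test.
    """
    if stratum not in STRATA:
        raise ConfigurationError(
            f"stratum must be one of {sorted(STRATA)}, got {stratum!r}")
    gene_list = [g for g in gene_list if g in expr.gene_ids]
    if not gene_list:
        raise ConfigurationError("gene list is empty (after intersection)")
    is_hyb, treatment = STRATA[stratum]
    meta = meta.loc[expr.sample_ids]
    sel = meta[(meta["is_hybrid"] == is_hyb)
               & (meta["treatment"] == treatment)]
    if len(sel) < 10:
        raise InsufficientDataError(
            f"stratum {stratum} has {len(sel)} samples (< 10)")
    sids = list(sel.index)
    genos = sel["genotype_id"]
    missing = set(genos) - set(burden.index)
    if missing:
        raise ConfigurationError(
            f"genotypes without burden rows: {sorted(missing)[:5]}")

    n = len(sids)
    rank_sum = np.zeros(n)
    rank_cnt = np.zeros(n)
    low_burdens, high_burdens = [], []
    k_decile = max(1, int(round(0.1 * n)))
    n_skipped = 0
    for g in gene_list:
        vals = expr.data.loc[g, sids].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            n_skipped += 1
            continue
        b = burden.loc[genos, g].to_numpy(dtype=float)
        ranks = stats.rankdata(vals, method="average")
        bucket = np.clip(np.round(ranks).astype(int) - 1, 0, n - 1)
        np.add.at(rank_sum, bucket, b)
        np.add.at(rank_cnt, bucket, 1)
        order = np.argsort(vals, kind="stable")
        low_burdens.append(b[order[:k_decile]])
        high_burdens.append(b[order[-k_decile:]])
    if n_skipped:
        logger.warning("%d constant-expression genes excluded", n_skipped)
    with np.errstate(invalid="ignore"):
        profile = np.where(rank_cnt > 0, rank_sum / rank_cnt, np.nan)
    ranks = np.arange(1, n + 1)
    ok = ~np.isnan(profile)
    smooth = np.full(n, np.nan)
    if ok.sum() >= 3:
        sm = lowess(profile[ok], ranks[ok], frac=lowess_frac, it=2,
                    return_sorted=False)
        smooth[ok] = sm
    low = np.concatenate(low_burdens) if low_burdens else np.array([])
    high = np.concatenate(high_burdens) if high_burdens else np.array([])
    if low.size and np.ptp(np.concatenate([low, high])) > 0:
        p = stats.mannwhitneyu(low, high, alternative="two-sided").pvalue
    else:
        p = 1.0
    return {
        "profile": pd.DataFrame({"rank": ranks, "mean_burden": profile,
                                 "lowess": smooth}),
        "decile_p": float(p),
        "bottom_decile_mean": float(low.mean()) if low.size else np.nan,
        "top_decile_mean": float(high.mean()) if high.size else np.nan,
        "n_genes": len(gene_list) - n_skipped,
        "n_samples": n,
    }


def burden_mph_correlation(burden: pd.DataFrame, size_mph: pd.Series,
                           trios: pd.DataFrame, gene_list
                           ) -> tuple[pd.DataFrame, float, float]:
    """Rank-wise correlation of parental rare-allele burden with size MPH.

    F1s are ranked by the mean parental rare-allele count averaged over the
    gene list; per rank the burden and the rosette-size MPH are tabulated
    and the Pearson r between the two profiles is returned.  (Ranking by
    single-gene burdens is dominated by ties — upstream burden is sparse —
    so the gene-list average is the ranking variable.)
    """
    trios = trios[trios["trio_id"].isin(size_mph.index)]
    if len(trios) < 10:
        raise InsufficientDataError(
            f"burden-MPH correlation needs >= 10 trios, got {len(trios)}")
    gene_list = [g for g in gene_list if g in burden.columns]
    if not gene_list:
        raise ConfigurationError("gene list empty (after intersection)")
    n = len(trios)
    y = size_mph.loc[trios["trio_id"]].to_numpy(dtype=float)
    pb = (burden.loc[trios["parent_a"], gene_list].to_numpy()
          + burden.loc[trios["parent_b"], gene_list].to_numpy()) / 2.0
    mean_burden = pb.mean(axis=1)
    order = np.argsort(mean_burden, kind="stable")
    burden_by_rank = mean_burden[order]
    mph_by_rank = y[order]
    table = pd.DataFrame({"rank": np.arange(1, n + 1),
                          "mean_parental_burden": burden_by_rank,
                          "mean_size_mph": mph_by_rank})
    if np.ptp(burden_by_rank) == 0 or np.ptp(mph_by_rank) == 0:
        logger.warning("degenerate rank profile; correlation undefined")
        return table, np.nan, np.nan
    r, p = stats.pearsonr(burden_by_rank, mph_by_rank)
    return table, float(r), float(p)


def genetic_distance(genotypes: GenotypePanel, maf_min: float = 0.2,
                     subset_windows: pd.DataFrame | None = None
                     ) -> pd.DataFrame:
    """Pairwise SNP Hamming distances over common (MAF > maf_min) sites.

    ``subset_windows`` (columns chrom, lo, hi; 1-based inclusive)
    restricts to sites inside the windows, e.g. gene body + 1 kb upstream
    of a gene list.  Distance = number of sites with differing genotype
    calls; symmetric with zero diagonal.
    """
    sites = genotypes.sites[genotypes.sites["maf"] > maf_min]
    if subset_windows is not None:
        keep = []
        for c, grp in sites.groupby("chrom"):
            wins = subset_windows[subset_windows["chrom"] == c]
            if wins.empty:
                continue
            pos = grp["pos"].to_numpy()
            inside = np.zeros(len(pos), dtype=bool)
            for _, w in wins.iterrows():
                inside |= (pos >= w["lo"]) & (pos <= w["hi"])
            keep.extend(grp.index[inside])
        sites = sites.loc[keep]
    if len(sites) == 0:
        raise ConfigurationError(
            f"no sites remain after MAF > {maf_min} "
            f"{'and window subsetting' if subset_windows is not None else ''}")
    X = genotypes.dosage[sites.index].to_numpy(dtype=np.int16)
    n = X.shape[0]
    dist = np.zeros((n, n), dtype=int)
    for i in range(n):
        dist[i] = (X != X[i]).sum(axis=1)
    return pd.DataFrame(dist, index=genotypes.dosage.index,
                        columns=genotypes.dosage.index)


def distance_mph_correlation(distances: pd.DataFrame, size_mph: pd.Series,
                             trios: pd.DataFrame) -> tuple[float, float]:
    """Pearson r between parental genetic distance and trio size MPH."""
    trios = trios[trios["trio_id"].isin(size_mph.index)]
    d = np.array([distances.loc[row["parent_a"], row["parent_b"]]
                  for _, row in trios.iterrows()], dtype=float)
    y = size_mph.loc[trios["trio_id"]].to_numpy(dtype=float)
    if np.ptp(d) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(d, y)
    return float(r), float(p)
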