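"""Synthetic trio panels with known ground truth.

Generates a panel of inbred accessions, F1 crosses, a genes x samples log2
expression matrix, rosette-size phenotypes and upstream rare-allele
genotypes, with every planted signal recorded in a truth table so the
downstream callers can be scored against it.

The generative model mirrors the structure the analysis assumes:

* additive genes — F1 expression equals the mid-parent value (MPV) plus
  noise; accession effects are Gaussian on the log2 scale.
* dominant genes — driven by large-effect biallelic cis variation
  (presence/absence-like low-expression alleles segregating across
  accessions, the classic source of below-MPV expression dominance in
  A. thaliana); the F1 sits ``dominance_shift`` log2 units below (or above)
  the MPV, clamped at the extreme parent.
* "neither" genes — F1 expression is decoupled from the MPV (idiosyncratic
  per hybrid), with a spread matched to the pairwise-MPV null.
* planted expression clusters — two groups of dominant genes share a common
  low-allele pattern; rosette size is generated from their cluster-mean
  expression with opposite signs, plus a hybrid offset and a rare-allele
  burden penalty, so size covariation and burden analyses have a known
  answer.

All randomness flows from ``SimConfig.seed`` through named child streams
(`numpy` ``SeedSequence`` spawn keys), so each stage is independently
reproducible and the whole panel is byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimConfig
from .containers import ConfigurationError, ExpressionMatrix, validate_trios

__all__ = [
    "GenotypePanel", "SimPanel",
    "generate_gene_annotation", "generate_genotypes", "generate_trios",
    "simulate_expression", "simulate_phenotypes", "simulate_panel",
]

# spread of the per-gene Gaussian accession effect around each cis allele
WITHIN_ALLELE_SD = 0.25
# low-expression cis allele effect range (log2) for dominant genes
CIS_DELTA_RANGE = (2.0, 4.0)
# frequency range of the low allele
CIS_FREQ_RANGE = (0.3, 0.7)
CHROMOSOMES = ("Chr1", "Chr2", "Chr3", "Chr4", "Chr5")
GENE_SPACING = 6000
GENE_LENGTH = 2000
UPSTREAM_WINDOW = 1000


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Child generator for a named stage; deterministic in (seed, key)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=key))


@dataclass
class GenotypePanel:
    """Biallelic SNP sites plus per-accession alternate-allele dosages."""

    sites: pd.DataFrame       # snp_id, chrom, pos, ref, alt, gene_id, region, maf, is_rare
    dosage: pd.DataFrame      # accessions x snp_id, values in {0, 2} (inbreds)

    @property
    def accessions(self) -> pd.Index:
        return self.dosage.index


@dataclass
class SimPanel:
    """Everything one simulated study produces."""

    config: SimConfig
    annotation: pd.DataFrame
    genotypes: GenotypePanel
    burden: pd.DataFrame      # accessions x genes, rare upstream site counts
    trios: pd.DataFrame
    expression: ExpressionMatrix   # log2 scale
    meta: pd.DataFrame
    truth: pd.DataFrame


def _accession_ids(n: int) -> list[str]:
    return [f"acc{i + 1:03d}" for i in range(n)]


def _gene_ids(n: int) -> list[str]:
    return [f"g{i + 1:05d}" for i in range(n)]


def generate_gene_annotation(config: SimConfig) -> pd.DataFrame:
    """Deterministic gene layout: genes round-robin over five chromosomes,
    alternating strand, fixed spacing, protein-coding, length >= 150 nt."""
    genes = _gene_ids(config.n_genes)
    rows = []
    per_chrom: dict[str, int] = {c: 0 for c in CHROMOSOMES}
    for idx, gid in enumerate(genes):
        chrom = CHROMOSOMES[idx % len(CHROMOSOMES)]
        k = per_chrom[chrom]
        per_chrom[chrom] += 1
        start = 2000 + k * GENE_SPACING          # 1-based inclusive
        end = start + GENE_LENGTH - 1
        strand = "+" if idx % 2 == 0 else "-"
        tss, tts = (start, end) if strand == "+" else (end, start)
        rows.append((gid, chrom, start, end, strand, tss, tts,
                     "protein_coding", GENE_LENGTH))
    return pd.DataFrame(rows, columns=[
        "gene_id", "chromosome", "start", "end", "strand", "tss", "tts",
        "biotype", "effective_length"]).set_index("gene_id", drop=False)


def _upstream_interval(row) -> tuple[int, int]:
    """1-based inclusive upstream window, strand-aware, excluding the TSS.

    '+' gene: [TSS-1000, TSS-1]; '-' gene: [TSS+1, TSS+1000]."""
    if row["strand"] == "+":
        return max(1, row["tss"] - UPSTREAM_WINDOW), row["tss"] - 1
    return row["tss"] + 1, row["tss"] + UPSTREAM_WINDOW


def generate_genotypes(config: SimConfig,
                       annotation: pd.DataFrame | None = None
                       ) -> tuple[GenotypePanel, pd.DataFrame]:
    """Plant biallelic SNPs in upstream windows and gene bodies.

    Each gene's 1 kb upstream window receives Poisson(``burden_rate``) rare
    variants (panel MAF < 0.05 whenever the panel is large enough) plus a
    background of common variants (MAF >= 0.2) used for genetic-distance
    computation.  Accessions differ in their genome-wide rare-allele load
    (a Gamma-distributed propensity), so total burden varies realistically
    across the panel.  Returns the genotype panel and the accession x gene
    BurdenTable of rare upstream site counts.
    """
    config.validate()
    if annotation is None:
        annotation = generate_gene_annotation(config)
    rng = _rng(config.seed, 1)
    n = config.n_inbreds
    accessions = _accession_ids(n)
    # genome-wide rare-load propensity per accession (mean 1, right-skewed)
    load = rng.gamma(2.0, 0.5, size=n)
    load_p = load / load.sum()
    max_rare_carriers = max(1, int(np.ceil(0.05 * n)) - 1)

    site_rows = []
    dosage_cols = {}
    burden = np.zeros((n, config.n_genes), dtype=int)
    snp_counter = 0
    common_lo = max(1, int(np.ceil(0.25 * n)))
    common_hi = max(common_lo, n // 2)

    for g_idx, (gid, row) in enumerate(annotation.iterrows()):
        lo, hi = _upstream_interval(row)
        # --- rare upstream variants -----------------------------------
        n_rare = rng.poisson(config.burden_rate)
        n_rare = min(n_rare, hi - lo + 1)
        if n_rare > 0:
            positions = np.sort(rng.choice(np.arange(lo, hi + 1),
                                           size=n_rare, replace=False))
            for pos in positions:
                k = int(rng.integers(1, max_rare_carriers + 1))
                carriers = rng.choice(n, size=k, replace=False, p=load_p)
                dos = np.zeros(n, dtype=np.int8)
                dos[carriers] = 2
                snp_counter += 1
                sid = f"snp{snp_counter:07d}"
                site_rows.append((sid, row["chromosome"], int(pos), "A", "T",
                                  gid, "upstream", k / n, True))
                dosage_cols[sid] = dos
                burden[carriers, g_idx] += 1
        # --- common variants (upstream + gene body) -------------------
        for region, span, count in (
                ("upstream", (lo, hi), config.n_common_upstream),
                ("genebody", (row["start"], row["end"]),
                 config.n_common_genebody)):
            if count <= 0:
                continue
            positions = np.sort(rng.choice(
                np.arange(span[0], span[1] + 1), size=count, replace=False))
            for pos in positions:
                k = int(rng.integers(common_lo, common_hi + 1))
                carriers = rng.choice(n, size=k, replace=False)
                dos = np.zeros(n, dtype=np.int8)
                dos[carriers] = 2
                snp_counter += 1
                sid = f"snp{snp_counter:07d}"
                site_rows.append((sid, row["chromosome"], int(pos), "C", "G",
                                  gid, region, k / n, False))
                dosage_cols[sid] = dos

    sites = pd.DataFrame(site_rows, columns=[
        "snp_id", "chrom", "pos", "ref", "alt", "gene_id", "region",
        "maf", "is_rare"]).set_index("snp_id", drop=False)
    dosage = pd.DataFrame(dosage_cols, index=pd.Index(accessions,
                                                      name="accession"))
    burden_df = pd.DataFrame(burden, index=dosage.index,
                             columns=annotation.index)
    return GenotypePanel(sites=sites, dosage=dosage), burden_df


def generate_trios(config: SimConfig, accessions: list[str]) -> pd.DataFrame:
    """Random crosses: n_trios parent pairs with unique F1 ids.

    Without parent reuse each accession appears in at most one trio, which
    requires 2 * n_trios <= n_inbreds; with reuse, unordered parent pairs
    are still kept distinct.
    """
    rng = _rng(config.seed, 2)
    n = len(accessions)
    if not config.allow_parent_reuse:
        if 2 * config.n_trios > n:
            raise ConfigurationError(
                f"{config.n_trios} trios need {2 * config.n_trios} distinct "
                f"parents but only {n} accessions exist (no-reuse policy)")
        chosen = rng.choice(n, size=2 * config.n_trios, replace=False)
        pairs = [(chosen[2 * t], chosen[2 * t + 1])
                 for t in range(config.n_trios)]
    else:
        max_pairs = n * (n - 1) // 2
        if config.n_trios > max_pairs:
            raise ConfigurationError(
                f"{config.n_trios} distinct crosses impossible with {n} "
                f"accessions ({max_pairs} unordered pairs)")
        seen = set()
        pairs = []
        while len(pairs) < config.n_trios:
            a, b = rng.choice(n, size=2, replace=False)
            key = (min(a, b), max(a, b))
            if key not in seen:
                seen.add(key)
                pairs.append((a, b))
    trios = pd.DataFrame({
        "trio_id": [f"trio{t + 1:03d}" for t in range(config.n_trios)],
        "parent_a": [accessions[a] for a, _ in pairs],
        "parent_b": [accessions[b] for _, b in pairs],
        "f1": [f"f1_{t + 1:03d}" for t in range(config.n_trios)],
    })
    validate_trios(trios)
    return trios


def _allocate_labels(config: SimConfig, rng: np.random.Generator
                     ) -> np.ndarray:
    """Deterministic counts by rounding; assignment by seeded permutation."""
    n = config.n_genes
    n_add = int(round(config.frac_additive * n))
    n_dom = int(round(config.frac_dominant * n))
    n_below = int(round(config.frac_dominant_below * n_dom))
    labels = np.array(["neither"] * n, dtype=object)
    order = rng.permutation(n)
    labels[order[:n_add]] = "additive"
    labels[order[n_add:n_add + n_below]] = "dominant_below"
    labels[order[n_add + n_below:n_add + n_dom]] = "dominant_above"
    return labels


def simulate_expression(config: SimConfig, trios: pd.DataFrame,
                        burdens: pd.DataFrame
                        ) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate the log2 expression matrix, sample sheet and truth table.

    Inbred expression = gene baseline + accession (cis) effect
    - burden_effect x rare-allele count + batch effects + noise.  Additive
    genes put the F1 at the MPV; dominant genes shift it by
    ``dominance_shift`` toward (and clamped at) the extreme parent;
    "neither" genes give each F1 an idiosyncratic level.  BTH samples of
    responsive genes receive a per-gene treatment effect.
    """
    config.validate()
    accessions = list(burdens.index)
    missing = (set(trios["parent_a"]) | set(trios["parent_b"])) - set(accessions)
    if missing:
        raise ConfigurationError(
            f"trios reference accessions absent from burden table: "
            f"{sorted(missing)[:5]}")
    genes = list(burdens.columns)
    n_genes = len(genes)
    n_acc = len(accessions)
    n_f1 = len(trios)
    rng = _rng(config.seed, 3)

    labels = _allocate_labels(config, rng)
    is_dom = np.char.startswith(labels.astype(str), "dominant")

    # planted size-linked clusters: two disjoint groups of dominant_below
    # genes sharing a low-allele pattern (co-regulated upstream haplotype)
    below_idx = np.flatnonzero(labels == "dominant_below")
    k_cluster = min(config.cluster_genes, len(below_idx) // 2)
    pos_cluster = below_idx[:k_cluster]
    neg_cluster = below_idx[k_cluster:2 * k_cluster]
    cluster_of = np.array([""] * n_genes, dtype=object)
    cluster_of[pos_cluster] = "positive"
    cluster_of[neg_cluster] = "negative"

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, n_genes)

    # accession-level (cis) effects
    acc_eff = rng.normal(0.0, config.accession_sd, (n_acc, n_genes))
    delta = rng.uniform(*CIS_DELTA_RANGE, n_genes)
    qlo = rng.uniform(*CIS_FREQ_RANGE, n_genes)
    low_allele = rng.random((n_acc, n_genes)) < qlo[None, :]
    # cluster members share one carrier pattern per cluster
    for members in (pos_cluster, neg_cluster):
        if len(members) > 0:
            shared = rng.random(n_acc) < float(np.mean(qlo[members]))
            low_allele[:, members] = shared[:, None]
    dom_eff = -delta[None, :] * low_allele \
        + rng.normal(0.0, WITHIN_ALLELE_SD, (n_acc, n_genes))
    acc_eff = np.where(is_dom[None, :], dom_eff, acc_eff)

    # genotype-level true means: inbreds
    mu_inbred = baseline[None, :] + acc_eff \
        - config.burden_effect * burdens.to_numpy(dtype=float)

    # F1 genotype means from the gene-action rules
    ia = np.array([accessions.index(a) for a in trios["parent_a"]])
    ib = np.array([accessions.index(b) for b in trios["parent_b"]])
    mpv = (mu_inbred[ia] + mu_inbred[ib]) / 2.0
    low = np.minimum(mu_inbred[ia], mu_inbred[ib])
    high = np.maximum(mu_inbred[ia], mu_inbred[ib])
    own = baseline[None, :] \
        + rng.normal(0.0, config.accession_sd / np.sqrt(2), (n_f1, n_genes)) \
        - config.burden_effect * (burdens.to_numpy(dtype=float)[ia]
                                  + burdens.to_numpy(dtype=float)[ib]) / 2.0
    mu_f1 = np.where(labels[None, :] == "additive", mpv, own)
    mu_f1 = np.where(labels[None, :] == "dominant_below",
                     np.maximum(low, mpv - config.dominance_shift), mu_f1)
    mu_f1 = np.where(labels[None, :] == "dominant_above",
                     np.minimum(high, mpv + config.dominance_shift), mu_f1)

    # treatment responsiveness
    responsive = rng.random(n_genes) < config.frac_bth_responsive
    treat_eff = np.where(responsive,
                         rng.normal(0.0, config.treatment_effect_sd, n_genes),
                         0.0)

    # batch structure
    lib_batch_eff = rng.normal(0.0, config.batch_sd, config.n_batches)
    gene_batch_scale = rng.normal(1.0, 0.3, n_genes)
    plant_batch_eff = rng.normal(0.0, config.plant_batch_sd,
                                 config.n_plant_batches)

    # sample sheet
    genotype_ids = accessions + list(trios["f1"])
    is_hybrid = np.array([False] * n_acc + [True] * n_f1)
    mu = np.vstack([mu_inbred, mu_f1])
    treatments = ["mock", "BTH"] if config.treated else ["mock"]
    records = []
    for gi, gid in enumerate(genotype_ids):
        for treatment in treatments:
            for rep in range(1, config.n_replicates + 1):
                records.append((f"{gid}_{treatment}_r{rep}", gid,
                                bool(is_hybrid[gi]), treatment, rep, gi))
    meta = pd.DataFrame(records, columns=[
        "sample_id", "genotype_id", "is_hybrid", "treatment", "replicate",
        "_gi"])
    n_samples = len(meta)
    meta["library_batch"] = [f"lib{b + 1}" for b in
                             rng.integers(0, config.n_batches, n_samples)]
    meta["plant_batch"] = [f"pb{b + 1}" for b in
                           rng.integers(0, config.n_plant_batches, n_samples)]
    meta["mapped_reads"] = rng.integers(3_000_000, 8_000_000, n_samples)
    meta["rosette_area"] = np.nan

    lib_idx = meta["library_batch"].str.removeprefix("lib").astype(int) - 1
    pb_idx = meta["plant_batch"].str.removeprefix("pb").astype(int) - 1
    is_bth = (meta["treatment"] == "BTH").to_numpy()

    values = mu[meta["_gi"].to_numpy()]
    values = values + np.outer(is_bth, treat_eff)
    values = values + lib_batch_eff[lib_idx][:, None] * gene_batch_scale[None, :]
    values = values + plant_batch_eff[pb_idx][:, None]
    values = values + rng.normal(0.0, config.noise_sd, (n_samples, n_genes))

    expr = ExpressionMatrix(
        pd.DataFrame(values.T, index=pd.Index(genes, name="gene_id"),
                     columns=meta["sample_id"]),
        scale="log2")
    meta = meta.drop(columns="_gi").set_index("sample_id", drop=False)

    true_class = np.array(["none"] * n_genes, dtype=object)
    true_class[pos_cluster] = "positive-positive" if config.treated else "positive"
    true_class[neg_cluster] = "negative-negative" if config.treated else "negative"
    truth = pd.DataFrame({
        "gene_id": genes,
        "true_action": labels,
        "true_bth_responsive": responsive,
        "true_mph_class": true_class,
        "planted_cluster": cluster_of,
        "planted_burden_effect": config.burden_effect,
        "planted_treatment_effect": treat_eff,
    }).set_index("gene_id", drop=False)
    return expr, meta, truth


def simulate_phenotypes(config: SimConfig, expr: ExpressionMatrix,
                        meta: pd.DataFrame, burdens: pd.DataFrame,
                        truth: pd.DataFrame, trios: pd.DataFrame
                        ) -> pd.DataFrame:
    """Fill rosette areas (mm^2) from planted cluster expression.

    area = intercept + positive_coef * mean(positive-cluster genes)
         - negative_coef * mean(negative-cluster genes)
         + hybrid_offset - burden_penalty * mean parental total rare count
         (hybrids only) + noise, then a multiplicative BTH reduction.
    Cluster-mean expression enters centred on its panel mean so the
    intercept is the size of an average mock inbred.
    """
    sm = config.size_model
    rng = _rng(config.seed, 4)
    meta = meta.copy()
    pos_genes = truth.index[truth["planted_cluster"] == "positive"]
    neg_genes = truth.index[truth["planted_cluster"] == "negative"]

    def cluster_term(genes_):
        if len(genes_) == 0:
            return np.zeros(len(meta))
        m = expr.data.loc[genes_, meta["sample_id"]].mean(axis=0).to_numpy()
        return m - m.mean()

    area = np.full(len(meta), float(sm.intercept))
    area += sm.positive_coef * cluster_term(pos_genes)
    area -= sm.negative_coef * cluster_term(neg_genes)
    area += np.where(meta["is_hybrid"].to_numpy(), sm.hybrid_offset, 0.0)

    total_burden = burdens.sum(axis=1)
    parent_mean = {
        row["f1"]: (total_burden[row["parent_a"]]
                    + total_burden[row["parent_b"]]) / 2.0
        for _, row in trios.iterrows()}
    hybrid_burden = meta["genotype_id"].map(parent_mean).fillna(0.0).to_numpy()
    area -= sm.burden_penalty * np.where(meta["is_hybrid"].to_numpy(),
                                         hybrid_burden, 0.0)
    area += rng.normal(0.0, sm.noise_sd, len(meta))
    area = np.where((meta["treatment"] == "BTH").to_numpy(),
                    area * sm.bth_factor, area)
    if np.any(area <= 0):
        raise ConfigurationError(
            "size_model coefficients produced non-positive rosette areas; "
            "increase the intercept or reduce the penalties")
    meta["rosette_area"] = area
    return meta


def simulate_panel(config: SimConfig) -> SimPanel:
    """Run all generator stages in order and bundle the outputs."""
    annotation = generate_gene_annotation(config)
    genotypes, burden = generate_genotypes(config, annotation)
    trios = generate_trios(config, list(genotypes.accessions))
    expr, meta, truth = simulate_expression(config, trios, burden)
    meta = simulate_phenotypes(config, expr, meta, burden, truth, trios)
    return SimPanel(config=config, annotation=annotation,
                    genotypes=genotypes, burden=burden, trios=trios,
                    expression=expr, meta=meta, truth=truth)
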