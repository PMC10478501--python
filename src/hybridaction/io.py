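"""Readers and writers for the plain-text interchange formats.

Expression matrices, sample sheets, trio tables and truth tables travel as
TSV; gene annotation as TSV (native) or GFF3; genotypes as VCF v4.2 written
through pysam; genomic windows as BED6 (0-based half-open).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import pysam

from .containers import write_sample_sheet, write_trio_table
from .synthetic import SimPanel, GenotypePanel, _upstream_interval

__all__ = [
    "write_panel", "write_vcf", "write_bed",
    "read_annotation", "read_annotation_tsv", "read_annotation_gff3",
]

ANNOTATION_COLUMNS = ["gene_id", "chromosome", "start", "end", "strand",
                      "tss", "tts", "biotype", "effective_length"]


def write_vcf(genotypes: GenotypePanel, path: str) -> None:
    """Write the panel's biallelic SNPs as VCF v4.2 (pysam).

    Inbred accessions are emitted as homozygous calls; the panel MAF and
    the associated gene window are carried in INFO.
    """
    header = pysam.VariantHeader()
    header.add_meta("fileformat", "VCFv4.2")
    for chrom in sorted(genotypes.sites["chrom"].unique()):
        max_pos = int(genotypes.sites.loc[
            genotypes.sites["chrom"] == chrom, "pos"].max())
        header.contigs.add(chrom, length=max_pos + 10_000)
    header.formats.add("GT", 1, "String", "Genotype")
    header.info.add("MAF", 1, "Float", "Panel minor allele frequency")
    header.info.add("GENE", 1, "String", "Gene whose window contains the SNP")
    for acc in genotypes.accessions:
        header.add_sample(acc)
    sites = genotypes.sites.sort_values(["chrom", "pos"])
    dosage = genotypes.dosage
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for _, site in sites.iterrows():
            rec = vcf.new_record(
                contig=site["chrom"], start=int(site["pos"]) - 1,
                stop=int(site["pos"]), alleles=(site["ref"], site["alt"]),
                id=site["snp_id"])
            rec.info["MAF"] = float(site["maf"])
            rec.info["GENE"] = site["gene_id"]
            col = dosage[site["snp_id"]]
            for acc in genotypes.accessions:
                gt = (1, 1) if col[acc] == 2 else \
                     ((0, 1) if col[acc] == 1 else (0, 0))
                rec.samples[acc]["GT"] = gt
            vcf.write(rec)


def write_bed(annotation: pd.DataFrame, path: str,
              region: str = "genebody") -> None:
    """BED6 of gene bodies or strand-aware 1 kb upstream windows."""
    rows = []
    for _, row in annotation.iterrows():
        if region == "genebody":
            start1, end1 = row["start"], row["end"]
        elif region == "upstream":
            start1, end1 = _upstream_interval(row)
        else:
            raise ValueError(f"unknown region {region!r}")
        rows.append((row["chromosome"], start1 - 1, end1, row["gene_id"],
                     0, row["strand"]))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_annotation_tsv(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise ValueError(f"annotation TSV missing columns: {sorted(missing)}")
    return ann.set_index("gene_id", drop=False)


def read_annotation_gff3(path) -> pd.DataFrame:
    """Gene-level records from a GFF3 file.

    Reads `gene` features; biotype from the `biotype` or `gene_biotype`
    attribute (default protein_coding); effective length defaults to the
    genomic span when no explicit attribute is present.
    """
    names = ["seqid", "source", "type", "start", "end", "score", "strand",
             "phase", "attributes"]
    raw = pd.read_csv(path, sep="\t", comment="#", header=None, names=names)
    genes = raw[raw["type"] == "gene"]
    rows = []
    for _, row in genes.iterrows():
        attrs = dict(item.split("=", 1) for item in
                     str(row["attributes"]).split(";") if "=" in item)
        gid = attrs.get("ID") or attrs.get("gene_id")
        biotype = attrs.get("biotype") or attrs.get("gene_biotype") \
            or "protein_coding"
        eff_len = int(attrs.get("effective_length",
                                row["end"] - row["start"] + 1))
        tss, tts = ((row["start"], row["end"]) if row["strand"] == "+"
                    else (row["end"], row["start"]))
        rows.append((gid, row["seqid"], row["start"], row["end"],
                     row["strand"], tss, tts, biotype, eff_len))
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS) \
        .set_index("gene_id", drop=False)


def read_annotation(path) -> pd.DataFrame:
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        return read_annotation_gff3(path)
    return read_annotation_tsv(path)


def write_panel(panel: SimPanel, outdir: str) -> dict[str, str]:
    """Write every panel component as plain text; returns name -> path."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    panel.expression.to_tsv(p("expression_log2.tsv"))
    tpm = np.exp2(panel.expression.data) - panel.expression.pseudocount
    tpm.clip(lower=0.0).to_csv(p("expression_tpm.tsv"), sep="\t",
                               float_format="%.6g")
    write_sample_sheet(panel.meta, p("samples.tsv"))
    write_trio_table(panel.trios, p("trios.tsv"))
    panel.truth.to_csv(p("truth.tsv"), sep="\t", index=False,
                       float_format="%.6g")
    panel.annotation.to_csv(p("annotation.tsv"), sep="\t", index=False)
    panel.burden.to_csv(p("burden.tsv"), sep="\t")
    write_vcf(panel.genotypes, p("genotypes.vcf"))
    write_bed(panel.annotation, p("genes.bed"), region="genebody")
    write_bed(panel.annotation, p("upstream_windows.bed"), region="upstream")
    panel.config.to_yaml(p("sim_config.yaml"))
    return paths
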