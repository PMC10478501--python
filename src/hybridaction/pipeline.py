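"""End-to-end orchestration with a provenance manifest.

``run_pipeline`` executes the stages in dependency order — preprocess,
gene action, cluster/spline, treatment response, MPH covariation, variant
burden — from a single validated configuration, writes every stage's
tables under the output directory and records input checksums, parameters
and per-stage row counts in ``manifest.json``.  Re-running with the same
configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import (ConfigurationError, ExpressionMatrix,
                         read_sample_sheet, read_trio_table)
from .io import read_annotation
from .preprocessing import preprocess
from .gene_action import call_gene_action
from .cluster_spline import kmeans_cluster, SizeSplineModel, \
    cluster_size_correlation
from .treatment_response import call_bth_responsive
from .mph import MphCovariationModel, trio_size_mph
from .burden import (load_genotypes_vcf, count_upstream_rare, add_f1_burden,
                     rank_burden_profile, burden_mph_correlation,
                     genetic_distance, distance_mph_correlation)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

#: default parameter profile: the study-scale analysis constants
STUDY_DEFAULTS = {
    "min_reads": 2_000_000, "pca_sd_k": 4.0,
    "mean_min": 0.3, "cv_min": 0.15, "trim_frac": 0.1,
    "slope_min": 0.5, "r2_min": 0.4, "q_max_dominant": 0.001,
    "k": "auto", "spline_df": 4, "n_sim": 10_000,
    "n_perm": 10_000, "q_max_bth": 0.001,
    "n_extreme": 4, "k_max_mph": 12,
    "window": 1000, "maf_max": 0.05, "maf_min": 0.2,
    "seed": 0,
}


@dataclass
class PipelineConfig:
    expression: str
    samples: str
    trios: str
    annotation: str
    vcf: str | None = None
    out_dir: str = "pipeline_out"
    expression_scale: str = "linear"
    stages: list[str] = field(default_factory=lambda: [
        "preprocess", "gene_action", "cluster_spline",
        "treatment_response", "mph", "burden"])
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        merged = dict(STUDY_DEFAULTS)
        merged.update(self.params or {})
        self.params = merged
        if not isinstance(self.params["seed"], (int, np.integer)):
            raise ConfigurationError("seed must be an integer")

    def validate_paths(self) -> None:
        paths = [self.expression, self.samples, self.trios, self.annotation]
        if self.vcf and "burden" in self.stages:
            paths.append(self.vcf)
        missing = [p for p in paths if p and not os.path.exists(p)]
        if missing:
            raise ConfigurationError(f"missing input files: {missing}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(frame: pd.DataFrame, path: str, index: bool = True) -> int:
    frame.to_csv(path, sep="\t", index=index, float_format="%.8g")
    return len(frame)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns the manifest dict."""
    config.validate_paths()
    os.makedirs(config.out_dir, exist_ok=True)
    p = config.params
    manifest = {
        "version": __version__,
        "inputs": {name: {"path": path, "sha256": _sha256(path)}
                   for name, path in [
                       ("expression", config.expression),
                       ("samples", config.samples),
                       ("trios", config.trios),
                       ("annotation", config.annotation),
                       ("vcf", config.vcf)] if path},
        "params": {k: v for k, v in p.items()},
        "stages": {},
    }

    def out(name):
        return os.path.join(config.out_dir, name)

    try:
        raw = ExpressionMatrix.read_tsv(config.expression,
                                        scale=config.expression_scale)
        meta = read_sample_sheet(config.samples)
        trios = read_trio_table(config.trios)
        annotation = read_annotation(config.annotation)

        # ---- preprocess --------------------------------------------------
        if "preprocess" in config.stages:
            expr, meta, report = preprocess(
                raw, annotation, meta, min_reads=p["min_reads"],
                pca_sd_k=p["pca_sd_k"], mean_min=p["mean_min"],
                cv_min=p["cv_min"], trim_frac=p["trim_frac"])
            expr.to_tsv(out("expression_filtered.tsv"))
            _write(report, out("filter_report.tsv"), index=False)
            manifest["stages"]["preprocess"] = {
                "genes": expr.shape[0], "samples": expr.shape[1],
                "removed": len(report)}
        else:
            expr = raw if raw.scale == "log2" else raw.to_log2()

        # ---- gene action -------------------------------------------------
        calls = None
        if "gene_action" in config.stages:
            calls = call_gene_action(
                expr, meta, trios, slope_min=p["slope_min"],
                r2_min=p["r2_min"], q_max=p["q_max_dominant"])
            _write(calls, out("gene_action_calls.tsv"))
            for name, genes in [
                    ("additive", calls.index[calls["action"] == "additive"]),
                    ("dominant", calls.index[calls["action"] == "dominant"]),
                    ("dominant_below", calls.index[
                        (calls["action"] == "dominant")
                        & (calls["direction"] == "below_mpv")]),
                    ("dominant_above", calls.index[
                        (calls["action"] == "dominant")
                        & (calls["direction"] == "above_mpv")])]:
                with open(out(f"genes_{name}.txt"), "w") as fh:
                    fh.write("\n".join(genes) + ("\n" if len(genes) else ""))
            manifest["stages"]["gene_action"] = {
                "genes": len(calls),
                "additive": int((calls["action"] == "additive").sum()),
                "dominant": int((calls["action"] == "dominant").sum())}

        # ---- clustering + size splines ------------------------------------
        if "cluster_spline" in config.stages and calls is not None:
            dominant = list(calls.index[calls["action"] == "dominant"])
            if len(dominant) >= 4:
                assignment = kmeans_cluster(expr.data.loc[dominant],
                                            k=p["k"], seed=p["seed"])
                _write(assignment.labels.to_frame(), out("clusters.tsv"))
                table, corr = cluster_size_correlation(assignment, expr,
                                                       meta,
                                                       treatment="mock")
                _write(table, out("cluster_size_correlation.tsv"))
                _write(corr, out("cluster_cross_correlation.tsv"))
                fits = []
                curves = []
                for c in sorted(assignment.labels.unique()):
                    mean = expr.data.loc[assignment.genes_in(c)].mean(axis=0)
                    res = SizeSplineModel(mean, meta,
                                          df=p["spline_df"]).fit()
                    ci = res.credible_intervals(n_sim=p["n_sim"],
                                                seed=p["seed"])
                    ci = ci.assign(cluster=c)
                    fits.append(ci)
                    curves.append(res.fitted_curves().assign(cluster=c))
                _write(pd.concat(fits), out("spline_fits.tsv"))
                _write(pd.concat(curves, ignore_index=True),
                       out("spline_curves.tsv"), index=False)
                manifest["stages"]["cluster_spline"] = {
                    "k": assignment.k, "genes": len(dominant)}
            else:
                logger.warning("too few dominant genes for clustering")
                manifest["stages"]["cluster_spline"] = {"skipped": True}

        # ---- treatment response -------------------------------------------
        responsive: list[str] = []
        if "treatment_response" in config.stages:
            bth = call_bth_responsive(expr, meta, n_perm=p["n_perm"],
                                      q_max=p["q_max_bth"], seed=p["seed"])
            _write(bth.frame, out("bth_calls.tsv"))
            responsive = bth.responsive_genes
            with open(out("genes_bth_responsive.txt"), "w") as fh:
                fh.write("\n".join(responsive)
                         + ("\n" if responsive else ""))
            manifest["stages"]["treatment_response"] = {
                "genes": len(bth.frame), "responsive": len(responsive)}

        # ---- MPH covariation ----------------------------------------------
        mph_res = None
        if "mph" in config.stages:
            genes = responsive or None
            model = MphCovariationModel(expr, meta, trios, genes=genes)
            mph_res = model.fit(seed=p["seed"], k_max=p["k_max_mph"],
                                n_extreme=p["n_extreme"])
            _write(mph_res.data.records, out("mph_records.tsv"), index=False)
            _write(mph_res.labels.to_frame(), out("mph_clusters.tsv"))
            _write(mph_res.classes, out("mph_classes.tsv"))
            _write(mph_res.tests, out("mph_tests.tsv"), index=False)
            for pattern, fname in [("negative-negative", "negative"),
                                   ("positive-positive", "positive")]:
                gl = mph_res.genes_in_class(pattern)
                with open(out(f"genes_mph_{fname}.txt"), "w") as fh:
                    fh.write("\n".join(gl) + ("\n" if gl else ""))
            manifest["stages"]["mph"] = {
                "genes": len(mph_res.labels),
                "clusters": int(mph_res.classes.shape[0])}

        # ---- variant burden -------------------------------------------------
        if "burden" in config.stages and config.vcf:
            genotypes = load_genotypes_vcf(config.vcf)
            burden = count_upstream_rare(genotypes, annotation,
                                         window=p["window"],
                                         maf_max=p["maf_max"])
            burden_f1 = add_f1_burden(burden, trios)
            _write(burden_f1, out("burden_table.tsv"))
            gene_list = (mph_res.genes_in_class("negative-negative")
                         if mph_res is not None else []) \
                or (list(calls.index[calls["action"] == "dominant"])
                    if calls is not None else list(expr.gene_ids))
            profiles = []
            for stratum in ("inbred-mock", "F1-mock"):
                try:
                    prof = rank_burden_profile(expr, burden_f1, gene_list,
                                               meta, stratum)
                    profiles.append(prof["profile"].assign(
                        stratum=stratum, decile_p=prof["decile_p"]))
                except Exception as exc:
                    logger.warning("rank profile %s failed: %s",
                                   stratum, exc)
            if profiles:
                _write(pd.concat(profiles, ignore_index=True),
                       out("rank_burden_profiles.tsv"), index=False)
            size_mph = trio_size_mph(meta, trios)
            r = np.nan
            try:
                table, r, pval = burden_mph_correlation(
                    burden, size_mph, trios, gene_list)
                _write(table, out("burden_mph.tsv"), index=False)
            except Exception as exc:
                logger.warning("burden-MPH correlation skipped: %s", exc)
            dist = genetic_distance(genotypes, maf_min=p["maf_min"])
            _write(dist, out("genetic_distance.tsv"))
            dr, dp = distance_mph_correlation(dist, size_mph, trios)
            manifest["stages"]["burden"] = {
                "sites": len(genotypes.sites),
                "burden_mph_r": None if np.isnan(r) else round(r, 6),
                "distance_mph_r": None if np.isnan(dr) else round(dr, 6)}
    except Exception:
        with open(out("FAILED"), "w") as fh:
            fh.write("pipeline failed; see logs\n")
        raise

    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
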