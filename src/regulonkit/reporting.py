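"""Pipeline orchestration, classification bookkeeping and category folds.

Runs mapping -> preprocessing -> kinetic classification -> (optional FPR)
-> promoter statistics, joins the results, and emits a JSON summary whose
category counts partition the modeled gene set, plus per-stage TSV tables.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression_data, model_fitting, promoter_analysis, regulon_mapping
from .model_fitting import FitConfig, GeneClassification

__all__ = [
    "CategoryMap",
    "RunConfig",
    "category_fold_abundance",
    "classification_summary",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("constitutive", "regulated", "complex_only", "not_modeled")


@dataclass
class CategoryMap:
    """gene_id -> functional category label (one label per gene per level)."""

    labels: pd.DataFrame  # columns: gene_id, category

    @classmethod
    def read(cls, path) -> "CategoryMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"gene_id", "category"}.issubset(df.columns):
            raise ValueError("category table needs gene_id and category columns")
        if df.duplicated(subset=["gene_id"]).any():
            raise ValueError("a gene maps to more than one label")
        return cls(labels=df)


def category_fold_abundance(gene_set, category_map: CategoryMap | pd.DataFrame,
                            genome_total: int) -> pd.DataFrame:
    """Per-category over-representation of ``gene_set`` vs the genome.

    For a category with K genes genome-wide of which k are in the set of
    size m, fold = (k / K) / (m / genome_total).  Categories with K = 0 are
    omitted.
    """
    if genome_total <= 0:
        raise ValueError("genome_total must be positive")
    labels = category_map.labels if isinstance(category_map, CategoryMap) \
        else category_map
    gene_set = set(gene_set)
    m = len(gene_set)
    if genome_total < m:
        raise ValueError("genome_total smaller than the gene set")
    rows = []
    for category, group in labels.groupby("category"):
        K = len(group)
        if K == 0:
            continue
        k = len(set(group["gene_id"]) & gene_set)
        fold = (k / K) / (m / genome_total) if m else 0.0
        rows.append({"category": category, "k": k, "K": K, "m": m,
                     "genome_total": genome_total, "fold": fold})
    return pd.DataFrame(rows, columns=["category", "k", "K", "m",
                                       "genome_total", "fold"])


def classification_summary(classifications: list[GeneClassification]) -> dict:
    """Category partition counts plus nested improvement tiers."""
    counts = {c: 0 for c in CATEGORIES}
    tier_ge10 = tier_ge20 = 0
    for cl in classifications:
        counts[cl.category] += 1
        if cl.category == "regulated":
            if cl.tier in ("ge10", "ge20"):
                tier_ge10 += 1
            if cl.tier == "ge20":
                tier_ge20 += 1
    total = len(classifications)
    assert sum(counts.values()) == total
    return {
        "n_genes": total,
        "categories": counts,
        "tiers": {"ge10": tier_ge10, "ge20": tier_ge20},
        "regulated_or_complex": counts["regulated"] + counts["complex_only"],
    }


@dataclass
class RunConfig:
    """Flat configuration for an end-to-end run.

    Parsed from a ``key = value`` text file; unset optional stages are
    skipped.
    """

    expression: str = ""
    log_base: float | None = None
    regulator_gene: str = "regulator"
    cofactor_gene: str = "cofactor"
    peaks: str = ""
    peaks_dialect: str = "xls"
    genes: str = ""
    operons: str = ""
    genome: str = ""
    tss: str = ""
    categories: str = ""
    genome_total: int = 0
    outdir: str = "regulon_out"
    seed: int = 0
    max_upstream: int = 300
    p_max: float = 0.05
    fe_min: float = 2.0
    motif: str = "TANNNT"
    run_fpr: bool = False
    n_randomizations: int = 20
    epsilon: float = 0.2
    restarts: int = 2
    steps: int = 150
    n_anchors: int = 4
    max_genes: int = 0  # 0 = no cap

    @classmethod
    def read(cls, path) -> "RunConfig":
        known = {f.name: f for f in fields(cls)}
        kwargs = {}
        with open(path) as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in known:
                    raise ValueError(f"unknown config key {key!r}")
                typ = known[key].type
                if typ in ("int", int):
                    kwargs[key] = int(value)
                elif typ in ("float", float) or key == "log_base":
                    kwargs[key] = float(value)
                elif typ in ("bool", bool):
                    kwargs[key] = value.lower() in ("1", "true", "yes")
                else:
                    kwargs[key] = value
        return cls(**kwargs)


def _stage(name: str):
    logger.info("stage %s starting", name)
    return time.monotonic()


def _stage_done(name: str, t0: float) -> None:
    logger.info("stage %s done in %.2f s", name, time.monotonic() - t0)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all configured stages and write the report bundle.

    Returns the summary dict (also written as ``summary.json``).  Every
    source of randomness is seeded from ``cfg.seed``; reruns are
    byte-identical.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "acceptance_rule":
                     f"rmse <= {cfg.epsilon} * mean(|target|)"}

    regulon_genes: list[str] | None = None
    genes = None
    if cfg.peaks and cfg.genes:
        t0 = _stage("mapping")
        try:
            peaks = regulon_mapping.read_peaks(cfg.peaks, cfg.peaks_dialect)
            genes = regulon_mapping.read_genes_gff3(cfg.genes)
            kept = regulon_mapping.filter_peaks(peaks, cfg.p_max, cfg.fe_min)
            table = regulon_mapping.assign_peaks_to_genes(
                kept, genes, cfg.max_upstream)
            if cfg.operons:
                operons = regulon_mapping.read_operons(cfg.operons)
                table = regulon_mapping.expand_operons(table, operons, genes)
            table.write(outdir / "regulon.tsv")
            summary["regulon"] = regulon_mapping.summarize_regulon(table, genes)
            regulon_genes = table.gene_ids
        except Exception as exc:
            raise RuntimeError(f"stage mapping failed: {exc}") from exc
        _stage_done("mapping", t0)

    classifications: list[GeneClassification] = []
    if cfg.expression:
        t0 = _stage("classification")
        try:
            matrix = expression_data.read_expression_matrix(
                cfg.expression, log_base=cfg.log_base)
            matrix = expression_data.normalize_timepoints(matrix)
            times = matrix.times
            smoothed = {
                gid: expression_data.smooth_profile(
                    times, matrix.values[i], n_anchors=cfg.n_anchors,
                    gene_id=gid)
                for i, gid in enumerate(matrix.gene_ids)
            }
            for name in (cfg.regulator_gene, cfg.cofactor_gene):
                if name not in smoothed:
                    raise ValueError(f"series {name!r} missing from expression")
            reg = smoothed[cfg.regulator_gene]
            cof = smoothed[cfg.cofactor_gene]
            targets = [g for g in matrix.gene_ids
                       if g not in (cfg.regulator_gene, cfg.cofactor_gene)]
            if regulon_genes is not None:
                targets = [g for g in targets if g in set(regulon_genes)]
            if cfg.max_genes:
                targets = targets[:cfg.max_genes]
            fit_cfg = FitConfig(seed=cfg.seed, epsilon=cfg.epsilon,
                                restarts=cfg.restarts, steps=cfg.steps,
                                n_randomizations=cfg.n_randomizations)
            rows = []
            for gid in targets:
                cl = model_fitting.classify_gene(times, smoothed[gid], reg,
                                                 cof, fit_cfg)
                classifications.append(cl)
                row = {"gene_id": gid, "category": cl.category,
                       "improvement": cl.improvement, "tier": cl.tier}
                for kind, fit in cl.fits.items():
                    row[f"rmse_{kind}"] = fit.rmse
                rows.append(row)
                logger.info("gene %s -> %s", gid, cl.category)
            pd.DataFrame(rows).to_csv(outdir / "classification.tsv", sep="\t",
                                      index=False)
            summary["classification"] = classification_summary(classifications)
            if cfg.run_fpr:
                t1 = _stage("fpr")
                target_matrix = expression_data.ExpressionMatrix(
                    gene_ids=targets, times=times,
                    values=np.array([matrix.row(g) for g in targets]))
                fpr = model_fitting.estimate_false_positive_rate(
                    target_matrix, matrix.row(cfg.regulator_gene), fit_cfg,
                    n_anchors=cfg.n_anchors)
                fpr.per_replicate.to_csv(outdir / "fpr_detail.tsv", sep="\t",
                                         index=False)
                summary["fpr"] = {
                    "n_randomizations": fpr.n_randomizations,
                    "fraction_accepted": fpr.fraction_accepted,
                    "fraction_false_positive": fpr.fraction_false_positive,
                }
                _stage_done("fpr", t1)
        except Exception as exc:
            raise RuntimeError(f"stage classification failed: {exc}") from exc
        _stage_done("classification", t0)

    if cfg.genome and cfg.tss:
        t0 = _stage("promoter")
        try:
            genome = promoter_analysis.read_genome_fasta(cfg.genome)
            tss = promoter_analysis.read_tss_table(cfg.tss)
            primary = promoter_analysis.filter_primary_tss(tss)
            dep_ids = set(regulon_genes) if regulon_genes is not None else None
            if dep_ids is None:
                dep_tss, ind_tss = primary, []
            else:
                dep_tss = [r for r in primary if r.gene_id in dep_ids]
                ind_tss = [r for r in primary if r.gene_id not in dep_ids]
            windows_dep = promoter_analysis.extract_windows(dep_tss, genome)
            windows_ind = promoter_analysis.extract_windows(ind_tss, genome)
            sites_dep = promoter_analysis.scan_motif(windows_dep, cfg.motif)
            sites_ind = promoter_analysis.scan_motif(windows_ind, cfg.motif)
            result = promoter_analysis.enrichment_report(sites_dep, sites_ind,
                                                         genome)
            site_rows = [{
                "gene_id": s.window.tss.gene_id, "tss": s.window.tss.position,
                "strand": s.window.tss.strand, "anchor_off": s.anchor_off,
                "motif": s.motif, "gg_class": s.gg_class,
                "upstream_dinucleotide": s.upstream_dinucleotide,
                "class": "dependent"} for s in sites_dep] + [{
                "gene_id": s.window.tss.gene_id, "tss": s.window.tss.position,
                "strand": s.window.tss.strand, "anchor_off": s.anchor_off,
                "motif": s.motif, "gg_class": s.gg_class,
                "upstream_dinucleotide": s.upstream_dinucleotide,
                "class": "independent"} for s in sites_ind]
            pd.DataFrame(site_rows).to_csv(outdir / "promoter_sites.tsv",
                                           sep="\t", index=False)
            summary["promoter"] = {
                "n_primary_tss": len(primary),
                "n_sites_dependent": result.n_sites,
                "counts": result.counts,
                "genome_gg_frequency": result.genome_gg_frequency,
                "expected_gg": result.expected_gg,
                "expected_gg_rounded": result.expected_gg_rounded,
                "fisher_p": result.fisher_p,
            }
        except Exception as exc:
            raise RuntimeError(f"stage promoter failed: {exc}") from exc
        _stage_done("promoter", t0)

    if cfg.categories and cfg.genome_total and classifications:
        t0 = _stage("enrichment")
        try:
            cmap = CategoryMap.read(cfg.categories)
            modeled = [cl.gene_id for cl in classifications
                       if cl.category in ("regulated", "complex_only")]
            folds = category_fold_abundance(modeled, cmap, cfg.genome_total)
            folds.to_csv(outdir / "category_folds.tsv", sep="\t", index=False)
            summary["category_folds"] = {
                row.category: row.fold for row in folds.itertuples()}
        except Exception as exc:
            raise RuntimeError(f"stage enrichment failed: {exc}") from exc
        _stage_done("enrichment", t0)

    payload = json.dumps(summary, indent=2, sort_keys=True)
    (outdir / "summary.json").write_text(payload + "\n")
    return summary


def configure_logging(verbose: bool = True) -> None:
    logging.basicConfig(stream=sys.stderr,
                        level=logging.INFO if verbose else logging.WARNING,
                        format="%(asctime)s %(name)s: %(message)s")
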