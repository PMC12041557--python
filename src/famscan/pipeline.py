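"""End-to-end orchestration of the comparative gene-family analysis.

Stages, in order: species completeness filtering -> gene-family filter
cascade -> trait log-transformation and brain-mass residualisation ->
single-predictor PGLS scans (lifespan, body mass, relative brain size,
gestation time, age at sexual maturity) -> two-predictor scan (lifespan +
relative brain size) -> total-gene-count control regression -> family-level
GO resampling enrichment of the expanding lifespan-associated families ->
chi-square overlap of curated gene lists with lifespan-associated genes ->
leave-one-out sensitivity of the two-predictor scan -> expression /
transcript-diversity comparison. All tabular outputs are TSV; a JSON run
report records sizes, counts, seeds and parameters for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocess
from .enrichment import (AnnotationMap, chi_square_overlap, filter_terms,
                         lift_go_to_families, sampling_enrichment)
from .pgls import ScanResult, scan_families, total_count_regression
from .phylo import read_newick
from .robustness import compare_expression, loo_scan

__all__ = ["PipelineConfig", "run_pipeline", "summarize_overlap_of_scans"]

log = logging.getLogger(__name__)

SINGLE_PREDICTORS = ("log10_mlsp", "log10_body_mass", "relative_brain_size",
                     "log10_gestation_time", "log10_age_sexual_maturity")
TWO_PREDICTORS = ("log10_mlsp", "relative_brain_size")


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full pipeline run.

    Threshold defaults: completeness strictly above 0.80; families must vary,
    reach 3 genes in some species and be present in 80% of species; scan
    significance at BH q < 0.05; term-level enrichment with 1,000 resamples,
    keeping terms on at least 50 families (family level) or 200 genes
    (gene level).
    """

    tree: str = "tree.nwk"
    counts: str = "counts.tsv"
    traits: str = "traits.tsv"
    completeness: str = "completeness.tsv"
    annotations: str = "annotations.tsv"
    membership: str = "membership.tsv"
    genelists_dir: str = "genelists"
    expression: str = "expression.tsv"
    outdir: str = "results"
    completeness_threshold: float = 0.80
    presence_fraction: float = 0.80
    min_max_count: int = 3
    alpha: float = 0.05
    n_samples: int = 1000
    min_term_families: int = 50
    min_term_genes: int = 200
    log1p_response: bool = False
    seed: int = 0

    @staticmethod
    def from_yaml(path, overrides: dict | None = None) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = PipelineConfig(**data)
        for key, value in (overrides or {}).items():
            if not hasattr(cfg, key):
                raise KeyError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                value = str(value).lower() in ("1", "true", "yes")
            elif current is not None:
                value = type(current)(value)
            setattr(cfg, key, value)
        return cfg

    def resolve(self, base: Path) -> "PipelineConfig":
        """Interpret relative input paths against a base directory."""
        out = dataclasses.replace(self)
        for name in ("tree", "counts", "traits", "completeness", "annotations",
                     "membership", "genelists_dir", "expression"):
            p = Path(getattr(self, name))
            if not p.is_absolute():
                setattr(out, name, str(base / p))
        return out


def _read_gene_lists(directory) -> dict:
    """Gene-list files (one gene per line) with optional .background companions."""
    directory = Path(directory)
    lists: dict = {}
    if not directory.is_dir():
        return lists
    for path in sorted(directory.glob("*.txt")):
        genes = {line.strip() for line in path.read_text().splitlines()
                 if line.strip()}
        bg_path = path.with_suffix(".background")
        background = None
        if bg_path.exists():
            background = {line.strip() for line in bg_path.read_text().splitlines()
                          if line.strip()}
        lists[path.stem] = (genes, background)
    return lists


def summarize_overlap_of_scans(scan_a: ScanResult, scan_b: ScanResult,
                               predictor_a: str | None = None,
                               predictor_b: str | None = None) -> dict:
    """Shared / a-only / b-only counts of significant families."""
    if set(scan_a.family_ids) != set(scan_b.family_ids):
        raise ValueError("scans cover different family universes")
    sig_a = scan_a.significant_families(predictor_a)
    sig_b = scan_b.significant_families(predictor_b)
    return {"shared": len(sig_a & sig_b), "a_only": len(sig_a - sig_b),
            "b_only": len(sig_b - sig_a)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run report (also written as JSON)."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config), "stages": {}}

    def stage(name):
        log.info("stage: %s", name)
        return report["stages"].setdefault(name, {})

    # ---- load & species filtering --------------------------------------
    s = stage("inputs")
    tree = read_newick(Path(config.tree).read_text())
    counts = preprocess.read_counts(config.counts)
    traits = preprocess.read_trait_table(config.traits)
    completeness = preprocess.read_completeness(config.completeness)
    s.update(n_tree_tips=tree.n_tips, n_families_raw=len(counts),
             n_species_counts=counts.shape[1], n_trait_species=len(traits))

    s = stage("completeness_filter")
    good = preprocess.filter_species_by_completeness(
        completeness, config.completeness_threshold)
    analysis_species = sorted(good & set(tree.tip_labels)
                              & set(counts.columns) & set(traits.index))
    dropped = sorted(set(counts.columns) - set(analysis_species))
    if dropped:
        log.warning("dropping species outside the tree/traits/completeness "
                    "intersection: %s", dropped)
    counts = counts[analysis_species]
    s.update(n_pass_completeness=len(good), n_analysis_species=len(analysis_species),
             dropped_species=dropped)

    s = stage("family_filter")
    counts = preprocess.filter_families(counts, config.presence_fraction,
                                        config.min_max_count)
    s.update(n_families_retained=len(counts))

    s = stage("trait_prep")
    traits = preprocess.log10_traits(traits)
    traits = preprocess.relative_brain_size(traits)
    s.update(n_species_with_brain_residual=
             int(traits["relative_brain_size"].notna().sum()))

    # ---- scans ----------------------------------------------------------
    scans: dict[str, ScanResult] = {}
    s = stage("single_predictor_scans")
    for pred in SINGLE_PREDICTORS:
        if pred not in traits.columns or traits[pred].notna().sum() < 4:
            log.warning("skipping scan for %s: insufficient data", pred)
            continue
        res = scan_families(counts, traits, tree, [pred], alpha=config.alpha,
                            log1p_response=config.log1p_response)
        res.write_tsv(outdir / f"scan_{pred}.tsv")
        scans[pred] = res
        s[pred] = {"n_species": len(res.species), **res.call_counts()}

    s = stage("two_predictor_scan")
    scan2 = scan_families(counts, traits, tree, TWO_PREDICTORS,
                          alpha=config.alpha,
                          log1p_response=config.log1p_response)
    scan2.write_tsv(outdir / "scan_two_predictor.tsv")
    for pred in TWO_PREDICTORS:
        s[pred] = scan2.call_counts(pred)
    s["n_species"] = len(scan2.species)
    if "log10_mlsp" in scans:
        s["overlap_with_single_mlsp"] = summarize_overlap_of_scans(
            scan2, scans["log10_mlsp"], "log10_mlsp", "log10_mlsp")
    s["shared_between_predictors"] = len(
        scan2.significant_families("log10_mlsp", "expanding")
        & scan2.significant_families("relative_brain_size", "expanding"))

    s = stage("total_count_control")
    control = total_count_regression(counts, "log10_mlsp", traits, tree)
    c = control.coef("log10_mlsp")
    s.update({k: float(v) for k, v in c.items()})

    # ---- enrichment ------------------------------------------------------
    mlsp_sig = scan2.significant_families("log10_mlsp", "expanding")
    ann_df = preprocess.read_annotation_tsv(config.annotations)
    memb_df = pd.read_csv(config.membership, sep="\t", dtype=str)
    membership = dict(zip(memb_df.iloc[:, 0], memb_df.iloc[:, 1]))
    gene_terms = AnnotationMap.from_pairs(
        zip(ann_df["element_id"], ann_df["term_id"]), background=membership)
    fam_ann_all = lift_go_to_families(gene_terms, membership)
    # restrict the enrichment background to the scanned family universe
    scanned = set(scan2.family_ids)
    fam_ann = AnnotationMap(
        {f: ts for f, ts in fam_ann_all.mapping.items() if f in scanned},
        frozenset(scanned))
    fam_ann = filter_terms(fam_ann, config.min_term_families)
    s = stage("go_enrichment_families")
    if mlsp_sig and fam_ann.terms:
        enr = sampling_enrichment(mlsp_sig, fam_ann, config.n_samples,
                                  seed=config.seed)
        enr.to_csv(outdir / "enrichment_families.tsv", sep="\t", index=False)
        s.update(n_terms_tested=len(enr),
                 n_significant=int((enr["q"] < config.alpha).sum()))
    else:
        s.update(n_terms_tested=0, n_significant=0,
                 note="no focal families or no terms above the size filter")

    s = stage("gene_list_overlap")
    focal_genes = {g for g, f in membership.items() if f in mlsp_sig}
    study_background = set(membership)
    rows = []
    for name, (genes, background) in _read_gene_lists(config.genelists_dir).items():
        res = chi_square_overlap(genes, background, focal_genes, study_background)
        rows.append({"gene_list": name, "chi2": res.chi2, "p": res.p,
                     "direction": res.direction, "log2_fold": res.log2_fold,
                     "n_background": res.n_background,
                     "unreliable": res.unreliable})
    if rows:
        pd.DataFrame(rows).to_csv(outdir / "overlap.tsv", sep="\t", index=False)
    s["n_lists"] = len(rows)
    s["significant_lists"] = [r["gene_list"] for r in rows
                              if r["p"] < config.alpha]

    # ---- robustness ------------------------------------------------------
    s = stage("leave_one_out")
    if mlsp_sig:
        loo = loo_scan(counts, traits, tree, scan2, alpha=config.alpha)
        loo.to_csv(outdir / "loo.tsv", sep="\t", index=False)
        s.update(n_refits=len(loo),
                 max_abs_cohens_d=float(loo["cohens_d"].abs().max()),
                 influential_species=list(loo.loc[loo["influential"],
                                                  "species_dropped"]))
    else:
        s["note"] = "no significant families; LOO skipped"

    s = stage("expression_comparison")
    expr_path = Path(config.expression)
    if expr_path.exists() and focal_genes:
        expr = pd.read_csv(expr_path, sep="\t", index_col=0)
        background_genes = study_background - focal_genes
        comp = compare_expression(expr, focal_genes, background_genes)
        comp.to_csv(outdir / "expression_comparison.tsv", sep="\t", index=False)
        s.update({row["measure"]: {"p": float(row["p"]),
                                   "median_difference":
                                   float(row["median_difference"])}
                  for _, row in comp.iterrows()})
    else:
        s["note"] = "expression table absent or no focal genes"

    report["wall_clock_seconds"] = round(time.time() - t0, 2)
    report["seed"] = config.seed
    (outdir / "report.json").write_text(json.dumps(report, indent=1,
                                                   default=str))
    return report
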