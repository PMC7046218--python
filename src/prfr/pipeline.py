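"""End-to-end pipeline orchestration: one config in, a run directory of
diffable stage outputs (TSV + JSON) out.

Stage order mirrors the analysis: QC -> association (training set,
pre-imputation) -> sporadic-missing imputation -> train/validation split ->
preconditioning -> model training -> repeated-CV evaluation -> VIM-based
prioritization (re-modeling top 25/50/75% and keeping the fraction that
maximizes validation AUC) -> gene mapping / enrichment / eQTL annotation.

A single master seed deterministically derives per-stage seeds as
sha256(master:stage), so reruns with the same config and seed produce a
byte-identical run directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc_mod
from . import evaluation as eval_mod
from . import prioritization as prio_mod
from .io_formats import (
    GenotypeMatrix,
    PhenotypeTable,
    read_gene_bed,
    read_genotypes_raw,
    read_gmt,
    read_eqtl,
    read_ld_pairs,
    read_phenotypes,
)
from .modeling import ForestSpec, compute_vim, lasso_selection_frequency
from .preconditioning import fit_supervised_pca, precondition_outcomes

logger = logging.getLogger("prfr")


@dataclass
class PipelineConfig:
    """All inputs, thresholds and protocol sizes of one pipeline run."""

    genotypes: str = ""
    phenotypes: str = ""
    genes_bed: str | None = None
    gene_sets_gmt: str | None = None
    ld_pairs: str | None = None
    eqtl: str | None = None

    maf_min: float = 0.01
    missing_max: float = 0.05
    hwe_p_min: float = 1e-5
    snp_p_cutoff: float = 0.001
    clinical_p_cutoff: float = 0.05
    n_pc: int = 2
    n_trees: int = 1000
    min_node_size: int = 5
    n_repeats: int = 100
    n_folds: int = 5
    top_fractions: tuple[float, ...] = (0.25, 0.5, 0.75)
    gene_window: int = 50_000
    fdr_cutoff: float = 0.05
    r2_min: float = 0.8
    fraction_train: float = 2 / 3
    split_priority: list[str] = field(default_factory=list)
    model_families: tuple[str, ...] = eval_mod.MODEL_FAMILIES
    lasso_selection_iterations: int = 0  # 0 = skip the selection-frequency stage
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            0 <= self.maf_min <= 0.5,
            0 <= self.missing_max < 1,
            0 <= self.hwe_p_min < 1,
            0 < self.snp_p_cutoff <= 1,
            0 < self.clinical_p_cutoff <= 1,
            self.n_pc >= 1,
            self.n_trees >= 1,
            self.n_repeats >= 1,
            self.n_folds >= 2,
            all(0 < f <= 1 for f in self.top_fractions),
            self.gene_window >= 0,
            0 < self.fdr_cutoff <= 1,
            0 <= self.r2_min <= 1,
            0 < self.fraction_train < 1,
        ]
        if not all(checks):
            raise ValueError("pipeline config has a threshold outside its valid range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("top_fractions", "model_families"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["top_fractions"] = list(d["top_fractions"])
        d["model_families"] = list(d["model_families"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["top_fractions"] = list(d["top_fractions"])
        d["model_families"] = list(d["model_families"])
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _write_json(obj: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    genotypes: GenotypeMatrix | None = None,
    phenotypes: PhenotypeTable | None = None,
) -> dict:
    """Execute the full pipeline, writing every stage output under ``out_dir``.

    ``genotypes``/``phenotypes`` may be passed in memory; otherwise they are
    read from the paths in the config.  Returns the machine-readable summary
    (also written as summary.json).  On a stage failure, partial outputs are
    kept and a FAILED marker names the stage.
    """
    out = Path(out_dir)
    # config errors (missing inputs) surface before anything is written
    if genotypes is None and not Path(config.genotypes).exists():
        raise FileNotFoundError(f"genotype file not found: {config.genotypes}")
    if phenotypes is None and not Path(config.phenotypes).exists():
        raise FileNotFoundError(f"phenotype file not found: {config.phenotypes}")
    for name in ("genes_bed", "gene_sets_gmt", "ld_pairs", "eqtl"):
        path = getattr(config, name)
        if path and not Path(path).exists():
            raise FileNotFoundError(f"{name} file not found: {path}")
    out.mkdir(parents=True, exist_ok=True)
    stage = "load_inputs"
    try:
        if genotypes is None:
            genotypes = read_genotypes_raw(config.genotypes)
        if phenotypes is None:
            phenotypes = read_phenotypes(config.phenotypes)
        summary: dict = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_samples": genotypes.n_individuals,
            "n_snps_input": genotypes.n_snps,
        }
        config.to_yaml(out / "config.yaml")

        # -- QC -------------------------------------------------------------
        stage = "qc"
        thresholds = assoc_mod.QCThresholds(
            maf_min=config.maf_min,
            snp_missing_max=config.missing_max,
            sample_missing_max=config.missing_max,
            hwe_p_min=config.hwe_p_min,
        )
        geno_qc, qc_report = assoc_mod.qc_filter(genotypes, thresholds)
        pheno = phenotypes.subset(geno_qc.sample_ids)

        # -- split ----------------------------------------------------------
        stage = "split"
        split = eval_mod.stratified_split(
            pheno,
            fraction_train=config.fraction_train,
            priority=config.split_priority,
            seed=stage_seed(config.seed, "split"),
        )
        _write_tsv(split.as_frame(), out / "split.tsv")
        geno_train = geno_qc.subset_samples(split.training)
        geno_valid = geno_qc.subset_samples(split.validation)
        y_train = pheno.outcomes_for(split.training)
        y_valid = pheno.outcomes_for(split.validation)

        # -- association on the training set, pre-imputation ----------------
        stage = "association"
        assoc = assoc_mod.association_table(geno_train, pheno)
        _write_tsv(assoc, out / "association.tsv")
        lam = assoc_mod.genomic_inflation(assoc["chi2"].to_numpy())
        qc_report.lambda_gc = lam
        _write_json(qc_report.as_dict(), out / "qc_report.json")
        _write_tsv(assoc_mod.qq_points(assoc["p"].to_numpy()), out / "qq.tsv")
        clinical = assoc_mod.univariate_clinical_tests(pheno.subset(split.training))
        _write_tsv(clinical, out / "clinical_tests.tsv")
        selected_clinical = assoc_mod.filter_clinical_by_p(
            clinical, config.clinical_p_cutoff
        )
        filtered = assoc_mod.filter_snps_by_p(assoc, config.snp_p_cutoff)
        if len(filtered) < config.n_pc:
            filtered = (
                assoc.sort_values(["p", "snp_id"], kind="mergesort")["snp_id"]
                .head(config.n_pc)
                .tolist()
            )
            logger.warning(
                "fewer than %d SNPs passed the filter; using the most associated",
                config.n_pc,
            )
        pd.DataFrame({"snp_id": filtered}).to_csv(
            out / "filtered_snps.tsv", sep="\t", index=False
        )
        summary.update(
            {
                "lambda_gc": lam,
                "n_snps_qc": geno_qc.n_snps,
                "n_snps_filtered": len(filtered),
                "clinical_variables_selected": selected_clinical,
            }
        )

        # -- imputation for modeling ----------------------------------------
        stage = "imputation"
        geno_train = assoc_mod.impute_sporadic_missing(geno_train)
        geno_valid = assoc_mod.impute_sporadic_missing(geno_valid)

        # -- preconditioning -------------------------------------------------
        stage = "preconditioning"
        sub_train = geno_train.subset_snps(filtered)
        spca = fit_supervised_pca(sub_train, y_train, n_pc=config.n_pc)
        pre = precondition_outcomes(spca, sub_train, y_train)
        _write_tsv(
            pd.DataFrame(
                {
                    "sample_id": split.training,
                    "y_binary": y_train,
                    "y_preconditioned": [pre[s] for s in split.training],
                }
            ),
            out / "preconditioned.tsv",
        )

        # -- final model on the full training set ----------------------------
        stage = "train"
        spec = ForestSpec(
            config.n_trees, config.min_node_size, stage_seed(config.seed, "train")
        )
        from .modeling import fit_prfr

        prfr_model = fit_prfr(sub_train, pre, spec)
        final_scores = prfr_model.predict(geno_valid)
        final_auc = eval_mod.auc(final_scores, y_valid)
        final_ci = eval_mod.bootstrap_auc_ci(
            final_scores, y_valid, seed=stage_seed(config.seed, "bootstrap")
        )
        final_p = eval_mod.auc_pvalue(final_scores, y_valid)
        vim = compute_vim(prfr_model, seed=stage_seed(config.seed, "vim"))
        _write_tsv(vim, out / "vim.tsv")
        summary["final_model"] = {
            "auc": final_auc,
            "ci_low": final_ci[0],
            "ci_high": final_ci[1],
            "p": final_p,
        }
        if config.lasso_selection_iterations > 0:
            freq = lasso_selection_frequency(
                sub_train,
                y_train,
                n_iterations=config.lasso_selection_iterations,
                seed=stage_seed(config.seed, "lasso_freq"),
            )
            _write_tsv(freq, out / "lasso_selection_frequency.tsv")

        # -- repeated-CV evaluation ------------------------------------------
        stage = "evaluation"
        long_frames = []
        summaries = []
        dists: dict[str, eval_mod.AUCDistribution] = {}
        for family in config.model_families:
            dist = eval_mod.repeated_cv_auc(
                geno_train,
                y_train,
                geno_valid,
                y_valid,
                family,
                n_repeats=config.n_repeats,
                n_folds=config.n_folds,
                seed=stage_seed(config.seed, f"cv:{family}"),
                snp_p_cutoff=config.snp_p_cutoff,
                n_pc=config.n_pc,
                forest_spec=ForestSpec(config.n_trees, config.min_node_size),
            )
            dists[family] = dist
            long_frames.append(dist.as_frame(config.n_folds))
            lo, hi = dist.ci
            summaries.append((family, dist.mean, lo, hi, dist.aucs.size))
        _write_tsv(pd.concat(long_frames, ignore_index=True), out / "cv_aucs.tsv")
        _write_tsv(
            pd.DataFrame(
                summaries, columns=["model", "mean_auc", "ci_low", "ci_high", "n_models"]
            ),
            out / "auc_summary.tsv",
        )
        _, baseline_auc = eval_mod.ancestry_pc_baseline(
            geno_train, y_train, geno_valid, y_valid
        )
        summary["evaluation"] = {
            f: {"mean_auc": dists[f].mean, "n_models": int(dists[f].aucs.size)}
            for f in config.model_families
        }
        summary["ancestry_pc_auc"] = baseline_auc

        # -- VIM-based prioritization and re-modeling -------------------------
        stage = "prioritization"
        best = None
        prio_rows = []
        for frac in config.top_fractions:
            subset = prio_mod.top_fraction(vim, frac, method="prfr_vim")
            model_f = fit_prfr(
                geno_train.subset_snps(subset.snp_ids),
                pre,
                ForestSpec(
                    config.n_trees,
                    config.min_node_size,
                    stage_seed(config.seed, f"prio:{frac}"),
                ),
            )
            auc_f = eval_mod.auc(model_f.predict(geno_valid), y_valid)
            prio_rows.append((frac, len(subset.snp_ids), auc_f))
            if best is None or auc_f > best[2]:
                best = (frac, subset, auc_f)
        _write_tsv(
            pd.DataFrame(prio_rows, columns=["fraction", "n_snps", "validation_auc"]),
            out / "prioritization_auc.tsv",
        )
        best_frac, best_set, best_auc = best
        pd.DataFrame({"snp_id": best_set.snp_ids}).to_csv(
            out / "prioritized_snps.tsv", sep="\t", index=False
        )
        summary["prioritization"] = {
            "best_fraction": best_frac,
            "n_snps": len(best_set.snp_ids),
            "validation_auc": best_auc,
        }

        # -- annotation --------------------------------------------------------
        stage = "annotation"
        if config.genes_bed:
            genes = read_gene_bed(config.genes_bed)
            snp_info = {s.snp_id: s for s in geno_qc.snps}
            mapping = prio_mod.map_snps_to_genes(
                [snp_info[s] for s in best_set.snp_ids], genes, config.gene_window
            )
            _write_tsv(mapping, out / "gene_mapping.tsv")
            query = set(prio_mod.mapped_genes(mapping))
            summary["annotation"] = {
                "n_genes_mapped": len(query),
                "n_intergenic_snps": int((mapping["gene_id"] == "").sum()),
            }
            if config.gene_sets_gmt:
                collection = read_gmt(config.gene_sets_gmt)
                universe = {g.gene_id for g in genes}
                enrich = prio_mod.hypergeometric_enrichment(
                    query & universe, collection, universe, config.fdr_cutoff
                )
                _write_tsv(enrich, out / "enrichment.tsv")
                summary["annotation"]["n_enriched_sets"] = int(
                    enrich["significant"].sum()
                )
            if config.ld_pairs and config.eqtl:
                eqtl_genes = prio_mod.join_ld_eqtl(
                    best_set.snp_ids,
                    read_ld_pairs(config.ld_pairs),
                    read_eqtl(config.eqtl),
                    config.r2_min,
                )
                _write_tsv(eqtl_genes, out / "eqtl_genes.tsv")
                summary["annotation"]["n_eqtl_genes"] = int(
                    eqtl_genes["gene_id"].nunique()
                )

        stage = "summary"
        _write_json(summary, out / "summary.json")
        return summary
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def make_report(run_dir: str | Path) -> str:
    """Assemble a deterministic human-readable summary of a completed run."""
    run = Path(run_dir)
    required = ["summary.json", "qc_report.json", "auc_summary.tsv"]
    missing = [f for f in required if not (run / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run; missing: {missing}")
    with open(run / "summary.json") as fh:
        summary = json.load(fh)
    with open(run / "qc_report.json") as fh:
        qc = json.load(fh)
    lines = [
        "PRFR pipeline report",
        "====================",
        f"config hash: {summary['config_hash']}   master seed: {summary['seed']}",
        "",
        "QC",
        f"  samples: {qc['n_samples_in']} -> {qc['n_samples_out']}",
        f"  SNPs:    {qc['n_snps_in']} -> {qc['n_snps_out']}",
        f"  removed: {json.dumps(qc['removed'], sort_keys=True)}",
        f"  genomic inflation lambda: {qc['lambda_gc']:.4f}",
        "",
        f"Association filter: {summary['n_snps_filtered']} SNPs entered modeling",
        "",
        "Hold-out AUC by model family (repeated CV)",
    ]
    auc_tab = pd.read_csv(run / "auc_summary.tsv", sep="\t")
    for rec in auc_tab.itertuples(index=False):
        lines.append(
            f"  {rec.model:<22s} mean {rec.mean_auc:.3f} "
            f"[{rec.ci_low:.3f}, {rec.ci_high:.3f}]  (n={rec.n_models})"
        )
    if "ancestry_pc_auc" in summary:
        lines.append(f"  {'ancestry_pc baseline':<22s} AUC {summary['ancestry_pc_auc']:.3f}")
    fm = summary.get("final_model", {})
    if fm:
        lines += [
            "",
            "Final PRFR model (full training set) on validation data",
            f"  AUC {fm['auc']:.3f}  bootstrap 95% CI [{fm['ci_low']:.3f}, "
            f"{fm['ci_high']:.3f}]  one-sided p {fm['p']:.3g}",
        ]
    prio = summary.get("prioritization")
    if prio:
        lines += [
            "",
            f"VIM prioritization: best fraction {prio['best_fraction']} "
            f"({prio['n_snps']} SNPs), validation AUC {prio['validation_auc']:.3f}",
        ]
    ann = summary.get("annotation")
    if ann:
        lines += ["", "Annotation"]
        lines.append(f"  genes mapped (<=50 kb): {ann['n_genes_mapped']}")
        lines.append(f"  intergenic SNPs: {ann['n_intergenic_snps']}")
        if "n_enriched_sets" in ann:
            lines.append(f"  enriched gene sets (BH-FDR): {ann['n_enriched_sets']}")
        if "n_eqtl_genes" in ann:
            lines.append(f"  eQTL target genes via LD expansion: {ann['n_eqtl_genes']}")
    text = "\n".join(lines) + "\n"
    (run / "report.txt").write_text(text)
    return text
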