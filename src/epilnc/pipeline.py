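"""End-to-end orchestration: annotation -> DE / peaks / DMR -> classify ->
scoring -> survival, driven by a single validated YAML config.

Every stage reads and writes flat files so intermediate results are
inspectable; each output table carries a run-metadata header (version, seed,
stage parameters) as ``#``-prefixed comment lines.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__
from . import annotation as ann_mod
from . import diffexpr, diffpeaks, dmr as dmr_mod, epi_classify, scoring, survival

logger = logging.getLogger(__name__)


class StageParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    promoter_upstream: int = 2000
    promoter_downstream: int = 500
    fdr_cut: float = 0.05
    lfc_cut: float = 1.0
    peak_p: float = 0.05
    min_overlap: int = 1
    max_gap: int = 500
    delta_cut: float = 0.1
    smooth_window: int = 5
    permutations: int = 100
    dmr_p: float = 0.01
    min_evidence: int = 1
    knn_k: int = 10
    ssgsea_alpha: float = 0.25
    surv_alpha: float = 0.05
    horizons: list[int] = [365, 1095, 1825]


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    gtf: str
    enhancer_bed: str
    enhancer_assoc: str
    counts: str
    tpm: str
    conditions: str
    methylation: str
    clinical: str | None = None
    # mark -> {"tumor": path, "normal": path}
    peak_files: dict[str, dict[str, str]] = {}
    seed: int = 0
    out_dir: str = "epilnc_out"
    params: StageParams = StageParams()


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig.model_validate(raw)


def config_for_bundle(bundle_dir, out_dir, seed: int = 0,
                      marks=("H3K27ac", "H3K4me1", "H3K4me3")) -> PipelineConfig:
    """Convenience config pointing at a ``write_bundles`` output directory."""
    b = Path(bundle_dir)
    return PipelineConfig(
        gtf=str(b / "annotation.gtf"),
        enhancer_bed=str(b / "enhancers.bed"),
        enhancer_assoc=str(b / "enhancer_gene.tsv"),
        counts=str(b / "counts.tsv"),
        tpm=str(b / "tpm.tsv"),
        conditions=str(b / "conditions.tsv"),
        methylation=str(b / "methylation_beta.tsv"),
        clinical=str(b / "clinical.tsv"),
        peak_files={
            m: {c: str(b / f"peaks_{m}_{c}.narrowPeak") for c in ("tumor", "normal")}
            for m in marks
        },
        seed=seed,
        out_dir=str(out_dir),
    )


def _check_inputs(cfg: PipelineConfig) -> None:
    paths = {"gtf": cfg.gtf, "enhancer_bed": cfg.enhancer_bed,
             "enhancer_assoc": cfg.enhancer_assoc, "counts": cfg.counts,
             "tpm": cfg.tpm, "conditions": cfg.conditions,
             "methylation": cfg.methylation}
    if cfg.clinical:
        paths["clinical"] = cfg.clinical
    for mark, files in cfg.peak_files.items():
        for cond, p in files.items():
            paths[f"peak_files.{mark}.{cond}"] = p
    missing = {k: p for k, p in paths.items() if not Path(p).exists()}
    if missing:
        raise FileNotFoundError(f"missing pipeline inputs: {missing}")


def _write(df: pd.DataFrame, path: Path, cfg: PipelineConfig, stage: str,
           index_label=None, **kwargs) -> None:
    with open(path, "w") as fh:
        fh.write(f"# epilnc v{__version__} stage={stage} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index_label=index_label,
                  index=index_label is not None, **kwargs)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_annotation(cfg: PipelineConfig):
    genes = ann_mod.read_gtf(cfg.gtf)
    promoters = ann_mod.promoters_frame(
        genes, cfg.params.promoter_upstream, cfg.params.promoter_downstream)
    enh = ann_mod.read_enhancer_bed(cfg.enhancer_bed)
    assoc = pd.read_csv(cfg.enhancer_assoc, sep="\t")
    enhancers = ann_mod.regions_frame(ann_mod.assign_enhancers(enh, assoc, genes))
    regions = pd.concat([promoters, enhancers], ignore_index=True)
    return genes, regions


def stage_de(cfg: PipelineConfig, out: Path):
    counts = pd.read_csv(cfg.counts, sep="\t", index_col="gene_id", comment="#")
    condition = pd.read_csv(cfg.conditions, sep="\t", index_col="sample_id",
                            comment="#")["condition"]
    de = diffexpr.test_de(counts, condition, cfg.params.fdr_cut, cfg.params.lfc_cut)
    _write(de, out / "de_results.tsv", cfg, "de", index_label="gene_id")
    return de, counts, condition


def stage_peaks(cfg: PipelineConfig, regions: pd.DataFrame, out: Path):
    events = []
    all_diff = []
    for mark, files in cfg.peak_files.items():
        t = diffpeaks.read_narrowpeak(files["tumor"], mark, "tumor")
        n = diffpeaks.read_narrowpeak(files["normal"], mark, "normal")
        diff = diffpeaks.find_condition_specific(
            t, n, mark, cfg.params.min_overlap, cfg.params.peak_p)
        all_diff.append(diff)
        events.append(diffpeaks.overlap_regions(diff, regions))
    diff_df = pd.concat(all_diff, ignore_index=True) if all_diff else pd.DataFrame(
        columns=["chrom", "start", "end", "mark", "condition", "p_value", "direction"])
    ev_df = pd.concat(events, ignore_index=True) if events else pd.DataFrame(
        columns=["gene_id", "element", "source", "direction"])
    _write(diff_df, out / "diff_peaks.tsv", cfg, "peaks")
    _write(ev_df, out / "peak_events.tsv", cfg, "peaks")
    return ev_df


def stage_dmr(cfg: PipelineConfig, regions: pd.DataFrame, out: Path):
    meth = pd.read_csv(cfg.methylation, sep="\t", index_col="probe_id",
                       comment="#", na_values="NA")
    probes = meth[["chrom", "pos"]].reset_index()
    beta = meth.drop(columns=["chrom", "pos"])
    beta = dmr_mod.knn_impute(beta, k=cfg.params.knn_k)
    condition = pd.read_csv(cfg.conditions, sep="\t", index_col="sample_id",
                            comment="#")["condition"]
    dmrs = dmr_mod.find_bumps(
        probes, beta, condition,
        max_gap=cfg.params.max_gap, delta_cut=cfg.params.delta_cut,
        w=cfg.params.smooth_window, B=cfg.params.permutations,
        seed=cfg.seed, p_cut=cfg.params.dmr_p)
    events = dmr_mod.overlap_dmrs(dmrs, regions)
    _write(dmrs, out / "dmrs.tsv", cfg, "dmr")
    _write(events, out / "dmr_events.tsv", cfg, "dmr")
    return events


def stage_classify(cfg, genes, de, peak_events, dmr_events, out: Path):
    biotypes = pd.Series({g.gene_id: g.biotype for g in genes}, name="biotype")
    events = pd.concat([peak_events, dmr_events], ignore_index=True)
    annotations = epi_classify.classify(de, events, biotypes, cfg.params.min_evidence)
    _write(annotations, out / "epi_annotations.tsv", cfg, "classify",
           index_label="gene_id")
    counts = epi_classify.epi_counts(annotations)
    summary: dict = {"epi_counts": counts}
    if annotations["is_epi"].any():
        _, element_distribution, n_sources = epi_classify.landscape(annotations)
        summary["element_distribution"] = element_distribution
        summary["multi_source_genes"] = int((n_sources >= 2).sum())
    (out / "landscape.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return annotations


def stage_scoring(cfg, annotations, out: Path):
    tpm = pd.read_csv(cfg.tpm, sep="\t", index_col="gene_id", comment="#")
    condition = pd.read_csv(cfg.conditions, sep="\t", index_col="sample_id",
                            comment="#")["condition"]
    sets = scoring.build_epi_sets(annotations, biotype="lncRNA")
    if not sets:
        logger.warning("scoring: no epi-lncRNA sets of sufficient size; stage skipped")
        return None
    scores = scoring.ssgsea_score(tpm, sets, alpha=cfg.params.ssgsea_alpha)
    tests = scoring.compare_groups(scores, condition)
    _write(scores, out / "ssgsea_scores.tsv", cfg, "score", index_label="set")
    _write(tests, out / "ssgsea_group_tests.tsv", cfg, "score", index_label="set")
    return scores


def stage_survival(cfg, annotations, out: Path):
    if not cfg.clinical:
        return None
    tpm = pd.read_csv(cfg.tpm, sep="\t", index_col="gene_id", comment="#")
    clinical = pd.read_csv(cfg.clinical, sep="\t", comment="#")
    candidates = list(annotations.index[annotations["is_epi"]
                                        & (annotations["biotype"] == "lncRNA")])
    if not candidates:
        logger.warning("survival: no epi-lncRNA candidates; stage skipped")
        return None
    screen = survival.univariate_screen(tpm, clinical, candidates,
                                        alpha=cfg.params.surv_alpha)
    _write(screen, out / "univariate_screen.tsv", cfg, "survive",
           index_label="gene_id")
    panel = list(screen.index[screen["selected"]])
    result = {"n_candidates": len(candidates), "panel": panel}
    if not panel:
        logger.warning("survival: univariate screen selected no genes")
        (out / "risk_model.json").write_text(json.dumps(result, indent=1))
        return result
    try:
        model, fit = survival.fit_risk_model(tpm, clinical, panel)
    except (RuntimeError, ValueError) as exc:
        logger.warning("survival: multivariate fit failed (%s)", exc)
        result["error"] = str(exc)
        (out / "risk_model.json").write_text(json.dumps(result, indent=1))
        return result
    rs = survival.risk_score(model, tpm, clinical["sample_id"])
    _write(rs, out / "risk_scores.tsv", cfg, "survive", index_label="sample_id")
    groups = rs["group"].to_numpy()
    time = clinical["time_days"].to_numpy()
    event = clinical["event"].to_numpy()
    if len(np.unique(groups)) == 2:
        chi2, p = survival.logrank(time, event, groups)
    else:
        chi2, p = float("nan"), float("nan")
    aucs = survival.time_dependent_auc(rs["score"].to_numpy(), time, event,
                                       cfg.params.horizons)
    result.update({
        "model": model.to_dict(),
        "wald_p": fit.p_value.tolist(),
        "logrank_chi2": chi2,
        "logrank_p": p,
        "auc": {str(k): (None if np.isnan(v) else v) for k, v in aucs.items()},
    })
    (out / "risk_model.json").write_text(json.dumps(result, indent=1, sort_keys=True))
    return result


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage in dependency order; returns the result manifest."""
    _check_inputs(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes, regions = stage_annotation(cfg)
    de, _, _ = stage_de(cfg, out)
    peak_events = stage_peaks(cfg, regions, out)
    dmr_events = stage_dmr(cfg, regions, out)
    annotations = stage_classify(cfg, genes, de, peak_events, dmr_events, out)
    stage_scoring(cfg, annotations, out)
    surv = stage_survival(cfg, annotations, out)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "n_genes": len(genes),
        "epi_counts": epi_classify.epi_counts(annotations),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        "survival": {"panel": surv.get("panel", [])} if isinstance(surv, dict) else None,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
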