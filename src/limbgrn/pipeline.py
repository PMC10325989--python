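"""End-to-end orchestration from a single configuration.

Stages run in dependency order — replicate consensus, co-binding
classification with chromatin overlay, DEG integration, the single-cell
co-expression stage, TAD-scoped enhancer prioritization, TAD regulatory
scoring, and the cross-tissue comparison — and the run report records
per-stage counts, thresholds, and the seed. INFO logging narrates each
filter's in/out counts so the report's arithmetic can be reconstructed
from the log.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import cistrome as ct
from . import cross_tissue as xt
from . import deg as dg
from . import landscape as ls
from . import singlecell as sc
from . import simulate as sim
from .intervals import ConsensusConfig, ValidationError, consensus_replicates, read_peaks, write_peaks

logger = logging.getLogger("limbgrn")


@dataclass(frozen=True)
class RunConfig:
    """Thresholds for every stage (defaults are the study values) plus the
    input directory layout produced by :func:`limbgrn.simulate.simulate_to_dir`."""

    input_dir: str
    output_dir: str
    seed: int = 0
    stringent_p: float = 1e-10
    weak_p: float = 1e-6
    min_replicates: int = 2
    min_overlap_bp: int = 1
    promoter_halfwidth_bp: int = 2000
    fc_min: float = 1.2
    fdr_max: float = 0.05
    auc_min: float = 0.55
    min_fold: float = 15.0
    qc: sc.QcThresholds = field(default_factory=sc.QcThresholds)
    resolutions: tuple[float, ...] = sc.DEFAULT_RESOLUTIONS
    cluster_cells: bool = True

    def validate(self) -> None:
        ConsensusConfig(
            stringent_p=self.stringent_p,
            weak_p=self.weak_p,
            min_replicates=self.min_replicates,
            min_overlap_bp=self.min_overlap_bp,
        )
        if not self.fc_min > 1:
            raise ValidationError(f"fc_min must be > 1, got {self.fc_min}")
        if not (0 < self.fdr_max < 1):
            raise ValidationError("fdr_max must be in (0, 1)")
        if not (0 < self.auc_min < 1):
            raise ValidationError("auc_min must be in (0, 1)")
        if self.min_fold < 0:
            raise ValidationError("min_fold must be >= 0")
        if self.promoter_halfwidth_bp <= 0:
            raise ValidationError("promoter_halfwidth_bp must be > 0")
        if not os.path.isdir(self.input_dir):
            raise ValidationError(f"input directory {self.input_dir!r} does not exist")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    qc = raw.pop("qc", None)
    cfg = RunConfig(**raw, qc=sc.QcThresholds(**qc) if qc else sc.QcThresholds())
    return cfg


def _consensus_from_dir(peaks_dir: str, stem: str, n_reps: int, cfg: ConsensusConfig):
    reps = [
        read_peaks(os.path.join(peaks_dir, f"{stem}_rep{r}.narrowPeak"), replicate=r)
        for r in range(1, n_reps + 1)
    ]
    cons = consensus_replicates(reps, cfg)
    logger.info(
        "consensus %s: %s replicate peaks -> %d consensus regions",
        stem, [len(r) for r in reps], len(cons),
    )
    return cons, sum(len(r) for r in reps)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and return (and write) the run report.

    Any stage failure is recorded in the report with its cause and the
    downstream stages are skipped.
    """
    cfg.validate()
    os.makedirs(cfg.output_dir, exist_ok=True)
    report: dict = {
        "seed": cfg.seed,
        "thresholds": {
            "stringent_p": cfg.stringent_p,
            "weak_p": cfg.weak_p,
            "min_replicates": cfg.min_replicates,
            "min_overlap_bp": cfg.min_overlap_bp,
            "promoter_halfwidth_bp": cfg.promoter_halfwidth_bp,
            "fc_min": cfg.fc_min,
            "fdr_max": cfg.fdr_max,
            "auc_min": cfg.auc_min,
            "min_fold": cfg.min_fold,
            "qc": asdict(cfg.qc),
        },
        "stages": {},
    }
    state: dict = {}
    stage_fns = [
        ("consensus", _stage_consensus),
        ("classify", _stage_classify),
        ("integrate_degs", _stage_degs),
        ("sc_coexpression", _stage_sc),
        ("enhancers", _stage_enhancers),
        ("tad_score", _stage_tad_score),
        ("cross_tissue", _stage_cross_tissue),
    ]
    failed = False
    for name, fn in stage_fns:
        if failed:
            report["stages"][name] = {"status": "skipped"}
            continue
        try:
            result = fn(cfg, state)
            result["status"] = "ok"
            report["stages"][name] = result
        except Exception as exc:  # noqa: BLE001 - report the cause, skip downstream
            logger.error("stage %s failed: %s", name, exc)
            report["stages"][name] = {"status": "failed", "cause": str(exc)}
            failed = True
    audit_report(report)
    with open(os.path.join(cfg.output_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_consensus(cfg: RunConfig, state: dict) -> dict:
    ccfg = ConsensusConfig(
        stringent_p=cfg.stringent_p,
        weak_p=cfg.weak_p,
        min_replicates=cfg.min_replicates,
        min_overlap_bp=cfg.min_overlap_bp,
    )
    peaks_dir = os.path.join(cfg.input_dir, "peaks")
    n_reps = {"pbx": 2, "hand2": 2, "atac": 3, "h3k27ac": 2, "h3k27me3": 2, "ctcf": 2}
    counts = {}
    for stem, n in n_reps.items():
        cons, n_in = _consensus_from_dir(peaks_dir, stem, n, ccfg)
        state[f"cons_{stem}"] = cons
        write_peaks(cons, os.path.join(cfg.output_dir, f"consensus_{stem}.narrowPeak"))
        counts[stem] = {"input_peaks": n_in, "consensus_regions": len(cons)}
    # the enhancer stage has its own replicate calls restricted to the TAD
    enh_dir = os.path.join(cfg.input_dir, "enhancer")
    for stem, n in (("pbx_tad", 2), ("h3k27ac_tad", 2), ("atac_tad", 3)):
        cons, n_in = _consensus_from_dir(enh_dir, stem, n, ccfg)
        state[f"cons_{stem}"] = cons
        counts[stem] = {"input_peaks": n_in, "consensus_regions": len(cons)}
    return {"collections": counts}


def _stage_classify(cfg: RunConfig, state: dict) -> dict:
    genes = ct.read_gene_models(os.path.join(cfg.input_dir, "genes.gff3"), "gff3")
    state["genes"] = genes
    part = ct.partition_cobinding(
        state["cons_pbx"], state["cons_hand2"], cfg.min_overlap_bp
    )
    part = ct.annotate_contexts(part, genes, cfg.promoter_halfwidth_bp)
    part = ct.annotate_chromatin(
        part,
        {
            "h3k27ac": state["cons_h3k27ac"],
            "h3k27me3": state["cons_h3k27me3"],
            "atac": state["cons_atac"],
            "ctcf": state["cons_ctcf"],
        },
    )
    state["partition"] = part
    part.to_dataframe().to_csv(
        os.path.join(cfg.output_dir, "partition.tsv"), sep="\t", index=False
    )
    counts = part.class_counts()
    logger.info("partition classes: %s (total %d)", counts, ct.partition_total(counts))
    kw = ct.compare_classes(ct.class_signal_values(part, "atac"), "kruskal_wallis")
    context_counts = pd.Series(part.context_of).value_counts().to_dict()
    return {
        "class_counts": counts,
        "total_regions": ct.partition_total(counts),
        "context_counts": {k: int(v) for k, v in context_counts.items()},
        "atac_kruskal_wallis": {"statistic": kw.statistic, "p_value": kw.p_value},
    }


def _stage_degs(cfg: RunConfig, state: dict) -> dict:
    table_a = dg.read_deg_table(os.path.join(cfg.input_dir, "deg_pbx.tsv"))
    table_b = dg.read_deg_table(os.path.join(cfg.input_dir, "deg_hand2.tsv"))
    degs_a = dg.filter_degs(table_a, cfg.fc_min, cfg.fdr_max)
    degs_b = dg.filter_degs(table_b, cfg.fc_min, cfg.fdr_max)
    logger.info("DEGs: %d in contrast A, %d in contrast B", len(degs_a), len(degs_b))
    universe = dg.detection_universe(table_a, table_b)
    shared = dg.intersect_contrasts(degs_a, degs_b, universe)
    dg.write_shared_targets(shared, os.path.join(cfg.output_dir, "shared_targets.tsv"))
    state["shared_targets"] = shared
    return {
        "n_deg_a": len(degs_a),
        "n_deg_b": len(degs_b),
        "universe_size": len(universe),
        "shared_counts": shared.counts(),
    }


def _stage_sc(cfg: RunConfig, state: dict) -> dict:
    adata = sim.read_sc_matrix(os.path.join(cfg.input_dir, "sc"))
    n_before = adata.n_obs
    adata = sc.qc_filter(adata, cfg.qc)
    logger.info("QC: %d of %d cells retained", adata.n_obs, n_before)
    norm = sc.log_normalize(adata)
    result: dict = {"cells_before_qc": n_before, "cells_after_qc": int(adata.n_obs)}
    if cfg.cluster_cells:
        res, labels = sc.select_resolution(
            norm, resolutions=cfg.resolutions, seed=cfg.seed
        )
        norm.obs["cluster"] = pd.Categorical([str(l) for l in labels])
        markers = sc.find_markers(norm, labels)
        markers.to_csv(os.path.join(cfg.output_dir, "markers.tsv"), sep="\t", index=False)
        result["selected_resolution"] = res
        result["n_clusters"] = int(len(np.unique(labels)))
        result["n_marker_rows"] = int(len(markers))
    dp = sc.double_positive_cells(norm)
    # background: cells of the double-positive cells' dominant cluster that
    # are not themselves double positive (the co-expressing subpopulation's
    # own cluster is the relevant comparison compartment)
    if cfg.cluster_cells:
        clusters = norm.obs["cluster"].to_numpy()
        dp_cluster = pd.Series(clusters[dp]).mode()
        dp_cluster = dp_cluster.iloc[0] if not dp_cluster.empty else None
        background = (clusters == dp_cluster) & ~dp
    else:
        background = ~dp
    screen = sc.coexpression_screen(norm, dp, background, auc_min=cfg.auc_min)
    screen.to_csv(os.path.join(cfg.output_dir, "coexpression_auc.tsv"), sep="\t", index=False)
    passing = screen[screen["passes"]]["gene_id"].tolist()
    logger.info("co-expression screen: %d of %d genes pass AUC >= %s",
                len(passing), len(screen), cfg.auc_min)
    result.update(
        {
            "n_double_positive": int(dp.sum()),
            "n_background": int(np.asarray(background).sum()),
            "n_auc_pass": len(passing),
            "n_genes_screened": int(len(screen)),
        }
    )
    if passing:
        scores = sc.module_score(norm, passing, seed=cfg.seed)
        result["module_score_mean_dp"] = float(np.mean(scores[dp]))
        result["module_score_mean_other"] = float(np.mean(scores[~dp]))
    state["sc_screen"] = screen
    return result


def _stage_enhancers(cfg: RunConfig, state: dict) -> dict:
    tads = ls.read_tads(os.path.join(cfg.input_dir, "tads.bed"))
    state["tads"] = tads
    conserved = ls.read_bed_intervals(os.path.join(cfg.input_dir, "conserved.bed"))
    tad = tads[0]
    candidates = ls.prioritize_enhancers(
        tad,
        state["cons_pbx_tad"],
        state["cons_h3k27ac_tad"],
        state["cons_atac_tad"],
        conserved,
        state["genes"],
        min_fold=cfg.min_fold,
        promoter_halfwidth_bp=cfg.promoter_halfwidth_bp,
    )
    df = ls.candidates_to_dataframe(candidates)
    df.to_csv(os.path.join(cfg.output_dir, "enhancer_candidates.tsv"), sep="\t", index=False)
    state["enhancer_candidates"] = candidates
    n_pass = int(sum(c.passes for c in candidates))
    logger.info("enhancers: %d of %d candidates pass all filters", n_pass, len(candidates))
    return {"tad_id": tad.tad_id, "n_candidates": len(candidates), "n_passing": n_pass}


def _stage_tad_score(cfg: RunConfig, state: dict) -> dict:
    genes = state["genes"]
    gene_to_tad: dict[str, str] = {}
    tads_with_genes = []
    for tad in state["tads"]:
        tad_genes = tuple(
            g.gene_id for g in genes if g.interval.overlaps(tad.interval)
        )
        tads_with_genes.append(ls.TadRecord(tad.interval, tad.tad_id, tad_genes))
        for g in tad_genes:
            gene_to_tad[g] = tad.tad_id
    scores = {
        tad.tad_id: ls.tad_regulatory_score(
            tad,
            [state["cons_pbx"], state["cons_hand2"]],
            genes,
            cfg.promoter_halfwidth_bp,
        )
        for tad in tads_with_genes
    }
    shared = state["shared_targets"]
    deg_genes = shared.shared() | shared.a_only | shared.b_only
    deg_tad_ids = {gene_to_tad[g] for g in deg_genes if g in gene_to_tad}
    deg_scores = [s for t, s in scores.items() if t in deg_tad_ids]
    other_scores = [s for t, s in scores.items() if t not in deg_tad_ids]
    result = {
        "n_tads": len(scores),
        "n_deg_tads": len(deg_scores),
        "mean_strength_deg": float(np.mean([s.summed_strength for s in deg_scores]))
        if deg_scores else 0.0,
        "mean_strength_other": float(np.mean([s.summed_strength for s in other_scores]))
        if other_scores else 0.0,
    }
    if deg_scores and other_scores:
        cmp = ls.compare_tad_scores(deg_scores, other_scores)
        result["strength_p_one_sided"] = cmp["summed_strength"].p_value
        result["count_p_one_sided"] = cmp["n_distal_sites"].p_value
    pd.DataFrame(
        {
            "tad_id": list(scores),
            "n_distal_sites": [s.n_distal_sites for s in scores.values()],
            "summed_strength": [s.summed_strength for s in scores.values()],
            "contains_deg": [t in deg_tad_ids for t in scores],
        }
    ).to_csv(os.path.join(cfg.output_dir, "tad_scores.tsv"), sep="\t", index=False)
    return result


def _stage_cross_tissue(cfg: RunConfig, state: dict) -> dict:
    ct_dir = os.path.join(cfg.input_dir, "cross_tissue")
    tissues = sorted(
        f.split("_", 1)[1].split(".")[0]
        for f in os.listdir(ct_dir)
        if f.startswith("pbx_")
    )
    pbx = {
        t: read_peaks(os.path.join(ct_dir, f"pbx_{t}.narrowPeak"), tissue=t)
        for t in tissues
    }
    summary = xt.multi_tissue_overlap(pbx, cfg.min_overlap_bp)
    fractions = {}
    for t in tissues:
        path = os.path.join(ct_dir, f"cofactor_{t}.narrowPeak")
        if os.path.exists(path):
            cof = read_peaks(path, tissue=t)
            frac = xt.cofactor_selection_fraction(pbx[t], cof, cfg.min_overlap_bp)
            fractions[t] = {
                "fraction": frac.fraction,
                "n_overlapping": frac.n_overlapping,
                "n_cofactor": frac.n_cofactor,
            }
    table = pd.read_csv(os.path.join(ct_dir, "signal_table.tsv"), sep="\t")
    sig_tissues = [c.removeprefix("signal_") for c in table.columns if c.startswith("signal_")]
    fc_table, cmp = xt.signal_log2fc(table, sig_tissues[0], sig_tissues[1])
    fc_table.to_csv(os.path.join(cfg.output_dir, "signal_log2fc.tsv"), sep="\t", index=False)
    return {
        "tissue_counts": summary.tissue_counts,
        "core_count": summary.core_count,
        "shared_fraction_of": summary.shared_fraction_of,
        "cofactor_fractions": fractions,
        "signal_log2fc_p": cmp.p_value,
        "signal_groups": list(cmp.group_sizes),
    }


# ---------------------------------------------------------------------------
# post-run audit
# ---------------------------------------------------------------------------

def audit_report(report: dict) -> None:
    """Internal-consistency checks on a run report (class sizes sum to
    totals, fractions in range). Raises on violation."""
    stages = report.get("stages", {})
    cls = stages.get("classify", {})
    if cls.get("status") == "ok":
        if ct.partition_total(cls["class_counts"]) != cls["total_regions"]:
            raise ValidationError("audit: partition class counts do not sum to total")
    degs = stages.get("integrate_degs", {})
    if degs.get("status") == "ok":
        counts = degs["shared_counts"]
        if any(v < 0 for v in counts.values()):
            raise ValidationError("audit: negative shared-target count")
    xts = stages.get("cross_tissue", {})
    if xts.get("status") == "ok":
        for t, frac in xts["shared_fraction_of"].items():
            if not (0.0 <= frac <= 1.0):
                raise ValidationError(f"audit: shared fraction out of range for {t}")
        for t, rec in xts["cofactor_fractions"].items():
            if not (0.0 <= rec["fraction"] <= 1.0):
                raise ValidationError(f"audit: cofactor fraction out of range for {t}")
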