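"""Seeded synthetic-data generators for every pipeline input.

The generators emulate the statistical structure the downstream analysis
assumes — planted co-binding with elevated accessibility at co-bound
sites, replicate peak calls as jittered copies of true regions, planted
concordant/discordant differential expression, negative-binomial UMI
counts with a double-positive mesenchymal subpopulation, a TAD with
planted passing/failing enhancer candidates, and cross-tissue cistromes
with a shared core and planted cofactor-selection rates — so every stage
is testable against sidecar truth with no download.

Every generator is a pure function of :class:`SimConfig`: a fixed seed
yields byte-identical outputs. Truth labels are written to sidecar TSVs,
never embedded in the standard-format files.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import io as scipy_io
from scipy import sparse

from .cistrome import GeneModel
from .intervals import (
    GenomicInterval,
    PeakCollection,
    ScoredPeak,
    ValidationError,
    write_peaks,
)
from .landscape import TadRecord

PEAK_HALFWIDTH = 150
SLOT_STEP = 2000
PROMOTER_EXCLUSION = 2400  # keeps jittered non-promoter peaks out of TSS windows


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CistromePlan:
    n_regions_a: int = 1000          # PBX1 binding regions
    n_b_specific: int = 300          # HAND2-only regions
    cobound_fraction: float = 0.3    # P(a region is also bound by B)
    cobound_signal_shift: float = 3.0  # added to ATAC/H3K27ac -log10 p at co-bound sites
    n_replicates_tf: int = 2
    n_replicates_atac: int = 3
    n_replicates_histone: int = 2
    n_irreproducible: int = 30       # per factor, present in a single replicate
    n_background_marks: int = 200    # ATAC/H3K27ac peaks away from TF regions
    n_h3k27me3: int = 150
    n_ctcf: int = 150
    pos_jitter_sd: float = 20.0
    score_jitter_sd: float = 0.5
    tf_neglog10_range: tuple[float, float] = (8.0, 20.0)
    atac_neglog10_range: tuple[float, float] = (7.0, 10.0)
    fold_range: tuple[float, float] = (5.0, 40.0)


@dataclass(frozen=True)
class DegPlan:
    concordant_up: int = 20
    concordant_down: int = 15
    discordant: int = 10
    a_only: int = 30
    b_only: int = 30
    effect_log2fc: float = 1.0
    frac_undetected: float = 0.05    # null genes missing from the detection universe


@dataclass(frozen=True)
class ScPlan:
    cells_per_cluster: tuple[int, ...] = (600, 200, 200)
    n_posterior: int = 300           # double-positive subpopulation inside cluster 0
    n_genes: int = 1500
    n_mito: int = 50
    markers_per_cluster: int = 20
    marker_fold: float = 6.0
    nb_dispersion: float = 2.0
    total_range: tuple[float, float] = (7000.0, 16000.0)
    mito_frac: float = 0.04
    planted_targets: tuple[str, ...] = (
        "Msx1", "Alx3", "Lhx9", "Prrx1", "Zfhx4", "Ets2", "Snai1",
    )
    target_effect_log: float = 1.5   # log-units of elevation in double positives
    hand_mean: float = 10.0          # Hand2 mean count in posterior cells
    hand_background_mean: float = 0.02
    pbx1_mean: float = 8.0
    pbx2_mean: float = 4.0
    n_fail_low_total: int = 8
    n_fail_high_total: int = 4
    n_fail_high_mito: int = 8


@dataclass(frozen=True)
class EnhancerPlan:
    n_passing: int = 5
    n_failing: int = 10              # two of each failure mode, cycled
    pass_fold_range: tuple[float, float] = (18.0, 30.0)
    low_fold: float = 10.0


@dataclass(frozen=True)
class CrossTissuePlan:
    tissues: tuple[str, ...] = ("HL", "BA2", "MF")
    n_core: int = 600                # regions shared by all tissues
    n_specific: int = 400            # per-tissue private regions
    n_cofactor: int = 400
    cofactor_rates: tuple[tuple[str, float], ...] = (("HL", 0.48), ("MF", 0.18))
    n_signal_cobound: int = 300
    n_signal_other: int = 300
    signal_shift_log2: float = 1.0


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    chrom_lengths: tuple[tuple[str, int], ...] = (
        ("chr1", 30_000_000),
        ("chr2", 30_000_000),
    )
    n_genes: int = 300
    n_tads: int = 20
    n_conserved_background: int = 300
    cistrome: CistromePlan = field(default_factory=CistromePlan)
    deg: DegPlan = field(default_factory=DegPlan)
    sc: ScPlan = field(default_factory=ScPlan)
    enhancer: EnhancerPlan = field(default_factory=EnhancerPlan)
    cross_tissue: CrossTissuePlan = field(default_factory=CrossTissuePlan)

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if self.n_tads < 1:
            raise ValidationError("n_tads must be >= 1")
        if not (0.0 <= self.cistrome.cobound_fraction <= 1.0):
            raise ValidationError("cobound_fraction must be in [0, 1]")


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeLayout:
    genes: tuple[GeneModel, ...]
    tads: tuple[TadRecord, ...]
    conserved_background: tuple[GenomicInterval, ...]
    peak_slots: tuple[tuple[str, int], ...]  # shuffled pool of usable peak centers


def gen_genome(cfg: SimConfig) -> GenomeLayout:
    """Deterministic genome layout: TADs tile the chromosomes, gene bodies
    sit on a regular non-overlapping grid inside each TAD, conserved
    elements are scattered, and a shuffled pool of peak-center slots (away
    from every promoter) is prepared for the other generators."""
    total_len = sum(l for _, l in cfg.chrom_lengths)
    gene_len = 20_000
    # TADs tile each chromosome, proportional to its length
    tads: list[TadRecord] = []
    tad_bounds: list[tuple[str, int, int]] = []
    for chrom, length in cfg.chrom_lengths:
        n = max(1, round(cfg.n_tads * length / total_len))
        size = length // n
        for i in range(n):
            start, end = i * size, (i + 1) * size
            tads.append(TadRecord(GenomicInterval(chrom, start, end), f"tad_{len(tads):03d}"))
            tad_bounds.append((chrom, start, end))
    # genes distributed across TADs on a fixed grid
    per_tad = math.ceil(cfg.n_genes / len(tads))
    for chrom, start, end in tad_bounds:
        usable = (end - start) - 200_000
        if usable < per_tad * (gene_len + 10_000):
            raise ValidationError("genome too small for requested genes")
    genes: list[GeneModel] = []
    tad_genes: dict[str, list[str]] = {t.tad_id: [] for t in tads}
    gi = 0
    for ti, (chrom, start, end) in enumerate(tad_bounds):
        spacing = ((end - start) - 200_000) // per_tad
        for j in range(per_tad):
            if gi >= cfg.n_genes:
                break
            gstart = start + 100_000 + j * spacing
            strand = "+" if (gi % 2 == 0) else "-"
            iv = GenomicInterval(chrom, gstart, gstart + gene_len, strand)
            tss = iv.start if strand == "+" else iv.end - 1
            gene_id = f"g{gi:04d}"
            genes.append(GeneModel(gene_id, iv, tss))
            tad_genes[tads[ti].tad_id].append(gene_id)
            gi += 1
    tads = [
        TadRecord(t.interval, t.tad_id, tuple(tad_genes[t.tad_id])) for t in tads
    ]
    # peak-center slots: a regular grid, excluding promoter neighborhoods
    tss_by_chrom: dict[str, np.ndarray] = {}
    for chrom, _ in cfg.chrom_lengths:
        tss_by_chrom[chrom] = np.array(
            sorted(g.tss for g in genes if g.interval.chrom == chrom), dtype=int
        )
    slots: list[tuple[str, int]] = []
    for chrom, length in cfg.chrom_lengths:
        centers = np.arange(SLOT_STEP, length - SLOT_STEP, SLOT_STEP)
        tss = tss_by_chrom[chrom]
        if tss.size:
            idx = np.searchsorted(tss, centers)
            left = np.where(idx > 0, centers - tss[np.maximum(idx - 1, 0)], np.inf)
            right = np.where(
                idx < tss.size, tss[np.minimum(idx, tss.size - 1)] - centers, np.inf
            )
            keep = np.minimum(left, right) >= PROMOTER_EXCLUSION + PEAK_HALFWIDTH
            centers = centers[keep]
        slots.extend((chrom, int(c)) for c in centers)
    rng = _rng(cfg, 1)
    order = rng.permutation(len(slots))
    shuffled = tuple(slots[i] for i in order)
    # conserved background elements on their own slots (taken from the tail
    # of the pool so the head remains available to the peak generators)
    n_cons = min(cfg.n_conserved_background, len(shuffled) // 10)
    conserved = tuple(
        GenomicInterval(c, pos - 100, pos + 100) for c, pos in shuffled[-n_cons:]
    )
    return GenomeLayout(
        genes=tuple(genes),
        tads=tuple(tads),
        conserved_background=conserved,
        peak_slots=shuffled[: len(shuffled) - n_cons],
    )


def _slot_iter(layout: GenomeLayout):
    """Simple disjoint slot dispenser."""
    return iter(layout.peak_slots)


def _take_slots(slot_iter, n: int, within: Optional[GenomicInterval] = None) -> list[tuple[str, int]]:
    out = []
    while len(out) < n:
        try:
            chrom, center = next(slot_iter)
        except StopIteration:
            raise ValidationError("slot pool exhausted; enlarge the genome") from None
        if within is not None and not (
            chrom == within.chrom
            and within.start + SLOT_STEP <= center < within.end - SLOT_STEP
        ):
            continue
        out.append((chrom, center))
    return out


def _peak(chrom: str, center: int, neglog10: float, fold: Optional[float], name: str) -> ScoredPeak:
    start = max(0, center - PEAK_HALFWIDTH)
    return ScoredPeak(
        GenomicInterval(chrom, start, center + PEAK_HALFWIDTH),
        neglog10_p=max(neglog10, 0.0),
        fold_enrichment=fold,
        name=name,
    )


def _jittered_replicates(
    rng: np.random.Generator,
    true_sites: Sequence[tuple[str, int, float, Optional[float], str]],
    n_replicates: int,
    pos_sd: float,
    score_sd: float,
    assay: str,
    factor: str,
    tissue: str = "HL",
    min_neglog10: float = 6.1,
) -> list[PeakCollection]:
    """Replicates are jittered copies of true sites: centers displaced by
    N(0, pos_sd), scores by N(0, score_sd), floored above the weak
    admission threshold so planted sites survive consensus."""
    reps = []
    for ri in range(n_replicates):
        peaks = []
        for chrom, center, nl, fold, name in true_sites:
            c = int(round(center + rng.normal(0.0, pos_sd)))
            score = max(nl + rng.normal(0.0, score_sd), min_neglog10)
            peaks.append(_peak(chrom, c, score, fold, f"{name}_r{ri + 1}"))
        reps.append(
            PeakCollection(peaks=peaks, assay=assay, factor=factor, tissue=tissue, replicate=ri + 1)
        )
    return reps


# ---------------------------------------------------------------------------
# cistrome generator
# ---------------------------------------------------------------------------

@dataclass
class CistromeData:
    replicates: dict[str, list[PeakCollection]]  # factor/mark -> per-replicate calls
    truth: pd.DataFrame                          # one row per true region


def gen_peaksets(cfg: SimConfig, layout: Optional[GenomeLayout] = None) -> CistromeData:
    """Planted TF-A/TF-B co-binding structure with chromatin overlays.

    ``cobound_fraction`` of A regions carry a coincident B site; co-bound
    regions receive ``cobound_signal_shift`` extra -log10 p on their ATAC
    and H3K27ac peaks. Per-factor replicates are jittered copies, plus a
    handful of irreproducible single-replicate peaks that the consensus
    stage must reject.
    """
    layout = layout or gen_genome(cfg)
    plan = cfg.cistrome
    rng = _rng(cfg, 2)
    slots = _slot_iter(layout)

    a_slots = _take_slots(slots, plan.n_regions_a)
    b_slots = _take_slots(slots, plan.n_b_specific)
    cobound = rng.random(plan.n_regions_a) < plan.cobound_fraction

    def draw_nl(n, lo, hi):
        return rng.uniform(lo, hi, n)

    a_nl = draw_nl(plan.n_regions_a, *plan.tf_neglog10_range)
    b_extra_nl = draw_nl(plan.n_b_specific, *plan.tf_neglog10_range)
    b_at_a_nl = draw_nl(plan.n_regions_a, *plan.tf_neglog10_range)
    a_fold = rng.uniform(*plan.fold_range, plan.n_regions_a)
    b_fold = rng.uniform(*plan.fold_range, plan.n_b_specific)

    truth_rows = []
    a_sites, b_sites = [], []
    for i, (chrom, center) in enumerate(a_slots):
        cls = "both" if cobound[i] else "A_only"
        a_sites.append((chrom, center, a_nl[i], a_fold[i], f"A_{i}"))
        if cobound[i]:
            b_sites.append((chrom, center, b_at_a_nl[i], None, f"Bco_{i}"))
        truth_rows.append({"chrom": chrom, "center": center, "class": cls})
    for i, (chrom, center) in enumerate(b_slots):
        b_sites.append((chrom, center, b_extra_nl[i], b_fold[i], f"B_{i}"))
        truth_rows.append({"chrom": chrom, "center": center, "class": "B_only"})
    truth = pd.DataFrame(truth_rows)

    # chromatin overlays: ATAC + H3K27ac at every TF region (shifted where
    # co-bound), plus background peaks elsewhere
    atac_sites, k27ac_sites = [], []
    lo, hi = plan.atac_neglog10_range
    for i, (chrom, center, cls) in enumerate(
        zip(truth["chrom"], truth["center"], truth["class"])
    ):
        shift = plan.cobound_signal_shift if cls == "both" else 0.0
        atac_sites.append((chrom, center, rng.uniform(lo, hi) + shift, None, f"atac_{i}"))
        k27ac_sites.append((chrom, center, rng.uniform(lo, hi) + shift, None, f"k27ac_{i}"))
    bg_slots = _take_slots(slots, plan.n_background_marks)
    for i, (chrom, center) in enumerate(bg_slots):
        atac_sites.append((chrom, center, rng.uniform(lo, hi), None, f"atac_bg_{i}"))
        k27ac_sites.append((chrom, center, rng.uniform(lo, hi), None, f"k27ac_bg_{i}"))
    k27me3_slots = _take_slots(slots, plan.n_h3k27me3)
    k27me3_sites = [
        (c, p, rng.uniform(lo, hi), None, f"k27me3_{i}") for i, (c, p) in enumerate(k27me3_slots)
    ]
    ctcf_slots = _take_slots(slots, plan.n_ctcf)
    ctcf_sites = [
        (c, p, rng.uniform(lo, hi), None, f"ctcf_{i}") for i, (c, p) in enumerate(ctcf_slots)
    ]

    reps = {
        "pbx": _jittered_replicates(
            rng, a_sites, plan.n_replicates_tf, plan.pos_jitter_sd, plan.score_jitter_sd,
            "TF-ChIP", "PBX1",
        ),
        "hand2": _jittered_replicates(
            rng, b_sites, plan.n_replicates_tf, plan.pos_jitter_sd, plan.score_jitter_sd,
            "TF-ChIP", "HAND2",
        ),
        "atac": _jittered_replicates(
            rng, atac_sites, plan.n_replicates_atac, plan.pos_jitter_sd, plan.score_jitter_sd,
            "ATAC", "ATAC",
        ),
        "h3k27ac": _jittered_replicates(
            rng, k27ac_sites, plan.n_replicates_histone, plan.pos_jitter_sd, plan.score_jitter_sd,
            "histone-ChIP", "H3K27ac",
        ),
        "h3k27me3": _jittered_replicates(
            rng, k27me3_sites, plan.n_replicates_histone, plan.pos_jitter_sd, plan.score_jitter_sd,
            "histone-ChIP", "H3K27me3",
        ),
        "ctcf": _jittered_replicates(
            rng, ctcf_sites, plan.n_replicates_histone, plan.pos_jitter_sd, plan.score_jitter_sd,
            "CTCF", "CTCF",
        ),
    }
    # irreproducible peaks: appended to the first replicate only
    for key, factor in (("pbx", "PBX1"), ("hand2", "HAND2")):
        irr_slots = _take_slots(slots, plan.n_irreproducible)
        for i, (chrom, center) in enumerate(irr_slots):
            reps[key][0].peaks.append(
                _peak(chrom, center, rng.uniform(*plan.tf_neglog10_range),
                      rng.uniform(*plan.fold_range), f"{factor}_irr_{i}")
            )
    return CistromeData(replicates=reps, truth=truth)


# ---------------------------------------------------------------------------
# DEG tables
# ---------------------------------------------------------------------------

def gen_deg_tables(cfg: SimConfig, layout: Optional[GenomeLayout] = None):
    """Two DEG tables with planted concordant/discordant classes.

    Planted genes receive |log2FC| comfortably above log2(1.2) and FDR
    well below 0.05 in the designated contrasts; null genes always fail
    the FDR threshold. Returns (table_a, table_b, truth DataFrame).
    """
    layout = layout or gen_genome(cfg)
    plan = cfg.deg
    rng = _rng(cfg, 3)
    gene_ids = [g.gene_id for g in layout.genes]
    n_planted = (
        plan.concordant_up + plan.concordant_down + plan.discordant + plan.a_only + plan.b_only
    )
    if n_planted > len(gene_ids):
        raise ValidationError("deg plan exceeds the number of genes")
    chosen = rng.choice(len(gene_ids), size=n_planted, replace=False)
    classes = (
        ["concordant_up"] * plan.concordant_up
        + ["concordant_down"] * plan.concordant_down
        + ["discordant"] * plan.discordant
        + ["a_only"] * plan.a_only
        + ["b_only"] * plan.b_only
    )
    truth = {gene_ids[i]: c for i, c in zip(chosen, classes)}

    def sig_lfc(sign):
        return sign * plan.effect_log2fc * rng.uniform(1.0, 2.0)

    def sig_fdr():
        return 10.0 ** rng.uniform(-6.0, -2.0)

    def null_lfc():
        return rng.normal(0.0, 0.1)

    def null_fdr():
        return rng.uniform(0.2, 1.0)

    rows_a, rows_b, truth_rows = [], [], []
    for g in gene_ids:
        cls = truth.get(g, "null")
        detected = True
        if cls == "null" and rng.random() < plan.frac_undetected:
            detected = False
        if cls == "concordant_up":
            la, fa, lb, fb = sig_lfc(1), sig_fdr(), sig_lfc(1), sig_fdr()
        elif cls == "concordant_down":
            la, fa, lb, fb = sig_lfc(-1), sig_fdr(), sig_lfc(-1), sig_fdr()
        elif cls == "discordant":
            s = 1 if rng.random() < 0.5 else -1
            la, fa, lb, fb = sig_lfc(s), sig_fdr(), sig_lfc(-s), sig_fdr()
        elif cls == "a_only":
            la, fa = sig_lfc(1 if rng.random() < 0.5 else -1), sig_fdr()
            lb, fb = null_lfc(), null_fdr()
        elif cls == "b_only":
            la, fa = null_lfc(), null_fdr()
            lb, fb = sig_lfc(1 if rng.random() < 0.5 else -1), sig_fdr()
        else:
            la, fa, lb, fb = null_lfc(), null_fdr(), null_lfc(), null_fdr()
        rows_a.append(
            {"gene_id": g, "log2fc": la, "fdr": fa, "detected_all_reps": detected}
        )
        rows_b.append(
            {"gene_id": g, "log2fc": lb, "fdr": fb, "detected_all_reps": detected}
        )
        truth_rows.append({"gene_id": g, "class": cls, "detected": detected})
    return pd.DataFrame(rows_a), pd.DataFrame(rows_b), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# single-cell counts
# ---------------------------------------------------------------------------

def gen_sc_counts(cfg: SimConfig) -> AnnData:
    """Negative-binomial UMI counts with planted cluster structure, a
    double-positive posterior-mesenchyme subpopulation inside cluster 0,
    planted co-expressed target genes, flagged mitochondrial genes, and
    cells planted to fail each QC rule.

    Truth lives in ``obs`` (true_cluster, is_posterior, planted_fail) and
    ``var`` (mito, planted_target, cluster_marker).
    """
    plan = cfg.sc
    rng = _rng(cfg, 4)
    n_clusters = len(plan.cells_per_cluster)
    if plan.n_posterior > plan.cells_per_cluster[0]:
        raise ValidationError("n_posterior exceeds cluster 0 size")

    special = ["Hand2", "Pbx1", "Pbx2", *plan.planted_targets]
    n_regular = plan.n_genes - len(special) - plan.n_mito
    if n_regular <= n_clusters * plan.markers_per_cluster:
        raise ValidationError("sc plan leaves too few regular genes")
    gene_names = (
        special
        + [f"mt-{i + 1}" for i in range(plan.n_mito)]
        + [f"gsc{i:04d}" for i in range(n_regular)]
    )
    mito = np.zeros(plan.n_genes, dtype=bool)
    mito[len(special) : len(special) + plan.n_mito] = True

    # relative abundance weights; cluster markers boosted per cluster
    w = rng.gamma(2.0, 1.0, plan.n_genes)
    w[: len(special)] = 0.0  # special genes handled via absolute means
    w[mito] = w[mito] / w[mito].sum() * (plan.mito_frac / (1 - plan.mito_frac)) * w[~mito].sum()
    marker_idx = {}
    regular_start = len(special) + plan.n_mito
    for c in range(n_clusters):
        lo = regular_start + c * plan.markers_per_cluster
        marker_idx[c] = np.arange(lo, lo + plan.markers_per_cluster)
    target_idx = np.array([gene_names.index(g) for g in plan.planted_targets])

    cells = []
    cell_truth = []
    for c, n_cells in enumerate(plan.cells_per_cluster):
        for i in range(n_cells):
            posterior = c == 0 and i < plan.n_posterior
            cells.append((c, posterior, ""))
    for _ in range(plan.n_fail_low_total):
        cells.append((0, False, "low_total"))
    for _ in range(plan.n_fail_high_total):
        cells.append((0, False, "high_total"))
    for _ in range(plan.n_fail_high_mito):
        cells.append((0, False, "high_mito"))

    n_cells_total = len(cells)
    counts = np.zeros((n_cells_total, plan.n_genes), dtype=np.int64)
    theta = plan.nb_dispersion
    for ci, (clus, posterior, fail) in enumerate(cells):
        wc = w.copy()
        wc[marker_idx[clus]] *= plan.marker_fold
        if fail == "high_mito":
            wc[mito] = wc[mito] / wc[mito].sum() * 0.45 * wc[~mito].sum()
        total = rng.uniform(*plan.total_range)
        if fail == "low_total":
            total = 1500.0
        elif fail == "high_total":
            total = 40000.0
        mean = wc / wc.sum() * total
        scale = total / 10000.0
        mean[gene_names.index("Hand2")] = (
            plan.hand_mean if posterior else plan.hand_background_mean
        ) * scale
        mean[gene_names.index("Pbx1")] = plan.pbx1_mean * scale
        mean[gene_names.index("Pbx2")] = plan.pbx2_mean * scale
        base_target = 3.0 * scale
        mean[target_idx] = base_target * (
            math.exp(plan.target_effect_log) if posterior else 1.0
        )
        p = theta / (theta + mean)
        counts[ci] = rng.negative_binomial(theta, p)
        cell_truth.append(
            {"true_cluster": clus if not fail else -1, "is_posterior": posterior, "planted_fail": fail}
        )

    obs = pd.DataFrame(cell_truth, index=[f"cell_{i:05d}" for i in range(n_cells_total)])
    var = pd.DataFrame(
        {
            "mito": mito,
            "planted_target": np.isin(np.arange(plan.n_genes), target_idx),
            "cluster_marker": np.isin(
                np.arange(plan.n_genes), np.concatenate(list(marker_idx.values()))
            ),
        },
        index=gene_names,
    )
    return AnnData(X=counts, obs=obs, var=var)


# ---------------------------------------------------------------------------
# enhancer landscape
# ---------------------------------------------------------------------------

FAIL_MODES = ("low_fold", "promoter", "no_h3k27ac", "no_atac", "not_conserved")


@dataclass
class EnhancerLandscape:
    tad: TadRecord
    target_gene: GeneModel
    tf_replicates: list[PeakCollection]
    h3k27ac_replicates: list[PeakCollection]
    atac_replicates: list[PeakCollection]
    conserved: list[GenomicInterval]
    truth: pd.DataFrame  # center, passes, fail_mode


def gen_enhancer_landscape(
    cfg: SimConfig, layout: Optional[GenomeLayout] = None
) -> EnhancerLandscape:
    """A TAD with planted passing candidates and candidates that each
    violate exactly one evidence filter."""
    layout = layout or gen_genome(cfg)
    plan = cfg.enhancer
    cist = cfg.cistrome
    rng = _rng(cfg, 5)
    tad = layout.tads[0]
    target_gene = next(g for g in layout.genes if g.gene_id in tad.genes)
    # consume a dedicated stretch of the slot pool restricted to the TAD
    slots = _slot_iter(layout)
    centers = _take_slots(slots, plan.n_passing + plan.n_failing, within=tad.interval)

    tad_gene_models = [g for g in layout.genes if g.gene_id in tad.genes]
    tf_sites, k27_sites, atac_sites, conserved = [], [], [], []
    truth_rows = []
    promoter_uses = 0
    lo, hi = cist.atac_neglog10_range
    for i, (chrom, center) in enumerate(centers):
        if i < plan.n_passing:
            mode = ""
        else:
            mode = FAIL_MODES[(i - plan.n_passing) % len(FAIL_MODES)]
        fold = plan.low_fold if mode == "low_fold" else rng.uniform(*plan.pass_fold_range)
        if mode == "promoter":
            # each promoter-failing candidate sits on a distinct TSS so that
            # consensus merging keeps them separate
            center = tad_gene_models[promoter_uses].tss
            promoter_uses += 1
        nl = rng.uniform(*cist.tf_neglog10_range)
        tf_sites.append((chrom, center, nl, fold, f"cand_{i}"))
        if mode != "no_h3k27ac":
            k27_sites.append((chrom, center, rng.uniform(lo, hi), None, f"ek27_{i}"))
        if mode != "no_atac":
            atac_sites.append((chrom, center, rng.uniform(lo, hi), None, f"eatac_{i}"))
        if mode != "not_conserved":
            conserved.append(GenomicInterval(chrom, center - 100, center + 100))
        truth_rows.append(
            {"chrom": chrom, "center": center, "passes": mode == "", "fail_mode": mode}
        )
    conserved.extend(layout.conserved_background)
    return EnhancerLandscape(
        tad=tad,
        target_gene=target_gene,
        tf_replicates=_jittered_replicates(
            rng, tf_sites, cist.n_replicates_tf, cist.pos_jitter_sd, cist.score_jitter_sd,
            "TF-ChIP", "PBX1",
        ),
        h3k27ac_replicates=_jittered_replicates(
            rng, k27_sites, cist.n_replicates_histone, cist.pos_jitter_sd,
            cist.score_jitter_sd, "histone-ChIP", "H3K27ac",
        ),
        atac_replicates=_jittered_replicates(
            rng, atac_sites, cist.n_replicates_atac, cist.pos_jitter_sd,
            cist.score_jitter_sd, "ATAC", "ATAC",
        ),
        conserved=conserved,
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# cross-tissue cistromes
# ---------------------------------------------------------------------------

@dataclass
class CrossTissueData:
    pbx_by_tissue: dict[str, PeakCollection]
    cofactor_by_tissue: dict[str, PeakCollection]
    signal_table: pd.DataFrame
    truth: dict


def gen_cross_tissue(cfg: SimConfig, layout: Optional[GenomeLayout] = None) -> CrossTissueData:
    """Multi-tissue PBX cistromes with a shared core, cofactor peaks
    planted at per-tissue selection rates, and a signal table with a
    planted log2FC shift at cofactor-co-bound regions."""
    layout = layout or gen_genome(cfg)
    plan = cfg.cross_tissue
    cist = cfg.cistrome
    rng = _rng(cfg, 6)
    # a fresh pass over the slot pool: internal disjointness is what the
    # cross-tissue analysis needs, and its inputs never meet the other
    # generators' collections
    slots = _slot_iter(layout)
    core = _take_slots(slots, plan.n_core)
    pbx_by_tissue: dict[str, PeakCollection] = {}
    tissue_slots: dict[str, list[tuple[str, int]]] = {}
    for tissue in plan.tissues:
        specific = _take_slots(slots, plan.n_specific)
        all_slots = core + specific
        tissue_slots[tissue] = all_slots
        peaks = [
            _peak(chrom, center, rng.uniform(*cist.tf_neglog10_range),
                  rng.uniform(*cist.fold_range), f"pbx_{tissue}_{i}")
            for i, (chrom, center) in enumerate(all_slots)
        ]
        pbx_by_tissue[tissue] = PeakCollection(
            peaks=peaks, assay="TF-ChIP", factor="PBX1", tissue=tissue, replicate=0
        )

    rates = dict(plan.cofactor_rates)
    cofactor_by_tissue: dict[str, PeakCollection] = {}
    planted_hits: dict[str, int] = {}
    for tissue, rate in rates.items():
        hits = rng.random(plan.n_cofactor) < rate
        on_pbx = rng.choice(len(tissue_slots[tissue]), size=int(hits.sum()), replace=False)
        off_slots = _take_slots(slots, int((~hits).sum()))
        peaks = []
        oi = 0
        pi = 0
        for i in range(plan.n_cofactor):
            if hits[i]:
                chrom, center = tissue_slots[tissue][on_pbx[pi]]
                pi += 1
            else:
                chrom, center = off_slots[oi]
                oi += 1
            peaks.append(
                _peak(chrom, center, rng.uniform(*cist.tf_neglog10_range), None,
                      f"cof_{tissue}_{i}")
            )
        cofactor_by_tissue[tissue] = PeakCollection(
            peaks=peaks, assay="TF-ChIP", factor="HAND2", tissue=tissue, replicate=0
        )
        planted_hits[tissue] = int(hits.sum())

    # signal table: planted log2FC shift at cofactor-co-bound regions
    n_rows = plan.n_signal_cobound + plan.n_signal_other
    sig_slots = _take_slots(slots, n_rows)
    base_a = rng.lognormal(3.0, 0.5, n_rows)
    base_b = rng.lognormal(3.0, 0.5, n_rows)
    labels = ["cofactor_cobound"] * plan.n_signal_cobound + ["other"] * plan.n_signal_other
    shift = np.where(
        np.arange(n_rows) < plan.n_signal_cobound, 2.0 ** plan.signal_shift_log2, 1.0
    )
    ta, tb = plan.tissues[0], plan.tissues[1]
    signal_table = pd.DataFrame(
        {
            "chrom": [c for c, _ in sig_slots],
            "start": [p - PEAK_HALFWIDTH for _, p in sig_slots],
            "end": [p + PEAK_HALFWIDTH for _, p in sig_slots],
            f"signal_{ta}": base_a * shift,
            f"signal_{tb}": base_b,
            "subset_label": labels,
        }
    )
    truth = {
        "cofactor_rates": rates,
        "planted_hits": planted_hits,
        "n_cofactor": plan.n_cofactor,
        "n_core": plan.n_core,
        "signal_shift_log2": plan.signal_shift_log2,
    }
    return CrossTissueData(
        pbx_by_tissue=pbx_by_tissue,
        cofactor_by_tissue=cofactor_by_tissue,
        signal_table=signal_table,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_gff3(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.interval.chrom,
                        "limbgrn_sim",
                        "gene",
                        str(g.interval.start + 1),  # GFF is 1-based inclusive
                        str(g.interval.end),
                        ".",
                        g.interval.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


def write_bed(intervals: Sequence[GenomicInterval], path, names: Optional[Sequence[str]] = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv_{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def write_sc_matrix(adata: AnnData, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    mat = sparse.csr_matrix(np.asarray(adata.X))
    scipy_io.mmwrite(os.path.join(outdir, "matrix.mtx"), mat.T)  # genes x cells
    adata.var["mito"].astype(int).to_csv(
        os.path.join(outdir, "genes.tsv"), sep="\t", header=False
    )
    pd.Series(adata.obs_names).to_csv(
        os.path.join(outdir, "barcodes.tsv"), sep="\t", header=False, index=False
    )


def read_sc_matrix(indir) -> AnnData:
    mat = scipy_io.mmread(os.path.join(indir, "matrix.mtx")).T.tocsr()
    genes = pd.read_csv(os.path.join(indir, "genes.tsv"), sep="\t", header=None, index_col=0)
    barcodes = pd.read_csv(os.path.join(indir, "barcodes.tsv"), sep="\t", header=None)
    adata = AnnData(X=np.asarray(mat.todense()).astype(np.int64))
    adata.obs_names = barcodes[0].astype(str).tolist()
    adata.var_names = genes.index.astype(str).tolist()
    adata.var["mito"] = genes[1].astype(bool).to_numpy()
    return adata


def simulate_to_dir(cfg: SimConfig, outdir) -> dict:
    """Generate every pipeline input under ``outdir`` (standard formats)
    with truth sidecars under ``outdir/truth``. Returns the path map."""
    layout = gen_genome(cfg)
    outdir = str(outdir)
    peaks_dir = os.path.join(outdir, "peaks")
    enh_dir = os.path.join(outdir, "enhancer")
    ct_dir = os.path.join(outdir, "cross_tissue")
    truth_dir = os.path.join(outdir, "truth")
    sc_dir = os.path.join(outdir, "sc")
    for d in (outdir, peaks_dir, enh_dir, ct_dir, truth_dir, sc_dir):
        os.makedirs(d, exist_ok=True)

    write_gff3(layout.genes, os.path.join(outdir, "genes.gff3"))
    write_bed(
        [t.interval for t in layout.tads],
        os.path.join(outdir, "tads.bed"),
        names=[t.tad_id for t in layout.tads],
    )

    cist = gen_peaksets(cfg, layout)
    for key, reps in cist.replicates.items():
        for coll in reps:
            write_peaks(
                coll, os.path.join(peaks_dir, f"{key}_rep{coll.replicate}.narrowPeak")
            )
    cist.truth.to_csv(os.path.join(truth_dir, "cistrome.tsv"), sep="\t", index=False)

    deg_a, deg_b, deg_truth = gen_deg_tables(cfg, layout)
    deg_a.to_csv(os.path.join(outdir, "deg_pbx.tsv"), sep="\t", index=False)
    deg_b.to_csv(os.path.join(outdir, "deg_hand2.tsv"), sep="\t", index=False)
    deg_truth.to_csv(os.path.join(truth_dir, "deg.tsv"), sep="\t", index=False)

    adata = gen_sc_counts(cfg)
    write_sc_matrix(adata, sc_dir)
    adata.obs.to_csv(os.path.join(truth_dir, "sc_cells.tsv"), sep="\t")
    adata.var.to_csv(os.path.join(truth_dir, "sc_genes.tsv"), sep="\t")

    enh = gen_enhancer_landscape(cfg, layout)
    for coll in enh.tf_replicates:
        write_peaks(coll, os.path.join(enh_dir, f"pbx_tad_rep{coll.replicate}.narrowPeak"))
    for coll in enh.h3k27ac_replicates:
        write_peaks(coll, os.path.join(enh_dir, f"h3k27ac_tad_rep{coll.replicate}.narrowPeak"))
    for coll in enh.atac_replicates:
        write_peaks(coll, os.path.join(enh_dir, f"atac_tad_rep{coll.replicate}.narrowPeak"))
    write_bed(enh.conserved, os.path.join(outdir, "conserved.bed"))
    enh.truth.to_csv(os.path.join(truth_dir, "enhancer.tsv"), sep="\t", index=False)
    with open(os.path.join(truth_dir, "enhancer_meta.json"), "w") as fh:
        json.dump({"tad_id": enh.tad.tad_id, "target_gene": enh.target_gene.gene_id}, fh)

    ct = gen_cross_tissue(cfg, layout)
    for tissue, coll in ct.pbx_by_tissue.items():
        write_peaks(coll, os.path.join(ct_dir, f"pbx_{tissue}.narrowPeak"))
    for tissue, coll in ct.cofactor_by_tissue.items():
        write_peaks(coll, os.path.join(ct_dir, f"cofactor_{tissue}.narrowPeak"))
    ct.signal_table.to_csv(os.path.join(ct_dir, "signal_table.tsv"), sep="\t", index=False)
    with open(os.path.join(truth_dir, "cross_tissue.json"), "w") as fh:
        json.dump(ct.truth, fh, sort_keys=True)

    return {"outdir": outdir}
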