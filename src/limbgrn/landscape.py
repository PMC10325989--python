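"""TAD-scoped enhancer prioritization and regulatory scoring.

Candidate enhancers inside a TAD are consensus TF peaks that pass the
conjunction of six evidence filters: replicated binding, fold enrichment
>= 15, no promoter overlap, H3K27ac overlap, open chromatin (ATAC), and
overlap with a conserved noncoding element. A TAD's regulatory score is
the count and summed strength (-log10 p) of the distal (non-promoter)
sites bound within it; DEG-containing TADs are compared to the rest with a
one-sided rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from scipy import stats

from .cistrome import ClassComparison, DEFAULT_PROMOTER_HALFWIDTH, GeneModel, P_FLOOR
from .intervals import (
    GenomicInterval,
    PeakCollection,
    ValidationError,
    build_trees,
    merge_union,
    query_overlaps,
)

DEFAULT_MIN_FOLD = 15.0

ENHANCER_FLAGS = (
    "replicated_tf",
    "min_fold",
    "non_promoter",
    "h3k27ac",
    "atac",
    "conserved",
)


@dataclass(frozen=True)
class TadRecord:
    """A topologically associating domain and the genes it contains."""

    interval: GenomicInterval
    tad_id: str
    genes: tuple[str, ...] = ()


@dataclass
class EnhancerCandidate:
    interval: GenomicInterval
    fold_enrichment: float
    flags: dict[str, bool] = field(default_factory=dict)
    name: str = "."

    @property
    def passes(self) -> bool:
        return all(self.flags[f] for f in ENHANCER_FLAGS)


@dataclass(frozen=True)
class TadScore:
    tad_id: str
    n_distal_sites: int
    summed_strength: float

    def __post_init__(self) -> None:
        if self.n_distal_sites < 0 or self.summed_strength < 0:
            raise ValidationError("TAD score components must be non-negative")


def read_tads(path) -> list[TadRecord]:
    """Read TAD definitions from BED (chrom, start, end[, tad_id])."""
    tads = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            tad_id = f[3] if len(f) > 3 else f"tad_{i}"
            tads.append(TadRecord(GenomicInterval(f[0], int(f[1]), int(f[2])), tad_id))
    return tads


def read_bed_intervals(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
    return out


def _promoter_windows(
    genes: Sequence[GeneModel], halfwidth_bp: int
) -> list[GenomicInterval]:
    return [g.promoter_window(halfwidth_bp) for g in genes]


def prioritize_enhancers(
    tad: TadRecord,
    tf_peaks: PeakCollection,
    h3k27ac: PeakCollection,
    atac: PeakCollection,
    conserved: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    min_fold: float = DEFAULT_MIN_FOLD,
    promoter_halfwidth_bp: int = DEFAULT_PROMOTER_HALFWIDTH,
) -> list[EnhancerCandidate]:
    """One candidate per consensus TF peak inside the TAD, with the six
    evidence flags evaluated by >= 1 bp overlap. ``passes`` is their
    conjunction."""
    k27_trees = build_trees([p.interval for p in h3k27ac])
    atac_trees = build_trees([p.interval for p in atac])
    cons_trees = build_trees(list(conserved))
    prom_trees = build_trees(_promoter_windows(genes, promoter_halfwidth_bp))
    out: list[EnhancerCandidate] = []
    for p in tf_peaks:
        if not p.interval.overlaps(tad.interval):
            continue
        fold = p.fold_enrichment if p.fold_enrichment is not None else 0.0
        flags = {
            "replicated_tf": True,  # input contract: tf_peaks is a consensus set
            "min_fold": fold >= min_fold,
            "non_promoter": not query_overlaps(prom_trees, p.interval, 1),
            "h3k27ac": bool(query_overlaps(k27_trees, p.interval, 1)),
            "atac": bool(query_overlaps(atac_trees, p.interval, 1)),
            "conserved": bool(query_overlaps(cons_trees, p.interval, 1)),
        }
        out.append(
            EnhancerCandidate(
                interval=p.interval, fold_enrichment=fold, flags=flags, name=p.name
            )
        )
    return out


def candidates_to_dataframe(candidates: Sequence[EnhancerCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        row = {
            "chrom": c.interval.chrom,
            "start": c.interval.start,
            "end": c.interval.end,
            "name": c.name,
            "fold_enrichment": c.fold_enrichment,
        }
        row.update({f: c.flags[f] for f in ENHANCER_FLAGS})
        row["passes"] = c.passes
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reporter-assay ledger
# ---------------------------------------------------------------------------

LEDGER_COLUMNS = (
    "element_id",
    "previously_known_limb",
    "tested",
    "any_tissue_activity",
    "reproducible_limb_domain",
)


def validate_reporter_ledger(ledger: pd.DataFrame) -> None:
    missing = set(LEDGER_COLUMNS) - set(ledger.columns)
    if missing:
        raise ValidationError(f"ledger missing columns {sorted(missing)}")
    if ledger["element_id"].duplicated().any():
        raise ValidationError("ledger rows must be unique by element_id")
    bad = ledger["reproducible_limb_domain"] & ~ledger["tested"]
    if bad.any():
        raise ValidationError(
            "reproducible_limb_domain implies tested; violated by "
            + ", ".join(ledger.loc[bad, "element_id"].astype(str))
        )


def tally_reporter_assays(ledger: pd.DataFrame) -> dict[str, int]:
    """Row-set cardinalities of a transgenic reporter ledger. The total
    number of validated limb enhancers is the previously known ones plus
    those with a reproducible limb-domain activity in this round."""
    validate_reporter_ledger(ledger)
    known = int(ledger["previously_known_limb"].sum())
    reproducible = int(ledger["reproducible_limb_domain"].sum())
    return {
        "known_limb": known,
        "tested": int(ledger["tested"].sum()),
        "tissue_active": int(ledger["any_tissue_activity"].sum()),
        "reproducible_limb": reproducible,
        "total_validated_limb": known + reproducible,
    }


# ---------------------------------------------------------------------------
# TAD regulatory score
# ---------------------------------------------------------------------------

def tad_regulatory_score(
    tad: TadRecord,
    site_collections: Sequence[PeakCollection],
    genes: Sequence[GeneModel],
    promoter_halfwidth_bp: int = DEFAULT_PROMOTER_HALFWIDTH,
) -> TadScore:
    """Count and summed strength of the distal bound sites within a TAD.

    Sites are the union-merged regions of the given consensus collections
    restricted to the TAD; regions overlapping any promoter window are
    excluded. A merged region's strength is its best member -log10 p.
    """
    merged = merge_union(list(site_collections))
    prom_trees = build_trees(_promoter_windows(genes, promoter_halfwidth_bp))
    n, strength = 0, 0.0
    for region in merged:
        if not region.interval.overlaps(tad.interval):
            continue
        if query_overlaps(prom_trees, region.interval, 1):
            continue
        n += 1
        strength += region.neglog10_p
    return TadScore(tad_id=tad.tad_id, n_distal_sites=n, summed_strength=strength)


def compare_tad_scores(
    deg_tads: Sequence[TadScore], other_tads: Sequence[TadScore]
) -> dict[str, ClassComparison]:
    """One-sided Mann-Whitney tests (DEG TADs greater) on both the summed
    strength and the distal-site count."""
    if not deg_tads or not other_tads:
        raise ValidationError("both TAD score lists must be non-empty")
    out = {}
    for attr in ("summed_strength", "n_distal_sites"):
        a = [float(getattr(t, attr)) for t in deg_tads]
        b = [float(getattr(t, attr)) for t in other_tads]
        if all(x == a[0] for x in a + b):
            stat, p = len(a) * len(b) / 2.0, 1.0
        else:
            res = stats.mannwhitneyu(a, b, alternative="greater")
            stat, p = float(res.statistic), float(res.pvalue)
        out[attr] = ClassComparison(
            test="mann_whitney_greater",
            statistic=stat,
            p_value=max(p, P_FLOOR),
            group_sizes=(len(a), len(b)),
            floored=p < P_FLOOR,
        )
    return out
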