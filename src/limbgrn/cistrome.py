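"""Co-binding cistrome classification and chromatin-state overlay.

Partitions the merged regions of two consensus cistromes into A-only /
B-only / co-bound classes, annotates each region's genomic context against
a gene model (promoter / intragenic / intergenic with precedence in that
order), overlays chromatin-state evidence (H3K27ac, H3K27me3, ATAC, CTCF),
and runs the class-wise rank tests.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    GenomicInterval,
    MergedRegion,
    PeakCollection,
    ValidationError,
    build_trees,
    merge_union,
    query_overlaps,
)

logger = logging.getLogger("limbgrn")

COBINDING_CLASSES = ("A_only", "B_only", "both")
CONTEXT_LABELS = ("promoter", "intragenic", "intergenic")
CHROMATIN_MARKS = ("h3k27ac", "h3k27me3", "atac", "ctcf")

DEFAULT_PROMOTER_HALFWIDTH = 2000

#: smallest positive subnormal double; p-values are floored here, never 0
P_FLOOR = sys.float_info.min * sys.float_info.epsilon


@dataclass(frozen=True)
class GeneModel:
    """A gene body with its strand-aware transcription start site."""

    gene_id: str
    interval: GenomicInterval
    tss: int

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.tss < self.interval.end):
            raise ValidationError(
                f"TSS {self.tss} outside gene body {self.interval} for {self.gene_id}"
            )

    def promoter_window(self, halfwidth_bp: int) -> GenomicInterval:
        start = max(0, self.tss - halfwidth_bp)
        return GenomicInterval(self.interval.chrom, start, self.tss + halfwidth_bp)


@dataclass
class CistromePartition:
    """Disjoint classification of merged regions into A-only / B-only /
    co-bound, with optional genomic-context and chromatin-state layers."""

    regions: list[MergedRegion]
    class_of: list[str]
    a_label: str = "A"
    b_label: str = "B"
    context_of: Optional[list[str]] = None
    evidence: Optional[list[dict[str, bool]]] = None
    signal: Optional[list[dict[str, float]]] = None

    def __post_init__(self) -> None:
        if len(self.regions) != len(self.class_of):
            raise ValidationError("regions and class_of must have equal length")
        for c in self.class_of:
            if c not in COBINDING_CLASSES:
                raise ValidationError(f"unknown class label {c!r}")

    def __len__(self) -> int:
        return len(self.regions)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in COBINDING_CLASSES}
        for c in self.class_of:
            counts[c] += 1
        return counts

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            "chrom": [r.interval.chrom for r in self.regions],
            "start": [r.interval.start for r in self.regions],
            "end": [r.interval.end for r in self.regions],
            "class": list(self.class_of),
        }
        if self.context_of is not None:
            data["context"] = list(self.context_of)
        if self.evidence is not None:
            for mark in CHROMATIN_MARKS:
                data[mark] = [e[mark] for e in self.evidence]
        if self.signal is not None:
            for mark in CHROMATIN_MARKS:
                data[f"{mark}_signal"] = [s[mark] for s in self.signal]
        return pd.DataFrame(data)


def partition_total(class_counts: Mapping[str, int]) -> int:
    """Total size of a partitioned merged set (the class counts are
    exhaustive and mutually exclusive, so the total is their sum)."""
    if any(v < 0 for v in class_counts.values()):
        raise ValidationError("class counts must be non-negative")
    return int(sum(class_counts.values()))


@dataclass(frozen=True)
class ClassComparison:
    """Result of a rank-based comparison between region classes."""

    test: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    floored: bool = False

    def format_p(self) -> str:
        return f"< {P_FLOOR:g}" if self.floored else f"{self.p_value:g}"


# ---------------------------------------------------------------------------
# gene-model I/O (GFF3/GTF gene features, or BED12)
# ---------------------------------------------------------------------------

def _gff_attr(attrs: str, key: str) -> Optional[str]:
    for part in attrs.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:  # GFF3
            k, v = part.split("=", 1)
            if k.strip() == key:
                return v.strip()
        else:  # GTF: key "value"
            bits = part.split(None, 1)
            if len(bits) == 2 and bits[0] == key:
                return bits[1].strip().strip('"')
    return None


def read_gene_models(path, format: str = "gff3") -> list[GeneModel]:
    """Read gene models from GFF3/GTF (``gene`` features only) or BED12.

    GFF coordinates are 1-based inclusive and converted to 0-based
    half-open here. The TSS is the strand-aware 5' end of the gene body.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    if format in ("gff3", "gtf"):
        key = "ID" if format == "gff3" else "gene_id"
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9:
                    raise ValidationError(f"{path}: line {lineno}: expected 9 columns")
                if fields[2] != "gene":
                    continue
                chrom = fields[0]
                start = int(fields[3]) - 1  # 1-based -> 0-based
                end = int(fields[4])
                strand = fields[6] if fields[6] in ("+", "-") else "."
                gene_id = _gff_attr(fields[8], key) or _gff_attr(fields[8], "gene_id") or f"gene_{lineno}"
                tss = start if strand != "-" else end - 1
                genes.append(
                    GeneModel(gene_id, GenomicInterval(chrom, start, end, strand), tss)
                )
    elif format == "bed12":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 6:
                    raise ValidationError(f"{path}: line {lineno}: expected >= 6 columns")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                strand = fields[5] if fields[5] in ("+", "-") else "."
                tss = start if strand != "-" else end - 1
                genes.append(
                    GeneModel(fields[3], GenomicInterval(chrom, start, end, strand), tss)
                )
    else:
        raise ValidationError(f"unknown gene-model format {format!r}")
    for g in genes:
        if g.gene_id in seen:
            raise ValidationError(f"duplicate gene_id {g.gene_id!r} in {path}")
        seen.add(g.gene_id)
    return genes


# ---------------------------------------------------------------------------
# partition, context, chromatin overlay
# ---------------------------------------------------------------------------

def partition_cobinding(
    a: PeakCollection, b: PeakCollection, min_overlap_bp: int = 1
) -> CistromePartition:
    """Merge two consensus cistromes and label every merged region as
    bound by A only, by B only, or by both (co-bound)."""
    if min_overlap_bp < 0:
        raise ValidationError("min_overlap_bp must be >= 0")
    if len(a) == 0 and len(b) == 0:
        logger.warning("partition_cobinding called with two empty collections")
        return CistromePartition(regions=[], class_of=[], a_label=a.factor or "A", b_label=b.factor or "B")
    merged = merge_union([a, b], labels=["__A__", "__B__"])
    a_trees = build_trees([p.interval for p in a])
    b_trees = build_trees([p.interval for p in b])
    classes: list[str] = []
    for region in merged:
        hit_a = bool(query_overlaps(a_trees, region.interval, min_overlap_bp))
        hit_b = bool(query_overlaps(b_trees, region.interval, min_overlap_bp))
        if hit_a and hit_b:
            classes.append("both")
        elif hit_a:
            classes.append("A_only")
        else:
            classes.append("B_only")
    return CistromePartition(
        regions=merged, class_of=classes, a_label=a.factor or "A", b_label=b.factor or "B"
    )


def assign_context(
    region: GenomicInterval,
    genes: Sequence[GeneModel],
    promoter_halfwidth_bp: int = DEFAULT_PROMOTER_HALFWIDTH,
) -> str:
    """Label a region promoter / intragenic / intergenic against a gene
    model, with precedence promoter > intragenic > intergenic."""
    if promoter_halfwidth_bp <= 0:
        raise ValidationError("promoter_halfwidth_bp must be > 0")
    intragenic = False
    for g in genes:
        if g.interval.chrom != region.chrom:
            continue
        if region.overlaps(g.promoter_window(promoter_halfwidth_bp)):
            return "promoter"
        if region.overlaps(g.interval):
            intragenic = True
    return "intragenic" if intragenic else "intergenic"


def annotate_contexts(
    partition: CistromePartition,
    genes: Sequence[GeneModel],
    promoter_halfwidth_bp: int = DEFAULT_PROMOTER_HALFWIDTH,
) -> CistromePartition:
    """Assign a genomic context to every region of a partition."""
    contexts = [
        assign_context(r.interval, genes, promoter_halfwidth_bp) for r in partition.regions
    ]
    return replace(partition, context_of=contexts)


def annotate_chromatin(
    partition: CistromePartition, marks: Mapping[str, PeakCollection]
) -> CistromePartition:
    """Overlay chromatin-state evidence onto a partition.

    Per region, each mark's boolean flag is set by >= 1 bp overlap with any
    peak of that mark, and the signal map carries the maximum -log10 p
    among overlapping mark peaks (0 if none). Marks not supplied stay
    False / 0.
    """
    for name in marks:
        if name not in CHROMATIN_MARKS:
            raise ValidationError(
                f"unknown mark {name!r}; expected subset of {CHROMATIN_MARKS}"
            )
    trees = {name: build_trees([p.interval for p in coll]) for name, coll in marks.items()}
    evidence: list[dict[str, bool]] = []
    signal: list[dict[str, float]] = []
    for region in partition.regions:
        flags = {m: False for m in CHROMATIN_MARKS}
        sig = {m: 0.0 for m in CHROMATIN_MARKS}
        for name, coll in marks.items():
            hits = query_overlaps(trees[name], region.interval, 1)
            if hits:
                flags[name] = True
                sig[name] = max(coll[j].neglog10_p for j in hits)
        evidence.append(flags)
        signal.append(sig)
    return replace(partition, evidence=evidence, signal=signal)


# ---------------------------------------------------------------------------
# class-wise rank tests
# ---------------------------------------------------------------------------

def compare_classes(
    values_by_class: Mapping[str, Sequence[float]], test: str
) -> ClassComparison:
    """Rank-based comparison of per-class value distributions.

    ``kruskal_wallis`` for >= 2 groups; ``mann_whitney_two_sided`` for
    exactly 2. Midrank tie handling throughout; the returned p-value is
    floored at the smallest positive double and never reported as 0.
    Fully tied inputs (zero rank variance) yield the null result
    (MW p = 1 at U = n1*n2/2; KW statistic 0, p = 1).
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_class.items()}
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    for k, v in groups.items():
        if v.size == 0:
            raise ValidationError(f"group {k!r} is empty")
    arrays = list(groups.values())
    sizes = tuple(int(v.size) for v in arrays)
    all_values = np.concatenate(arrays)
    fully_tied = np.all(all_values == all_values[0])
    if test == "mann_whitney_two_sided":
        if len(arrays) != 2:
            raise ValidationError("mann_whitney_two_sided requires exactly 2 groups")
        if fully_tied:
            stat, p = sizes[0] * sizes[1] / 2.0, 1.0
        else:
            res = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
    elif test == "kruskal_wallis":
        if fully_tied:
            stat, p = 0.0, 1.0
        else:
            res = stats.kruskal(*arrays)
            stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValidationError(f"unknown test {test!r}")
    floored = p < P_FLOOR
    return ClassComparison(
        test=test,
        statistic=stat,
        p_value=max(p, P_FLOOR),
        group_sizes=sizes,
        floored=floored,
    )


def class_signal_values(
    partition: CistromePartition, mark: str
) -> dict[str, list[float]]:
    """Per-class lists of a chromatin mark's signal values, for feeding
    :func:`compare_classes` (e.g. ATAC accessibility across binding
    classes)."""
    if partition.signal is None:
        raise ValidationError("partition has no chromatin signal; run annotate_chromatin")
    if mark not in CHROMATIN_MARKS:
        raise ValidationError(f"unknown mark {mark!r}")
    out: dict[str, list[float]] = {c: [] for c in COBINDING_CLASSES}
    for cls, sig in zip(partition.class_of, partition.signal):
        out[cls].append(sig[mark])
    return {c: v for c, v in out.items() if v}
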