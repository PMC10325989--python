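"""Genomic-interval data model, peak-file I/O, overlap arithmetic, and
replicate-consensus peak combination.

Coordinates are 0-based half-open throughout (BED convention); any 1-based
input is converted at the boundary by its reader.

The consensus combiner mirrors the common ChIP-seq replicate workflow: a
peak participates only if it passes a *weak* per-peak p-value threshold in
its own replicate; groups of mutually overlapping peaks supported by the
required number of replicates are then kept when their Fisher-combined
p-value (-2*sum(ln p_i), chi-square with 2k df) passes the *stringent*
threshold. The combined value becomes the consensus region's score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

logger = logging.getLogger("limbgrn")

VALID_STRANDS = ("+", "-", ".")

#: ceiling applied to -log10(p) when an input p-value underflows to zero
DEFAULT_NEGLOG10_CEILING = 300.0


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


class ParseError(ValueError):
    """Raised when a file does not parse under the declared dialect."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"strand must be one of {VALID_STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval", min_overlap_bp: int = 1) -> bool:
        return self.overlap_length(other) >= min_overlap_bp


@dataclass(frozen=True)
class ScoredPeak:
    """A genomic interval with a -log10 p-value score and optional fold
    enrichment; the atom of all cistrome analysis."""

    interval: GenomicInterval
    neglog10_p: float
    fold_enrichment: Optional[float] = None
    name: str = "."

    def __post_init__(self) -> None:
        if not (self.neglog10_p >= 0):
            raise ValidationError(f"neglog10_p must be >= 0, got {self.neglog10_p}")
        if self.fold_enrichment is not None and not (self.fold_enrichment >= 0):
            raise ValidationError(
                f"fold_enrichment must be >= 0 when present, got {self.fold_enrichment}"
            )

    @property
    def p_value(self) -> float:
        return 10.0 ** (-self.neglog10_p)


@dataclass
class PeakCollection:
    """An ordered set of scored peaks from one assay/factor/tissue/replicate."""

    peaks: list[ScoredPeak] = field(default_factory=list)
    assay: str = "TF-ChIP"
    factor: str = ""
    tissue: str = ""
    replicate: int = 1

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[ScoredPeak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> ScoredPeak:
        return self.peaks[i]

    def sorted(self) -> "PeakCollection":
        order = sorted(
            range(len(self.peaks)),
            key=lambda i: (
                self.peaks[i].interval.chrom,
                self.peaks[i].interval.start,
                self.peaks[i].interval.end,
            ),
        )
        return replace(self, peaks=[self.peaks[i] for i in order])

    def label(self) -> str:
        return f"{self.factor or self.assay}:{self.tissue}:rep{self.replicate}"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [p.interval.chrom for p in self.peaks],
                "start": [p.interval.start for p in self.peaks],
                "end": [p.interval.end for p in self.peaks],
                "name": [p.name for p in self.peaks],
                "neglog10_p": [p.neglog10_p for p in self.peaks],
                "strand": [p.interval.strand for p in self.peaks],
                "fold_enrichment": [p.fold_enrichment for p in self.peaks],
            }
        )


@dataclass(frozen=True)
class ConsensusConfig:
    """Thresholds for replicate-consensus combination.

    ``stringent_p`` is the combined-evidence threshold and ``weak_p`` the
    per-peak admission threshold (defaults 1e-10 / 1e-6, the values used for
    the hindlimb ChIP-seq and ATAC-seq replicate merging).
    """

    stringent_p: float = 1e-10
    weak_p: float = 1e-6
    min_replicates: int = 2
    min_overlap_bp: int = 1
    neglog10_ceiling: float = DEFAULT_NEGLOG10_CEILING

    def __post_init__(self) -> None:
        if not (0 < self.stringent_p <= self.weak_p < 1):
            raise ValidationError(
                "require 0 < stringent_p <= weak_p < 1, got "
                f"stringent_p={self.stringent_p}, weak_p={self.weak_p}"
            )
        if self.min_replicates < 1:
            raise ValidationError("min_replicates must be >= 1")
        if self.min_overlap_bp < 0:
            raise ValidationError("min_overlap_bp must be >= 0")


@dataclass(frozen=True)
class MergedRegion:
    """A maximal region produced by merging overlapping peaks, annotated
    with the labels of the collections that contributed to it."""

    interval: GenomicInterval
    sources: frozenset[str]
    neglog10_p: float = 0.0  # max over contributing peaks
    n_members: int = 0


# ---------------------------------------------------------------------------
# I/O: narrowPeak (ENCODE 10-column) and BED6
# ---------------------------------------------------------------------------

_FORMATS = ("narrowPeak", "BED6")


def _fmt_float(x: float) -> str:
    # repr keeps round-trips exact; integers render without trailing zeros
    return repr(float(x))


def read_peaks(path, format: str = "narrowPeak", **collection_kwargs) -> PeakCollection:
    """Read a peak file into a :class:`PeakCollection`.

    narrowPeak column 8 (1-based) maps to ``neglog10_p`` and column 7 to
    ``fold_enrichment`` (negative signalValue is treated as missing, per the
    ENCODE use of -1 for absent statistics). For BED6 the score column maps
    to ``neglog10_p``.
    """
    if format not in _FORMATS:
        raise ValidationError(f"format must be one of {_FORMATS}, got {format!r}")
    ncol = 10 if format == "narrowPeak" else 6
    peaks: list[ScoredPeak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < ncol:
                raise ParseError(
                    f"{path}: line {lineno}: expected {ncol} columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                strand = fields[5] if fields[5] in VALID_STRANDS else "."
                if format == "narrowPeak":
                    signal = float(fields[6])
                    fold = None if signal < 0 else signal
                    neglog10_p = float(fields[7])
                else:
                    fold = None
                    neglog10_p = float(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if start >= end:
                raise ValidationError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            peaks.append(
                ScoredPeak(
                    interval=GenomicInterval(chrom, start, end, strand),
                    neglog10_p=neglog10_p,
                    fold_enrichment=fold,
                    name=name,
                )
            )
    return PeakCollection(peaks=peaks, **collection_kwargs)


def write_peaks(collection: PeakCollection, path, format: str = "narrowPeak") -> None:
    """Write a collection in the named dialect (inverse of :func:`read_peaks`)."""
    if format not in _FORMATS:
        raise ValidationError(f"format must be one of {_FORMATS}, got {format!r}")
    with open(path, "w") as fh:
        for p in collection:
            iv = p.interval
            if format == "narrowPeak":
                fold = -1.0 if p.fold_enrichment is None else p.fold_enrichment
                fh.write(
                    "\t".join(
                        [
                            iv.chrom,
                            str(iv.start),
                            str(iv.end),
                            p.name,
                            "0",
                            iv.strand,
                            _fmt_float(fold),
                            _fmt_float(p.neglog10_p),
                            "-1",
                            "-1",
                        ]
                    )
                    + "\n"
                )
            else:
                fh.write(
                    "\t".join(
                        [
                            iv.chrom,
                            str(iv.start),
                            str(iv.end),
                            p.name,
                            _fmt_float(p.neglog10_p),
                            iv.strand,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# overlap arithmetic
# ---------------------------------------------------------------------------

def build_trees(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    """Index intervals by chromosome for overlap queries."""
    trees: dict[str, IntervalTree] = {}
    for i, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    return trees


def query_overlaps(
    trees: dict[str, IntervalTree], iv: GenomicInterval, min_overlap_bp: int = 1
) -> list[int]:
    """Indices of indexed intervals overlapping ``iv`` by >= min_overlap_bp."""
    tree = trees.get(iv.chrom)
    if tree is None:
        return []
    hits = []
    for hit in tree.overlap(iv.start, iv.end):
        if min(hit.end, iv.end) - max(hit.begin, iv.start) >= min_overlap_bp:
            hits.append(hit.data)
    return sorted(hits)


def overlap_pairs(
    a: PeakCollection, b: PeakCollection, min_overlap_bp: int = 1
) -> list[tuple[int, int]]:
    """All (i, j) with a.peaks[i] and b.peaks[j] intersecting by at least
    ``min_overlap_bp`` bases. Symmetric under argument swap (indices
    exchanged)."""
    if min_overlap_bp < 0:
        raise ValidationError("min_overlap_bp must be >= 0")
    trees = build_trees([p.interval for p in b])
    pairs: list[tuple[int, int]] = []
    for i, peak in enumerate(a):
        for j in query_overlaps(trees, peak.interval, min_overlap_bp):
            pairs.append((i, j))
    pairs.sort()
    return pairs


def merge_union(
    collections: Sequence[PeakCollection], labels: Optional[Sequence[str]] = None
) -> list[MergedRegion]:
    """Merge all peaks of all collections into maximal non-overlapping
    regions, recording per region which source collections contributed."""
    if not collections:
        raise ValidationError("merge_union requires at least one collection")
    if labels is None:
        labels = [c.label() for c in collections]
    if len(labels) != len(collections):
        raise ValidationError("labels must match collections")
    records = []
    for lab, coll in zip(labels, collections):
        for p in coll:
            records.append((p.interval.chrom, p.interval.start, p.interval.end, lab, p.neglog10_p))
    records.sort(key=lambda r: (r[0], r[1], r[2]))
    merged: list[MergedRegion] = []
    cur = None  # [chrom, start, end, sources, max_score, n]
    for chrom, start, end, lab, score in records:
        if cur is not None and chrom == cur[0] and start < cur[2]:
            cur[2] = max(cur[2], end)
            cur[3].add(lab)
            cur[4] = max(cur[4], score)
            cur[5] += 1
        else:
            if cur is not None:
                merged.append(
                    MergedRegion(
                        GenomicInterval(cur[0], cur[1], cur[2]),
                        frozenset(cur[3]),
                        cur[4],
                        cur[5],
                    )
                )
            cur = [chrom, start, end, {lab}, score, 1]
    if cur is not None:
        merged.append(
            MergedRegion(
                GenomicInterval(cur[0], cur[1], cur[2]), frozenset(cur[3]), cur[4], cur[5]
            )
        )
    return merged


# ---------------------------------------------------------------------------
# replicate consensus
# ---------------------------------------------------------------------------

def fisher_combine(neglog10_ps: Sequence[float], ceiling: float = DEFAULT_NEGLOG10_CEILING) -> tuple[float, float]:
    """Fisher-combine per-replicate -log10 p-values.

    Returns ``(statistic, combined_p)`` where the statistic is
    -2*sum(ln p_i), chi-square distributed with 2k degrees of freedom under
    the null. For k = 1 the combined p equals the member's p exactly.
    Scores above ``ceiling`` are clamped (and the clamp logged) so that
    p = 0 inputs stay finite.
    """
    clamped = []
    for nl in neglog10_ps:
        if not math.isfinite(nl) or nl > ceiling:
            logger.warning("clamping -log10(p) %s to ceiling %s", nl, ceiling)
            nl = ceiling
        clamped.append(nl)
    ps = np.power(10.0, -np.asarray(clamped, dtype=float))
    res = stats.combine_pvalues(ps, method="fisher")
    return float(res.statistic), float(res.pvalue)


def consensus_replicates(
    reps: Sequence[PeakCollection], cfg: ConsensusConfig = ConsensusConfig()
) -> PeakCollection:
    """Combine per-replicate peak calls into a consensus collection.

    Output regions are unions of overlapping peak groups supported by at
    least ``cfg.min_replicates`` replicates, where every member passes the
    weak threshold and the group's Fisher-combined p-value passes the
    stringent threshold. The consensus region's score is the combined
    -log10 p; its fold enrichment is the maximum over members.
    """
    if len(reps) < cfg.min_replicates:
        raise ValidationError(
            f"need at least {cfg.min_replicates} replicate collections, got {len(reps)}"
        )
    weak_neglog10 = -math.log10(cfg.weak_p)
    admitted: list[tuple[int, ScoredPeak]] = []  # (replicate index, peak)
    for ri, rep in enumerate(reps):
        for p in rep:
            nl = min(p.neglog10_p, cfg.neglog10_ceiling)
            if not math.isfinite(p.neglog10_p):
                logger.warning("clamping infinite -log10(p) in %s", rep.label())
            if nl >= weak_neglog10:
                admitted.append((ri, p))
    # group admitted peaks into connected components of the overlap graph
    admitted.sort(key=lambda t: (t[1].interval.chrom, t[1].interval.start, t[1].interval.end))
    groups: list[list[tuple[int, ScoredPeak]]] = []
    cur_chrom, cur_end = None, -1
    for ri, p in admitted:
        iv = p.interval
        min_ov = max(cfg.min_overlap_bp, 1)
        if cur_chrom == iv.chrom and min(cur_end, iv.end) - iv.start >= min_ov:
            groups[-1].append((ri, p))
            cur_end = max(cur_end, iv.end)
        else:
            groups.append([(ri, p)])
            cur_chrom, cur_end = iv.chrom, iv.end
    out: list[ScoredPeak] = []
    for gi, group in enumerate(groups):
        support = {ri for ri, _ in group}
        if len(support) < cfg.min_replicates:
            continue
        stat, combined_p = fisher_combine(
            [p.neglog10_p for _, p in group], ceiling=cfg.neglog10_ceiling
        )
        if combined_p > cfg.stringent_p:
            continue
        start = min(p.interval.start for _, p in group)
        end = max(p.interval.end for _, p in group)
        chrom = group[0][1].interval.chrom
        folds = [p.fold_enrichment for _, p in group if p.fold_enrichment is not None]
        neglog10 = (
            cfg.neglog10_ceiling if combined_p <= 0 else min(-math.log10(combined_p), cfg.neglog10_ceiling)
        )
        out.append(
            ScoredPeak(
                interval=GenomicInterval(chrom, start, end),
                neglog10_p=neglog10,
                fold_enrichment=max(folds) if folds else None,
                name=f"consensus_{gi}",
            )
        )
    first = reps[0]
    return PeakCollection(
        peaks=out, assay=first.assay, factor=first.factor, tissue=first.tissue, replicate=0
    )
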