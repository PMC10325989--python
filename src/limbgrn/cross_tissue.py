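"""Cross-tissue binding-specificity analysis.

Compares a factor's consensus cistromes across embryonic tissues
(hindlimb, second branchial arch, midface): Venn-style overlap on the
merged-region universe, cofactor-selection fractions (what fraction of a
cofactor's peaks fall on the factor's peaks in each tissue), and per-region
log2 fold changes of normalized binding signal between tissues, compared
between region subsets with a two-sided rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cistrome import ClassComparison, P_FLOOR
from .intervals import (
    PeakCollection,
    ValidationError,
    build_trees,
    merge_union,
    query_overlaps,
)

logger = logging.getLogger("limbgrn")


@dataclass(frozen=True)
class TissueOverlapSummary:
    """Venn-region counts of per-tissue cistromes on the merged-region
    universe, plus each tissue's fraction of peaks in the all-tissue
    core."""

    tissue_counts: dict[str, int]
    venn_counts: dict[frozenset, int]
    shared_fraction_of: dict[str, float]

    @property
    def core_count(self) -> int:
        all_tissues = frozenset(self.tissue_counts)
        return self.venn_counts.get(all_tissues, 0)


@dataclass(frozen=True)
class CofactorFraction:
    fraction: float
    n_overlapping: int
    n_cofactor: int


def multi_tissue_overlap(
    peaksets: Mapping[str, PeakCollection], min_overlap_bp: int = 1
) -> TissueOverlapSummary:
    """Membership of every merged-universe region in each tissue's
    cistrome, aggregated into Venn-region counts. Permutation-invariant in
    tissue order."""
    if len(peaksets) < 2:
        raise ValidationError("need at least two tissues")
    tissues = sorted(peaksets)
    for t in tissues:
        if len(peaksets[t]) == 0:
            logger.warning("tissue %r has an empty collection", t)
    universe = merge_union([peaksets[t] for t in tissues], labels=tissues)
    trees = {t: build_trees([p.interval for p in peaksets[t]]) for t in tissues}
    venn: dict[frozenset, int] = {}
    core_regions = []
    for region in universe:
        members = frozenset(
            t for t in tissues if query_overlaps(trees[t], region.interval, min_overlap_bp)
        )
        venn[members] = venn.get(members, 0) + 1
        if members == frozenset(tissues):
            core_regions.append(region)
    core_trees = build_trees([r.interval for r in core_regions])
    shared_fraction = {}
    for t in tissues:
        n = len(peaksets[t])
        if n == 0:
            shared_fraction[t] = 0.0
            continue
        k = sum(
            1
            for p in peaksets[t]
            if query_overlaps(core_trees, p.interval, min_overlap_bp)
        )
        shared_fraction[t] = k / n
    return TissueOverlapSummary(
        tissue_counts={t: len(peaksets[t]) for t in tissues},
        venn_counts=venn,
        shared_fraction_of=shared_fraction,
    )


def cofactor_selection_fraction(
    pbx: PeakCollection, cofactor: PeakCollection, min_overlap_bp: int = 1
) -> CofactorFraction:
    """Fraction of cofactor peaks overlapping at least one factor peak.
    Numerator and denominator are reported so the alternative denominator
    (factor peaks) can be audited."""
    if len(cofactor) == 0:
        raise ValidationError("cofactor collection is empty")
    if len(pbx) == 0:
        raise ValidationError("factor collection is empty")
    trees = build_trees([p.interval for p in pbx])
    k = sum(1 for p in cofactor if query_overlaps(trees, p.interval, min_overlap_bp))
    return CofactorFraction(fraction=k / len(cofactor), n_overlapping=k, n_cofactor=len(cofactor))


def signal_log2fc(
    table: pd.DataFrame,
    tissue_a: str,
    tissue_b: str,
    pseudocount: float = 1.0,
    subset_column: str = "subset_label",
) -> tuple[pd.DataFrame, ClassComparison]:
    """Per-region log2((signal_a + pc) / (signal_b + pc)) plus a two-sided
    Mann-Whitney comparison of the log2FC between the two subset groups.

    ``table`` must carry one row per region with non-negative
    ``signal_<tissue>`` columns and a two-level subset label column.
    """
    col_a, col_b = f"signal_{tissue_a}", f"signal_{tissue_b}"
    for col in (col_a, col_b, subset_column):
        if col not in table.columns:
            raise ValidationError(f"signal table missing column {col!r}")
    a = table[col_a].to_numpy(dtype=float)
    b = table[col_b].to_numpy(dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValidationError("signals must be non-negative")
    log2fc = np.log2((a + pseudocount) / (b + pseudocount))
    out = table.copy()
    out["log2fc"] = log2fc
    groups = out.groupby(subset_column)["log2fc"]
    keys = sorted(groups.groups)
    if len(keys) != 2:
        raise ValidationError(f"expected exactly 2 subset labels, got {keys}")
    g1, g2 = groups.get_group(keys[0]).to_numpy(), groups.get_group(keys[1]).to_numpy()
    allv = np.concatenate([g1, g2])
    if np.all(allv == allv[0]):
        stat, p = g1.size * g2.size / 2.0, 1.0
    else:
        res = stats.mannwhitneyu(g1, g2, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    cmp = ClassComparison(
        test="mann_whitney_two_sided",
        statistic=stat,
        p_value=max(p, P_FLOOR),
        group_sizes=(g1.size, g2.size),
        floored=p < P_FLOOR,
    )
    return out, cmp
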