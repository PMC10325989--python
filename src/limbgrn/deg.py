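"""Differential-expression integration across two mutant genotypes.

Applies the fold-change / FDR thresholds used for the bulk RNA-seq
contrasts (fold change >= 1.2 on the linear scale, i.e. |log2FC| >=
log2(1.2), and FDR <= 0.05), restricts to genes detected in all replicates
of both contrasts, and classifies the shared target set: genes up in both
mutants are repressed by both factors, genes down in both are positively
regulated by both, and opposite-sign genes are discordantly regulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import ValidationError

DEFAULT_FC_MIN = 1.2
DEFAULT_FDR_MAX = 0.05

REGULATION_LABELS = {
    "concordant_up": "repressed by both",
    "concordant_down": "positively regulated by both",
    "discordant": "discordantly regulated",
}


@dataclass(frozen=True)
class DegRecord:
    """Per-gene differential-expression evidence for one contrast."""

    gene_id: str
    log2fc: float
    fdr: float
    detected_all_reps: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.fdr <= 1.0):
            raise ValidationError(f"fdr must be in [0, 1], got {self.fdr}")


@dataclass(frozen=True)
class SharedTargetSet:
    """Concordant/discordant classification of two contrasts' DEGs,
    restricted to a common detection universe. The five sets are pairwise
    disjoint."""

    concordant_up: frozenset[str]
    concordant_down: frozenset[str]
    discordant: frozenset[str]
    a_only: frozenset[str]
    b_only: frozenset[str]

    def shared(self) -> frozenset[str]:
        return self.concordant_up | self.concordant_down | self.discordant

    def counts(self) -> dict[str, int]:
        return {
            "concordant_up": len(self.concordant_up),
            "concordant_down": len(self.concordant_down),
            "discordant": len(self.discordant),
            "a_only": len(self.a_only),
            "b_only": len(self.b_only),
        }


def read_deg_table(path) -> list[DegRecord]:
    """Read a tab-separated DEG table (gene_id, log2fc, fdr,
    detected_all_reps)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "fdr", "detected_all_reps"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return [
        DegRecord(
            gene_id=str(r.gene_id),
            log2fc=float(r.log2fc),
            fdr=float(r.fdr),
            detected_all_reps=bool(r.detected_all_reps),
        )
        for r in df.itertuples()
    ]


def write_deg_table(records: Sequence[DegRecord], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "log2fc": [r.log2fc for r in records],
            "fdr": [r.fdr for r in records],
            "detected_all_reps": [r.detected_all_reps for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def filter_degs(
    table: Sequence[DegRecord],
    fc_min: float = DEFAULT_FC_MIN,
    fdr_max: float = DEFAULT_FDR_MAX,
) -> dict[str, int]:
    """Significant genes with their fold-change sign (+1 up, -1 down).

    A gene is retained iff |log2fc| >= log2(fc_min) and fdr <= fdr_max;
    both bounds inclusive.
    """
    if not fc_min > 1:
        raise ValidationError(f"fc_min must be > 1, got {fc_min}")
    if not (0 < fdr_max < 1):
        raise ValidationError(f"fdr_max must be in (0, 1), got {fdr_max}")
    log2_cut = math.log2(fc_min)
    out: dict[str, int] = {}
    seen: set[str] = set()
    for rec in table:
        if rec.gene_id in seen:
            raise ValidationError(f"duplicate gene_id {rec.gene_id!r}")
        seen.add(rec.gene_id)
        if abs(rec.log2fc) >= log2_cut and rec.fdr <= fdr_max:
            out[rec.gene_id] = 1 if rec.log2fc > 0 else -1
    return out


def detection_universe(
    table_a: Sequence[DegRecord], table_b: Sequence[DegRecord]
) -> frozenset[str]:
    """Genes flagged as detected in all replicates of both contrasts."""
    in_a = {r.gene_id for r in table_a if r.detected_all_reps}
    in_b = {r.gene_id for r in table_b if r.detected_all_reps}
    return frozenset(in_a & in_b)


def intersect_contrasts(
    degs_a: Mapping[str, int], degs_b: Mapping[str, int], universe: Iterable[str]
) -> SharedTargetSet:
    """Classify genes by their significance/sign pattern across two
    contrasts, after discarding everything outside the detection
    universe."""
    uni = frozenset(universe)
    if not uni:
        raise ValidationError("detection universe is empty")
    a = {g: s for g, s in degs_a.items() if g in uni}
    b = {g: s for g, s in degs_b.items() if g in uni}
    up_up, down_down, disc, a_only, b_only = set(), set(), set(), set(), set()
    for g in set(a) | set(b):
        if g in a and g in b:
            if a[g] > 0 and b[g] > 0:
                up_up.add(g)
            elif a[g] < 0 and b[g] < 0:
                down_down.add(g)
            else:
                disc.add(g)
        elif g in a:
            a_only.add(g)
        else:
            b_only.add(g)
    return SharedTargetSet(
        concordant_up=frozenset(up_up),
        concordant_down=frozenset(down_down),
        discordant=frozenset(disc),
        a_only=frozenset(a_only),
        b_only=frozenset(b_only),
    )


def regulation_semantics(shared: SharedTargetSet) -> dict[str, str]:
    """Per-gene regulatory reading of the shared target classes: genes up
    in both mutants are repressed by both factors, genes down in both are
    positively regulated by both."""
    labels: dict[str, str] = {}
    for g in shared.concordant_up:
        labels[g] = REGULATION_LABELS["concordant_up"]
    for g in shared.concordant_down:
        labels[g] = REGULATION_LABELS["concordant_down"]
    for g in shared.discordant:
        labels[g] = REGULATION_LABELS["discordant"]
    return labels


def write_shared_targets(shared: SharedTargetSet, path) -> None:
    rows = []
    for cls in ("concordant_up", "concordant_down", "discordant", "a_only", "b_only"):
        for g in sorted(getattr(shared, cls)):
            rows.append({"gene_id": g, "class": cls})
    pd.DataFrame(rows, columns=["gene_id", "class"]).to_csv(path, sep="\t", index=False)
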