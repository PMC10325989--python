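"""Binding-site mutagenesis planning for enhancer reporter constructs.

Motif cores are disrupted with the fixed substitution map T->C, A->C,
C->A, G->A (no fixed points, so every core base counts as altered), which
removes both the TAAT/TGAT-type homeodomain cores and the CANNTG E-box
core without changing sequence length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .intervals import ValidationError

SUBSTITUTION_MAP = {"T": "C", "A": "C", "C": "A", "G": "A"}

MOTIF_CLASSES = ("PBX", "HAND")


@dataclass(frozen=True)
class MotifSite:
    """A motif occurrence inside an enhancer sequence.

    ``position`` is the 1-based offset of the site within the sequence;
    the disrupted core starts ``core_offset`` bases (0-based) into the
    site and spans ``core_length`` bases.
    """

    position: int
    motif_class: str
    core_length: int = 6
    core_offset: int = 0

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        if self.core_length < 1:
            raise ValidationError("core_length must be >= 1")
        if self.core_offset < 0:
            raise ValidationError("core_offset must be >= 0")
        if self.motif_class not in MOTIF_CLASSES:
            raise ValidationError(f"motif_class must be one of {MOTIF_CLASSES}")

    def core_range(self) -> range:
        """1-based positions of the core bases."""
        start = self.position + self.core_offset
        return range(start, start + self.core_length)


@dataclass(frozen=True)
class MutagenesisPlan:
    design_id: str
    sites: tuple[MotifSite, ...]
    edits: tuple[tuple[int, str, str], ...]  # (1-based position, ref, alt)

    @property
    def n_bases_altered(self) -> int:
        return sum(1 for _, ref, alt in self.edits if ref != alt)


def plan_mutagenesis(
    sequence: str, sites: Sequence[MotifSite], design_id: str = "design"
) -> MutagenesisPlan:
    """Build the deterministic edit list disrupting every site core.

    Overlapping cores are edited once per position. The substitution map
    has no fixed points, so the number of altered bases equals the number
    of distinct core positions.
    """
    seq = sequence.upper()
    positions: set[int] = set()
    for site in sites:
        core = site.core_range()
        if core.stop - 1 > len(seq):
            raise ValidationError(
                f"site core at position {site.position} (core bases "
                f"{core.start}-{core.stop - 1}) extends past sequence length {len(seq)}"
            )
        positions.update(core)
    edits = []
    for pos in sorted(positions):
        ref = seq[pos - 1]
        if ref not in SUBSTITUTION_MAP:
            raise ValidationError(f"non-ACGT base {ref!r} at position {pos}")
        edits.append((pos, ref, SUBSTITUTION_MAP[ref]))
    return MutagenesisPlan(design_id=design_id, sites=tuple(sites), edits=tuple(edits))


def apply_plan(sequence: str, plan: MutagenesisPlan) -> str:
    """Apply a plan's edits; output length equals input length and every
    position outside the edits is unchanged. A reference-base mismatch
    raises (guards stale plans)."""
    seq = list(sequence.upper())
    for pos, ref, alt in plan.edits:
        if pos > len(seq):
            raise ValidationError(f"edit position {pos} past sequence length {len(seq)}")
        if seq[pos - 1] != ref:
            raise ValidationError(
                f"reference mismatch at position {pos}: plan expects {ref!r}, "
                f"sequence has {seq[pos - 1]!r}"
            )
        seq[pos - 1] = alt
    return "".join(seq)


def compare_designs(plans: Sequence[MutagenesisPlan]) -> dict:
    """Per-design altered-base counts and an all-equal flag (reporter
    comparisons require the same number of altered bases across
    designs)."""
    if len(plans) < 2:
        raise ValidationError("need at least two plans to compare")
    counts = {p.design_id: p.n_bases_altered for p in plans}
    values = list(counts.values())
    return {
        "counts": counts,
        "all_equal": len(set(values)) == 1,
        "max_difference": max(values) - min(values),
    }


def read_sites_table(path) -> list[MotifSite]:
    """Read motif sites from TSV (position, motif_class, core_length,
    core_offset)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        MotifSite(
            position=int(r.position),
            motif_class=str(r.motif_class),
            core_length=int(getattr(r, "core_length", 6)),
            core_offset=int(getattr(r, "core_offset", 0)),
        )
        for r in df.itertuples()
    ]
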