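"""Reference tiers and the RNA-class taxonomy.

Reads are filtered through three consecutive reference sets:

* tier 1 — sequencing adapters/primers, mitochondrial transcripts,
  genomic-repeat consensi, tRNA/rRNA/snRNA/scRNA (the "major cellular RNA"
  set).  Adapter matches are filtered out and never reported.
* tier 2 — exonic RefSeq transcript sequences (mRNA, annotated ncRNA).
* tier 3 — the genome; anything placed only here is "non-RefSeq RNA".

Class labels follow the contribution-table taxonomy; 7SL-derived sequences
are labeled SINE by class-map assignment (not special-cased in code).
Coordinates in all reports are 1-based, fully closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .colorspace import NucleotideSeq, read_fasta

# Ordered taxonomy; 'adapter' is non-reportable (filtered, excluded from
# contribution tables, which list no adapter row).
CLASS_LABELS: tuple[str, ...] = (
    "adapter",
    "mitochondrial_RNA",
    "rRNA",
    "tRNA",
    "YRNA",
    "snRNA_7SK",
    "SINE",
    "LINE",
    "LTR",
    "DNA_repeat",
    "other_repeat",
    "mRNA",
    "ncRNA",
    "non_RefSeq",
)

NON_REPORTABLE: frozenset[str] = frozenset({"adapter"})
REPORTABLE_CLASSES: tuple[str, ...] = tuple(
    c for c in CLASS_LABELS if c not in NON_REPORTABLE
)

TIER1_CLASSES: frozenset[str] = frozenset(
    {
        "adapter",
        "mitochondrial_RNA",
        "rRNA",
        "tRNA",
        "YRNA",
        "snRNA_7SK",
        "SINE",
        "LINE",
        "LTR",
        "DNA_repeat",
        "other_repeat",
    }
)
TIER2_CLASSES: frozenset[str] = frozenset({"mRNA", "ncRNA"})
TIER3_CLASS = "non_RefSeq"

_TIER_ALLOWED: dict[int, frozenset[str]] = {
    1: TIER1_CLASSES,
    2: TIER2_CLASSES,
    3: frozenset({TIER3_CLASS}),
}


class ReferenceError_(ValueError):
    """Invalid reference tier or class map."""


@dataclass
class ReferenceTier:
    """One filtering stage: an ordered, class-annotated sequence set."""

    tier_index: int
    entries: list[tuple[str, NucleotideSeq, str]] = field(default_factory=list)
    description: str = ""

    def __post_init__(self) -> None:
        if self.tier_index not in (1, 2, 3):
            raise ReferenceError_(f"tier_index must be 1..3, got {self.tier_index}")
        seen: set[str] = set()
        allowed = _TIER_ALLOWED[self.tier_index]
        bad_class = []
        for seq_id, seq, label in self.entries:
            if seq_id in seen:
                raise ReferenceError_(
                    f"tier {self.tier_index}: duplicate seq_id {seq_id!r}"
                )
            seen.add(seq_id)
            if label not in CLASS_LABELS or label not in allowed:
                bad_class.append((seq_id, label))
        if bad_class:
            ids = ", ".join(f"{s}:{c}" for s, c in bad_class)
            raise ReferenceError_(
                f"tier {self.tier_index}: class labels not allowed in this tier "
                f"(allowed: {sorted(allowed)}): {ids}"
            )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def seq_ids(self) -> list[str]:
        return [sid for sid, _, _ in self.entries]

    def class_of(self, seq_id: str) -> str:
        for sid, _, label in self.entries:
            if sid == seq_id:
                return label
        raise KeyError(seq_id)

    def lengths(self) -> dict[str, int]:
        return {sid: len(seq) for sid, seq, _ in self.entries}


def read_classmap(path: str | Path) -> dict[str, str]:
    """Read a two-column seq_id <TAB> class_label TSV (strict)."""
    mapping: dict[str, str] = {}
    bad: list[str] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ReferenceError_(f"{path}:{ln}: expected 2 tab-separated fields")
            seq_id, label = parts
            if label not in CLASS_LABELS:
                bad.append(f"{seq_id} -> {label!r}")
            if seq_id in mapping:
                raise ReferenceError_(f"{path}:{ln}: duplicate seq_id {seq_id!r}")
            mapping[seq_id] = label
    if bad:
        raise ReferenceError_(f"{path}: unknown class labels: {'; '.join(bad)}")
    return mapping


def write_classmap(mapping: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id, label in mapping.items():
            fh.write(f"{seq_id}\t{label}\n")


def _tier_from_seqs(
    tier_index: int,
    seqs: Iterable[NucleotideSeq],
    classmap: Mapping[str, str],
    description: str,
) -> ReferenceTier:
    entries = []
    missing = []
    for seq in seqs:
        label = classmap.get(seq.seq_id)
        if label is None:
            missing.append(seq.seq_id)
            continue
        entries.append((seq.seq_id, seq, label))
    if missing:
        raise ReferenceError_(
            f"tier {tier_index}: sequences without class-map entry: {missing}"
        )
    return ReferenceTier(tier_index=tier_index, entries=entries, description=description)


def build_tiers(
    tier1_fasta: str | Path,
    tier1_classmap: str | Path,
    tier2_fasta: str | Path,
    tier2_classmap: str | Path,
    genome_fasta: str | Path,
) -> tuple[ReferenceTier, ReferenceTier, ReferenceTier]:
    """Assemble and validate the three filtering tiers from FASTA + class maps.

    Tier 1 must contain at least one adapter entry; tier-2 labels are
    restricted to mRNA/ncRNA; every genome chromosome is labeled non_RefSeq.
    """
    t1 = _tier_from_seqs(
        1, read_fasta(tier1_fasta), read_classmap(tier1_classmap),
        "adapters, mitochondrial, repeats, major cellular RNAs",
    )
    if "adapter" not in {label for _, _, label in t1.entries}:
        raise ReferenceError_("tier 1 must contain at least one adapter entry")
    t2 = _tier_from_seqs(
        2, read_fasta(tier2_fasta), read_classmap(tier2_classmap),
        "RefSeq exonic transcripts (NM/NR)",
    )
    genome = read_fasta(genome_fasta)
    t3 = ReferenceTier(
        tier_index=3,
        entries=[(s.seq_id, s, TIER3_CLASS) for s in genome],
        description="genome",
    )
    return t1, t2, t3


def classmap_census(tier: ReferenceTier) -> dict[str, int]:
    """Count reference entries per class label within one tier."""
    census: dict[str, int] = {}
    for _, _, label in tier.entries:
        census[label] = census.get(label, 0) + 1
    return census
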