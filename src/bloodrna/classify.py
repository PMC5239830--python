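"""Hierarchical (three-tier) read classification and class-contribution tables.

Each read is aligned against tier 1; only reads without any tier-1
placement proceed to tier 2; only reads unplaced in both proceed to the
genome tier (class non_RefSeq).  With k = 1 every aligned read gets exactly
one class assignment.  Adapter/primer matches are filtered: they never
appear in contribution tables and are excluded from the mapped-read total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .align import (
    AlignmentRecord,
    AlignParams,
    Read,
    TierIndex,
    TrimSchedule,
    align_read,
)
from .colorspace import ColorRead
from .references import NON_REPORTABLE, REPORTABLE_CLASSES, ReferenceTier


@dataclass(frozen=True)
class ClassAssignment:
    read_id: str
    class_label: str
    tier_index: int
    record: AlignmentRecord


@dataclass
class ClassTable:
    """Per-library RNA-class contribution (percent of reportable mapped reads)."""

    library_id: str
    counts: dict[str, int]
    total_mapped: int

    @property
    def contributions(self) -> dict[str, float]:
        if self.total_mapped == 0:
            return {c: math.nan for c in self.counts}
        return {c: 100.0 * n / self.total_mapped for c, n in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        contrib = self.contributions
        return pd.DataFrame(
            {
                "library_id": self.library_id,
                "class": list(self.counts),
                "reads": list(self.counts.values()),
                "pct": [contrib[c] for c in self.counts],
            }
        )


@dataclass
class ClassifyResult:
    assignments: list[ClassAssignment] = field(default_factory=list)
    adapter_ids: list[str] = field(default_factory=list)
    unmapped_ids: list[str] = field(default_factory=list)
    multi_records: dict[str, list[AlignmentRecord]] = field(default_factory=dict)
    tier_of_read: dict[str, int] = field(default_factory=dict)


def classify_reads(
    reads: Iterable[Read],
    tiers: Sequence[ReferenceTier | TierIndex],
    params: AlignParams | None = None,
    schedule: TrimSchedule | None = None,
) -> ClassifyResult:
    """Assign each read to an RNA class via consecutive tier filtering.

    ``params.k`` controls how many placements are retained per read in
    ``multi_records`` (for k = 2 feature quantification); the class
    assignment itself always follows the single best placement.
    """
    from .align import make_trim_schedule

    params = params or AlignParams()
    schedule = schedule or make_trim_schedule(50, 19)
    reads = list(reads)
    if len(tiers) != 3:
        raise ValueError("expected exactly three tiers")
    indexes = []
    space = "color" if reads and isinstance(reads[0], ColorRead) else "base"
    for t in tiers:
        indexes.append(t if isinstance(t, TierIndex) else TierIndex(t, space=space))

    result = ClassifyResult()
    for read in reads:
        rid = read.read_id if isinstance(read, ColorRead) else read.seq_id
        placed = False
        for index in indexes:
            recs = align_read(read, index, params, schedule)
            if not recs:
                continue
            placed = True
            best = recs[0]
            label = index.tier.class_of(best.ref_id)
            result.tier_of_read[rid] = index.tier.tier_index
            if label in NON_REPORTABLE:
                result.adapter_ids.append(rid)
            else:
                result.assignments.append(
                    ClassAssignment(rid, label, index.tier.tier_index, best)
                )
                result.multi_records[rid] = recs
            break
        if not placed:
            result.unmapped_ids.append(rid)
    return result


def class_table(
    assignments: Iterable[ClassAssignment], library_id: str
) -> ClassTable:
    """Tabulate reportable class counts and percent contributions."""
    counts: dict[str, int] = {}
    total = 0
    for a in assignments:
        if a.class_label in NON_REPORTABLE:
            continue
        counts[a.class_label] = counts.get(a.class_label, 0) + 1
        total += 1
    if total == 0:
        import warnings

        warnings.warn(f"{library_id}: no reportable mapped reads", stacklevel=2)
    return ClassTable(library_id=library_id, counts=counts, total_mapped=total)


def write_class_table(table: ClassTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")


def wide_class_table(tables: Iterable[ClassTable]) -> pd.DataFrame:
    """Fraction x cohort layout: one row per class, one column per library.

    Library ids of the form ``<fraction>_<cohort>`` order columns by
    fraction then cohort, mirroring the published table layout.
    """
    frames = []
    for t in tables:
        contrib = t.contributions
        frames.append(
            pd.Series(
                {c: contrib.get(c, 0.0) for c in REPORTABLE_CLASSES}, name=t.library_id
            )
        )
    wide = pd.concat(frames, axis=1)
    wide.index.name = "class"
    return wide
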