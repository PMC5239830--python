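"""Feature-level abundance: fragment counts, FPKM, and the eligibility cut-off.

Quantification runs on k = 2 alignments: a read with a single placement
contributes one fragment to its feature; a read with two placements splits
uniformly, half a fragment to each (configurable to primary-only).  FPKM is
fragments x 1e9 / (feature_length x total mapped fragments).  Features are
eligible for differential testing only when their summed fragment count
across the compared libraries reaches the minimum-alignment-count cut-off
(default 100).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .align import AlignmentRecord


@dataclass(frozen=True)
class EligibilityFilter:
    """Minimum summed fragment count for a feature to be tested."""

    min_alignment_count: float = 100

    def __post_init__(self) -> None:
        if self.min_alignment_count < 0:
            raise ValueError("threshold must be >= 0")


def count_fragments(
    multi_records: Mapping[str, list[AlignmentRecord]],
    features: Iterable[str] | None = None,
    weight: str = "uniform",
) -> dict[str, float]:
    """Per-feature fragment counts from per-read alignment lists (k <= 2).

    ``weight='uniform'`` splits a 2-placement read half-and-half;
    ``weight='primary'`` gives the whole fragment to the best placement.
    Counts sum to the number of placed reads either way.
    """
    if weight not in ("uniform", "primary"):
        raise ValueError("weight must be 'uniform' or 'primary'")
    counts: dict[str, float] = {f: 0.0 for f in features} if features else {}
    for recs in multi_records.values():
        if not recs:
            continue
        if weight == "primary" or len(recs) == 1:
            counts[recs[0].ref_id] = counts.get(recs[0].ref_id, 0.0) + 1.0
        else:
            share = 1.0 / len(recs)
            for rec in recs:
                counts[rec.ref_id] = counts.get(rec.ref_id, 0.0) + share
    return counts


def fpkm(count: float, feature_length: int, total_mapped: float) -> float:
    """Fragments per kilobase of feature per million mapped fragments."""
    if feature_length <= 0:
        raise ValueError("feature_length must be > 0")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    return count * 1e9 / (feature_length * total_mapped)


def abundance_table(
    counts: Mapping[str, float],
    feature_lengths: Mapping[str, int],
    library_id: str,
) -> pd.DataFrame:
    """Per-feature abundance records (feature_id, library_id, length, count, fpkm)."""
    total = float(sum(counts.values()))
    rows = []
    for fid, n in counts.items():
        length = feature_lengths[fid]
        rows.append(
            {
                "feature_id": fid,
                "library_id": library_id,
                "length": length,
                "count": n,
                "fpkm": fpkm(n, length, total) if total > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["feature_id", "library_id", "length", "count", "fpkm"])


def count_matrix(per_library_counts: Mapping[str, Mapping[str, float]]) -> pd.DataFrame:
    """Features x libraries fragment-count matrix (missing -> 0)."""
    return (
        pd.DataFrame(per_library_counts).fillna(0.0).rename_axis("feature_id").sort_index()
    )


def apply_min_count(
    matrix: pd.DataFrame,
    filt: EligibilityFilter = EligibilityFilter(),
    libraries: Iterable[str] | None = None,
) -> list[str]:
    """Features whose summed count across the compared libraries meets the cut-off."""
    sub = matrix[list(libraries)] if libraries is not None else matrix
    total = sub.sum(axis=1)
    return list(total.index[total >= filt.min_alignment_count])


def write_abundance(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
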