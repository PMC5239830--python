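"""Shared fixtures: tiny reference tiers and a literal brute-force aligner.

The oracle aligner below deliberately shares no code with the package's
search: the di-base table is written out pairwise, references are scanned
at every offset of every strand and ladder length with plain string
comparison, and ranking is applied by explicit sort.  It defines what the
fast aligner must reproduce.
"""

from __future__ import annotations

import numpy as np
import pytest

from bloodrna.align import AlignmentRecord, ladder_lengths
from bloodrna.colorspace import ColorRead, NucleotideSeq
from bloodrna.references import ReferenceTier

# pairwise di-base transition table, written out longhand
DIBASE = {}
for _x, _row in zip("ACGT", ("0123", "1032", "2301", "3210")):
    for _y, _c in zip("ACGT", _row):
        DIBASE[_x + _y] = _c

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def ref_colors(bases: str) -> str:
    return "".join(DIBASE[bases[i : i + 2]] for i in range(len(bases) - 1))


def oracle_align_read(read, tier: ReferenceTier, params, schedule) -> list[AlignmentRecord]:
    """Exhaustive scan over all offsets, strands, and ladder lengths."""
    is_color = isinstance(read, ColorRead)
    rid = read.read_id if is_color else read.seq_id
    if len(read) < schedule.min_length:
        return []
    for step, length in enumerate(ladder_lengths(len(read), schedule)):
        hits = []
        if is_color:
            query = read.colors[1:length]
        else:
            query = read.bases[:length]
        for ref_id, seq, _label in tier.entries:
            R = len(seq.bases)
            if is_color:
                strands = {"+": ref_colors(seq.bases), "-": ref_colors(revcomp(seq.bases))}
            else:
                strands = {"+": seq.bases, "-": revcomp(seq.bases)}
            for strand, text in strands.items():
                for off in range(len(text) - len(query) + 1):
                    mm = sum(a != b for a, b in zip(query, text[off : off + len(query)]))
                    if mm <= params.max_mismatches:
                        if strand == "+":
                            pos = off + 1
                        else:
                            # leftmost forward-strand base of the placement
                            if is_color:
                                pos = R - off - length + 1
                            else:
                                pos = R - off - length + 1
                        hits.append(
                            AlignmentRecord(rid, ref_id, pos, strand, length, mm, step)
                        )
        if hits:
            hits.sort(key=AlignmentRecord.sort_key)
            return hits[: params.k]
    return []


def random_tier(rng: np.random.Generator, n_refs: int, max_len: int,
                tier_index: int = 3) -> ReferenceTier:
    entries = []
    for i in range(n_refs):
        length = int(rng.integers(60, max_len + 1))
        bases = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
        entries.append((f"ref{i:02d}", NucleotideSeq(f"ref{i:02d}", bases), "non_RefSeq"))
    return ReferenceTier(tier_index=tier_index, entries=entries)


@pytest.fixture(scope="session")
def small_tiers():
    """Three tiny validated tiers with known, collision-free sequences."""
    from bloodrna.synthetic_data import SimConfig, generate_references

    t1, t2, t3, manifest = generate_references(
        SimConfig(seed=42, n_reads=10),
        ref_spec={
            "adapter": (1, 40, 45, 1),
            "tRNA": (3, 70, 90, 1),
            "rRNA": (2, 300, 500, 1),
            "mitochondrial_RNA": (2, 200, 400, 1),
            "mRNA": (4, 300, 800, 2),
            "ncRNA": (2, 300, 500, 2),
            "non_RefSeq": (1, 2000, 2000, 3),
        },
    )
    return t1, t2, t3, manifest
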