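"""SOLiD di-base (2-base-encoding) color space.

Each color symbol 0-3 encodes the transition between two adjacent bases.
A read of L colors, anchored by a known primer base, decodes to L bases:
the first color is the (primer, base1) transition, color i>1 the
(base_{i-1}, base_i) transition.  The transition code is symmetric
(code(x, y) == code(y, x)) and complement-invariant
(code(x, y) == code(comp x, comp y)), which makes color strings
strand-symmetric up to reversal.

Transition table: identical pair -> 0; {A,C} or {G,T} -> 1;
{A,G} or {C,T} -> 2; complementary pair ({A,T}, {C,G}) -> 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
COLORS = "0123"

_BASE_IDX = {b: i for i, b in enumerate(BASES)}

# color(x, y) == index(x) XOR index(y) with A,C,G,T -> 0,1,2,3; this is
# exactly the SOLiD di-base table (identity 0, A/C & G/T 1, A/G & C/T 2,
# complements 3).
_XOR_IS_TABLE = True


class ColorSpaceError(ValueError):
    """Invalid color-space or nucleotide input."""


def _check_base(b: str, context: str) -> None:
    if b not in _BASE_IDX:
        raise ColorSpaceError(f"{context}: invalid base {b!r} (expected one of A,C,G,T)")


@dataclass(frozen=True)
class NucleotideSeq:
    """A plain uppercase nucleotide sequence (no ambiguity codes)."""

    seq_id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise ColorSpaceError(f"{self.seq_id}: empty sequence")
        for i, b in enumerate(self.bases):
            if b not in _BASE_IDX:
                raise ColorSpaceError(
                    f"{self.seq_id}: invalid base {b!r} at position {i + 1}"
                )

    def __len__(self) -> int:
        return len(self.bases)

    def revcomp(self) -> "NucleotideSeq":
        return NucleotideSeq(self.seq_id, str(Seq(self.bases).reverse_complement()))


@dataclass(frozen=True)
class ColorRead:
    """One SOLiD read: primer base + color string + per-color qualities."""

    read_id: str
    primer_base: str
    colors: str
    quals: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        _check_base(self.primer_base, f"{self.read_id}: primer")
        if not self.colors:
            raise ColorSpaceError(f"{self.read_id}: empty color string")
        for i, c in enumerate(self.colors):
            if c not in COLORS:
                if c == ".":
                    raise ColorSpaceError(
                        f"{self.read_id}: missing color call '.' at position {i + 1} "
                        "is not supported"
                    )
                raise ColorSpaceError(
                    f"{self.read_id}: invalid color {c!r} at position {i + 1}"
                )
        if self.quals and len(self.quals) != len(self.colors):
            raise ColorSpaceError(
                f"{self.read_id}: {len(self.quals)} quality values for "
                f"{len(self.colors)} colors"
            )
        if any(q < 0 for q in self.quals):
            raise ColorSpaceError(f"{self.read_id}: negative quality value")

    def __len__(self) -> int:
        return len(self.colors)

    def decode(self) -> NucleotideSeq:
        return decode_colorspace(self.primer_base, self.colors, seq_id=self.read_id)


def color_code(x: str, y: str) -> int:
    """Di-base transition code of the ordered pair (x, y)."""
    _check_base(x, "transition")
    _check_base(y, "transition")
    return _BASE_IDX[x] ^ _BASE_IDX[y]


def encode_colorspace(bases: str, primer_base: str) -> str:
    """Encode a base string into SOLiD colors anchored at ``primer_base``.

    Returns one color per base; color i is the transition code of
    (previous base, current base), with "previous" starting at the primer.
    """
    _check_base(primer_base, "primer")
    out = []
    prev = _BASE_IDX[primer_base]
    for i, b in enumerate(bases):
        if b not in _BASE_IDX:
            raise ColorSpaceError(f"invalid base {b!r} at position {i + 1}")
        cur = _BASE_IDX[b]
        out.append(COLORS[prev ^ cur])
        prev = cur
    if not out:
        raise ColorSpaceError("empty sequence cannot be color-encoded")
    return "".join(out)


def decode_colorspace(primer_base: str, colors: str, seq_id: str = "decoded") -> NucleotideSeq:
    """Invert :func:`encode_colorspace`: colors + primer -> base string."""
    _check_base(primer_base, "primer")
    if not colors:
        raise ColorSpaceError("empty color string")
    out = []
    prev = _BASE_IDX[primer_base]
    for i, c in enumerate(colors):
        if c not in COLORS:
            raise ColorSpaceError(f"invalid color {c!r} at position {i + 1}")
        prev = prev ^ int(c)
        out.append(BASES[prev])
    return NucleotideSeq(seq_id, "".join(out))


def encode_reference_colors(bases: str) -> str:
    """Color sequence of a reference: transitions between adjacent bases.

    A reference of R bases yields R-1 colors (no primer anchor).  The
    reverse complement's color sequence is the reverse of this one.
    """
    if len(bases) < 2:
        return ""
    out = []
    prev = _BASE_IDX[bases[0]]
    for b in bases[1:]:
        cur = _BASE_IDX[b]
        out.append(COLORS[prev ^ cur])
        prev = cur
    return "".join(out)


# ---------------------------------------------------------------------------
# csfasta / qual / FASTA I/O
# ---------------------------------------------------------------------------

def _iter_fasta_like(handle: TextIO) -> Iterator[tuple[str, str]]:
    header = None
    chunks: list[str] = []
    for raw in handle:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            if header is not None:
                yield header, "".join(chunks)
            header = line[1:].split()[0]
            chunks = []
        else:
            if header is None:
                raise ColorSpaceError("sequence data before first '>' header")
            chunks.append(line)
    if header is not None:
        yield header, "".join(chunks)


def read_csfasta(path: str | Path, qual_path: str | Path | None = None) -> list[ColorRead]:
    """Read a csfasta file (primer base + color digits per record).

    If ``qual_path`` is given, per-color Phred-like qualities are attached;
    ids must match record-for-record.
    """
    with open(path) as fh:
        records = list(_iter_fasta_like(fh))
    quals: dict[str, tuple[int, ...]] = {}
    if qual_path is not None:
        with open(qual_path) as fh:
            for rid, line in _iter_fasta_like(fh):
                quals[rid] = tuple(int(tok) for tok in line.split())
    reads = []
    for rid, seq in records:
        if len(seq) < 2:
            raise ColorSpaceError(f"{rid}: csfasta record too short")
        reads.append(
            ColorRead(
                read_id=rid,
                primer_base=seq[0],
                colors=seq[1:],
                quals=quals.get(rid, ()),
            )
        )
    return reads


def write_csfasta(
    reads: Iterable[ColorRead], path: str | Path, qual_path: str | Path | None = None
) -> None:
    reads = list(reads)
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.primer_base}{r.colors}\n")
    if qual_path is not None:
        with open(qual_path, "w") as fh:
            for r in reads:
                q = r.quals if r.quals else tuple([30] * len(r.colors))
                fh.write(f">{r.read_id}\n{' '.join(str(v) for v in q)}\n")


def read_fasta(path: str | Path) -> list[NucleotideSeq]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(NucleotideSeq(rec.id, str(rec.seq).upper()))
    return out


def write_fasta(seqs: Iterable[NucleotideSeq], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.bases), id=s.seq_id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")
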