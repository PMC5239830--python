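"""Trim ladder and aligner, checked against the literal brute-force oracle."""

import numpy as np
import pytest

from bloodrna.align import (
    AlignParams,
    ScheduleError,
    TierIndex,
    TrimSchedule,
    align_library,
    align_read,
    make_trim_schedule,
)
from bloodrna.colorspace import ColorRead, NucleotideSeq, encode_colorspace
from bloodrna.references import ReferenceTier
from .conftest import oracle_align_read, random_tier, revcomp


class TestTrimSchedule:
    def test_canonical_50_to_19_ladder(self):
        s = make_trim_schedule(50, 19)
        assert len(s.steps) == 11
        assert set(s.steps) <= {4, 3, 2}
        assert s.lengths() == [50, 46, 43, 40, 37, 34, 31, 28, 25, 23, 21, 19]

    @pytest.mark.parametrize(
        "initial, minimum, steps",
        [(19, 19, ()), (23, 19, (4,)), (21, 19, (2,)), (26, 20, (4, 2)),
         (29, 19, (4, 4, 2))],
    )
    def test_generic_rule_fewest_steps_larger_first(self, initial, minimum, steps):
        s = make_trim_schedule(initial, minimum)
        assert s.steps == steps
        assert s.lengths()[-1] == minimum

    def test_below_size_selection_floor_rejected(self):
        with pytest.raises(ScheduleError):
            make_trim_schedule(50, 18)

    def test_inconsistent_steps_rejected(self):
        with pytest.raises(ScheduleError):
            TrimSchedule(50, 19, (4, 4))


def _random_colorread(rng, rid, bases=None, n=50):
    if bases is None:
        bases = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
    return ColorRead(rid, "T", encode_colorspace(bases, "T"))


class TestAlignRead:
    def test_exact_substring_full_length(self, small_tiers):
        t1 = small_tiers[0]
        ref_id, seq, _ = t1.entries[2]
        read = _random_colorread(None, "r0", bases=seq.bases[10:60])
        recs = align_read(read, t1, AlignParams(2, 1), make_trim_schedule(50, 19))
        assert len(recs) == 1
        rec = recs[0]
        assert (rec.ref_id, rec.position, rec.strand) == (ref_id, 11, "+")
        assert rec.mismatches == 0 and rec.trim_step == 0
        assert rec.end == 60

    def test_reverse_strand_placement(self, small_tiers):
        t1 = small_tiers[0]
        ref_id, seq, _ = t1.entries[2]
        read = _random_colorread(None, "r1", bases=revcomp(seq.bases[10:60]))
        rec = align_read(read, t1, AlignParams(2, 1), make_trim_schedule(50, 19))[0]
        assert (rec.ref_id, rec.position, rec.strand) == (ref_id, 11, "-")

    def test_unplaceable_read_returns_empty(self, small_tiers):
        t1 = small_tiers[0]
        rng = np.random.default_rng(77)
        # a random 50-mer is not a <=2-mismatch substring of ~2 kb of refs
        read = _random_colorread(rng, "r2")
        assert align_read(read, t1, AlignParams(2, 1), make_trim_schedule(50, 19)) == []

    def test_adapter_readthrough_recovered_at_matching_trim_step(self, small_tiers):
        """28-nt insert + adapter aligns once the ladder reaches 28 nt."""
        t1 = small_tiers[0]
        ref_id, seq, _ = next(
            (e for e in t1.entries if e[2] == "rRNA"), t1.entries[1]
        )
        adapter = next(s.bases for _, s, c in t1.entries if c == "adapter")
        insert = seq.bases[50:78]  # 28 nt
        read = _random_colorread(None, "r3", bases=(insert + adapter)[:50])
        schedule = make_trim_schedule(50, 19)
        recs = align_read(read, t1, AlignParams(2, 1), schedule)
        # ladder: 50,46,43,40,37,34,31,28 -> step index 7 reaches 28 nt
        assert recs and recs[0].aligned_length == 28
        assert recs[0].trim_step == schedule.lengths().index(28)
        assert recs[0].ref_id == ref_id and recs[0].position == 51

    def test_too_short_read_rejected_without_exception(self, small_tiers):
        t1 = small_tiers[0]
        read = _random_colorread(np.random.default_rng(1), "tiny", n=15)
        res = align_library([read], t1, AlignParams(2, 1), make_trim_schedule(50, 19))
        assert res.status == {"tiny": "too_short"}
        assert res.unaligned_ids == ["tiny"]


def _compare_with_oracle(rng, space, n_refs, max_len, n_reads, params, schedule):
    tier = random_tier(rng, n_refs, max_len)
    index = TierIndex(tier, space=space)
    mismatch_found = []
    for i in range(n_reads):
        if rng.random() < 0.6:  # read planted in a reference, maybe mutated
            ref_i = int(rng.integers(0, n_refs))
            bases = tier.entries[ref_i][1].bases
            n = int(rng.integers(19, min(51, len(bases) + 1)))
            off = int(rng.integers(0, len(bases) - n + 1))
            frag = bases[off : off + n]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            if rng.random() < 0.4:  # sprinkle substitutions
                pos = int(rng.integers(0, n))
                frag = frag[:pos] + "ACGT"[int(rng.integers(0, 4))] + frag[pos + 1:]
        else:
            n = int(rng.integers(19, 51))
            frag = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
        if space == "color":
            read = ColorRead(f"q{i}", "T", encode_colorspace(frag, "T"))
        else:
            read = NucleotideSeq(f"q{i}", frag)
        got = align_read(read, index, params, schedule)
        expected = oracle_align_read(read, tier, params, schedule)
        assert got == expected, f"read {i}: {got} != {expected}"
        mismatch_found.extend(r.mismatches for r in got)
    return mismatch_found


@pytest.mark.parametrize("space", ["color", "base"])
def test_oracle_equivalence_random_instances(space):
    """Fast aligner output equals the exhaustive scan on random instances."""
    rng = np.random.default_rng(2024 if space == "color" else 4202)
    schedule = make_trim_schedule(50, 19)
    mismatches = []
    for trial in range(10):
        params = AlignParams(max_mismatches=int(rng.integers(0, 3)),
                             k=int(rng.integers(1, 3)))
        mismatches += _compare_with_oracle(
            rng, space, n_refs=int(rng.integers(2, 8)),
            max_len=int(rng.integers(100, 501)),
            n_reads=30, params=params, schedule=schedule,
        )
    assert any(m > 0 for m in mismatches)  # the sweep exercised mismatch hits


def test_library_accounting(small_tiers):
    t1 = small_tiers[0]
    rng = np.random.default_rng(3)
    reads = []
    for i in range(30):  # planted reads
        _, seq, _ = t1.entries[int(rng.integers(0, len(t1.entries)))]
        n = min(50, len(seq.bases))
        off = int(rng.integers(0, len(seq.bases) - n + 1))
        reads.append(_random_colorread(None, f"p{i}", bases=seq.bases[off : off + n]))
    for i in range(10):  # random reads, not placeable
        reads.append(_random_colorread(rng, f"n{i}"))
    res = align_library(reads, t1, AlignParams(2, 1), make_trim_schedule(50, 19))
    aligned_ids = {r.read_id for r in res.records}
    assert aligned_ids.isdisjoint(res.unaligned_ids)
    assert len(aligned_ids) + len(res.unaligned_ids) == len(reads)
    assert {f"n{i}" for i in range(10)} <= set(res.unaligned_ids)
    assert {f"p{i}" for i in range(30)} <= aligned_ids


def test_empty_library(small_tiers):
    res = align_library([], small_tiers[0], AlignParams(), make_trim_schedule(50, 19))
    assert res.records == [] and res.unaligned_ids == []


def test_mismatch_monotonicity_and_k_prefix():
    """More allowed mismatches never aligns fewer reads; k=1 prefixes k=2."""
    rng = np.random.default_rng(8)
    tier = random_tier(rng, 5, 300)
    schedule = make_trim_schedule(50, 19)
    reads = []
    for i in range(40):
        ref_i = int(rng.integers(0, 5))
        bases = tier.entries[ref_i][1].bases
        off = int(rng.integers(0, len(bases) - 50 + 1))
        frag = list(bases[off : off + 50])
        for _ in range(int(rng.integers(0, 4))):
            frag[int(rng.integers(0, 50))] = "ACGT"[int(rng.integers(0, 4))]
        reads.append(ColorRead(f"m{i}", "T", encode_colorspace("".join(frag), "T")))
    index = TierIndex(tier, space="color")
    aligned_by_mm = []
    for mm in (0, 1, 2, 3):
        res = align_library(reads, index, AlignParams(mm, 1), schedule)
        aligned_by_mm.append(len(reads) - len(res.unaligned_ids))
    assert aligned_by_mm == sorted(aligned_by_mm)
    for read in reads:
        one = align_read(read, index, AlignParams(2, 1), schedule)
        two = align_read(read, index, AlignParams(2, 2), schedule)
        assert two[: len(one)] == one
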