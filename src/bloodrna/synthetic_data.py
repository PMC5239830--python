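"""Synthetic references and color-space read libraries for the pipeline.

Emulates the study design the analysis assumes: 15 libraries (five blood
fractions x three donor cohorts: healthy, LSCC, LAC), 50-nt SOLiD reads
from RNase-fragmented, size-selected inserts (>19 nt and <=100 nt), with
per-library RNA-class mixtures defaulting to the published contribution
table.  Inserts shorter than the read length run through into adapter
sequence, which exercises the 3'-trimming ladder downstream.

Sequences are i.i.d. random nucleotides with class-typical lengths; no
attempt is made at human sequence homology, GC bias, or PCR duplication.
Everything is deterministic in the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .colorspace import (
    ColorRead,
    NucleotideSeq,
    encode_colorspace,
    write_csfasta,
    write_fasta,
)
from .references import (
    REPORTABLE_CLASSES,
    ReferenceTier,
    TIER3_CLASS,
    write_classmap,
)

FRACTIONS = ("I", "II", "III", "IV", "V")
COHORTS = ("H", "LSCC", "LAC")

# Synthetic stand-in for the platform's P2 adapter (40 nt, fixed literal so
# outputs are stable); long enough to pad any retained insert to 50 nt.
DEFAULT_ADAPTER = "CGCCTTGGCCGTACAGCAGAGTCGGTGCTATGGGCAGTCG"

# Published per-library class mixtures (percent of reportable mapped reads);
# columns ordered fraction I..V, each H, LSCC, LAC.  Used, renormalized to
# sum to 1, as the default simulation profiles.
CONTRIBUTION_TABLE: dict[str, tuple[float, ...]] = {
    "mitochondrial_RNA": (2.45, 5.38, 0.72, 13.76, 8.89, 0.33, 17.84, 12.01, 1.01,
                          2.83, 1.16, 0.12, 7.52, 0.61, 0.09),
    "rRNA": (23.69, 18.21, 27.63, 35.01, 18.06, 4.36, 40.39, 19.89, 1.81,
             20.60, 25.17, 51.27, 29.61, 12.18, 2.20),
    "tRNA": (0.70, 0.36, 2.74, 2.39, 0.70, 0.21, 0.42, 0.23, 1.05,
             0.50, 0.57, 0.52, 1.06, 0.86, 0.53),
    "YRNA": (1.83, 0.88, 1.53, 1.48, 1.31, 0.37, 5.01, 1.29, 4.80,
             1.31, 0.79, 0.64, 1.62, 0.25, 3.73),
    "snRNA_7SK": (0.52, 0.22, 0.56, 0.20, 0.07, 0.07, 0.06, 0.04, 0.02,
                  0.17, 0.31, 0.70, 0.18, 0.15, 0.12),
    "SINE": (1.18, 0.27, 0.79, 0.61, 0.28, 0.16, 0.64, 0.47, 0.08,
             0.17, 0.26, 0.14, 0.51, 0.13, 0.06),
    "LINE": (0.46, 0.23, 0.17, 0.23, 0.35, 0.15, 0.15, 0.28, 0.14,
             0.18, 0.32, 0.17, 0.28, 0.51, 0.18),
    "LTR": (0.09, 0.06, 0.04, 0.06, 0.09, 0.02, 0.04, 0.07, 0.05,
            0.03, 0.10, 0.08, 0.07, 0.17, 0.05),
    "DNA_repeat": (0.04, 0.08, 0.17, 0.03, 0.05, 0.02, 0.02, 0.05, 0.04,
                   0.08, 0.06, 0.08, 0.05, 0.06, 0.03),
    "other_repeat": (0.03, 0.07, 0.03, 0.09, 0.07, 0.02, 0.06, 0.05, 0.03,
                     0.05, 0.25, 0.13, 0.75, 3.85, 0.03),
    "mRNA": (22.50, 30.54, 26.08, 19.80, 34.12, 30.24, 15.21, 29.88, 31.28,
             25.16, 33.98, 20.11, 21.09, 35.80, 31.36),
    "ncRNA": (22.71, 3.55, 2.95, 2.84, 2.92, 4.16, 1.62, 3.27, 16.30,
              2.25, 3.13, 2.95, 3.60, 3.19, 17.93),
    "non_RefSeq": (23.79, 40.14, 36.60, 23.50, 33.10, 59.89, 18.54, 32.47, 43.39,
                   46.67, 33.89, 23.08, 33.67, 42.23, 43.69),
}

# (count, min_len, max_len, tier) per class: class-typical sequence sizes.
DEFAULT_REF_SPEC: dict[str, tuple[int, int, int, int]] = {
    "adapter": (2, 40, 45, 1),
    "mitochondrial_RNA": (10, 200, 1600, 1),
    "rRNA": (4, 1500, 5000, 1),
    "tRNA": (10, 70, 90, 1),
    "YRNA": (5, 83, 112, 1),
    "snRNA_7SK": (12, 100, 330, 1),
    "SINE": (4, 250, 320, 1),
    "LINE": (2, 4000, 6000, 1),
    "LTR": (2, 400, 600, 1),
    "DNA_repeat": (2, 250, 350, 1),
    "other_repeat": (2, 171, 250, 1),
    "mRNA": (20, 500, 3000, 2),
    "ncRNA": (8, 500, 2000, 2),
    "non_RefSeq": (2, 30000, 30000, 3),  # genome stand-in, >=50 kb total
}


@dataclass(frozen=True)
class SimConfig:
    """Read-simulation settings (library geometry and noise)."""

    seed: int = 0
    n_reads: int = 2000
    read_length: int = 50
    insert_min: int = 20  # retained inserts strictly > 19 nt
    insert_max: int = 100
    adapter: str = DEFAULT_ADAPTER
    primer_base: str = "T"
    color_error_rate: float = 0.0
    qual: int = 30

    def __post_init__(self) -> None:
        if self.insert_min <= 19:  # retained inserts are strictly > 19 nt
            raise ValueError("insert_min must be > 19 (size-selection floor)")
        if self.insert_max < self.insert_min:
            raise ValueError("insert_max < insert_min")
        if len(self.adapter) < self.read_length - self.insert_min:
            raise ValueError("adapter too short to pad the shortest insert")
        if not 0.0 <= self.color_error_rate <= 1.0:
            raise ValueError("color_error_rate must be in [0, 1]")


@dataclass
class FractionProfile:
    """Class mixture and within-class feature weights for one library."""

    fraction_id: str
    cohort: str
    class_proportions: dict[str, float]
    feature_weights: dict[str, dict[str, float]] | None = None

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        if any(p < 0 for p in self.class_proportions.values()):
            raise ValueError("negative class proportion")

    @property
    def library_id(self) -> str:
        return f"{self.fraction_id}_{self.cohort}"


@dataclass(frozen=True)
class PlantedEffect:
    """Multiply one feature's within-class weight in selected fractions."""

    feature_id: str
    fractions: tuple[str, ...]
    fold: float


def default_profile(fraction_id: str, cohort: str) -> FractionProfile:
    """Profile seeded from the published contribution-table column."""
    col = FRACTIONS.index(fraction_id) * 3 + COHORTS.index(cohort)
    raw = {cls: CONTRIBUTION_TABLE[cls][col] for cls in CONTRIBUTION_TABLE}
    total = sum(raw.values())
    return FractionProfile(
        fraction_id, cohort, {cls: v / total for cls, v in raw.items()}
    )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def generate_references(
    config: SimConfig,
    ref_spec: Mapping[str, tuple[int, int, int, int]] | None = None,
) -> tuple[ReferenceTier, ReferenceTier, ReferenceTier, pd.DataFrame]:
    """Random reference tiers with class-typical lengths, plus a manifest.

    The simulation adapter itself is always the first tier-1 adapter entry,
    so adapter-only reads are filterable.  The manifest records id, class,
    tier and length of every entry.
    """
    ref_spec = dict(ref_spec or DEFAULT_REF_SPEC)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    tier_entries: dict[int, list[tuple[str, NucleotideSeq, str]]] = {1: [], 2: [], 3: []}
    manifest_rows = []

    for cls in sorted(ref_spec):
        count, lo, hi, tier = ref_spec[cls]
        label = TIER3_CLASS if tier == 3 else cls
        for i in range(count):
            seq_id = f"{cls}_{i + 1:02d}" if tier != 3 else f"chr{i + 1}"
            if cls == "adapter" and i == 0:
                bases = config.adapter
            else:
                bases = _random_seq(rng, int(rng.integers(lo, hi + 1)))
            tier_entries[tier].append((seq_id, NucleotideSeq(seq_id, bases), label))
            manifest_rows.append(
                {"seq_id": seq_id, "class": label, "tier": tier, "length": len(bases)}
            )

    tiers = tuple(
        ReferenceTier(tier_index=t, entries=tier_entries[t]) for t in (1, 2, 3)
    )
    manifest = pd.DataFrame(manifest_rows, columns=["seq_id", "class", "tier", "length"])
    return tiers[0], tiers[1], tiers[2], manifest


def audit_unique_substrings(
    tiers: Iterable[ReferenceTier], k: int = 19
) -> list[tuple[str, str]]:
    """Pairs of distinct entries sharing any k-mer (either strand).

    An empty list certifies that no read-sized fragment of one reference
    can be placed on another, so truth classes are unambiguous.
    """
    owner: dict[str, str] = {}
    collisions: set[tuple[str, str]] = set()
    for tier in tiers:
        for seq_id, seq, _ in tier.entries:
            for strand_seq in (seq.bases, seq.revcomp().bases):
                for off in range(len(strand_seq) - k + 1):
                    kmer = strand_seq[off : off + k]
                    prev = owner.get(kmer)
                    if prev is None:
                        owner[kmer] = seq_id
                    elif prev != seq_id:
                        collisions.add(tuple(sorted((prev, seq_id))))
    return sorted(collisions)


def _feature_weights(
    rng: np.random.Generator,
    tiers: Iterable[ReferenceTier],
    sigma: float = 1.0,
) -> dict[str, dict[str, float]]:
    """Log-normal within-class abundance weights, one draw per feature."""
    weights: dict[str, dict[str, float]] = {}
    for tier in tiers:
        for seq_id, _, label in tier.entries:
            if label == "adapter":
                continue
            weights.setdefault(label, {})[seq_id] = float(
                rng.lognormal(mean=0.0, sigma=sigma)
            )
    return weights


def simulate_library(
    profile: FractionProfile,
    tiers: tuple[ReferenceTier, ReferenceTier, ReferenceTier],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[ColorRead], pd.DataFrame]:
    """Simulate one library: color-space reads plus a truth table.

    Per read: class ~ profile proportions; feature ~ log-normal weights
    within the class; insert uniform within the feature with length
    uniform on [insert_min, insert_max] (clipped to the feature); the read
    is the first ``read_length`` bases of insert + adapter, color-encoded
    against the primer base.  Truth rows give read_id, class, feature,
    1-based closed insert coordinates and insert length.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 202, FRACTIONS.index(profile.fraction_id),
                                    COHORTS.index(profile.cohort)])
        )
    seqs = {sid: seq.bases for tier in tiers for sid, seq, _ in tier.entries}
    weights = profile.feature_weights or _feature_weights(
        np.random.default_rng(np.random.SeedSequence([config.seed, 303])), tiers
    )
    classes = [c for c, p in profile.class_proportions.items() if p > 0]
    for cls in classes:
        feats = weights.get(cls)
        if not feats:
            raise ValueError(f"class {cls!r} has nonzero proportion but no features")
    probs = np.array([profile.class_proportions[c] for c in classes])
    probs = probs / probs.sum()
    per_class_feats = {
        cls: (
            list(weights[cls].keys()),
            np.array(list(weights[cls].values())) / sum(weights[cls].values()),
        )
        for cls in classes
    }

    class_draws = rng.choice(len(classes), size=config.n_reads, p=probs)
    reads: list[ColorRead] = []
    truth_rows = []
    lib = profile.library_id
    for i in range(config.n_reads):
        cls = classes[class_draws[i]]
        feat_ids, feat_p = per_class_feats[cls]
        fid = feat_ids[rng.choice(len(feat_ids), p=feat_p)]
        ref = seqs[fid]
        max_len = min(config.insert_max, len(ref))
        if max_len < config.insert_min:
            raise ValueError(f"feature {fid} shorter than the minimum insert")
        ins_len = int(rng.integers(config.insert_min, max_len + 1))
        start = int(rng.integers(0, len(ref) - ins_len + 1))
        insert = ref[start : start + ins_len]
        template = (insert + config.adapter)[: config.read_length]
        colors = encode_colorspace(template, config.primer_base)
        if config.color_error_rate > 0:
            chars = list(colors)
            for j in range(len(chars)):
                if rng.random() < config.color_error_rate:
                    chars[j] = "0123"[
                        (int(chars[j]) + int(rng.integers(1, 4))) % 4
                    ]
            colors = "".join(chars)
        rid = f"{lib}_{i:06d}"
        reads.append(
            ColorRead(
                read_id=rid,
                primer_base=config.primer_base,
                colors=colors,
                quals=tuple([config.qual] * len(colors)),
            )
        )
        truth_rows.append(
            {
                "read_id": rid,
                "class": cls,
                "feature_id": fid,
                "start": start + 1,
                "end": start + ins_len,
                "insert_length": ins_len,
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "class", "feature_id", "start", "end", "insert_length"],
    )
    return reads, truth


@dataclass
class Fixture:
    """A full simulated study: references, 15 libraries, truth, sample sheet."""

    tiers: tuple[ReferenceTier, ReferenceTier, ReferenceTier]
    manifest: pd.DataFrame
    libraries: dict[str, list[ColorRead]] = field(default_factory=dict)
    truth: dict[str, pd.DataFrame] = field(default_factory=dict)
    sample_sheet: pd.DataFrame = field(default_factory=pd.DataFrame)
    profiles: dict[str, FractionProfile] = field(default_factory=dict)


def make_fixture(
    config: SimConfig,
    planted: Iterable[PlantedEffect] = (),
    fractions: Iterable[str] = FRACTIONS,
    cohorts: Iterable[str] = COHORTS,
) -> Fixture:
    """One library per (fraction, cohort), profiles from the default table.

    Within-class feature weights are drawn once per fraction and shared by
    its cohorts, so cohorts act as replicates of a fraction; planted
    effects multiply a feature's weight in the chosen fractions (all
    cohorts), leaving other features' expected proportions unchanged up to
    renormalization.
    """
    t1, t2, t3, manifest = generate_references(config)
    fixture = Fixture(tiers=(t1, t2, t3), manifest=manifest)
    sheet_rows = []
    for f in fractions:
        weights = _feature_weights(
            np.random.default_rng(
                np.random.SeedSequence([config.seed, 404, FRACTIONS.index(f)])
            ),
            (t1, t2, t3),
        )
        for effect in planted:
            if f in effect.fractions:
                for cls_weights in weights.values():
                    if effect.feature_id in cls_weights:
                        cls_weights[effect.feature_id] *= effect.fold
        for c in cohorts:
            profile = replace(
                default_profile(f, c), feature_weights=weights
            )
            reads, truth = simulate_library(profile, (t1, t2, t3), config)
            fixture.libraries[profile.library_id] = reads
            fixture.truth[profile.library_id] = truth
            fixture.profiles[profile.library_id] = profile
            sheet_rows.append(
                {"library_id": profile.library_id, "fraction": f, "cohort": c}
            )
    fixture.sample_sheet = pd.DataFrame(
        sheet_rows, columns=["library_id", "fraction", "cohort"]
    )
    return fixture


def write_fixture(fixture: Fixture, outdir: str | Path) -> None:
    """Write references, class maps, libraries, truth and sample sheet."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t1, t2, t3 = fixture.tiers
    for tier, name in ((t1, "tier1"), (t2, "tier2"), (t3, "genome")):
        write_fasta((seq for _, seq, _ in tier.entries), outdir / f"{name}.fasta")
        if name != "genome":
            write_classmap(
                {sid: label for sid, _, label in tier.entries},
                outdir / f"{name}.classmap.tsv",
            )
    fixture.manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    for lib, reads in fixture.libraries.items():
        write_csfasta(reads, outdir / f"{lib}.csfasta", outdir / f"{lib}.qual")
        fixture.truth[lib].to_csv(outdir / f"{lib}.truth.tsv", sep="\t", index=False)
    fixture.sample_sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
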