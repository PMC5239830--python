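"""End-to-end orchestration: simulate -> align/classify -> quantify -> diff.

The pipeline consumes reference tiers plus per-library read files (or an
in-memory fixture), runs k=1 classification for class-contribution tables,
k=2 classification for feature-level fragment counts and FPKM, and the two
contrast schemes of the study design; every stage's read accounting lands
in a JSON run manifest alongside the configuration hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .align import AlignParams, TrimSchedule, TierIndex, make_trim_schedule
from .classify import ClassTable, class_table, classify_reads, wide_class_table, write_class_table
from .colorspace import read_csfasta
from .diffabund import read_sample_sheet, run_contrasts
from .quantify import (
    EligibilityFilter,
    abundance_table,
    count_fragments,
    count_matrix,
    write_abundance,
)
from .references import build_tiers

log = logging.getLogger("bloodrna")


@dataclass
class RunConfig:
    """Paths and parameters for a full pipeline run."""

    tier1_fasta: str
    tier1_classmap: str
    tier2_fasta: str
    tier2_classmap: str
    genome_fasta: str
    sample_sheet: str
    reads_dir: str
    output_dir: str
    seed: int = 0
    max_mismatches: int = 2
    min_alignment_count: float = 100
    read_length: int = 50
    min_trim_length: int = 19
    trim_steps: tuple[int, ...] | None = None  # override the default ladder
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "trim_steps" in data and data["trim_steps"] is not None:
            data["trim_steps"] = tuple(data["trim_steps"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def schedule(self) -> TrimSchedule:
        if self.trim_steps is not None:
            return TrimSchedule(self.read_length, self.min_trim_length, tuple(self.trim_steps))
        return make_trim_schedule(self.read_length, self.min_trim_length)


def _check_paths(config: RunConfig) -> None:
    for attr in (
        "tier1_fasta", "tier1_classmap", "tier2_fasta", "tier2_classmap",
        "genome_fasta", "sample_sheet", "reads_dir",
    ):
        p = Path(getattr(config, attr))
        if not p.exists():
            raise FileNotFoundError(f"{attr}: {p} does not exist")


def run(config: RunConfig) -> Path:
    """Execute all stages; returns the output directory.

    Writes per-library class tables, the wide contribution table, per-library
    abundance tables, the fragment count matrix, one differential table per
    contrast, and ``run_manifest.json``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    _check_paths(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    tiers = build_tiers(
        config.tier1_fasta, config.tier1_classmap,
        config.tier2_fasta, config.tier2_classmap,
        config.genome_fasta,
    )
    schedule = config.schedule()
    sheet = read_sample_sheet(config.sample_sheet)
    indexes = tuple(TierIndex(t, space="color") for t in tiers)
    feature_lengths = {
        sid: len(seq) for t in tiers for sid, seq, label in t.entries if label != "adapter"
    }

    accounting: dict[str, dict] = {}
    tables: list[ClassTable] = []
    per_lib_counts: dict[str, dict[str, float]] = {}
    for lib in sheet["library_id"]:
        reads = read_csfasta(
            Path(config.reads_dir) / f"{lib}.csfasta",
            Path(config.reads_dir) / f"{lib}.qual",
        )
        log.info("library %s: %d reads", lib, len(reads))
        res1 = classify_reads(
            reads, indexes, AlignParams(config.max_mismatches, k=1), schedule
        )
        table = class_table(res1.assignments, lib)
        write_class_table(table, outdir / f"{lib}.class_table.tsv")
        tables.append(table)

        res2 = classify_reads(
            reads, indexes, AlignParams(config.max_mismatches, k=2), schedule
        )
        counts = count_fragments(res2.multi_records)
        per_lib_counts[lib] = counts
        write_abundance(
            abundance_table(counts, feature_lengths, lib),
            outdir / f"{lib}.abundance.tsv",
        )
        accounting[lib] = {
            "reads": len(reads),
            "reportable": table.total_mapped,
            "adapter": len(res1.adapter_ids),
            "unmapped": len(res1.unmapped_ids),
        }

    wide = wide_class_table(tables)
    wide.to_csv(outdir / "class_contributions_wide.tsv", sep="\t", float_format="%.4f")

    matrix = count_matrix(per_lib_counts)
    matrix.to_csv(outdir / "count_matrix.tsv", sep="\t", float_format="%.6g")

    results = run_contrasts(
        matrix, sheet, EligibilityFilter(config.min_alignment_count)
    )
    for name, frame in results.items():
        frame.to_csv(outdir / f"diff_{name}.tsv", sep="\t", index=False,
                     float_format="%.6g")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "schedule_steps": list(schedule.steps),
        "libraries": accounting,
        "n_contrasts": len(results),
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
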