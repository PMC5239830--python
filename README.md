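# bloodrna

RNA-class profiling of small RNA-seq libraries from fractionated human
blood, built around SOLiD color-space reads.

## The problem

Human blood can be separated by sequential centrifugation into cells,
plasma, a 16,000 g pellet (microvesicles and cell-free mitochondria), a
160,000 g pellet (exosome-enriched), and vesicle-depleted supernatant.
Sequencing the RNA of each fraction asks two questions: *what kinds of RNA*
circulate in each compartment, and *which transcripts differ* between
compartments or between healthy and lung-cancer donors.  Answering them
from 50-nt SOLiD reads of short (20–100 nt) inserts requires a pipeline
that (a) handles di-base color-space encoding, (b) removes 3′ adapter
read-through by progressive trimming, (c) resolves each read's RNA class
against overlapping reference sets, and (d) tests count differences with
very few replicates.

`bloodrna` implements that pipeline as a library + CLI, together with a
synthetic-data generator that reproduces the study geometry (15 libraries
= 5 fractions × 3 cohorts) so every stage is testable without any
external download.

## Method

* **Color space.** Each color `c_i ∈ {0,1,2,3}` encodes the di-base
  transition `(b_{i-1}, b_i)` (identity → 0, A↔C/G↔T → 1, A↔G/C↔T → 2,
  complements → 3), anchored by a known primer base.  Reads are aligned in
  color space against the color-encoded reference; color strings are
  strand-symmetric up to reversal.
* **Trimming ladder.** A read is tried at full length (50 nt), then
  trimmed from the 3′ end in 11 steps of 4/3/2 nt
  (50 → 46 → 43 → … → 21 → 19), stopping at the first length with a
  placement of ≤ 2 mismatches.  19 nt is the size-selection floor.
* **Three-tier classification.**  Tier 1: adapters/primers, mitochondrial
  transcripts, repeat consensi (SINE incl. 7SL, LINE, LTR, DNA, other),
  tRNA/rRNA/snRNA+7SK/Y RNA.  Tier 2: exonic RefSeq transcripts (mRNA,
  ncRNA).  Tier 3: genome (class `non_RefSeq`).  A read only reaches tier
  *t*+1 if it has no placement in tier *t*.  With one placement per read
  (k = 1) this yields per-library **class contribution tables** (percent
  of mapped, reportable reads; adapter matches are filtered out).
* **Quantification.**  With k = 2 a read may have two placements (½
  fragment each); `FPKM = fragments · 10⁹ / (length · total fragments)`.
  Features are tested only when their summed fragment count over the
  compared libraries reaches the min-alignment-count cut-off (default 100).
* **Differential distribution.**  Upper-quartile normalization, NB
  dispersion (`Var = μ + αμ²`) by method of moments shrunk toward a
  mean-dispersion trend — pooled ("blind") for single-replicate contrasts,
  per-condition with the maximum otherwise — then a Wald test on log group
  means (exact-style conditional beta-binomial test for 1-vs-1 contrasts)
  and Benjamini–Hochberg q-values per contrast.  Contrasts follow the
  study design: all 10 fraction pairs (cohorts as replicates) and, within
  each fraction, healthy vs LSCC and healthy vs LAC.

## Worked example

```python
from bloodrna import (AlignParams, SimConfig, default_profile,
                      generate_references, simulate_library)
from bloodrna.classify import class_table, classify_reads

cfg = SimConfig(seed=0, n_reads=20_000)
tiers = generate_references(cfg)[:3]
profile = default_profile("III", "H")      # 16,000 g pellet, healthy donors
reads, truth = simulate_library(profile, tiers, cfg)
result = classify_reads(reads, tiers, AlignParams(max_mismatches=2, k=1))
table = class_table(result.assignments, "III_H")
print(table.to_frame().sort_values("reads", ascending=False).to_string(index=False))
```

prints

```
library_id             class  reads    pct
     III_H              rRNA   8125 40.625
     III_H        non_RefSeq   3715 18.575
     III_H mitochondrial_RNA   3607 18.035
     III_H              mRNA   3012 15.060
     III_H              YRNA    967  4.835
     III_H             ncRNA    310  1.550
     III_H              SINE    120  0.600
     III_H              tRNA     82  0.410
     III_H              LINE     33  0.165
     III_H      other_repeat     10  0.050
     III_H         snRNA_7SK     10  0.050
     III_H               LTR      6  0.030
     III_H        DNA_repeat      3  0.015
```

All 20,000 reads are mapped; the recovered percentages sit within
sampling error of the fraction-III healthy-donor mixture the simulator
targets (e.g. 18.04 % mitochondrial vs the 17.84 % setting, 40.63 % rRNA
vs 40.39 %) — the adapter read-through of every insert shorter than 50 nt
has been resolved by the trimming ladder rather than inflating the
unmapped count.

The same flow is available from the shell:

```bash
bloodrna simulate --seed 0 --n-reads 2000 --out sim/
bloodrna classify --refs sim/ --reads sim/III_H.csfasta --out III_H.classes.tsv
bloodrna diff --matrix counts.tsv --sample-sheet sim/sample_sheet.tsv --out diff/
```

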