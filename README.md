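# eukbench

Benchmarking machinery for **eukaryotic metatranscriptome assembly**: build
mock communities with known ground truth, simulate sequencing from them,
consolidate multi-assembler outputs, and measure how faithfully a
reassembly recovers what went in.

De novo metatranscriptome assembly of environmental eukaryotic communities
is hard to validate: the organisms are diverse, reference databases are
sparse, and different assemblers recover different (partially overlapping)
contig sets. The standard way to judge a pipeline is to feed it a
*designer metatranscriptome* — a gold-standard contig set sampled from
reference transcriptomes under controlled diversity and orthology
structure — simulate reads from it, and check what comes back. This
package implements that whole loop as a library:

* **Synthetic reference panels** (`panels`): multi-organism transcriptome
  sets with designed gene families (star topology around an ancestral
  sequence), designated near-identical strain pairs, single-copy
  orthogroups, and taxonomy/function labels. Every gene's orthogroup is
  known by construction, so downstream steps are testable without any
  reference download; real FASTA panels can be substituted.
* **Similarity and diversity** (`similarity`): bottom-s MinHash sketches
  over canonical k-mers (default k = 31, s = 1000); Jaccard estimates;
  ANI via the Mash transform `ANI = 100·(1 + ln(2j/(1+j))/k)`; the ≥ 80%
  ANI rule for "highly related partner" pairs; Shannon index
  `H = −Σ pᵢ ln pᵢ`, richness, and a composite score
  `Σᵢ Σⱼ (1 − sᵢⱼ)·min(pᵢ, pⱼ)` that weights pairwise sketch
  dissimilarity by the rarer member's abundance.
* **Orthology** (`orthology`): OrthoFinder-dialect `Orthogroups.tsv`
  read/write, single-copy group detection against a community roster, and
  approximate orthogroup inference by single-linkage over local
  alignments.
* **Community design** (`design`): six community templates (single
  dominant; strain-pair majority; exclusive-gene skew; high richness with
  related pairs; mutually related; maximal even richness) and
  ortholog-aware contig selection — force-include 10% of single-copy
  orthogroups across all members, then fill each organism's abundance
  quota 75%/25% from shared/exclusive orthogroups (flipped when the
  organism has no ≥ 80%-ANI partner) — with a per-contig provenance
  manifest.
* **Read simulation** (`reads`): 75 bp paired-end reads from 180 ± 40 bp
  truncated-normal fragments, per-cycle substitution errors at
  `10^(−Q/10)`, plus a Trimmomatic-style trimmer
  (LEADING/TRAILING/SLIDINGWINDOW:4:2/MINLEN:50 semantics).
* **Merging and clustering** (`cluster`, `align`): an exact
  Smith–Waterman kernel (identity = matches / alignment columns, gaps
  included) behind greedy linclust-style clustering, and the merge
  hierarchy AGM (concatenate) → dedup (100% containment) → CAG (98%
  identity) → MAD (cross-sample 98%).
* **Evaluation** (`evaluate`): N50 and contig statistics, six-frame ORF
  finding (≥ 100 aa), protein-space recovery at 90% identity / 90% target
  coverage, a k-mer pseudo-mapper as a quantification proxy (percentage
  mapping, TPM), taxonomic match/conflict/unannotated classification,
  function-token match/false-positive/not-recovered sets, multi-assembler
  consensus support, OLS (with optional zero intercept) and Welch's *t*.

## Worked example

`examples/02_design_community.py` builds a 6-organism panel with one
strain pair and designs a template-2 (strain-pair-dominated) community:

```
community members and proportions:
  org01: 0.400 (partnered)
  org02: 0.350 (partnered)
  org03: 0.083
  org04: 0.083
  org06: 0.083

designer metatranscriptome: 40 contigs
selection categories per organism:
category  exclusive_og  shared_og
organism
org01                4         12
org02                3         11
org03                3          1
org04                2          1
org06                2          1

Shannon index 1.355, richness 5, composite score 2.031
```

The strain pair holds 75% of the community; its members draw ~75% of
their quota from shared orthogroups (12 of 16, 11 of 14 — largest-
remainder rounding at small quotas), while the unpartnered members draw
~75% from exclusive ones. The Shannon index sits below ln 5 ≈ 1.609
because the community is uneven, and the composite score reflects that
four of the five members are mutually dissimilar while the strain pair
contributes almost no dissimilarity.

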