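# Methods

This note documents the models, parameter choices and numerical
conventions behind `eukbench`, and what the synthetic benchmarks do and do
not demonstrate about real data.

## Synthetic reference panels

A panel emulates a curated collection of single-organism eukaryotic
reference transcriptomes. Gene families follow a **star topology**: each
family has one ancestral sequence, and every member organism carries an
independently mutated copy (substitutions uniform over the three
alternative bases). This is the simplest model that gives direct control
over pairwise identity; it deliberately ignores tree-shaped phylogeny,
codon usage, expression-level realism, and intron/UTR structure.

Ancestral genes are built as one full-length open reading frame (ATG,
random non-stop codons, terminal stop), lengths uniform on [300, 3000] bp
— transcript-scale contigs. After mutation, each member's frame is
*repaired* (start codon and terminal stop restored, internal in-frame
stops recoded by a T→C first-position change): real orthologs keep their
frame under purifying selection, while neutral mutation at 15–30%
divergence would riddle them with stops and make protein-space evaluation
vacuous.

Key rates (per-base substitution probabilities, all overridable):

| parameter | default | rationale |
|---|---|---|
| `within_family_sub_rate` (member vs ancestor) | 0.15 | cross-genus orthologs in real reference panels sit near 70–75% nucleotide identity (two members are ~2× the per-member rate apart) |
| `strain_pair_sub_rate` | 0.02 | strains of one species are ~98% identical |
| `fraction_single_copy` | 0.1 | a modest core of universal single-copy families |
| `fraction_shared_families` | 0.5 | half of the non-core genes have homologs elsewhere |

A designated strain partner is generated by mirroring its partner's genes
at the strain-pair rate: all single-copy and shared families, plus half of
the partner's exclusive families (so both strains retain exclusive genes —
needed for the 25% exclusive draw during community design); its remaining
genes are fresh exclusive families.

The within-family default interacts with partner detection. The Mash
transform `ANI = 100·(1 + ln(2j/(1+j))/k)` saturates high at small
Jaccard: at k = 31, any j ≳ 0.001 maps above 80%. Organisms sharing
families at ~10% pairwise divergence (per-member rate 0.05) would
therefore exceed the 80% "highly related partner" cutoff despite not
being strains. At the default 0.15 the shared-family k-mer signal drops
below the sketch detection limit and the cutoff separates cleanly:
strain pairs land at 95–98% estimated ANI, everything else below ~77%.
Tests that need low within-family divergence (orthogroup-inference
recovery, which is specified for ≤ 10% divergence panels) construct
panels at a 0.05 rate explicitly.

## Similarity, diversity

Sketches are bottom-s MinHash over canonical k-mers (min of the packed
2-bit forward and reverse-complement integers), hashed with a seeded
splitmix64 finalizer; Jaccard is estimated over the merged bottom-s set.
ANI uses the Mash distance transform and is floored at 0; Jaccard 0 is
reported as "below detection" rather than ANI 0 being meaningful. This is
a whole-transcriptome sketch ANI, not a fragment-mapping ANI: it
reproduces the ≥ 80% partner rule's behavior at panel divergences but is
not a general-purpose ANI estimator between distant genomes.

Shannon index uses the conventional `H = −Σ p ln p` (natural log);
richness counts members with p > 0. The composite score is the literal
double sum over ordered pairs `Σᵢ Σⱼ (1 − sᵢⱼ)·min(pᵢ, pⱼ)` with zero
diagonal, so each unordered pair counts twice; it is invariant under
member relabeling and collapses to 0 for a single-member community.

## Community design

Template proportions are package defaults chosen to realize each
template's qualitative description: T1 richness 4 (0.85/0.05/0.05/0.05);
T2 richness 5 (strain pair 0.40/0.35, rest splitting 0.25); T3 richness 8
with geometric decay (ratio 0.7); T4 richness 10, even, preferring two
partner pairs; T5 richness 7, even, preferring related members; T6
richness 12, even. All are overridable via `CommunitySpec`.

Selection: 10% of the community's single-copy orthogroups (rounded) are
drawn and force-included for every member; forced genes do **not** count
against per-organism quotas (the rules are silent on this; counting them
would make small communities infeasible and couples quota splits to the
single-copy pool size). Quotas are the remaining budget allocated by
largest-remainder over proportions; within an organism the 75/25
shared/exclusive split (flipped for unpartnered members) is also
largest-remainder, ties to the majority category. "Shared" means the
orthogroup contains at least one *other community member's* gene —
membership is always evaluated against the community roster, not the full
panel. Expression weights default to proportion/contig-count (uniform
within organism) with an optional lognormal(σ = 1) multiplier; the
within-organism expression distribution is not specified anywhere, and
uniform keeps read-count expectations analytic for testing.

## Read simulation and trimming

Fragments are `Normal(180, 40)` truncated (by resampling) to
[read length, contig length] and rounded to integers; with 5 kb contigs
the truncated model's analytic mean/sd are ≈ 180.5/39.3 bp, and the
empirical moments are checked against those analytic values (checking
against the untruncated 180/40 would conflate the truncation the model
itself imposes with simulator error). Contigs are drawn proportional to
weight × (length − read length + 1); fragment starts are uniform. R1 is
the fragment 5′ end on the forward strand, R2 the reverse complement of
the 3′ end. Substitutions are injected per cycle at `10^(−Q/10)` under a
linear Q38→Q25 default profile (the upstream simulator's built-in profile
is not published; a gentle linear decay is typical of modern short-read
data). Q ≥ 60 is the error-free sentinel. Indel sequencing errors, PCR
duplicates and adapters are not simulated.

The trimmer implements LEADING/TRAILING clipping, the sliding-window rule
(cut at the start of the first window whose mean quality falls below the
threshold; defaults window 4, quality 2), and MINLEN 50 with unpaired
routing. Windows are only evaluated where a full window fits.

## Alignment and clustering

The kernel is exact Smith–Waterman (match +1, mismatch −2, linear gap −2)
with **identity = matches / alignment columns, gap columns included** —
stated explicitly because it decides borderline cases near 98%. With
these scores any ≥ 70% identical overlap extends fully, so the 80/90/98/
100% thresholds all operate in the regime where the local alignment spans
the homologous region. Coverage is the aligned span over the sequence
length, applied to the shorter sequence or to the target (representative
/ designer protein) depending on the step.

Greedy clustering visits sequences longest-first (ties by id), joining
the first (by founding order) representative that passes both thresholds,
with a shared canonical 15-mer prefilter; this makes output independent
of input order. The representative is the longest member. The 98% rounds
use shorter-sequence coverage 0.8: the upstream description fixes only
the identity threshold for these rounds, and 0.8 tolerates the ragged
ends real assemblers produce while still requiring substantial overlap.
The 100% dedup round uses shorter-sequence coverage 1.0 (strict
containment).

## Evaluation

* **N50**: sort lengths descending, return the length where the
  cumulative sum first reaches half the total.
* **ORFs**: six-frame scan, start-to-stop (or open-ended) stretches with
  ≥ 100 aa and a required ATG by default; coordinates are 0-based
  half-open on the forward strand. This replaces model-based coding
  prediction; panel contigs are built ORF-bearing so the simplification
  costs nothing on synthetic data, but on real assemblies it will call
  spurious ORFs in long contigs and miss non-ATG starts.
* **Protein recovery**: an assembly contig is *matched* when any of its
  ORF proteins aligns to a designer protein at ≥ 90% identity covering
  ≥ 90% of the designer protein. All matched designer ids are recorded;
  when different ORFs match different designer contigs the report keeps
  them all and leaves interpretation to the caller.
* **Pseudo-mapping**: a read maps to the contig sharing the most of its
  canonical 31-mers if that share reaches 70% of the read's k-mers; TPM
  is count/kb normalized to 10⁶. This is a deliberate proxy, stringent
  against divergent contigs (one substitution kills up to k k-mers);
  results are labeled proxy and externally computed count tables can be
  supplied instead wherever abundances are consumed.
* **Statistics**: OLS by normal equations; through-origin slope
  `Σxy/Σx²` with intercept 0; Welch's t with Welch–Satterthwaite df
  (identical zero-variance samples return t = 0 by convention).

## What the synthetic benchmarks show — and what they do not

Passing tests demonstrate that the machinery implements its stated rules
exactly (selection fractions, thresholds, alignment identity accounting,
fragment model) and that the pipeline is self-consistent (designer
self-recovery is perfect, degradation moves metrics monotonically). They
do **not** demonstrate performance on real communities: synthetic panels
have no repeats, no alternative splicing, no expression skew beyond the
designed proportions, frame-preserving divergence only, and uniform base
composition. Absolute recovery numbers on real data depend on assembler
behavior and database coverage, which are outside this package's scope
(assemblies are consumed as FASTA; annotations as label tables).

## Problem sizes

Default scales are desk-scale by design: panels of 4–12 organisms with
tens to hundreds of genes each, designer budgets of tens to a few
thousand contigs, 10³–10⁵ read pairs in tests and checks. The
paper-scale regime (~50k contigs, 10⁶ pairs) is supported by
configuration but not exercised in the test suite.
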