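# Methods

## Problem setting

Transfecting cells with an antagomir (a single-stranded antisense
oligonucleotide against a miRNA) can perturb not only its intended target
but also unrelated miRNAs, e.g. by competing for RISC loading or by pairing
with another miRNA's primary transcript. Detecting such perturbation takes
three computational pieces, all implemented here: (i) quantifying each
mature miRNA in small-RNA-seq libraries by exact matching of reads to
reference sequences, (ii) relative quantification of qPCR threshold cycles,
and (iii) scanning the antagomir against candidate pri-miRNA sequences for
ungapped complementary regions.

## Seed-and-grow matching

Reads are adapter-trimmed, collapsed to distinct sequences with occurrence
counts, and matched against a panel of reference small RNAs:

1. **Seeding.** Every 16-mer of every reference is indexed with its 0-based
   offset. A reference of length L contributes exactly L − 15 seeds (a 23-nt
   siRNA has 8; the 25-nt anti-miR21 has 10). Seeds are exact; `N` never
   matches.
2. **Growth.** Each (read 16-mer, indexed reference 16-mer) anchor is
   extended one base at a time toward the 5′ end and then the 3′ end while
   read base equals reference base and neither sequence is exhausted. The
   grown region is the matched span; mismatches are never absorbed into it.
3. **Reporting.** Each record carries the 1-based inclusive reference span,
   the read bases left outside the span as 5′/3′ flanks, and the collapsed
   occurrence count. The invariant `sequence == flank5 + span + flank3`
   holds for every record and is asserted throughout the tests. Anchors that
   grow to the same (reference, span, read placement) are deduplicated;
   distinct maximal spans (reference-internal repeats) are all reported.

Matches are sorted by descending matched length, then reference id, then
start. `match_library` offers two multi-reference policies: `all` reports
every hit; `best` (the default used for quantification) keeps only the
top-sorted hit per distinct sequence so library counts are never inflated by
references that share a 16-mer. Reverse-complement ("anti-sense") matching
is realized at the sequence level — `build_index(..., add_reverse_complements=True)`
indexes each reference's reverse complement under `<id>|rc` — keeping the
matcher itself strand-agnostic.

The matcher is validated against an independent brute-force oracle that
extends every (read offset, reference offset) base pair maximally and keeps
runs of ≥ 16; the two agree exactly on thousands of random, mutated,
embedded and unrelated pairs (lengths 16–40).

`export_stack` renders all matches to one reference as a padded, strictly
gapless stacked alignment (reference row first, matched bases uppercase,
flanks lowercase, `.` padding) — a deterministic text replacement for an
interactive alignment viewer.

### Numerical/representational choices

- Internal coordinates are 0-based half-open; reported coordinates are
  1-based inclusive ("bases 1–16" style).
- Alphabet is normalized to DNA ({A,C,G,T,N}, U→T) on input; references must
  be N-free, reads may contain N (treated as a universal mismatch).
- Adapter trimming cuts at the leftmost position where an adapter prefix of
  length ℓ ≥ `min_overlap` (default 6) aligns with at most
  ⌊ℓ·`max_mismatch_rate`⌋ mismatches (default rate 0.1). Inserts shorter
  than 16 nt are dropped: they cannot hold a seed. Trim decisions are cached
  per distinct sequence for speed; the cut rule is sequence-deterministic so
  caching is exact.

## Quantification and comparison

Best-mode match records are totalled into a reference × sample count table.
Conditions are compared per reference by `fold_change = mean(treated) /
mean(control)` on raw counts (all simulated libraries have equal depth;
counts-per-million is available behind `use_cpm=True` and makes fold changes
invariant to per-sample scaling), `percent_change = (fold − 1) × 100`, and a
two-tailed unpaired equal-variance Student's t-test when both conditions
have ≥ 2 replicates (Welch's variant is available behind a flag). Degenerate
inputs are handled explicitly: zero control mean raises an error rather than
returning infinity; zero pooled variance gives t = 0, p = 1 for equal means
and a flagged p = 0 for unequal means. No multiple-testing correction is
applied — comparisons are per-miRNA, as in the assay design this mirrors;
for genome-wide panels a correction would be required.

## 2^−ΔΔCt relative quantification

ΔCt = mean(Ct_target) − mean(Ct_reference gene) within a condition
(replicates averaged at the Ct level, the standard Livak choice);
ΔΔCt = ΔCt_treated − ΔCt_control; RQ = 2^−ΔΔCt. No amplification-efficiency
correction is applied. Useful identities, all property-tested: RQ(0) = 1,
RQ(a+b) = RQ(a)·RQ(b), −log2 RQ(x) = x, and RQ is invariant to shifting
every Ct by a constant. A ΔΔCt of 0.152 cycles is a 10% reduction; 2.3219
cycles is an 80% reduction. Ct values must lie in (0, 40), the run length of
the assay emulated.

## Antagomir complementarity scan

The full-length query slides over the target without gaps. In `complement`
mode (default) window position i pairs target base `t[offset+i]` with query
base `q[L−1−i]` — the antiparallel duplex geometry — scoring Watson–Crick
pairs 1.0 and, optionally, G:U wobbles (G·T in DNA alphabet) at weight 0.5.
In `identity` mode positions score on equality (useful when "homology" to a
printed sequence, not pairing, is the question); with wobble weight 0,
complement mode equals identity mode applied to the reverse-complemented
query. Hits are ranked by descending score, ties by ascending target start;
the top hit is the candidate hybrid region. This is pure match counting: no
thermodynamic (ΔG) model, no secondary-structure prediction. Wobble pairs
are not invariant under reverse-complementing both strands (G:U ↦ C:A), so
the strand-symmetry property holds exactly only at wobble weight 0.

## Synthetic data generator

The simulator stands in for sequencing libraries that cannot be downloaded:
it emulates a two-condition (mock vs antagomir-transfected), replicated
small-RNA-seq experiment with known ground truth.

- **Reads** are `insert + 3′ adapter` (default: the TruSeq small-RNA
  adapter). Per library, per-reference read counts are a multinomial draw
  from the condition's abundance fractions; these pre-noise counts are the
  recorded truth and sum exactly to the library size.
- **isomiR end heterogeneity**: independent 5′ and 3′ end shifts drawn from
  a distribution over {−2…+2} (default P(0)=0.80, P(±1)=0.08, P(±2)=0.02 per
  end). Negative shifts trim the mature sequence; positive shifts extend
  into a fixed per-reference flanking context, i.e. all shifts are
  templated, so every read's true source reference is unambiguous.
  Non-templated tailing is deliberately not modelled.
- **Errors**: uniform per-base substitutions on the insert (default 0.001,
  HiSeq-like). No indels — the matcher is gapless, and indel reads would
  only add an unmatched fraction without testing anything new. Qualities are
  constant (unused downstream).
- **Determinism**: each library's generator is seeded by (experiment seed,
  condition index, replicate index), so any library is a pure function of
  the configuration and identical configs give byte-identical FASTQ.

Default conditions — chosen once as a realistic small panel, not tuned:
3 replicates × 50,000 reads per library; panel of five miRBase-style mature
sequences (miR21, miR21\*, miR30, miR20, miR28) with control fractions
0.35/0.05/0.25/0.20/0.15; treated-arm factors 0.87 (miR21), 0.20 (miR30) and
6.0 (miR21\*, the antagomir-borne star-strand sequence), with the remaining
mass shared by miR20/miR28 in their control proportions so the configured
fold changes hold exactly in expectation at equal depth. These factors
emulate the direction and magnitude of the perturbations the pipeline is
meant to detect (a modest ~13% miR21 reduction, a strong miR30 reduction, a
dramatic miR21\* increase).

**What passing recovery tests shows — and what it does not.** The generator
produces reads whose only deviations from the reference are templated end
shifts and uniform substitutions. Real libraries additionally contain
ligation bias, PCR duplication, non-templated tailing, other small-RNA
classes and cross-mapping families; recovery of configured fold changes here
demonstrates the pipeline's correctness (trimming, matching, counting and
comparison introduce no bias), not robustness to those real-data artifacts.

Recovery is checked on the log2 scale: with p the reference's abundance
fraction, N the library size and r replicates, the estimator's binomial
standard error is

    se(log2 FC) = (1/ln 2) · sqrt[(1−p_t)/(r·N·p_t) + (1−p_c)/(r·N·p_c)]

and the pipeline estimate must fall within 3 se of the configured value.
Matching losses (reads whose substitution lands so that no 16-nt perfect run
survives) are condition-independent per reference and therefore cancel in
the fold change.

## Problem sizes

Unit tests use 200–5,000-read libraries; the end-to-end recovery check and
the acceptance script run the full default experiment (2 × 3 × 50,000
reads), which completes in a few seconds. Oracle-equivalence checks use
1,000+ random pairs per run.

## Known limitations

- Counting is reference-panel based; reads from small RNAs outside the panel
  are simply unmatched. No genome mapping, no isomiR nomenclature, no SAM
  output.
- The 16-nt perfect seed makes the matcher blind to reads whose every 16-mer
  carries an error; at realistic substitution rates this loss is <3% and
  condition-balanced, but the matcher is not meant for high-error platforms.
- The complementarity scan counts matches; it does not rank by hybridization
  energy, and a high score need not imply a stable duplex in vivo.
- The equal-variance t-test on counts is the comparison this package
  formalizes; it is not a dispersion-modelling differential-expression
  method and should not be used as one.
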