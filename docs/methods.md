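# Methods

This note documents the models, rules and numerical choices behind
`amphap454`, in the order data flows through the pipeline, and states what
the simulator does and does not emulate.

## Read model and ingest

A read is a basecall string over {A,C,G,T,N} with one Phred score per base
(Sanger +33 encoding, scores 0–60; higher scores are rejected loudly as a
likely +64 dialect rather than silently re-interpreted). Native flowgram
(SFF) ingestion is deliberately out of scope: every rule below operates on
basecalls and qualities, so FASTQ or FASTA+QUAL is the ingest contract.
Reads additionally carry two clip counters recording how many bases quality
trimming removed from each end; these are metadata (excluded from equality)
and round-trip through FASTQ via the record description. Their role is
explained under *Pileup construction*.

## Demultiplexing

Amplicons are built from fusion primers, so a read — in either orientation —
has the layout `adaptor, MID, primer, insert, rc(primer), rc(MID),
rc(adaptor)`, with the same MID on both ends because both of an
individual's fusion primers carry it. Reads are processed by rules in a
fixed order (the order is a package choice; each rule is independently
configurable):

1. **Length ≥ 150 bp**, strict, on the raw read.
2. **Mean quality ≥ 30**, strict, arithmetic mean over the raw read. The
   alternative (trimmed-read mean) is defensible; we fix raw-read mean and
   apply the length rule again after trimming, logging both short counts.
3. **MID at both ends.** The adaptor is a known constant and is *located*
   with a small mismatch tolerance (default ≤ 2), but MID matching itself is
   exact by default: the barcode must appear immediately after the 5′
   adaptor and its reverse complement immediately before the 3′ adaptor, and
   both must be the same barcode. An optional ≤ 1-substitution mode exists
   but is off: the barcode sets are designed error-tolerant, and the discard
   rule is "did not match". Absent adaptors are tolerated (reads may begin
   at the MID). Demultiplexing requires MIDs to be unique within one
   sequencing region: the locus table carries no species column, so a
   barcode shared by two samples of different species could not be resolved
   through the declared interfaces.
4. **Whole primer present.** The complete template-specific primer must
   follow the MID with zero mismatches, IUPAC degeneracies expanded
   (degenerate positions in a primer match any base in their expansion; an
   uncalled N in the read matches only a wildcard position). The opposite
   primer's reverse complement must likewise close the insert at the 3′
   end. Matching two loci (possible with degenerate panels) discards the
   read as ambiguous rather than guessing.
5. **Quality trimming** of the insert: modified-Mott end trimming, per-base
   score `cutoff − P_error` with cutoff 0.05, keeping the maximal-scoring
   contiguous interval; then the length rule is re-checked. Trimmed ends are
   recorded as clips.

Reverse-orientation inserts are reverse-complemented (bases and reversed
quals, clips swapped) so downstream pileups are single-stranded. The ledger
partitions the input exactly — every read appears once, kept or with one
discard reason — and is sorted by read id, so output is independent of input
order.

## Pileup construction

Bins are assembled reference-free by star alignment: a seed read is chosen
and every other read is globally aligned to it (match +1, mismatch −2, gap
open −4, gap extend −1, end gaps free) with `Bio.Align.PairwiseAligner`;
insertions relative to the seed open new columns at their junction.

Two choices here matter and were made after observing failure modes on
simulated data:

* **Seed = longest read** (ties: higher mean quality, then smallest id), not
  simply the highest-quality read. A quality-trimmed seed truncates the
  column space: template-end bases seen by full-length reads would surface
  as end-junction insertion columns and masquerade as indel variation.
* **Informative end gaps.** Because demultiplexing demanded both barcodes,
  an amplicon read's untrimmed end *observed* the template end. For a read
  whose 5′ (3′) clip is zero, alignment end gaps on that side are therefore
  counted as gap votes ("no base here"); for a trimmed end they are counted
  as not-covered. Without this distinction, a terminal homopolymer slip in
  one or two reads acquires a private column that nothing can vote down.

Coordinates are 0-based, half-open, on the forward strand of the trimmed
insert.

## Column calls and the 75 % rule

A column is heterozygous iff its plurality symbol accounts for strictly less
than 75 % of the column depth. Depth counts gaps and excludes N (gaps are
real observations of absence; N observes nothing). Two pragmatic gates
surround the rule:

* Columns with depth < 4 (default `min_het_depth`) are not eligible as het
  sites: one stray read at a two-read contig edge is not evidence of
  heterozygosity. The rule itself is unchanged where depth is informative.
* Columns consumed by homopolymer arbitration (below) are not het-callable
  as gap sites.

## Homopolymer arbitration

Run-length miscalls are the platform's dominant error mode, so length
variation of a same-base run is treated as error, not allelic variation. A
*region* is a maximal stretch of ≥ 2 adjacent columns sharing one pure
plurality base in which at least one spanning read carries an alignment
gap. Two guards keep real variation out of regions: substitution-only
variation never triggers one (under the gap-averse scoring a true variant
base aligns as a mismatch, not a gap), and a column with a credible second
base (≥ 25 % of column depth — the het rule's own denominator) splits a run
rather than joining it, so a heterozygous base inside or beside a run stays
callable.

Within a region, three criteria decide the emitted run length, in order:
(1) a length class supported by ≥ 75 % of spanning reads wins; (2) otherwise
the class whose supporting reads have the higher mean quality across the run
wins; (3) quality ties break toward the shorter run. Below 10× spanning
coverage, criterion (2) decides alone. A zero-length observation (the run
deleted entirely) takes its confidence from the nearest covered flanking
base.

Consequence, inherent to this design: a genuine allelic homopolymer-length
polymorphism is always collapsed to a single length. The population-level
singleton edit (below) embodies the same judgement — one-base homopolymer
differences are overwhelmingly artifacts at this platform's error profile.

## Phasing, chimera removal, allele sequences

Each read is keyed by its symbol vector across the het sites; the two most
frequent complete keys become the allelic states (supports are exact key
counts; support ties order alleles lexicographically). Reads not spanning
every het site are keyed on the sites they span and assigned only when
consistent with exactly one state.

A read is chimeric iff, over the sites where the two states differ, it
matches state 1 at ≥ 1 site and state 2 at ≥ 1 other — the signature of a
single PCR template switch between the two true templates. Chimeras are
removed and counted; bins without ≥ 2 differing sites cannot yield chimeras,
and homozygous calls are never modified.

Allele sequences are then re-derived per read class: column-wise plurality
consensus restricted to the class (count first, summed quality on ties, then
a fixed symbol order), with het-site columns pinned to the class's key
symbols. Unassigned reads whose key is strictly closer to one state are
included in that class's *consensus* (a lone miscalled site should not cost
a read's evidence everywhere else) but never in its support count.
Homopolymer regions are re-arbitrated within the class only when the class
has its own ≥ 75 % length majority; otherwise the full-depth arbitration is
inherited — a phased subclass of seven reads should not re-litigate a run
length that forty reads already decided, unless the length is genuinely
allele-specific.

Exactly two alleles are ever emitted (diploidy is assumed); third-ranked
haplotypes are reported in a QC side channel. If fewer than two distinct
complete keys exist the call falls back to homozygous with a warning.

## Population curation

Per locus and population, both allele copies of every called individual are
pooled. A *singleton* (population count exactly 1) that differs from an
established allele (count ≥ 2) by exactly one one-base indel inside a
homopolymer run (run length ≥ 2 in the longer sequence; a lone-base
insertion beside a different base is not eligible) is rewritten to match.
Eligibility is judged against the pre-correction table and singletons are
processed in lexicographic order, so the result is independent of input
order; among multiple partners the highest count wins, then lexicographic.
Corrections are applied before heterozygote and unique-allele counting.
Total allele copies are conserved and the unique-allele count can only
shrink.

## Summary statistics

Coverage fractions (≥ 1×, ≥ 5×) are computed over every *attempted* bin —
a bin that yielded no reads counts as 0× — and the mean het allelic ratio is
the mean of per-bin support1/support2 over heterozygous calls. The
majority-consensus confidence for k clonal reads with per-read correctness p
is the binomial tail Σ_{i>k/2} C(k,i) p^i (1−p)^{k−i} (scipy's survival
function; an independent closed-form sum next to the caller cross-checks it
to 1e−12 in the tests).

## The simulator

`sim454` generates the design the pipeline assumes, with per-read truth.
Defaults are the study conditions of the multiplexed sea-star design the
package models; each is a config field.

* **Design**: 1 region per run (regions are separate files), 2 species × 20
  individuals × 5 loci, every individual in a region getting a distinct
  10-bp barcode (pairwise Hamming ≥ 3). The default primer panel is the
  ten species-specific EPIC pairs of the two sea-star species, including
  their genuinely degenerate positions; larger configurations fall back to
  random primers.
* **Genotypes**: per species × locus, an ancestral intron (random sequence
  with a few seeded 4–7-bp homopolymer runs, amplicon length uniform in
  400–600 bp) is mutated into a pool of 6 alleles by substitutions only;
  one common allele's frequency is solved so expected heterozygosity
  1 − Σp² equals the species' target. Defaults (0.5, 0.05) mirror the
  contrast between a high-diversity and a near-monomorphic species.
  Substitution-only allelic divergence is deliberate: the caller (like the
  workflow it implements) collapses allelic homopolymer-length
  polymorphism, so planting such alleles would measure the documented
  limitation, not the caller.
* **Coverage**: negative binomial, mean 70.7, dispersion 8 — heavy
  between-bin variance as observed in real multiplexed runs.
* **Substitution error**: 1 % mean per base, stratified by read: 10 % of
  reads are junk (6 % per-base error; they largely die at the mean-quality,
  barcode and primer rules, as junk reads do in real libraries) and the
  rest carry the residual ≈ 0.44 %. Qualities are drawn per base (good
  Q30–40, bad Q2–10) and each base substitutes with probability
  10^(−Q/10), so the emitted quality string is consistent with the injected
  error process and the mean-quality filter stays meaningful. An i.i.d.
  per-base model at the same 1 % rate would discard half the library at the
  exact-match rules — inconsistent with the ~70 % usable fraction such runs
  actually achieve — which is why the error mass is read-stratified.
* **Homopolymer errors**: each run of length L ≥ 2 gains or loses one base
  with probability min(0.5, 0.02·(L−1)); the miscalled run's bases are
  emitted at Q10–20, reflecting the ambiguous flow signal — the quality
  criterion of the arbitration rule depends on exactly this signal.
* **Chimeras**: in heterozygous bins, 12.5 % of reads are replaced by
  single-crossover recombinants of the two true alleles (uniform crossover
  point, random direction); allele choice for ordinary reads is skewed
  13:9. Truth rows flag every chimera, including the undetectable ones
  whose crossover falls outside the differing sites.
* **Contamination**: 5 % of reads are truncated to 30–149 bp with junk
  quality, emulating incompletely purified short products;
  `degrade_library` applies the same transformation at any rate to model a
  badly contaminated region.

Identical config + seed reproduces every output byte for byte.

**What passing on simulated data does not show.** The generator does not
model flowgram chemistry, emPCR duplicates, position-dependent quality
decay, non-specific priming (mispriming to a second genomic site),
cross-region contamination, or allelic indel variation. Real libraries can
fail in those ways; the tests certify the rules as specified, under the
statistical structure above.

## Numerical and determinism choices

All randomness flows from one integer seed through numpy Generators.
Deterministic tie-breaks throughout: haplotype-support ties to the
lexicographically smaller allele; homopolymer quality ties to the shorter
run; consensus ties by summed quality then a fixed symbol order; seed
choice and ledger order as stated above. Alignment scores are fixed
defaults, overridable for experimentation.

Problem sizes in the shipped tests and in `scripts/acceptance.py` are the
package's own choices: the end-to-end recovery measurement uses three
simulated regions (600 individual-locus bins, one seed), large enough to
estimate a ≥ 99 % exact-recovery rate against ~1 % binomial noise; unit
tests use 2–20 individuals. The residual end-to-end failures are intrinsic
to the 75 % rule at these conditions: heterozygous bins whose minor-allele
column fraction drifts below 25 % (most often genotypes differing at a
single site, or bins in the deep low-coverage tail).

## Known limitations

* Diploid only; no genotype likelihoods or base-quality recalibration.
* Reference-free by design; no mapping, no cross-locus contamination check.
* Allelic homopolymer-length polymorphism is systematically collapsed.
* CLI stage chaining writes bin FASTQs whose clip metadata travels in the
  record description; third-party FASTQs without it are treated as
  untrimmed (fully end-informative), which is correct for raw amplicon
  reads but optimistic for pre-trimmed input.
* The cost model is unit-agnostic arithmetic; no labor-time modelling
  beyond the printed constants, no vendor lookups.
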