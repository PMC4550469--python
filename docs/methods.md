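# Methods

## The problem

A honey sample is a mixture of plant material from the species a colony
foraged on. Melissopalynology estimates that mixture by classifying
~300 pollen grains per sample under a microscope; DNA metabarcoding
estimates it by amplifying the *rbcL* plant barcode from honey DNA with
sample-tagged fusion primers and sequencing thousands of amplicons.
`apiflora` implements the bioinformatic half of the DNA route and the
statistics for comparing both routes, and ships a generator that
produces complete synthetic studies with known ground truth.

## Read processing model

A raw read is modelled as `[5-bp tag][forward primer][insert][rc(reverse
primer)]`, possibly reverse-complemented as a whole and possibly
truncated at the 3′ end. Demultiplexing accepts a read only when its tag
— anchored within the first 3 positions to allow slight 5′ slop — is
followed immediately by the *complete* forward primer, with at most
`max_mismatch` substitutions over the combined tag+primer region
(default 0: strict matching). Reads failing forward detection are
rescanned reverse-complemented (`scan_reverse`, on by default), which
also orientation-normalises every kept read. A read matching two
samples' tags (possible only at `max_mismatch > 0`) is ambiguous and
rejected. After trimming the tag+primer and any trailing
reverse-complemented reverse primer, inserts of `min_len = 250` bp or
less are discarded. Quality is summarised (per-read mean QV, % of reads
with mean QV > 20) but never used to filter; only tag/primer presence
and length remove reads. Read counts are conserved: every input read is
kept in exactly one sample or tallied under exactly one rejection
reason, and the run log records every tally.

## Alignment and bit scores

The built-in engine is an exact Smith–Waterman local aligner with affine
gaps (numba-compiled), scoring match +1, mismatch −2, and a gap of
length *k* as −5 − 2*k* (NCBI-style existence + extension). Raw scores
are converted to bit scores with the Karlin–Altschul transform
`(λS − ln K)/ln 2`, λ = 0.625, K = 0.41. Every downstream decision uses
bit-score *ranks* only, so these constants are reporting conveniences —
rescaling them provably leaves assignments unchanged (tested). Both
strands are scored by default in the standalone `search` API; the
pipeline passes `strand="forward"` because demultiplexing has already
orientation-normalised the kept reads, halving alignment cost with
identical results. No word-seeding heuristic, E-value model or
identity/coverage floor is applied by default (a minimum-identity floor
exists but is off); hit tables from a real BLAST run can be imported via
the 12-column tabular dialect, making the consensus layer
engine-agnostic. Emitted hit tables contain fully traceback-computed
identity/coordinate columns for the top-scoring hits the pipeline keeps.

## Consensus assignment, groundtruthing, abundance floor

For each read, all hits within `tie_tol` (default 0 = exact equality) of
the top bit score form the tie set. Agreement is evaluated at the finest
rank shared by *all* tie-set taxa: one species → species; several
species, one genus → genus; several genera, one family → family; several
families → unknown. A genus-level reference tied with one of its own
species therefore yields genus — the conservative reading. Species-level
calls whose species is absent from the geographic checklist are demoted
to the genus of the binomial; genus- and family-rank calls are never
checklist-screened, and every demotion is logged. Taxa with fewer than
`min_reads = 10` reads per sample are then removed. By default the
threshold applies *after* checklist demotion (`filter_order =
"checklist_first"`), so demoted reads pool into their genus before
thresholding; the alternative order is a flag, since either reading of
the procedure is defensible.

## Comparison statistics

DNA and microscopy taxon lists are mixed-rank, so they are harmonised
before any overlap statistic: two taxa match when identical at the
coarser of their two ranks (species–species by name; species–genus by
the genus token; genus/species–family via the reference taxonomy). A
greedy matching over candidate pairs ordered by agreement fineness
yields a maximal matching preferring species-level pairings; each taxon
matches at most once. On top of this:

- **Overlap breakdown**: both / DNA-only / microscopy-only, the latter
  subdivided into multi-grain and single-grain support;
  `similarity = 100·both/total`, rounded half-up.
- **Replicate similarity**: `100·|shared|/|union|`, integer-rounded.
- **Resolution profile**: % of a list's taxa at family/genus/species.
- **Pooled t test** (scipy, `equal_var=True`) on resolution
  percentages; df = n₁+n₂−2.
- **Spearman correlations** of per-taxon relative abundances, built
  over the union of taxa detected by either method with zeros for the
  absent method, excluding microscopy single-grain-only taxa (both are
  flags). Exact permutation p-values (all n! orders) for n ≤ 8, t
  approximation above; Bonferroni m defaults to the number of samples;
  significance is reported at 0.05.
- **Frequency table**: per-taxon presence counts across samples for
  each method, flagging taxa seen in ≥ 2 samples.

Percentages shown in integer form are rounded half-up, matching the
usual tabular presentation.

## Synthetic data generator

`simulate_reference` mutates a random root sequence independently down
family/genus/species branches; the scalar `branch_divergence` (default
0.10, valid (0, 0.2]) is scaled per level (family 1.0×, genus 0.4×,
species 0.15×) so within-genus identity reliably exceeds between-family
identity (a tested invariant). 20% of species are marked absent from the
checklist. References are one-per-species (regional library when
checklist-listed, global otherwise) plus two genus-level references and
one species deliberately present in both libraries with an identical
sequence.

The default honey mixture has 3 dominant taxa (≈31/26/22%) over a
12-taxon tail from ≈3.6% down to 0.03%; the two rarest taxa draw fewer
than 10 reads at the default depth of 5000 reads/sample, exercising
low-abundance dropout. Reads carry per-base substitutions (1%), single
insertions/deletions in homopolymer runs ≥ 3 (1% per run — the
characteristic pyrosequencing error), 3′ truncation (20% of reads, to no
shorter than 240 bp), a 5% tagless contaminant fraction, random strand,
and per-read quality targeting mean QV 28 (SD 2). The amplicon is 300 bp
— a compact stand-in for the several-hundred-bp *rbcL* barcode region,
chosen so full studies simulate and align quickly. Pollen counts are a
multinomial draw of 300 grains from the same mixture, reweighted by
per-species log-normal bias multipliers (σ = 0.9) and blurred to genus
rank for 35% of species, emulating differential pollen production and
microscopy's limited morphological resolution. This makes the two
methods agree on dominant components while disagreeing on relative
abundance and on the rare tail — the qualitative pattern the comparison
statistics are designed to detect, including the higher replicate
similarity of the DNA arm.

What the generator does *not* emulate: PCR amplification bias and
chimeras, flowgram-level pyrosequencing noise, nectar-vs-pollen DNA
content differences, taxonomic synonymy between reference sources, and
incomplete reference libraries (every mixture species has a reference).
Passing tests therefore demonstrate the correctness of the decision
rules and the pipeline's behaviour under a plausible error model — not
quantitative accuracy on real honey.

## Numerical and design choices

- The default study scale is 9 honeys plus one replicate of the first,
  5000 reads and 300 grains per sample.
- Determinism: all randomness flows from `numpy.random.default_rng`
  seeded explicitly; scenario-level child seeds are spawned via
  `SeedSequence`. Reruns are byte-identical (tested).
- Ties in harmonisation and sorting are broken by normalised name, so
  outputs are independent of input order.
- `percent` rejects numerators outside [0, denominator]; Spearman
  signals zero-variance rank vectors instead of returning NaN.
- Stage outputs are written atomically (temp file + rename) so a failed
  run never leaves a partial output in place of a good one.
- FASTA/FASTQ parsers are strict (duplicate ids, length mismatches and
  malformed records are located errors naming the line); FASTQ is
  phred+33 only, rejected loudly otherwise.
- Synonym/spelling reconciliation between reference names and checklist
  names is deliberately out of scope: names are matched case-insensitively
  after whitespace normalisation, nothing fuzzier.

## Known limitations

- The aligner is exhaustive (no seeding), sized for amplicon-vs-library
  problems, not genome-scale search.
- Relative read abundance is not a calibrated estimate of plant
  abundance; the package reports it but makes no quantitative claim.
- The exact permutation p-value assumes untied ranks; with ties it is
  an approximation (the t branch handles larger n).
- Genus- and family-level checklist screening is intentionally not
  performed; only species claims are groundtruthed.
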