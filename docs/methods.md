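# Methods

## Scope and model

`isomirseq` quantifies mature miRNAs from single-end small RNA-seq libraries
by aligning read tags directly to hairpin precursor sequences, in the style
of the classic two-library (case vs. control pooled) liver profiling
experiments on the Illumina GAIIx. The analysis chain is:

1. **Preprocessing.** Reads failing a mean base-quality threshold are
   removed; the 3' sequencing adapter is trimmed; inserts shorter than 15 nt
   are discarded; survivors are collapsed into unique tags with counts.
2. **isomiR matching.** A tag is accepted as an isomiR of an annotated
   mature miRNA when it has an ungapped placement on the hairpin with at
   most 1 mismatch and both of its termini fall within ±4 nt of the mature
   ends. Hits carry the 5p/3p arm of the hairpin.
3. **Quantification.** Tags seen fewer than twice in a library are dropped.
   Two abundance estimators per mature miRNA: the count of the single most
   abundant isomiR (*dominant*) and the sum over all isomiRs (*sum*). Both
   are normalised to reads per million (RPM) of the library's mapped total.
4. **Differential expression.** log2(RPM_case / RPM_control) per miRNA; a
   call of up/down when the log2 ratio strictly exceeds ±2 (configurable).
   No p-values: one pooled library per condition admits no
   replication-based test.
5. **Grouping.** Genomic clusters (single-linkage, gap ≤ 10 kb, same
   chromosome and strand) and seed families (identical mature positions
   2–8, or an explicit family map), scored by sign-concordance of member
   fold changes.
6. **Enrichment.** Hypergeometric over-representation of the differential
   miRNAs' validated target genes in GMT pathway sets, BH-adjusted.

## Key interpretation choices

- **"Mature region ± 4 nt" is enforced per terminus**: each end offset must
  lie in [−4, +4]. The alternative reading — anywhere inside a ±4-expanded
  window — would accept short fragments floating inside the window with
  neither end anchored, which is not what isomiR classification means in
  practice.
- **Matching is ungapped** (Hamming). Substitutions are counted; indels are
  not modelled, matching how isomiR acceptance is conventionally stated.
- **Multi-mapping tags** (identical paralogs): default policy `all`
  attributes the full count to every mature hit, so paralogs share counts
  and RPM column sums may exceed 10^6. `fractional` (count/k) and
  `unique-only` (discard) are selectable; under `unique-only` the sum-RPM
  column sums to exactly 10^6.
- **RPM denominator** = mapped reads of the library after the count<2
  filter, each tag counted once, identical for both estimators — so any
  dominant-vs-sum difference reflects the numerator only. Whether the
  historical pipelines computed the total before or after the low-count
  filter is not recoverable; "after" is the default and it is configurable
  in the quantify call.
- **Fold-change cutoff.** The default is |log2 FC| > 2 (strict), i.e. a
  4-fold change. The frequently used 2-fold reading is `fc_threshold: 1.0`
  in the config. Both classifications are one flag apart by design because
  the two conventions coexist in the literature.
- **Pseudocount.** 0.5 RPM is added to both sides only when a miRNA is
  detected in exactly one condition; when both RPMs are positive the plain
  ratio is used (so 400 vs. 100 RPM gives exactly 2.0). miRNAs undetected
  in both conditions are reported as `undetected`, never zero-filled.
- **Concordance** is the fraction of group members whose fold-change sign
  agrees with the majority sign; an even split scores 0.5. Members with
  undefined or exactly zero fold change cast no vote; fewer than two votes
  gives NaN. Sign, not magnitude, is the statistic: the biological claim
  being scored is that co-located/homologous miRNAs move in the same
  direction even when their fold changes differ.
- **Quality filter.** The exact vendor chastity filter of the GAIIx era is
  not reconstructable; the package uses a mean-Phred threshold (default
  Q20, configurable) as a declared, reproducible proxy.
- **Adapter trimming** is seed-and-extend prefix matching: the leftmost
  position where an adapter prefix of ≥ 6 nt matches the read suffix at a
  mismatch rate ≤ 0.1 is truncated. Reads with no detectable adapter are
  kept whole (the insert may span the full 36 cycles) and flagged.
- **Enrichment statistic.** The hypergeometric tail with a user-controlled
  background is a transparent generic replacement for legacy web-service
  annotators whose background, annotation version and statistic are
  unspecified; p-values from such services are therefore not comparable
  targets. Default background: all genes in the supplied target table.

## The synthetic-data generator

The generator emulates the study design the pipeline is built for: two
conditions, one pooled 36-cycle library each, miRNAs expressed over several
orders of magnitude, isomiR diversity from imprecise hairpin processing,
and adapter read-through on every insert shorter than the read length
(mirroring the 110–130 bp library size selection).

Default conditions (field → value → rationale):

| parameter | default | meaning |
|---|---|---|
| `n_precursors` | 50 | hairpins; ~70 matures with `p_two_mature=0.3` |
| `n_clusters` / `cluster_span` | 3 / 10 kb | genomic clusters of 2–3 hairpins |
| `n_families` / `family_size` | 2 / 3 | seed-sharing paralog groups |
| `mature_len_range` | 20–24 nt | canonical mature length spread |
| `read_len` | 36 | GAIIx-era cycle count |
| `adapter3` | `TCGTATGCCGTCTTCTGCTTG` | classic small-RNA 3' adapter |
| `error_rate` | 0.005/base | substitution-only sequencing error |
| `cleavage_offset_probs` | {0:.6, ±1:.15, ±2:.05} | independent 5'/3' Drosha/Dicer offsets |
| `lib_depth` | 100,000 | reads per library |
| `frac_de` / `effect_log2` | 0.2 / 3.0 | DE fraction and true effect size |
| `low_quality_frac` | 1% | whole-read Q2 records exercising the quality filter |
| `abundance_sigma` | 1.0 | lognormal spread of baseline expression |

Mechanics worth knowing:

- **Exact truth.** DE matures are split equally up/down and the up set's
  baseline abundances are rescaled by `2^-effect × Σdown/Σup`, which keeps
  the total abundance mass identical between conditions. After per-condition
  normalisation, non-DE miRNAs therefore have a true log2 fold change of
  exactly 0 and DE miRNAs of exactly ±`effect_log2` — no approximation.
- **Group-coherent mode** (`de_respect_groups=True`) assigns effects at the
  cluster/family level, emulating co-transcription and homology-driven
  co-regulation; by default effects are per-mature.
- Each read samples a mature by abundance, draws independent 5' and 3'
  offsets, excises the hairpin substring (out-of-bounds excisions are
  resampled and counted), applies per-base substitution errors, appends the
  adapter plus fixed post-adapter bases, and truncates to 36 nt. Qualities
  are Q40, or Q2 for the low-quality fraction.
- Everything is deterministic for a fixed seed, including file bytes; the
  per-condition stream seed is derived with CRC32 of the condition label so
  determinism survives process restarts.

What the generator does **not** emulate: indel errors, non-templated 3'
additions (e.g. uridylation), ligation/sequence bias, quality decay along
the read, PCR duplication structure, and the other small-RNA classes
(tRNA/rRNA fragments) present in real libraries. Passing tests on synthetic
data therefore demonstrate the correctness of the pipeline's rules and
estimators under its own generative model, not concordance with any real
library, where adapter chemistry and contaminating RNA classes dominate the
error budget. Note also that seed-rule families group *any* matures sharing
a 7-mer seed, so random seed collisions can create small incidental
families alongside the constructed ones — as they do in real annotations.

## Numerical and tie-break conventions

- Coordinates are 0-based half-open internally; GFF3 (1-based inclusive) is
  converted at the I/O boundary. Matching happens on the hairpin's given
  strand only.
- Dominant-isomiR ties are broken by canonical-ness (smallest
  |offset5|+|offset3|), then lexicographic sequence — deterministic.
- Within one precursor only a tag's best placement is kept (fewest
  mismatches, then smallest |offset5|+|offset3|, then 5'-most).
- The batch matcher (tags grouped by length against concatenated hairpins)
  is an optimisation; property tests pin it to the per-pair scan and to a
  brute-force Hamming oracle.
- Arm auto-assignment when annotations lack 5p/3p labels: mature midpoint
  before the hairpin midpoint → 5p, else 3p.
- Degenerate inputs: empty tag tables, zero mapped reads (error naming the
  library), pathways with no background overlap (skipped, logged), empty
  differential sets (reported, not an error) are all handled explicitly.

## Problem sizes used in the checks

The bundled checks run the full pipeline on generated data at the default
study conditions (50 hairpins, 2 × 100,000 reads, 0.5% error): direction of
every detectable DE miRNA (expected mapped reads ≥ 10 in both conditions —
the stated detection floor) must be recovered and the median |estimated −
true| log2 fold change stays well under 0.5. The noiseless closure uses
2 × 20,000 reads with `error_rate=0`, canonical cleavage only and
`low_quality_frac=0` (all three knobs are part of "noiseless": a
quality-failed read is lost before counting, so exact count recovery
requires all of them off); per-miRNA sum counts then equal the generator's
truth exactly for every miRNA passing the count<2 filter. The concordance
summary uses group-coherent effects with every group perturbed
(`frac_de=1.0`), matching the situation the statistic describes —
aberrantly expressed clusters and families. Oracle-equivalence checks run
the matcher against a brute-force Hamming scan on 1,000 random instances,
and the hypergeometric tail against exact binomial-coefficient enumeration
for backgrounds up to N=25.

## Limitations

- Fold-change-only classification: with unreplicated pooled libraries the
  up/down calls carry no error control; they are descriptive.
- The ±4/≤1-mismatch acceptance rule is implemented directly rather than
  through a general aligner, so behaviour outside that rule (gapped
  isomiRs, heavily edited reads) is out of scope by construction.
- RPM is the only normalisation; no TMM/median-of-ratios style
  between-library factors are computed.
- Real-data reproduction of any particular published dataset additionally
  requires that dataset's raw libraries and the matching annotation
  release; the package runs in that mode through the standard `run`
  entry point but ships no external data.
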