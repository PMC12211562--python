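# Methods

## Problem and model

`kiquant` quantifies the outcomes of CRISPR knock-in experiments from
long-read (HiFi/CCS) amplicon sequencing. Each sequenced molecule derives
from one genomic template at the target locus and is assigned to exactly
one repair-outcome class:

| class           | meaning |
|-----------------|---------|
| `unmodified`    | no tag, no indel at the target site |
| `indel_no_tag`  | no tag, but insertions/deletions at the target site (including kilobase-scale deletions) |
| `precise_tag`   | a single tag copy with seamless (indel-free) junctions |
| `tag_5p_indel`  | single tag, indels confined 5′ of the tag midpoint |
| `tag_3p_indel`  | single tag, indels confined 3′ of the tag midpoint |
| `tag_both_indel`| single tag, indels on both sides |
| `multiple_tags` | two or more tag copies |
| `unclassified`  | alignment identity below 70% |

The three headline rates are class counts over **all** counted
representative reads: indel rate = `indel_no_tag`/total; total knock-in
rate = all tag-bearing classes/total; precise knock-in rate =
`precise_tag`/total. With this denominator the three rates plus the
unmodified and unclassified fractions sum to one. The alternative
odds-style denominator ("class versus complement") was considered and
rejected: rates are plotted and interpreted as percentages of all
embryo-derived molecules.

Because the initial linear amplification tags every primed template with
an 8-bp UMI, PCR "jackpot" over-amplification is corrected by collapsing
each UMI group to a single representative read before counting. The
representative is the group's most frequent exact sequence (ties: longest,
then lexicographically smallest, then smallest read id). Consensus
polishing of UMI groups is deliberately **not** performed - the method
being modeled selects a representative read, and we stay faithful to it.

## Pipeline stages and parameters

1. **Orientation.** The forward universal adapter is located by edit
   distance in the head of the read and of its reverse complement; the
   better side wins, ties stay unflipped; a read is unorientable when
   neither side comes within 2 x `prefix_max_edits`.
2. **Abnormal-read filter.** Keep lengths in [1000, 5000] bp (inclusive);
   drop reads whose first `prefix_check_len` (30) bases are more than
   `prefix_max_edits` (6) edits from the closest expected
   barcode+adapter prefix. The "significant deviation" threshold of 6/30
   is our operationalization; it is configurable.
3. **Demultiplexing.** Minimal combined edit distance over barcode pairs,
   at most 1 edit per barcode, unique minimum required; everything else
   is `undetermined`.
4. **Trim + UMI.** Forward adapter located by best semi-global alignment
   in the first 100 bases (<=20% edits), the next 8 bases are the UMI;
   the reverse adapter is located near the read end; adapters, barcodes
   and UMI are removed. Already-trimmed reads are rejected, not
   re-trimmed.
5. **UMI grouping.** Exact grouping by default (`merge_distance=0`). With
   `merge_distance=1`, a directional rule merges a group into a
   Hamming-1 neighbour at least twice its size (largest neighbour wins,
   ties to the lexicographically smallest UMI, smallest groups processed
   first, union-find chaining). An optional minimum group size filter
   (default 1) is available.
6. **Tag detection.** Smith-Waterman (match +2, mismatch -4, gap open
   -6, gap extend -1) of the tag against each read, both strands,
   iterative best-hit masking; a hit needs identity >= 0.80 over aligned
   columns and >= 0.80 tag coverage. Hit count 0/1/>=2 gives
   no-tag/single-tag/multiple-tags. The coverage threshold admits tags
   whose end was chewed by a junction deletion (local alignment clips
   rather than bridges such gaps, leaving as little as ~83% of the tag
   aligned) while still excluding short spurious matches; an inverted
   copy counts as a tag (total-KI) but can never be precise.
7. **Reference alignment and indel calling.** Global affine
   alignment to the precise reference (tagged reads) or the unmodified
   reference (tag-less reads). End gaps carry the ordinary affine cost:
   free read end gaps would let a kilobase deletion near one amplicon
   end be absorbed as an unpenalized end gap plus a mismatched flank,
   erasing the large-deletion class;
   equal-length pairs whose edit-distance path is indel-free skip the
   affine DP (identical result, much faster). Contiguous gap runs become
   events; events are left-shift normalized through repeat context, so
   coordinates are independent of aligner tie-breaking. Alignment
   identity is computed over aligned columns - matches/(matches +
   mismatches) - rather than over the reference span, so a genuine 1 kb
   deletion (half the amplicon) does not demote an otherwise clean read
   to `unclassified`; the 70% gate then acts purely on base-level
   accuracy.
8. **Classification windows.** Single-tag reads are scored across
   [5′ junction − arm − 10 bp, 3′ junction + arm + 10 bp); no indel in
   the window means precise. The 5′/3′ split point is the tag midpoint
   (the published description says only "based on the coordinates of the
   indels"; the midpoint convention avoids double counting and gives
   both-sided reads their own label). Tag-less reads use a +/-60 bp
   window around the insertion point - both 50 bp arms plus margin.
   Substitutions never affect labels; residual CCS errors are expected.
9. **SNP/PAM-edit readout.** The read base aligned to the configured
   site is reported as ref/template/other/uncovered. By default it
   annotates and does not gate the precise class; `require_template_snp`
   flips this. Both behaviours exist because published practice is
   ambiguous on whether the donor's PAM edit was required for a precise
   call.
10. **Natural-indel filter.** An event is removed when a control-sample
    event of the same kind lies within +/-10 bp position and +/-2 bp
    size. Applied to multi-tag reads by default (matching the described
    workflow), to all classes by flag. The tolerances are our choice;
    the source method states the concept without thresholds.

## Synthetic data generator

The simulator emulates the library architecture: per molecule, `barcode +
universal adapter + UMI(8) + amplicon + rc(universal) + rc(barcode)`,
random sequencing orientation, duplication counts from a zero-truncated
geometric (mean 2; an optional designated mega-jackpot molecule supports
deduplication tests), and independent per-copy errors.

Outcome construction: small indels are geometric (deletions mean 6 bp,
insertions mean 4 bp, 65% deletions - a Cas9-like spectrum where most
lesions are under 10 bp and deletions predominate) placed at the cut
site; junction indels are 1-10 bp within +/-10 bp of a junction; large
deletions span 100-1,000 bp across the insertion point but always retain
both primer-binding ends, because templates that lose a primer site
cannot amplify - the simulator reproduces this blind spot of the assay on
purpose. "Semi-random" UMIs are implemented as fully random 8-mers
(worst case for collisions; the real pattern is not public) and
collisions are allowed by default.

The error model applies substitutions, insertions and deletions
independently per base with a constant FASTQ quality. The default
HiFi-like composition puts 98% of the total rate on substitutions and 1%
each on indels, reflecting that circular-consensus calling removes
nearly all random indel errors outside homopolymers. **Not modeled:**
homopolymer-context indel errors (the dominant real HiFi error mode),
chimeras, quality variation, and multi-locus pools. Passing tests
therefore demonstrate correctness of the classification logic under
substitution-dominated noise; on real data, residual homopolymer indel
errors near the junctions would deflate the precise class unless
filtered upstream, and accuracy claims here do not extend to that
failure mode.

## Numerical and design choices

- Coordinates are 0-based, half-open, forward strand, everywhere.
- Scoring defaults (+2/-4/-6/-1) and thresholds (identity 0.80, coverage
  0.90) are package decisions - the published workflow delegates to
  aligners without stating parameters - and are exposed in
  `AlignmentScoring`.
- Founder rate is `round(100 * precise / total)` with halves away from
  zero, consistent with every published worked example we test.
- Determinism: a single seeded generator drives the simulator; reports
  are written with sorted keys and stable ordering; identical seeds give
  byte-identical FASTQ and reports.
- Problem sizes in the validation suite: the end-to-end recovery test
  uses 5,000 molecules at 0.5% error with PCR duplication (about 10,000
  reads); the jackpot test uses 1,000 molecules with one molecule
  duplicated 100x; oracle-equivalence tests use 200 short reads /
  200 perturbation trials / 50-read UMI sets. The acceptance script
  simulates 2,000 molecules, a size at which the binomial standard error
  on a 15% class is about 0.8 percentage points.

## Known limitations

- Representative selection cannot denoise groups whose copies all differ
  (with mean duplication 2 and per-read errors, ties are common); the
  representative is then an arbitrary-but-deterministic errored copy.
- A sequencing error inside the UMI creates a spurious singleton group
  (about 4% of reads at 0.5% error); `merge_distance=1` reabsorbs most
  of them.
- Integrations at off-target loci, phasing of multiple lesions, and
  molecules that lost a primer site are out of scope.
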