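# Methods

This note documents the models and procedures implemented in `sedadna`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic data can and cannot demonstrate.

## Screening model

The pipeline treats a sequenced *fragment* (a merged read pair) as the
unit of evidence and applies, in order:

1. **Demultiplexing.** A read belongs to a library only if both its i7
   and i5 index sequences match that library's expected pair exactly.
   No mismatch tolerance is offered: with double indexing, tolerant
   matching re-admits index-hopped reads, which is precisely what the
   filter exists to exclude.
2. **Length filter.** Fragments shorter than `min_length = 35` bp are
   discarded; below that length, short-read placements on a mitogenome
   panel are not reliably unique. The default order is length filter →
   duplicate collapse; the reverse order is available via
   `dedup_before_length_filter` (the two orders give identical results
   for exact duplicates, since identical sequences have identical
   lengths, but the flag keeps the pipeline explicit about the choice).
3. **Duplicate collapse.** In `sequence` mode, identical sequences are
   collapsed to one record carrying the copy count, and only records
   with multiplicity ≥ `min_multiplicity = 2` survive. Requiring two
   sightings suppresses both spurious molecules and sequencing errors
   (an error would have to recur identically to survive). This filter
   presumes sequencing deep enough that true molecules are usually seen
   more than once; at shallow depth it discards real signal — see the
   note on the synthetic datasets below. In `coordinates` mode
   (used for alignment-based duplicate removal), one representative is
   kept per (reference, start, end, strand) with no multiplicity
   threshold; the representative carries the most frequent sequence for
   the key, ties broken lexicographically, so output is deterministic.
4. **Taxonomic binning.** Each fragment is compared to a mitogenome
   panel by semi-global edit distance (edlib), on both strands; hits are
   all references within `floor(0.1 × length)` edits and within one edit
   of the best. The fragment's assignment is the lowest common ancestor
   of its hit taxa. Assignments are retained at the family level, and a
   fragment counts as *identifiable* when its LCA is at or below family
   rank — this is also the denominator of the presence rule: a family is
   *present* given ≥ `min_family_fragments = 3` fragments and
   ≥ `min_family_pct = 1.0` percent of identifiable fragments.
5. **Re-alignment and MQ filter.** Fragments of each candidate family
   are re-aligned to one representative mitogenome of that family and
   filtered at mapping quality ≥ `min_mq = 25`. The built-in aligner
   assigns MQ 37 to unique best placements and MQ 0 when an equally good
   placement exists elsewhere or on the opposite strand. Among
   equal-cost alignments of one placement it prefers the longest
   reference span, i.e. substitutions over terminal indels: a damaged
   terminal base must remain an aligned mismatch, because representing
   it as an insertion would silently delete the damage signal that the
   authentication test measures.
6. **Authentication.** Let n₅ be the number of re-aligned fragments
   whose first read position pairs with a reference C (complemented for
   reverse-strand alignments) and k₅ the number showing T there; n₃/k₃
   likewise at the last position. Each end is tested with the exact
   one-tailed binomial tail P(X ≥ k), X ~ Bin(n, p₀), p₀ =
   `damage_null_rate = 0.10`, computed by direct summation of the mass
   function (no normal approximation; the upper tail includes k). The
   fragment set is *ancient* iff both p-values fall below
   `alpha = 0.05`. Only the two terminal positions enter the test; the
   rest of the 15-position profile window is descriptive. With no
   reference-C terminus at either end the verdict is `not_assessable`.
   α is configurable; 0.05 is the conventional level. Multi-library
   samples can be authenticated per library and on the merged fragment
   set (`merge_fragment_sets`), since per-library counts are often too
   small to reach significance individually.

The per-position substitution profile, the end-flank base composition
(the reference base at offsets −10…+10 around each terminus, complemented
for reverse-strand fragments — depurination appears as a purine excess at
offset −1) and the length histogram are computed as descriptive evidence
alongside the test.

## Placement model

Given a multiple sequence alignment of a family's mitogenomes with
genus-level group labels (from the organism token in the sequence name,
or an explicit mapping table), a column anchored to the reference
sequence is *informative* for a group when the group's modal base is:

* **strict mode** — carried by every valid (A/C/G/T) group member and
  absent from every valid non-member;
* **frequency mode** — carried by ≥ `group_fixed_fraction = 0.90` of
  valid members, with ≥ 90% of valid non-members differing (not
  necessarily sharing a single alternative base).

Gap/ambiguous rows leave both denominators; columns that are gaps in the
reference are skipped (a fragment aligned to the reference cannot overlap
them); and a column is only evaluated with ≥ 2 valid members and ≥ 2
valid non-members, so a single sequence can never constitute "fixation".
Both thresholds are boundary-inclusive.

Before any tally, terminal deamination is **masked**: within the first
and last `mask_terminal = 3` alignment positions, T on forward-strand and
A on reverse-strand alignments (reference-forward representation) are
flagged and become invisible to support tallies and consensus. Masking
removes the base from the evidence rather than substituting N into the
read record: a terminal T is not known to be wrong, merely
uninterpretable. Support is reported as matches/overlaps per group,
counted as (fragment, site) observations — a fragment spanning several
sites contributes several observations.

The partial consensus calls a base at a reference position iff
≥ `min_coverage = 2` unmasked fragments cover it and the modal base's
fraction is ≥ `majority_fraction = 2/3`, compared as exact rationals so
that 2 of 3 passes ("two-thirds" and "67%" disagree exactly at coverage
3; the rational 2/3 is used because 2-of-3 agreement is plainly the
intended behaviour). Modal ties, thin coverage or insufficient majority
yield N; the output sequence is N-padded to the reference length.

## Synthetic data

The generator emulates the statistical structure the screening keys on,
each feature with an explicit parameter:

| parameter | default | meaning |
|---|---|---|
| `length_shape`, `length_scale` | 21, 1.75 | gamma length model; truncated to [`min_len` = 35, `max_len` = 100] it has mean ≈ 42 bp, sd ≈ 5.9 |
| `d_max` | 0.4 | terminal C→T amplitude |
| `decay` | 0.3 | per-position exponential decay rate |
| `d_bg` | 0.01 | background C→T |
| `purine_break_weight` | 3 | odds of a purine immediately flanking a breakpoint |
| `seq_error` | 0.001 | uniform per-base sequencing error |
| `dup_mean` | 0.5 | mean extra PCR copies (1 + Poisson) |
| `contam_fraction` | 0.2 | undamaged modern contaminant reads |

A C at 0-based distance *i* from the nearer read end flips to T with
probability `d_bg + d_max·exp(−decay·i)`, at both ends in read
orientation (single-stranded library chemistry; `single_stranded=False`
switches to the double-stranded geometry, C→T at 5′ / G→A at 3′ only).
Terminal position 1 therefore has expected C→T frequency
`d_bg + d_max = 0.41` at the defaults — the closed form the calibration
tests check against. Breakpoint purine bias is implemented by rejection
sampling: a candidate placement is accepted with probability 1 when the
read-orientation flank base is a purine and 1/w otherwise, independently
at both flanks, so the expected purine fraction at offset −1 is
`wq/(wq + 1 − q)` for reference purine fraction q — an exactly testable
prediction. References are circular; wrapped fragments are emitted as two
split alignment records and flagged in the truth table (consensus tests
exclude them by default). Contaminant reads are drawn from a separate
reference with no deamination and a longer length model (same shape,
scale 3.0, max 150 bp — modern DNA is not size-selected by decay). The
per-read truth table (source, interval, strand, deaminated and error
positions, duplicate provenance) is the single source for all recovery
tests.

`fit_damage_decay` inverts the damage model: it fits
`f(i) = d_bg + d_max·exp(−λ·i)` to the pooled 5′+3′ per-position C→T
frequencies by weighted least squares (weights = position denominators,
bounded scipy `curve_fit`), returning the estimates and residual sum of
squares.

The bundled demo datasets (`sedadna.datasets`) pair a damaged deer-like
component with an undamaged bovid-like contaminant over
simulator-generated stand-in mitogenomes. The screening dataset sets
`dup_mean = 2.0` (against the generator default of 0.5) because the
seen-at-least-twice duplicate filter is designed for deeply sequenced
capture libraries where most genuine molecules are observed repeatedly;
at `dup_mean = 0.5` the filter would discard ~60% of true molecules and
the demo would test sequencing depth rather than the screening logic.

**What passing tests do not show.** The simulator draws fragments
uniformly from a uniform-composition random reference; real mitogenomes
have skewed composition, repeats and conserved regions, and real capture
data has enrichment bias, quality-dependent errors and index hopping —
none of which are modelled. Agreement on synthetic data validates the
*logic* of the filters and tests, not their field performance on real
sediment libraries.

## Numerical and testing choices

* The binomial tail is summed directly with exact integer binomial
  coefficients (`math.comb`) and float powers; tests require agreement
  with an independent log-space (logsumexp) oracle to 1e-12 relative
  error for all n ≤ 30 and cross-check against
  `scipy.stats.binomtest(..., alternative="greater")`.
* Internal coordinates are 0-based half-open everywhere; SAM's 1-based
  inclusive coordinates are converted at the pysam boundary. Reverse-
  strand alignments store read bases reference-forward (SAM convention);
  read-orientation views are computed on demand, so there is a single
  canonical representation.
* Non-ACGT bases are carried through but never count as match or
  mismatch in any tally (profile, support, consensus) — the conservative
  reading when base identity is unknown.
* Power/error-rate simulation tests size their read sets analytically
  before running: the exact joint power of the two-ended binomial test
  at ~20 reference-C termini per end is only ≈ 0.91 at a true terminal
  rate of 0.4, so the power study uses ~70 termini per end, where the
  exact power exceeds 0.999 and a 1000-replicate Monte Carlo bound of
  0.99 is meaningful.
* The acceptance script and every test derive all randomness from
  explicit seeds; reports are written with fixed float formatting so
  reruns are byte-identical.

## Known limitations

* The built-in panel matcher and re-aligner are desk-scale: linear scans
  with edlib, suitable for a handful of mitogenomes, not a RefSeq-scale
  database; hit tables from an external search tool can be ingested
  instead (`hit_tables` in the run config).
* The LCA is unweighted (every hit counts equally); weighted or
  bit-score-aware variants are out of scope.
* Damage is modelled and fitted as a single exponential plus background;
  UDG-treated libraries and position-dependent error profiles are not
  modelled.
* Flank composition uses genomic arithmetic around fragment termini and
  is exact for gapless alignments; with indels the inside-fragment
  offsets are approximate.
* Informative-site discovery assumes the MSA is correct; alignment error
  masquerades as informativeness.
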