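# Methods

## Coordinate model

All positions are 0-based half-open on a fixed `GenomeLayout` (BED
convention); GTF input (1-based closed) is converted on read. Strand is
stored but ignored by every statistic — none of the spatial questions asked
here condition on orientation. Overlapping records of one feature kind
(transcript isoforms, per-exon CDS lines) are merged before testing so
overlap statistics never count a base twice; multi-line features are treated
as their per-line intervals and merged, not stitched into gapped models,
because all three statistics are base-wise. Interval sets are per-chromosome
sorted integer arrays; merge is a cumulative-max sweep, and coverage /
nearest-gap queries are binary searches, which keeps a full permutation run
vectorized.

## Spatial tests

Query set Q (a TE stratum) is tested against reference set R (a genic
feature). Chromosomes carrying no reference are dropped from the query set
first, so results are always conditional on chromosomes that have both
annotations.

* Jaccard: intersection over union of covered bases (both sets merged).
* Absolute distance: the mean of per-query nearest gaps in bp. A mean (rather
  than an ECDF functional) is the simplest summary that is monotone in the
  same direction; it is trivially auditable against the per-query values.
* Relative distance: per-query scaled midpoint offsets in [0, 0.5]. Queries
  outside the outermost reference midpoints are skipped — chromosomes are not
  treated as circular. Chromosomes with fewer than two reference midpoints
  contribute no values; if no chromosome qualifies the statistic is
  undefined and raises.

### Permutation null

Each query interval is independently repositioned uniformly on its own
chromosome (start uniform on [0, chrom_length − length]), preserving the
multiset of lengths and per-chromosome counts; permuted queries may overlap
each other. This is the simplest exchangeable null for "same insertions,
random positions". The reference set stays fixed. All requested statistics
are evaluated on the *same* permuted sets, so a three-test cell costs one
permutation stream. Per-permutation RNG streams are spawned from a single
root seed (`numpy` `SeedSequence`), making results bit-reproducible and
independent of evaluation order.

### p-values and direction

With n permutations, each one-sided tail is p = (r + 1)/(n + 1), r counting
null values at least as extreme as the observed; the reported p-value is the
two-sided min(1, 2·min(p_low, p_high)). Reporting the raw smaller tail
instead would double the type-I error (≈ 10% at a nominal 5% with n = 100),
which the calibration suite would flag; the doubled form keeps the null
rejection rate at ≈ 4% (slightly conservative from discreteness). Direction
(attraction vs repulsion) comes from which tail is the more extreme, with the
sign convention per statistic (larger Jaccard ⇒ attraction; smaller distance
statistics ⇒ attraction). Significance for the matrix coloring is α = 0.05
uncorrected; the matrix records how many tests were run so a reader can apply
their own multiplicity judgement.

### Correlation matrix

Strata with fewer than `min_group_size` insertions (default 10,000, a
full-genome scale) are marked `not_tested`; desk-scale analyses
lower it explicitly (the bundled synthetic runs use 1,000). Each matrix cell
derives its permutation seed from the root seed and the cell's position, so
cells are reproducible in isolation.

## TE pipeline

RepeatMasker `.out` rows are parsed (3 banner lines skipped, 1-based
inclusive query coordinates converted), classified by the class/family
prefix into LINE / SINE / LTR / DNA / RC, with any Helitron-flavoured string
mapped to RC and everything else (simple repeats, satellites, small RNAs,
unknowns) to OTHER. Filters, in order: length < 100 bp dropped; OTHER
dropped; RC dropped when the species config says the lineage has no credible
RC activity. Divergence is taken from the `%div` column as printed (raw
mismatch, not Kimura-corrected — the `.align`-based alternative can be
supplied by editing the column upstream).

Age: `age_my = (percent_divergence / 100) / rate_per_site_per_my`. Rates are
required, per-species config inputs; the default 2.5e-3 substitutions/site/My
is a placeholder for synthetic work and carries no biological claim. Whether
a factor of two (diploidy / branch counting) belongs in the rate is absorbed
into the rate value itself. Bins: young < 25 My, old > 40 My, intermediate
in between (boundaries inclusive on the intermediate side).

Size split: LINE and LTR insertions are split at 500 bp (large > 500);
"within transcript" means ≥ 1 bp overlap with the merged transcript set — no
overlap-fraction rule, since none is standard. The chi-square uses the
closed-form Yates-corrected statistic
N·(max(0, |ad − bc| − N/2))² / ((a+b)(c+d)(a+c)(b+d)) with 1 df; the test
suite pins it to an independent implementation (scipy's
`chi2_contingency(correction=True)`) to 1e-9 on 1,000 random tables.

## CpG-island detection

The detector is a deterministic sliding-window caller (window 200 bp, step
1 bp): a window passes if GC ≥ 0.50 and observed/expected CpG ≥ 0.60
(obs/exp = n_CpG·window/(n_C·n_G)); windows containing N are excluded.
Islands are maximal runs of passing windows — two passing windows belong to
one run while they still overlap — reported as the span of the passing
windows' **midpoints** and then filtered to ≥ 200 bp. The midpoint-span
convention is a deliberate choice over the union of passing windows: a
window can pass while most of it hangs outside a GC-rich block, so union
boundaries overshoot each true edge by ≈ (1 − f*)·window bases (f* being the
in-island fraction needed to pass, ≈ 0.44 at these defaults, i.e. ≈ 110 bp
per side), while the midpoint span's bias is ≈ (f* − ½)·window ≈ 10 bp. It
also suppresses isolated passing windows in background sequence, whose spans
fall under the length floor. Hidden-Markov-model callers used on real
genomes resolve boundaries differently; for real analyses a precomputed CGI
BED can be supplied and is used verbatim. Quantitative island counts from
the sliding-window detector are not claimed to match any HMM annotation.

## Synthetic genomes

The generator emulates the pipeline's inputs with planted truth:

* **Genes**: n non-overlapping genes placed uniformly per chromosome (exact
  uniform placement via sorted anchors plus cumulative offsets), each a
  single-exon transcript with an interior-60% CDS and a 3-bp strand-aware
  start codon. Deliberately minimal: the statistics are base-wise and never
  inspect splicing.
* **Sequence**: background bases i.i.d. at GC 0.38 (CpG obs/exp ≈ 1, so the
  GC criterion is the binding one and background false calls are rare); a
  CG-dinucleotide-enriched block (aggregate GC 0.65, emitted as a mixture of
  literal "CG" dinucleotides and single bases) of 1 kb centred on each gene's
  TSS, recorded in a truth BED.
* **TEs**: per-(class, age-bin) counts follow the census × age mix with
  deterministic largest-remainder rounding, so planted counts are exact.
  Lengths: SINE/DNA/RC uniform 80–400 bp; LINE/LTR a 90/10 mixture of
  100–1,000 bp truncated copies and 4,000–8,000 bp full-length elements.
  Placement: `independent` (uniform), `attracted` (with probability 0.8 the
  midpoint falls uniformly inside transcript ± 1 kb windows), or `repelled`
  (midpoints uniform on the window complement). The attraction defaults give
  near-saturating power at 10,000 insertions per stratum. Divergence is the
  bin-midpoint age (12.5 / 32.5 / 55 My — the old bin has no upper edge; 55
  is the generator's documented choice) times the rate, ×100, plus Gaussian
  noise (sd 0.5 divergence points) on the divergence scale, since that is
  the scale annotation tools report; the `.out` writer prints one decimal,
  matching the native format. With the default noise the nearest bin
  boundary lies > 6 sd away, so planted bins survive the round trip; with
  noise 0 recovery is exact and the validation suite asserts exactness.

What the synthetic model does **not** emulate: real TE sequence content (the
FASTA carries no TE sequence), target-site duplications, fragmentation and
defragmentation of old elements, nested insertions, isochore/GC structure,
or phylogenetic correlation across species. Passing tests therefore
demonstrate correctness of the statistics and pipeline logic under known
structure, not biological fidelity of any particular genome.

## Validation experiments (what the acceptance script recomputes)

Problem sizes are the package's study conditions: 2 × 5 Mb genomes, 200
genes, 10,000 query TEs, 100 permutations; 200 replicate datasets for null
calibration and 100 per planted direction.

* Interval algebra vs a per-base boolean bitmap on 100 random ≤ 50 kb
  genomes — exact agreement required.
* Null calibration: rejection rate of each test at α = 0.05 on independent
  placements, checked against the exact binomial 95% interval around 0.05.
* Relative-distance law: values in [0, 0.5], pooled mean within 3 SE of
  0.25, KS test against Uniform(0, 0.5) passing in ≥ 90% of datasets.
* Planted-signal recovery: Jaccard direction calls on attracted / repelled
  genomes; ≥ 95% sensitivity, zero inversions tolerated.
* Pipeline exactness: noise-free planted census (all five classes + OTHER,
  RC-excluding config) recovered exactly, including per-rule drop counts.
* Yates chi-square vs independent implementation: ≤ 1e-9 on 1,000 tables.
* CGI recovery: planted 1-kb islands in 100 kb recovered at Jaccard ≥ 0.9;
  < 1 false island per 100 kb on island-free background.
* Determinism: a compact end-to-end run (simulate → pipeline → matrix →
  chi-square) repeated with the same seed produces byte-identical TSVs.

## Numerical and degenerate-input policy

Jaccard on two empty sets, absolute distance with no shared chromosome,
relative distance with no two-reference chromosome, chi-square with a zero
marginal, and repositioning an interval longer than its chromosome all raise
`ValueError` rather than returning sentinels. Relative-distance ties between
duplicate reference midpoints score 0. Floating-point output in TSVs is
formatted at fixed precision so determinism checks are byte-level.

## Known limitations

* The permutation null randomizes queries only, not references, and allows
  permuted queries to overlap; nulls that preserve query spacing or mask
  assembly gaps would be stricter on real genomes.
* The absolute-distance summary (a mean) has different power than
  ECDF-functional variants, though the same direction on strong signals.
* No multiple-testing correction is applied to the matrix; only the test
  count is logged.
* The sliding-window CGI caller is not an HMM and its island counts are not
  comparable to HMM-based annotations.
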