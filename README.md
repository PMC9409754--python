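# tespatial

Spatial correlation between transposable elements (TEs) and genic features.

Mammalian genomes accumulate TE insertions non-randomly: insertion machinery
prefers accessible chromatin around genes, while purifying selection removes
insertions that disrupt coding sequence. The balance of those two pressures
differs by TE class (LINE, SINE, LTR, DNA, RC), by insertion age, and by
element size. `tespatial` is an analysis toolkit for quantifying that
balance: it stratifies a RepeatMasker-style TE annotation by class, age and
length, assembles genic feature sets (transcript, CDS, start codon, CpG
island), and tests every stratum against every feature with three interval
statistics under a permutation null, classifying each pair as **attraction**,
**repulsion** or not significant.

## The statistics

For a query set *Q* (one TE stratum) and reference set *R* (one genic
feature), both as merged genomic intervals:

* **Jaccard** — J(Q,R) = |Q ∩ R| / |Q ∪ R| in covered bases. Larger than
  expected ⇒ attraction (overlap enrichment).
* **Absolute distance** — mean over queries of the gap (bp) to the nearest
  reference interval on the same chromosome. Smaller ⇒ attraction.
* **Relative distance** — each query midpoint *m* between flanking reference
  midpoints r_k ≤ m ≤ r_{k+1} scores
  d = min(m − r_k, r_{k+1} − m) / (r_{k+1} − r_k) ∈ [0, 0.5];
  under independence d is Uniform(0, 0.5) with mean 0.25. A smaller mean ⇒
  attraction.

Significance: each query interval is repositioned uniformly at random on its
own chromosome (lengths and per-chromosome counts preserved; 100 permutations
by default). With one-sided tail probabilities p_tail = (r + 1)/(n + 1), the
reported p-value is the two-sided min(1, 2·min(p_low, p_high)); the direction
call comes from the more extreme tail, at α = 0.05 uncorrected.

The TE pipeline dates each insertion from its percent divergence *d* against
the family consensus, age = (d/100)/μ with μ the species neutral rate
(substitutions/site/My), and bins insertions as young (< 25 My),
intermediate (25–40 My) or old (> 40 My). A size-split analysis
cross-tabulates large (> 500 bp) vs small LINE/LTR insertions against
transcript overlap and applies a chi-square test with Yates' continuity
correction.

Because real TE landscapes have no ground truth, the package ships a
synthetic-genome generator that plants known structure — gene models, GC-rich
CpG-island blocks, and TE placements that are independent of, attracted to,
or repelled from gene-proximal windows — so every statistic can be validated
against truth tables.

## Worked example

Plant attraction (80% of 10,000 SINEs placed within 1 kb of a gene) and test
it against the transcripts:

```python
from tespatial import (PermutationConfig, SimulationConfig, run_spatial_tests,
                       read_gtf_features, simulate_layout_and_genes,
                       simulate_te_table, te_table_to_interval_set, write_gtf)

cfg = SimulationConfig(seed=7, placement_model="attracted",
                       n_te_per_class={"SINE": 10_000})
layout, genes = simulate_layout_and_genes(cfg)
write_gtf(genes, "genes.gtf")
transcripts = read_gtf_features("genes.gtf", layout, "transcript")

tes = te_table_to_interval_set(simulate_te_table(cfg, layout, genes), layout)
results = run_spatial_tests(tes, transcripts, PermutationConfig(n_permutations=100, seed=1))
for name, r in results.items():
    print(f"{name:18s} observed={r.observed:10.4f}  null_mean={r.null_mean:10.4f}  "
          f"p={r.p_value:.4f}  {r.direction}")
```

prints

```
jaccard            observed=    0.4385  null_mean=    0.1153  p=0.0198  attraction
absolute_distance  observed= 3285.7638  null_mean=15705.8713  p=0.0198  attraction
relative_distance  observed=    0.1309  null_mean=    0.2498  p=0.0198  attraction
```

Observed overlap (Jaccard 0.44) far exceeds the permutation null (0.12), the
mean gap to the nearest transcript is a fifth of the null's, and the relative
distance mean sits well below 0.25 — all three tests call the planted
attraction, at the smallest p-value 100 permutations can produce
(2/101 ≈ 0.0198).

## Analysis pipeline

The numbered scripts under `analysis/` run the full workflow on three
synthetic species (TEs attracted to / independent of / repelled from genes;
10 Mb genomes, 200 genes, 33,000 TEs across five classes), writing tables
under `results/`:

1. `01_simulate_genomes.py` — genomes, genes, sequence, TE annotation (raw
   files under `scratch/`).
2. `02_te_landscape.py` — composition by class × age bin; size spectra.
3. `03_genic_features.py` — feature assembly and CpG-island detection.
4. `04_spatial_correlation.py` — the full correlation matrix with heatmaps.
5. `05_size_split_chisq.py` — the large/small LINE+LTR chi-square.

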