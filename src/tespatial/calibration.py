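"""Validation experiments for the spatial-test machinery.

These routines generate synthetic datasets with known ground truth and
measure how the pipeline behaves on them: type-I error of the permutation
tests under independent placement, the distributional law of the relative
distance statistic, sensitivity to planted attraction/repulsion, exact
recovery of planted TE composition, agreement of the Yates chi-square with an
external implementation, CpG-island recovery, and byte-level determinism of
the tabular outputs. Both the test suite and the acceptance script call them.

Problem sizes default to the study conditions: 10 Mb genomes (2 x 5 Mb),
200 genes, 10,000 query TEs per dataset, 100 permutations.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genic import CgiParams, detect_cgi
from .intervals import GenomeLayout, IntervalSet, intersection_length, union_length
from .simulate import (
    SimulationConfig,
    simulate_layout_and_genes,
    simulate_sequence,
    simulate_te_annotation,
    simulate_te_table,
    te_table_to_interval_set,
    write_gtf,
)
from .spatial import PermutationConfig, run_spatial_tests, TEST_NAMES
from .te import (
    SpeciesConfig,
    add_ages,
    bin_by_age,
    chi_square_yates,
    ContingencyTable2x2,
    filter_records,
    parse_repeatmasker_out,
)

__all__ = [
    "null_calibration",
    "planted_direction_sensitivity",
    "pipeline_exactness",
    "chisq_oracle_comparison",
    "cgi_recovery",
    "determinism_check",
    "bitmap_oracle_comparison",
]


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def _base_config(seed: int, n_te: int, n_genes: int, model: str) -> SimulationConfig:
    return SimulationConfig(
        seed=seed, n_chroms=2, chrom_length_bp=5_000_000,
        n_genes=n_genes, gene_length_bp=10_000,
        n_te_per_class={"SINE": n_te}, placement_model=model,
    )


def _transcript_set(layout: GenomeLayout, genes: pd.DataFrame) -> IntervalSet:
    arrays = {
        chrom: (g["start"].to_numpy(np.int64), g["end"].to_numpy(np.int64))
        for chrom, g in genes.groupby("chrom", sort=False)
    }
    return IntervalSet.from_arrays(layout, arrays, validate=False).merge()


def _one_dataset(seed: int, n_te: int, n_genes: int, model: str):
    cfg = _base_config(seed, n_te, n_genes, model)
    layout, genes = simulate_layout_and_genes(cfg)
    table = simulate_te_table(cfg, layout, genes)
    queries = te_table_to_interval_set(table, layout)
    return queries, _transcript_set(layout, genes)


# -- null calibration and the relative-distance law -------------------------


@dataclass
class NullCalibrationResult:
    n_datasets: int
    alpha: float
    rejections: dict[str, int]
    rel_values_min: float
    rel_values_max: float
    rel_mean: float
    rel_se: float
    ks_pass: int

    @property
    def rejection_rates(self) -> dict[str, float]:
        return {t: k / self.n_datasets for t, k in self.rejections.items()}


def null_calibration(
    n_datasets: int = 200,
    seed: int = 0,
    n_te: int = 10_000,
    n_genes: int = 200,
    n_permutations: int = 100,
    alpha: float = 0.05,
) -> NullCalibrationResult:
    """Type-I error of the three tests on independently placed TEs.

    Each dataset redraws the gene layout and the TE positions from child
    seeds; every test runs with ``n_permutations`` shared permutations. Also
    collects the observed relative-distance values per dataset: their range,
    the pooled mean with its standard error, and how many datasets pass a KS
    test against Uniform(0, 0.5) at the 5% level.
    """
    from .spatial import relative_distance_values

    root = np.random.SeedSequence(seed)
    children = root.spawn(n_datasets)
    rejections = {t: 0 for t in TEST_NAMES}
    vmin, vmax = np.inf, -np.inf
    means, ns = [], []
    ks_pass = 0
    for child in children:
        data_seed, perm_seed = (_child_seed(s) for s in child.spawn(2))
        queries, tx = _one_dataset(data_seed, n_te, n_genes, "independent")
        results = run_spatial_tests(
            queries, tx, PermutationConfig(n_permutations=n_permutations, alpha=alpha, seed=perm_seed)
        )
        for t, res in results.items():
            if res.p_value <= alpha:
                rejections[t] += 1
        vals = relative_distance_values(queries, tx)
        vmin, vmax = min(vmin, float(vals.min())), max(vmax, float(vals.max()))
        means.append(float(vals.mean()))
        ns.append(vals.size)
        if stats.kstest(vals, "uniform", args=(0.0, 0.5)).pvalue >= 0.05:
            ks_pass += 1
    all_n = int(np.sum(ns))
    pooled_mean = float(np.average(means, weights=ns))
    # SE of the pooled mean under the uniform(0, 0.5) null: sd = 0.5/sqrt(12)
    se = (0.5 / np.sqrt(12.0)) / np.sqrt(all_n)
    return NullCalibrationResult(
        n_datasets=n_datasets, alpha=alpha, rejections=rejections,
        rel_values_min=vmin, rel_values_max=vmax,
        rel_mean=pooled_mean, rel_se=float(se), ks_pass=ks_pass,
    )


# -- planted-signal recovery -------------------------------------------------


@dataclass
class SensitivityResult:
    model: str
    expected_direction: str
    n_replicates: int
    n_expected: int
    n_inverted: int
    n_not_significant: int

    @property
    def sensitivity(self) -> float:
        return self.n_expected / self.n_replicates


def planted_direction_sensitivity(
    model: str,
    n_replicates: int = 100,
    seed: int = 0,
    n_te: int = 10_000,
    n_genes: int = 200,
    n_permutations: int = 100,
    test: str = "jaccard",
) -> SensitivityResult:
    """Fraction of planted attracted/repelled datasets called concordantly."""
    expected = "attraction" if model == "attracted" else "repulsion"
    inverse = "repulsion" if model == "attracted" else "attraction"
    root = np.random.SeedSequence((seed, 1 if model == "attracted" else 2))
    counts = {expected: 0, inverse: 0, "not_significant": 0}
    for child in root.spawn(n_replicates):
        data_seed, perm_seed = (_child_seed(s) for s in child.spawn(2))
        queries, tx = _one_dataset(data_seed, n_te, n_genes, model)
        res = run_spatial_tests(
            queries, tx, PermutationConfig(n_permutations=n_permutations, seed=perm_seed),
            tests=(test,),
        )[test]
        counts[res.direction] = counts.get(res.direction, 0) + 1
    return SensitivityResult(
        model=model, expected_direction=expected, n_replicates=n_replicates,
        n_expected=counts[expected], n_inverted=counts[inverse],
        n_not_significant=counts["not_significant"],
    )


# -- pipeline exactness ------------------------------------------------------


def pipeline_exactness(workdir, seed: int = 0) -> dict:
    """Parse -> classify -> filter -> age-bin on a noise-free synthetic `.out`.

    The planted census includes all five TE classes plus OTHER repeats and an
    RC-excluding species config, so every drop rule is exercised. Returns the
    recovered and expected per-(class, bin) count tables and whether they
    match exactly.
    """
    cfg = SimulationConfig(
        seed=seed,
        n_te_per_class={"SINE": 3000, "LINE": 2000, "LTR": 1200, "DNA": 1500, "RC": 900, "OTHER": 800},
        divergence_noise_sd=0.0,
        placement_model="independent",
    )
    layout, genes = simulate_layout_and_genes(cfg)
    out_path = os.path.join(workdir, "synthetic.out")
    truth = simulate_te_annotation(cfg, layout, genes, out_path)

    species = SpeciesConfig(species_id="test", rate_per_site_per_my=cfg.rate_per_site_per_my,
                            rc_allowed=False)
    records = parse_repeatmasker_out(out_path, layout)
    kept, drops = filter_records(records, species)
    binned = bin_by_age(add_ages(kept, species), species)
    recovered: dict[tuple[str, str], int] = {}
    for age_bin, recs in binned.items():
        for r in recs:
            recovered[(r.te_class, age_bin)] = recovered.get((r.te_class, age_bin), 0) + 1

    # independent expectation from the truth table, applying the same rules
    t = truth[truth["length"] >= species.min_te_length_bp]
    t = t[t["te_class"] != "OTHER"]
    t = t[t["te_class"] != "RC"]
    expected = t.groupby(["te_class", "age_bin"]).size().to_dict()

    exp_drops = {
        "short": int((truth["length"] < species.min_te_length_bp).sum()),
        "other_class": int(((truth["length"] >= species.min_te_length_bp)
                            & (truth["te_class"] == "OTHER")).sum()),
        "rc_excluded": int(((truth["length"] >= species.min_te_length_bp)
                            & (truth["te_class"] == "RC")).sum()),
    }
    return {
        "match": recovered == expected and drops == exp_drops,
        "recovered": recovered,
        "expected": expected,
        "drops": drops,
        "expected_drops": exp_drops,
        "n_planted": len(truth),
    }


# -- chi-square oracle -------------------------------------------------------


def chisq_oracle_comparison(n_tables: int = 1000, seed: int = 0) -> dict:
    """Max |difference| of the Yates chi-square vs scipy's implementation."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    for _ in range(n_tables):
        a, b, c, d = rng.integers(1, 501, size=4)
        stat, _ = chi_square_yates(ContingencyTable2x2(int(a), int(b), int(c), int(d)))
        ref = stats.chi2_contingency([[a, b], [c, d]], correction=True).statistic
        max_err = max(max_err, abs(stat - ref))
    indep_stat, indep_p = chi_square_yates(ContingencyTable2x2(10, 20, 30, 60))
    return {"max_abs_error": max_err, "n_tables": n_tables,
            "independence_stat": indep_stat, "independence_p": indep_p}


# -- CpG-island recovery -----------------------------------------------------


def cgi_recovery(seed: int = 0, n_background_chroms: int = 10) -> dict:
    """Planted-island recovery plus false-positive rate on pure background.

    Recovery: 10 x 1-kb islands planted in 100 kb; Jaccard of detected vs
    planted truth. False positives: islands called on
    ``n_background_chroms`` x 100 kb of island-free background, per 100 kb.
    """
    cfg = SimulationConfig(
        seed=seed, n_chroms=1, chrom_length_bp=100_000,
        n_genes=10, gene_length_bp=2_000, island_length_bp=1_000,
    )
    layout, genes = simulate_layout_and_genes(cfg)
    seqs, islands = simulate_sequence(cfg, layout, genes)
    detected = detect_cgi(seqs["chr1"], "chr1", CgiParams(), layout)
    truth = IntervalSet.from_arrays(
        layout, {"chr1": (islands["start"].to_numpy(np.int64), islands["end"].to_numpy(np.int64))}
    ).merge()
    inter = intersection_length(detected, truth)
    union = union_length(detected, truth)
    jac = inter / union if union else 0.0

    bg_cfg = SimulationConfig(seed=seed + 1, n_chroms=n_background_chroms,
                              chrom_length_bp=100_000, n_genes=0)
    bg_layout, bg_genes = simulate_layout_and_genes(bg_cfg)
    bg_seqs, _ = simulate_sequence(bg_cfg, bg_layout, bg_genes)
    n_false = sum(len(detect_cgi(s, c, CgiParams(), bg_layout)) for c, s in bg_seqs.items())
    fp_per_100kb = n_false / n_background_chroms
    return {"jaccard": jac, "n_islands_detected": len(detected),
            "n_islands_planted": len(truth), "false_islands_per_100kb": fp_per_100kb,
            "background_kb": n_background_chroms * 100}


# -- determinism -------------------------------------------------------------


def _mini_pipeline(workdir, seed: int) -> list[str]:
    """A compact end-to-end run; returns the paths of the TSVs it wrote."""
    from .spatial import build_correlation_matrix
    from .te import composition_summary, records_to_interval_set, size_split_table

    cfg = SimulationConfig(
        seed=seed, n_chroms=2, chrom_length_bp=1_000_000, n_genes=40,
        gene_length_bp=5_000,
        n_te_per_class={"SINE": 1500, "LINE": 1500},
        placement_model="attracted",
    )
    layout, genes = simulate_layout_and_genes(cfg)
    out_path = os.path.join(workdir, "te.out")
    gtf_path = os.path.join(workdir, "genes.gtf")
    simulate_te_annotation(cfg, layout, genes, out_path)
    write_gtf(genes, gtf_path)

    species = SpeciesConfig(species_id="sim", rate_per_site_per_my=cfg.rate_per_site_per_my)
    records = parse_repeatmasker_out(out_path, layout)
    kept, _ = filter_records(records, species)
    binned = bin_by_age(add_ages(kept, species), species)

    comp_path = os.path.join(workdir, "composition.tsv")
    composition_summary(binned).to_csv(comp_path, sep="\t", index=False, float_format="%.8g")

    from .intervals import read_gtf_features
    tx = read_gtf_features(gtf_path, layout, "transcript")
    groups = {
        (te_class, age_bin): records_to_interval_set(
            [r for r in recs if r.te_class == te_class], layout)
        for age_bin, recs in binned.items() if recs
        for te_class in {r.te_class for r in recs}
    }
    matrix = build_correlation_matrix(
        groups, {"transcript": tx},
        PermutationConfig(n_permutations=25, seed=seed),
        min_group_size=100, species="sim",
    )
    mat_path = os.path.join(workdir, "correlation.tsv")
    matrix.to_tsv(mat_path)

    table = size_split_table([r for r in kept if r.te_class in ("LINE", "LTR")], tx)
    stat, p = chi_square_yates(table)
    chi_path = os.path.join(workdir, "size_split.tsv")
    pd.DataFrame([{
        "large_within": table.a, "large_outside": table.b,
        "small_within": table.c, "small_outside": table.d,
        "chi2_yates": stat, "p_value": p,
    }]).to_csv(chi_path, sep="\t", index=False, float_format="%.8g")
    return [comp_path, mat_path, chi_path]


def determinism_check(workdir, seed: int = 0) -> dict:
    """Run the compact pipeline twice from the same seed; compare TSV bytes."""
    d1, d2 = os.path.join(workdir, "run1"), os.path.join(workdir, "run2")
    os.makedirs(d1, exist_ok=True)
    os.makedirs(d2, exist_ok=True)
    paths1 = _mini_pipeline(d1, seed)
    paths2 = _mini_pipeline(d2, seed)
    identical = all(
        open(p1, "rb").read() == open(p2, "rb").read() for p1, p2 in zip(paths1, paths2)
    )
    return {"identical": identical, "n_files": len(paths1)}


# -- interval-algebra bitmap oracle -----------------------------------------


def bitmap_oracle_comparison(n_genomes: int = 100, seed: int = 0, max_bp: int = 50_000) -> dict:
    """Interval algebra vs a per-base boolean-bitmap oracle on random genomes."""
    rng = np.random.default_rng(seed)
    max_err = 0
    for _ in range(n_genomes):
        n_chrom = int(rng.integers(1, 4))
        layout = GenomeLayout({f"c{i}": int(rng.integers(100, max_bp // n_chrom + 1))
                               for i in range(n_chrom)})

        def random_set() -> IntervalSet:
            arrays = {}
            for c in layout.chrom_names:
                n = int(rng.integers(0, 30))
                if n == 0:
                    continue
                starts = rng.integers(0, layout[c] - 1, size=n)
                lens = rng.integers(1, max(2, layout[c] // 10), size=n)
                ends = np.minimum(starts + lens, layout[c])
                arrays[c] = (starts, ends)
            return IntervalSet.from_arrays(layout, arrays, validate=False).merge()

        a, b = random_set(), random_set()
        inter_ref = union_ref = 0
        for c in layout.chrom_names:
            bm_a = np.zeros(layout[c], dtype=bool)
            bm_b = np.zeros(layout[c], dtype=bool)
            for s, e in zip(*a.arrays(c)):
                bm_a[s:e] = True
            for s, e in zip(*b.arrays(c)):
                bm_b[s:e] = True
            inter_ref += int((bm_a & bm_b).sum())
            union_ref += int((bm_a | bm_b).sum())
        max_err = max(max_err,
                      abs(intersection_length(a, b) - inter_ref),
                      abs(union_length(a, b) - union_ref))
    return {"max_abs_error": max_err, "n_genomes": n_genomes}
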