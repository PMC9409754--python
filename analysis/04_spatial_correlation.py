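#!/usr/bin/env python
"""The correlation matrix: every TE stratum vs every genic feature, three tests.

For each species, TE insertions are stratified by class and age bin (young /
old; intermediate strata are carried too) and tested against transcript,
CDS, start codon and CGI with the Jaccard, absolute-distance and
relative-distance permutation tests (100 permutations each). Direction calls
land in results/spatial_correlation.tsv with one heatmap per species.
"""

import os

import pandas as pd

from tespatial import (
    PermutationConfig,
    SpeciesConfig,
    add_ages,
    bin_by_age,
    build_correlation_matrix,
    build_genic_features,
    filter_records,
    parse_repeatmasker_out,
    read_chrom_sizes,
    records_to_interval_set,
)

from species_config import FIGURES, MIN_GROUP_SIZE, RATE_PER_SITE_PER_MY, RESULTS, SPECIES, paths


def main() -> None:
    frames = []
    for name in SPECIES:
        p = paths(name)
        layout = read_chrom_sizes(p["sizes"])
        species = SpeciesConfig(species_id=name, rate_per_site_per_my=RATE_PER_SITE_PER_MY)
        kept, _ = filter_records(parse_repeatmasker_out(p["out"], layout), species)
        binned = bin_by_age(add_ages(kept, species), species)
        groups = {
            (te_class, age_bin): records_to_interval_set(
                [r for r in recs if r.te_class == te_class], layout)
            for age_bin, recs in binned.items()
            for te_class in sorted({r.te_class for r in recs})
        }
        feats = build_genic_features(p["gtf"], layout, cgi_bed=p["cgi"])
        matrix = build_correlation_matrix(
            groups, feats.as_dict(),
            PermutationConfig(n_permutations=100, seed=SPECIES[name]["seed"]),
            min_group_size=MIN_GROUP_SIZE, species=name,
        )
        df = matrix.to_dataframe()
        frames.append(df)
        os.makedirs(FIGURES, exist_ok=True)
        matrix.plot_heatmap(os.path.join(FIGURES, f"correlation_{name}.png"))

        tested = df[df["direction"] != "not_tested"]
        calls = tested["direction"].value_counts().to_dict()
        print(f"{name}: {matrix.n_tests_run} tests run, calls: {calls}")

    os.makedirs(RESULTS, exist_ok=True)
    out = os.path.join(RESULTS, "spatial_correlation.tsv")
    pd.concat(frames, ignore_index=True).to_csv(out, sep="\t", index=False, float_format="%.8g")
    print(f"\nwrote {out} and per-species heatmaps under {FIGURES}")


if __name__ == "__main__":
    main()
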