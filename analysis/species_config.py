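"""Shared configuration for the synthetic-species analysis runs.

Three synthetic species span the placement models: one with TEs attracted to
gene-proximal windows, one with independent placement, and one with TEs
repelled from genes. Raw annotation files live under scratch/ (regenerable);
the numbered scripts write their tables under results/.
"""

import os

from tespatial import SimulationConfig

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
SCRATCH = os.path.join(ROOT, "scratch", "synthetic")
RESULTS = os.path.join(ROOT, "results")
FIGURES = os.path.join(RESULTS, "figures")

TE_CENSUS = {"SINE": 12_000, "LINE": 8_000, "LTR": 4_000, "DNA": 6_000, "RC": 3_000}

SPECIES = {
    "attractus": dict(placement_model="attracted", seed=101),
    "neutrus": dict(placement_model="independent", seed=102),
    "repulsus": dict(placement_model="repelled", seed=103),
}

#: desk-scale minimum stratum size (the full-scale default of 10,000 would
#: leave every synthetic stratum untested at this census)
MIN_GROUP_SIZE = 1_000

RATE_PER_SITE_PER_MY = 2.5e-3


def species_config(name: str) -> SimulationConfig:
    spec = SPECIES[name]
    return SimulationConfig(
        seed=spec["seed"],
        n_chroms=2,
        chrom_length_bp=5_000_000,
        n_genes=200,
        gene_length_bp=10_000,
        n_te_per_class=dict(TE_CENSUS),
        placement_model=spec["placement_model"],
        rate_per_site_per_my=RATE_PER_SITE_PER_MY,
    )


def species_dir(name: str) -> str:
    return os.path.join(SCRATCH, name)


def paths(name: str) -> dict[str, str]:
    d = species_dir(name)
    return {
        "sizes": os.path.join(d, "chrom.sizes"),
        "gtf": os.path.join(d, "genes.gtf"),
        "fasta": os.path.join(d, "genome.fa"),
        "out": os.path.join(d, "repeats.out"),
        "truth": os.path.join(d, "te_truth.tsv"),
        "islands": os.path.join(d, "cgi_truth.bed"),
        "cgi": os.path.join(d, "cgi_detected.bed"),
        "manifest": os.path.join(d, "manifest.json"),
    }
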