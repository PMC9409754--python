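"""Synthetic genome annotations with planted spatial structure.

Generates everything the pipeline consumes — chromosome layout, a gene GTF
(single-exon transcript, interior CDS, 3-bp start codon), a FASTA with
CpG-island blocks planted at gene 5' ends, and a RepeatMasker-style `.out`
table with class labels and divergence values drawn per age bin — together
with truth tables, so every statistic has a ground truth to be checked
against.

The TE placement model plants the spatial signal:

* ``independent`` — TE positions uniform on their chromosome (the null).
* ``attracted``   — with probability ``attraction_prob`` a TE midpoint falls
  inside a gene-proximal window (transcript +/- ``proximal_window_bp``),
  otherwise uniform. This emulates insertion preference for open chromatin
  around genes.
* ``repelled``    — TE midpoints uniform on the complement of the
  gene-proximal windows, emulating purifying selection against insertions in
  and around genes.

Ages: each record is assigned an age bin; its divergence is the bin
midpoint age times the neutral rate (as a percentage) plus Gaussian noise on
the divergence scale. The old bin (> 40 My) has no upper edge; its generator
midpoint is 55 My. All draws run through one seeded Generator, so outputs
are bit-reproducible from the config seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomeLayout, IntervalSet

__all__ = [
    "SimulationConfig",
    "simulate_layout_and_genes",
    "write_gtf",
    "simulate_sequence",
    "write_fasta",
    "simulate_te_table",
    "write_repeatmasker_out",
    "simulate_te_annotation",
    "te_table_to_interval_set",
    "gene_proximal_windows",
    "write_manifest",
]

AGE_BIN_MID_MY = {"young": 12.5, "intermediate": 32.5, "old": 55.0}

RM_CLASS_STRINGS = {
    "SINE": ("Ves1", "SINE/tRNA"),
    "LINE": ("L1-bat", "LINE/L1"),
    "LTR": ("ERV-bat", "LTR/ERVL"),
    "DNA": ("hAT-bat", "DNA/hAT"),
    "RC": ("Helitron-bat", "RC/Helitron"),
    "OTHER": ("(TA)n", "Simple_repeat"),
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome.

    Defaults give a 10 Mb genome (2 x 5 Mb), 200 non-overlapping 10-kb genes,
    and a multi-class TE census; the planted-signal defaults
    (attraction_prob 0.8 within 1-kb gene-proximal windows) produce
    near-saturating power at 10,000 insertions per stratum.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 5_000_000
    n_genes: int = 200
    gene_length_bp: int = 10_000
    n_te_per_class: dict[str, int] = field(
        default_factory=lambda: {"SINE": 12_000, "LINE": 8_000, "LTR": 4_000, "DNA": 6_000, "RC": 3_000}
    )
    placement_model: str = "independent"
    attraction_prob: float = 0.8
    proximal_window_bp: int = 1_000
    age_mix: dict[str, float] = field(
        default_factory=lambda: {"young": 0.3, "intermediate": 0.3, "old": 0.4}
    )
    divergence_noise_sd: float = 0.5
    rate_per_site_per_my: float = 2.5e-3
    island_length_bp: int = 1_000
    background_gc: float = 0.38
    island_gc: float = 0.65

    def __post_init__(self) -> None:
        if self.placement_model not in ("independent", "attracted", "repelled"):
            raise ValueError(f"unknown placement_model {self.placement_model!r}")
        total = sum(self.age_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"age_mix fractions must sum to 1 (got {total})")
        if not 0.0 <= self.attraction_prob <= 1.0:
            raise ValueError("attraction_prob must lie in [0, 1]")


def _largest_remainder(n: int, fractions: dict[str, float]) -> dict[str, int]:
    """Deterministic apportionment: counts sum to n exactly."""
    keys = list(fractions)
    raw = np.array([n * fractions[k] for k in keys])
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:short]:
        base[i] += 1
    return dict(zip(keys, base.tolist()))


# -- layout and genes -------------------------------------------------------


def simulate_layout_and_genes(config: SimulationConfig) -> tuple[GenomeLayout, pd.DataFrame]:
    """Uniform non-overlapping gene placement; returns layout and a gene table.

    Each gene carries a transcript spanning its full length, a CDS covering
    the interior 60%, and a 3-bp start codon at the CDS 5' end (strand-aware).
    """
    layout = GenomeLayout({f"chr{i + 1}": config.chrom_length_bp for i in range(config.n_chroms)})
    if config.n_genes * config.gene_length_bp >= layout.total_bp / 2:
        raise ValueError("infeasible packing: genes would cover more than half the genome")
    rng = np.random.default_rng(config.seed)
    quotas = _largest_remainder(
        config.n_genes, {c: layout[c] / layout.total_bp for c in layout.chrom_names}
    )
    rows = []
    gid = 0
    glen = config.gene_length_bp
    for chrom in layout.chrom_names:
        k = quotas[chrom]
        if k == 0:
            continue
        free = layout[chrom] - k * glen
        if free < 0:
            raise ValueError(f"cannot place {k} genes of {glen} bp on {chrom}")
        # sorted uniform draws plus cumulative gene lengths give an exact
        # uniform sample of non-overlapping placements
        anchors = np.sort(rng.integers(0, free + 1, size=k))
        starts = anchors + np.arange(k) * glen
        strands = rng.choice(np.array(["+", "-"]), size=k)
        for s, strand in zip(starts.tolist(), strands.tolist()):
            e = s + glen
            cds_s = s + round(0.2 * glen)
            cds_e = cds_s + round(0.6 * glen)
            codon_s, codon_e = (cds_s, cds_s + 3) if strand == "+" else (cds_e - 3, cds_e)
            gid += 1
            rows.append((chrom, s, e, strand, f"g{gid:05d}", cds_s, cds_e, codon_s, codon_e))
    genes = pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "strand", "gene_id",
        "cds_start", "cds_end", "codon_start", "codon_end",
    ])
    return layout, genes


def write_gtf(genes: pd.DataFrame, path) -> None:
    """Write transcript/CDS/start_codon records (GTF: 1-based closed coords)."""
    with open(path, "w") as fh:
        for g in genes.itertuples():
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            for feature, s, e in (
                ("transcript", g.start, g.end),
                ("CDS", g.cds_start, g.cds_end),
                ("start_codon", g.codon_start, g.codon_end),
            ):
                fh.write(f"{g.chrom}\tsim\t{feature}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")


# -- sequence ---------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _island_block(rng: np.random.Generator, length: int, gc: float, p_cg: float = 0.15) -> np.ndarray:
    """CG-dinucleotide-enriched block with aggregate GC fraction ~ ``gc``."""
    q = (gc * (1 + p_cg) - 2 * p_cg) / (1 - p_cg)  # single-base GC share
    q = min(max(q, 0.0), 1.0)
    emit_cg = rng.random(length) < p_cg
    singles = _random_bases(rng, length, q)
    parts = np.where(emit_cg, "CG", singles.astype("U1"))
    block = "".join(parts.tolist())[:length]
    return np.frombuffer(block.encode("ascii"), dtype="S1")


def simulate_sequence(
    config: SimulationConfig, layout: GenomeLayout, genes: pd.DataFrame
) -> tuple[dict[str, str], pd.DataFrame]:
    """Background sequence plus a planted CpG-island block at each gene 5' end.

    Returns per-chromosome sequences and the truth table of planted islands
    (one per gene, centred on the transcription start, clipped to bounds).
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(1,)))
    chrom_arrays = {
        chrom: _random_bases(rng, layout[chrom], config.background_gc)
        for chrom in layout.chrom_names
    }
    half = config.island_length_bp // 2
    rows = []
    for g in genes.itertuples():
        tss = g.start if g.strand == "+" else g.end
        s = max(0, tss - half)
        e = min(layout[g.chrom], s + config.island_length_bp)
        s = max(0, e - config.island_length_bp)
        chrom_arrays[g.chrom][s:e] = _island_block(rng, e - s, config.island_gc)
        rows.append((g.chrom, s, e, g.gene_id))
    islands = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])
    seqs = {c: a.tobytes().decode("ascii") for c, a in chrom_arrays.items()}
    return seqs, islands


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# -- TE annotation ----------------------------------------------------------


def gene_proximal_windows(
    layout: GenomeLayout, genes: pd.DataFrame, pad: int
) -> IntervalSet:
    """Merged transcript +/- pad windows, clipped to chromosome bounds."""
    arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in genes.groupby("chrom", sort=False):
        starts = np.maximum(sub["start"].to_numpy() - pad, 0)
        ends = np.minimum(sub["end"].to_numpy() + pad, layout[chrom])
        arrays[chrom] = (starts, ends)
    return IntervalSet.from_arrays(layout, arrays, validate=False).merge()


def _complement(windows: IntervalSet) -> IntervalSet:
    layout = windows.layout
    arrays = {}
    for chrom in layout.chrom_names:
        ws, we = windows.arrays(chrom)
        edges_s = np.concatenate(([0], we))
        edges_e = np.concatenate((ws, [layout[chrom]]))
        keep = edges_e > edges_s
        if np.any(keep):
            arrays[chrom] = (edges_s[keep], edges_e[keep])
    return IntervalSet.from_arrays(layout, arrays, validate=False)


def _sample_midpoints_in_regions(
    rng: np.random.Generator, regions: IntervalSet, n: int
) -> tuple[list[str], np.ndarray]:
    """n midpoints uniform over the total covered length of ``regions``."""
    chroms, seg_start, seg_len = [], [], []
    for chrom in regions.chroms:
        rs, re_ = regions.arrays(chrom)
        chroms.extend([chrom] * rs.size)
        seg_start.append(rs)
        seg_len.append(re_ - rs)
    seg_start = np.concatenate(seg_start)
    seg_len = np.concatenate(seg_len)
    cum = np.concatenate(([0], np.cumsum(seg_len)))
    u = rng.integers(0, cum[-1], size=n)
    seg = np.searchsorted(cum, u, side="right") - 1
    mids = seg_start[seg] + (u - cum[seg])
    return [chroms[i] for i in seg.tolist()], mids


def _uniform_placement(
    rng: np.random.Generator, layout: GenomeLayout, lengths: np.ndarray
) -> tuple[list[str], np.ndarray]:
    names = list(layout.chrom_names)
    clens = np.array([layout[c] for c in names], dtype=float)
    ci = rng.choice(len(names), size=lengths.size, p=clens / clens.sum())
    starts = np.empty(lengths.size, dtype=np.int64)
    for i, name in enumerate(names):
        mask = ci == i
        if np.any(mask):
            starts[mask] = rng.integers(0, layout[name] - lengths[mask] + 1)
    return [names[i] for i in ci.tolist()], starts


def _draw_lengths(rng: np.random.Generator, te_class: str, n: int) -> np.ndarray:
    """Class-typical insertion lengths.

    SINE/DNA/RC (and OTHER) are short non-autonomous copies (80-400 bp);
    LINE/LTR are a mixture of truncated copies / solo LTRs (100-1,000 bp,
    90%) and full-length elements (4,000-8,000 bp, 10%).
    """
    if te_class in ("LINE", "LTR"):
        full = rng.random(n) < 0.10
        out = rng.integers(100, 1001, size=n)
        out[full] = rng.integers(4000, 8001, size=int(full.sum()))
        return out
    return rng.integers(80, 401, size=n)


def simulate_te_table(
    config: SimulationConfig, layout: GenomeLayout, genes: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """The TE truth table: every planted record with class, bin and position.

    Per-(class, age-bin) counts follow ``n_te_per_class`` x ``age_mix`` with
    deterministic largest-remainder rounding, so planted counts are exact.
    ``in_window`` records whether the placed midpoint lies in a gene-proximal
    window.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(2,)))
    windows = gene_proximal_windows(layout, genes, config.proximal_window_bp) if len(genes) else None
    if config.placement_model in ("attracted", "repelled") and (windows is None or len(windows) == 0):
        raise ValueError(f"placement_model {config.placement_model!r} requires genes")
    complement = _complement(windows) if windows is not None else None
    if config.placement_model == "repelled" and (complement is None or len(complement) == 0):
        raise ValueError("degenerate model: gene-proximal windows cover the whole genome")

    frames = []
    for te_class in sorted(config.n_te_per_class):
        n_class = config.n_te_per_class[te_class]
        per_bin = _largest_remainder(n_class, config.age_mix)
        for age_bin in ("young", "intermediate", "old"):
            n = per_bin.get(age_bin, 0)
            if n == 0:
                continue
            lengths = _draw_lengths(rng, te_class, n)
            if config.placement_model == "attracted":
                in_win = rng.random(n) < config.attraction_prob
                chroms = np.empty(n, dtype=object)
                starts = np.empty(n, dtype=np.int64)
                k = int(in_win.sum())
                if k:
                    wc, wm = _sample_midpoints_in_regions(rng, windows, k)
                    ws = wm - lengths[in_win] // 2
                    wl = lengths[in_win]
                    ws = np.array([
                        min(max(s, 0), layout[c] - l)
                        for s, c, l in zip(ws.tolist(), wc, wl.tolist())
                    ], dtype=np.int64)
                    chroms[in_win] = wc
                    starts[in_win] = ws
                if k < n:
                    uc, us = _uniform_placement(rng, layout, lengths[~in_win])
                    chroms[~in_win] = uc
                    starts[~in_win] = us
                chroms = chroms.tolist()
            elif config.placement_model == "repelled":
                rc_, rm = _sample_midpoints_in_regions(rng, complement, n)
                starts = np.array([
                    min(max(m - l // 2, 0), layout[c] - l)
                    for m, c, l in zip(rm.tolist(), rc_, lengths.tolist())
                ], dtype=np.int64)
                chroms = rc_
            else:
                chroms, starts = _uniform_placement(rng, layout, lengths)

            mid_age = AGE_BIN_MID_MY[age_bin]
            div = mid_age * config.rate_per_site_per_my * 100.0
            noise = rng.normal(0.0, config.divergence_noise_sd, size=n) if config.divergence_noise_sd > 0 else 0.0
            pct_div = np.maximum(div + noise, 0.0)
            ends = starts + lengths
            in_window = np.zeros(n, dtype=bool)
            if windows is not None and len(windows):
                mids = (starts + ends) // 2
                chrom_arr = np.asarray(chroms, dtype=object)
                for c in set(chroms):
                    ws_, we_ = windows.arrays(c)
                    if ws_.size == 0:
                        continue
                    mask = chrom_arr == c
                    m = mids[mask]
                    i = np.searchsorted(ws_, m, side="right")
                    in_window[mask] = (i > 0) & (we_[np.maximum(i - 1, 0)] > m)
            family, rm_class = RM_CLASS_STRINGS.get(te_class, (te_class, te_class))
            frames.append(pd.DataFrame({
                "chrom": chroms, "start": starts, "end": ends, "length": lengths,
                "strand": rng.choice(np.array(["+", "-"]), size=n),
                "te_class": te_class, "family": family, "rm_class_string": rm_class,
                "age_bin": age_bin, "age_my_true": mid_age,
                "percent_divergence": np.round(pct_div, 4), "in_window": in_window,
            }))
    table = pd.concat(frames, ignore_index=True)
    return table


def write_repeatmasker_out(table: pd.DataFrame, path) -> None:
    """Write a RepeatMasker-format `.out`: 3 banner lines, 1-based coordinates.

    Percent divergence is printed with one decimal, matching the native
    format's precision.
    """
    header = (
        "   SW   perc perc perc  query      position in query           matching"
        "       repeat              position in repeat\n"
        "score   div. del. ins.  sequence    begin end          (left)  repeat"
        "         class/family      begin  end    (left)   ID\n"
        "\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for i, row in enumerate(table.itertuples(), start=1):
            strand = "+" if row.strand == "+" else "C"
            fh.write(
                f"{1000 + i % 9000:5d} {row.percent_divergence:5.1f}  0.0  0.0  "
                f"{row.chrom}  {row.start + 1}  {row.end}  (0)  {strand}  "
                f"{row.family}  {row.rm_class_string}  1  {row.length}  (0)  {i}\n"
            )


def simulate_te_annotation(
    config: SimulationConfig, layout: GenomeLayout, genes: pd.DataFrame,
    out_path, truth_path=None,
) -> pd.DataFrame:
    """Write the `.out` file (and optional truth TSV); return the truth table."""
    table = simulate_te_table(config, layout, genes)
    write_repeatmasker_out(table, out_path)
    if truth_path is not None:
        table.to_csv(truth_path, sep="\t", index=False)
    return table


def te_table_to_interval_set(
    table: pd.DataFrame, layout: GenomeLayout,
    te_class: str | None = None, age_bin: str | None = None,
) -> IntervalSet:
    """IntervalSet of (optionally stratified) truth-table records."""
    sub = table
    if te_class is not None:
        sub = sub[sub["te_class"] == te_class]
    if age_bin is not None:
        sub = sub[sub["age_bin"] == age_bin]
    arrays = {
        chrom: (g["start"].to_numpy(np.int64), g["end"].to_numpy(np.int64))
        for chrom, g in sub.groupby("chrom", sort=False)
    }
    return IntervalSet.from_arrays(layout, arrays, validate=False)


def write_manifest(config: SimulationConfig, path, extra: dict | None = None) -> None:
    doc = dataclasses.asdict(config)
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
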