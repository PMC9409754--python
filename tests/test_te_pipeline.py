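"""RepeatMasker parsing, TE classification, dating, stratification, chi-square."""

import numpy as np
import pytest
from scipy import stats

from tespatial import (
    ContingencyTable2x2,
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    SpeciesConfig,
    TERecord,
    add_ages,
    assign_class,
    bin_by_age,
    chi_square_yates,
    composition_summary,
    estimate_age,
    filter_records,
    parse_repeatmasker_out,
    size_distribution,
    size_split_table,
)

HEADER = (
    "   SW   perc perc perc  query  position in query  matching repeat  position in repeat\n"
    "score   div. del. ins.  sequence begin end (left) repeat class/family begin end (left) ID\n"
    "\n"
)


def rm_line(chrom="chr1", div=5.3, begin=101, end=200, family="L1-x", rm_class="LINE/L1"):
    return f" 1000 {div:5.1f}  0.0  0.0  {chrom}  {begin}  {end}  (0)  +  {family}  {rm_class}  1  100  (0)  1\n"


@pytest.fixture
def layout():
    return GenomeLayout({"chr1": 1_000_000, "chr2": 1_000_000})


def make_record(length=200, te_class="LINE", div=5.0, chrom="chr1", start=0, rm_class=None):
    return TERecord(
        interval=GenomicInterval(chrom, start, start + length),
        family_name="fam", rm_class_string=rm_class or te_class,
        te_class=te_class, percent_divergence=div,
    )


class TestParseRepeatmaskerOut:
    def test_coordinates_one_based_inclusive_to_half_open(self, tmp_path, layout):
        p = tmp_path / "a.out"
        p.write_text(HEADER + rm_line(begin=101, end=200, div=5.3))
        (rec,) = parse_repeatmasker_out(p, layout)
        assert (rec.interval.start, rec.interval.end, rec.length) == (100, 200, 100)
        assert rec.percent_divergence == 5.3
        assert rec.te_class == "LINE"

    def test_header_only_file_yields_no_records(self, tmp_path, layout):
        p = tmp_path / "a.out"
        p.write_text(HEADER)
        assert parse_repeatmasker_out(p, layout) == []

    def test_unknown_chromosome_skipped_with_warning(self, tmp_path, layout):
        p = tmp_path / "a.out"
        p.write_text(HEADER + rm_line(chrom="scaffold_99") + rm_line(chrom="chr1"))
        with pytest.warns(UserWarning, match="scaffold_99"):
            recs = parse_repeatmasker_out(p, layout)
        assert len(recs) == 1

    def test_malformed_row_names_line_number(self, tmp_path, layout):
        p = tmp_path / "a.out"
        p.write_text(HEADER + " 1000 bad 0.0 0.0 chr1 1 2 (0) + x LINE/L1 1 2 (0) 1\n")
        with pytest.raises(ValueError, match="line 4"):
            parse_repeatmasker_out(p, layout)


class TestAssignClass:
    @pytest.mark.parametrize("rm_class,expected", [
        ("LINE/L1", "LINE"),
        ("SINE/tRNA-Ves", "SINE"),
        ("LTR/ERVL", "LTR"),
        ("DNA/hAT-Charlie", "DNA"),
        ("RC/Helitron", "RC"),
        ("Unknown/Helitron-like", "RC"),
        ("Simple_repeat", "OTHER"),
        ("Low_complexity", "OTHER"),
        ("Satellite", "OTHER"),
        ("rRNA", "OTHER"),
    ])
    def test_prefix_mapping(self, rm_class, expected):
        assert assign_class(rm_class) == expected

    def test_empty_string_rejected(self):
        with pytest.raises(ValueError):
            assign_class("")


class TestEstimateAge:
    @pytest.mark.parametrize("div,rate,age", [(0.0, 0.0025, 0.0), (5.0, 0.0025, 20.0), (12.0, 0.0025, 48.0)])
    def test_divergence_over_rate(self, div, rate, age):
        assert estimate_age(div, rate) == pytest.approx(age)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            estimate_age(5.0, 0.0)
        with pytest.raises(ValueError):
            estimate_age(-1.0, 0.0025)

    def test_doubling_rate_halves_every_age(self):
        rng = np.random.default_rng(0)
        divs = rng.uniform(0, 30, size=50)
        ages1 = [estimate_age(d, 0.002) for d in divs]
        ages2 = [estimate_age(d, 0.004) for d in divs]
        assert np.allclose(np.array(ages2) * 2, ages1)


class TestFilterAndBin:
    def test_length_threshold_inclusive(self):
        cfg = SpeciesConfig()
        kept, drops = filter_records([make_record(length=99), make_record(length=100)], cfg)
        assert [r.length for r in kept] == [100]
        assert drops["short"] == 1

    def test_rc_and_other_exclusion(self):
        cfg = SpeciesConfig(rc_allowed=False)
        records = [
            make_record(te_class="RC", rm_class="RC/Helitron"),
            make_record(te_class="OTHER", rm_class="Simple_repeat"),
            make_record(te_class="SINE", rm_class="SINE/tRNA"),
        ]
        kept, drops = filter_records(records, cfg)
        assert [r.te_class for r in kept] == ["SINE"]
        assert drops == {"short": 0, "other_class": 1, "rc_excluded": 1}

    def test_rc_kept_when_allowed(self):
        kept, _ = filter_records([make_record(te_class="RC")], SpeciesConfig(rc_allowed=True))
        assert len(kept) == 1

    @pytest.mark.parametrize("age,expected", [
        (10.0, "young"), (24.999, "young"), (25.0, "intermediate"), (30.0, "intermediate"),
        (40.0, "intermediate"), (40.001, "old"), (50.0, "old"),
    ])
    def test_age_bins_exhaustive_disjoint(self, age, expected):
        cfg = SpeciesConfig()
        rec = make_record(div=age * 100 * cfg.rate_per_site_per_my)
        binned = bin_by_age(add_ages([rec], cfg), cfg)
        assert [b for b, recs in binned.items() if recs] == [expected]

    def test_config_yaml_round_trip(self, tmp_path):
        p = tmp_path / "species.yaml"
        p.write_text(
            "species:\n  batA:\n    rate_per_site_per_my: 0.0021\n    rc_allowed: true\n"
        )
        cfg = SpeciesConfig.from_yaml(p)
        assert cfg.species_id == "batA"
        assert cfg.rate_per_site_per_my == 0.0021


class TestSummaries:
    def test_composition_counts_and_proportions(self):
        cfg = SpeciesConfig()
        records = [make_record(te_class="SINE", div=2.0)] * 10 + [make_record(te_class="LINE", div=12.0)] * 5
        binned = bin_by_age(add_ages(records, cfg), cfg)
        df = composition_summary(binned)
        assert df["count"].sum() == 15
        assert dict(zip(zip(df.te_class, df.age_bin), df["count"])) == {
            ("SINE", "young"): 10, ("LINE", "old"): 5}
        for _, sub in df.groupby("age_bin"):
            assert sub["proportion_in_bin"].sum() == pytest.approx(1.0)

    def test_size_distribution_conserves_counts(self):
        records = [make_record(length=100)] * 4 + [make_record(length=5000, te_class="LTR")] * 3
        df = size_distribution(records)
        assert df["count"].sum() == 7
        single = df[df.te_class == "LINE"]
        assert len(single) == 1 and single.iloc[0]["log10_bin_lo"] == pytest.approx(2.0)


class TestSizeSplit:
    @pytest.fixture
    def transcripts(self, layout):
        return IntervalSet(layout, [GenomicInterval("chr1", 10_000, 20_000)]).merge()

    def test_threshold_and_overlap_rules(self, layout, transcripts):
        records = [
            make_record(length=501, te_class="LINE", start=10_100),  # large, within
            make_record(length=500, te_class="LINE", start=10_100),  # small, within
            make_record(length=501, te_class="LTR", start=500_000),  # large, outside
            make_record(length=500, te_class="LTR", start=500_000),  # small, outside
            make_record(length=9_999, te_class="SINE", start=10_100),  # ignored class
        ]
        t = size_split_table(records, transcripts)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_single_base_overlap_counts_as_within(self, layout, transcripts):
        rec = make_record(length=600, te_class="LINE", start=9_401)  # overlaps 1 bp
        t = size_split_table([rec, make_record(length=200, te_class="LINE", start=0)], transcripts)
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 1)

    def test_no_line_ltr_records_raises(self, transcripts):
        with pytest.raises(ValueError, match="LINE/LTR"):
            size_split_table([make_record(te_class="SINE")], transcripts)


class TestChiSquareYates:
    def test_independence_gives_zero_statistic(self):
        stat, p = chi_square_yates(ContingencyTable2x2(10, 20, 30, 60))  # ad == bc
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_scipy_oracle_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(1, 501, size=4))
            stat, p = chi_square_yates(ContingencyTable2x2(a, b, c, d))
            ref = stats.chi2_contingency([[a, b], [c, d]], correction=True)
            assert stat == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_doubling_cells_increases_statistic(self):
        s1, _ = chi_square_yates(ContingencyTable2x2(10, 20, 30, 40))
        s2, _ = chi_square_yates(ContingencyTable2x2(20, 40, 60, 80))
        assert s2 > s1

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_yates(ContingencyTable2x2(0, 0, 5, 5))
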