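"""SNP filtering, zygosity calls, corroboration, ratio, chimera logic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_records
from hybridkaryo import zygosity as zg
from hybridkaryo.synthetic import (
    ChimeraSpec,
    ChromosomeSpec,
    Gene,
    ReferenceModel,
    TruthSpec,
    generate_reference,
    simulate_variants,
)


class TestFlankFilter:
    def test_boundary_is_inclusive(self):
        recs = pd.concat(
            [
                make_records(left=4, right=10),  # below on one side -> discarded
                make_records(left=5, right=5),  # exactly at threshold -> kept
                make_records(left=12, right=3),
            ],
            ignore_index=True,
        )
        out = zg.filter_variants(recs, min_flank=5)
        assert len(out) == 1
        assert out.loc[0, "LEFT_FLANK"] == 5

    def test_empty_input_empty_output(self):
        empty = make_records(ad_ref=(), ad_alt=())
        assert len(zg.filter_variants(empty)) == 0

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            zg.filter_variants(make_records(), min_flank=-1)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 30))
    def test_survivors_shrink_as_threshold_rises(self, k):
        rng = np.random.default_rng(0)
        recs = make_records(
            ad_ref=tuple(rng.integers(5, 40, 200)),
            ad_alt=tuple(rng.integers(5, 40, 200)),
        )
        recs["LEFT_FLANK"] = rng.integers(0, 30, 200)
        recs["RIGHT_FLANK"] = rng.integers(0, 30, 200)
        tighter = set(zg.filter_variants(recs, k + 1).index)
        looser = set(zg.filter_variants(recs, k).index)
        assert len(tighter) <= len(looser)


class TestClassification:
    @pytest.mark.parametrize(
        "ad_ref, ad_alt, expected",
        [
            (25, 25, zg.HET),  # equal proportions
            (0, 50, zg.HOM),  # only the non-reference allele
            (40, 5, zg.AMBIGUOUS),  # fraction 0.11: outside both bands
        ],
    )
    def test_band_assignment(self, ad_ref, ad_alt, expected):
        out = zg.classify_zygosity(make_records(ad_ref=(ad_ref,), ad_alt=(ad_alt,)))
        assert out.loc[0, "CALL"] == expected

    def test_zero_depth_record_rejected(self):
        with pytest.raises(zg.VariantInputError):
            zg.classify_zygosity(make_records(ad_ref=(0,), ad_alt=(0,)))

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 60), st.integers(0, 60))
    def test_every_record_gets_exactly_one_label(self, ref, alt):
        if ref + alt == 0:
            return
        out = zg.classify_zygosity(make_records(ad_ref=(ref,), ad_alt=(alt,)))
        assert out.loc[0, "CALL"] in {zg.HET, zg.HOM, zg.AMBIGUOUS}


class TestChromosomeSummary:
    def test_het_dominated_supports_two_copies(self):
        recs = make_records(ad_ref=(25,) * 100 + (0,) * 2, ad_alt=(25,) * 100 + (50,) * 2)
        calls = zg.classify_zygosity(recs)
        s = zg.summarize_by_chromosome(calls)
        assert s.loc[0, "corroborated_copies"] == ">=2"

    def test_all_homozygous_supports_single_copy(self):
        calls = zg.classify_zygosity(make_records(ad_ref=(0,) * 50, ad_alt=(50,) * 50))
        s = zg.summarize_by_chromosome(calls)
        assert s.loc[0, "corroborated_copies"] == "1"

    def test_below_support_floor_indeterminate(self):
        calls = zg.classify_zygosity(make_records(ad_ref=(25,) * 10, ad_alt=(25,) * 10))
        s = zg.summarize_by_chromosome(calls, min_snps=20)
        assert s.loc[0, "corroborated_copies"] == "indeterminate"


class TestSubgenomeFraction:
    def test_two_percent_share(self):
        recs = pd.concat(
            [
                make_records(chrom="sc", subgenome="Scer", ad_ref=(25,) * 98, ad_alt=(25,) * 98),
                make_records(chrom="se", subgenome="Seub", ad_ref=(25,) * 2, ad_alt=(25,) * 2),
            ],
            ignore_index=True,
        )
        frac = zg.subgenome_snp_fraction(zg.classify_zygosity(recs))
        assert frac["Seub"] == pytest.approx(0.02)
        assert sum(frac.values()) == pytest.approx(1.0)

    def test_single_subgenome_is_total(self):
        frac = zg.subgenome_snp_fraction(
            zg.classify_zygosity(make_records(ad_ref=(25,) * 5, ad_alt=(25,) * 5))
        )
        assert frac == {"Scer": 1.0}

    def test_empty_input_errors(self):
        with pytest.raises(zg.VariantInputError):
            zg.subgenome_snp_fraction(make_records(ad_ref=(), ad_alt=()))


def two_subgenome_ref(length=100_000):
    return ReferenceModel(
        chromosomes=[("sc", "Scer", length), ("se", "Seub", length)],
        genes=[],
        mito_contigs={"Scer": ("m1", 100), "Seub": ("m2", 100)},
    )


class TestHeterozygosityRatio:
    def test_equal_densities_give_unity(self):
        recs = pd.concat(
            [
                make_records(chrom="sc", subgenome="Scer", ad_ref=(25,) * 40, ad_alt=(25,) * 40),
                make_records(chrom="se", subgenome="Seub", ad_ref=(25,) * 40, ad_alt=(25,) * 40),
            ],
            ignore_index=True,
        )
        r = zg.heterozygosity_ratio(zg.classify_zygosity(recs), two_subgenome_ref())
        assert r.ratio == pytest.approx(1.0)
        assert not r.undefined

    def test_zero_minor_density_yields_infinite_sentinel(self):
        recs = pd.concat(
            [
                make_records(chrom="sc", subgenome="Scer", ad_ref=(25,) * 40, ad_alt=(25,) * 40),
                # Seub chromosome corroborated >=2 but with ... no het at all
                make_records(chrom="se", subgenome="Seub", ad_ref=(25,) * 0, ad_alt=(25,) * 0),
            ],
            ignore_index=True,
        )
        r = zg.heterozygosity_ratio(zg.classify_zygosity(recs), two_subgenome_ref())
        assert math.isinf(r.ratio)
        assert r.undefined

    def test_density_recovery_from_simulation(self):
        spec = TruthSpec(
            seed=13,
            chromosomes=[
                ChromosomeSpec("sc", "Scer", 4_000_000, 2),
                ChromosomeSpec("se", "Seub", 4_000_000, 2),
            ],
            het_snp_density={"Scer": 2e-2, "Seub": 5e-4},  # 40:1
            hom_snp_density={"Scer": 0.0, "Seub": 0.0},
            genes_per_chromosome=2,
            gene_length=1_000,
        )
        calls = zg.classify_zygosity(
            zg.filter_variants(simulate_variants(generate_reference(spec), spec))
        )
        r = zg.heterozygosity_ratio(calls, generate_reference(spec))
        assert r.ratio == pytest.approx(40.0, rel=0.2)

    def test_missing_subgenome_in_reference_errors(self):
        ref = ReferenceModel(
            chromosomes=[("sc", "Scer", 1000)], genes=[], mito_contigs={}
        )
        calls = zg.classify_zygosity(make_records(ad_ref=(25,) * 30, ad_alt=(25,) * 30))
        with pytest.raises(zg.VariantInputError, match="Seub"):
            zg.heterozygosity_ratio(calls, ref)


def regime_records(pattern, per_block=25, chrom="x"):
    """Blocks of het ('H') / hom ('O') records laid consecutively by position."""
    ad_ref, ad_alt = [], []
    for state in pattern:
        for _ in range(per_block):
            if state == "H":
                ad_ref.append(25), ad_alt.append(25)
            else:
                ad_ref.append(0), ad_alt.append(50)
    n = len(ad_ref)
    return make_records(
        chrom=chrom, ad_ref=tuple(ad_ref), ad_alt=tuple(ad_alt), pos=np.arange(1, n + 1) * 1000
    )


class TestChimeraDetection:
    def test_uniform_chromosome_is_not_chimeric(self):
        calls = zg.classify_zygosity(regime_records("H" * 10))
        assert zg.detect_chimera(calls) == []

    def test_clean_breakpoint_detected_between_segments(self):
        calls = zg.classify_zygosity(regime_records("H" * 6 + "O" * 6))
        segs = zg.detect_chimera(calls)
        assert [s.state for s in segs] == ["het", "hom"]
        # breakpoint between SNP 150 (pos 150000) and SNP 151 (pos 151000)
        assert segs[0].breakpoint == pytest.approx(150_500)

    def test_alternating_short_runs_are_no_call(self):
        calls = zg.classify_zygosity(regime_records("HO" * 6))
        assert zg.detect_chimera(calls) == []

    def test_insufficient_data_is_no_call_not_error(self):
        calls = zg.classify_zygosity(make_records(ad_ref=(25,) * 30, ad_alt=(25,) * 30))
        assert zg.detect_chimera(calls, window_snps=25) == []

    def test_multiple_chromosomes_rejected(self):
        calls = zg.classify_zygosity(
            pd.concat(
                [regime_records("H" * 3, chrom="a"), regime_records("H" * 3, chrom="b")],
                ignore_index=True,
            )
        )
        with pytest.raises(zg.VariantInputError):
            zg.detect_chimera(calls)

    def test_simulated_breakpoint_recovered(self):
        spec = TruthSpec(
            seed=21,
            chromosomes=[ChromosomeSpec("scX", "Scer", 1_000_000, 2)],
            het_snp_density={"Scer": 1e-3, "Seub": 0.0},
            hom_snp_density={"Scer": 0.0, "Seub": 0.0},
            chimera_specs=[ChimeraSpec("scX", 500_000, "het", "hom")],
            genes_per_chromosome=2,
            gene_length=1_000,
        )
        calls = zg.classify_zygosity(
            zg.filter_variants(simulate_variants(generate_reference(spec), spec))
        )
        segs = zg.detect_chimera(calls)
        assert len(segs) == 2
        assert abs(segs[0].breakpoint - 500_000) <= 50_000
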