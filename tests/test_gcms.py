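"""GC-MS quantitation: area normalisation, filtering, descriptive stats."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import aromabsa as ab
from aromabsa.errors import (
    ConfigurationError,
    DataFormatError,
    DegenerateInputError,
)


def _peaks(areas, sample="S", rep=1, quality=95):
    return pd.DataFrame({
        "sample_id": sample,
        "replicate": rep,
        "compound": [f"c{i}" for i in range(len(areas))],
        "area": areas,
        "quality": quality,
    })


class TestRelativeComposition:
    def test_single_peak_is_100_percent(self):
        comp = ab.relative_composition(_peaks([7.3]))
        assert comp["c0"] == 100.0

    def test_proportionality(self):
        comp = ab.relative_composition(_peaks([25.0, 75.0]))
        assert comp["c0"] == 25.0 and comp["c1"] == 75.0

    def test_three_peaks_hand_arithmetic(self):
        comp = ab.relative_composition(_peaks([10.0, 30.0, 60.0]))
        assert list(comp) == [10.0, 30.0, 60.0]
        assert comp.sum() == pytest.approx(100.0, abs=1e-9)

    def test_absent_compounds_get_zero(self):
        comp = ab.relative_composition(_peaks([5.0]), compounds=["c0", "zz"])
        assert comp["zz"] == 0.0

    def test_all_zero_total_area_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            ab.relative_composition(_peaks([0.0, 0.0]))

    @given(st.lists(st.floats(0.01, 1e6), min_size=1, max_size=12),
           st.floats(0.001, 1e3))
    def test_sums_to_100_and_scale_invariant(self, areas, c):
        comp = ab.relative_composition(_peaks(areas))
        assert comp.sum() == pytest.approx(100.0, abs=1e-9)
        scaled = ab.relative_composition(_peaks([a * c for a in areas]))
        assert np.allclose(comp.to_numpy(), scaled.to_numpy(), atol=1e-8)


class TestQualityReplicateFilter:
    def test_confirmed_compound_retained(self, peak_frame):
        kept = ab.quality_replicate_filter(peak_frame)
        s1 = kept[kept.sample_id == "S1"]
        assert set(s1.compound) == {"methyl butanoate", "linalool"}

    def test_single_replicate_compound_removed(self, peak_frame):
        kept = ab.quality_replicate_filter(peak_frame)
        assert "hexanal" not in set(kept.compound)

    def test_quality_threshold_is_strict(self):
        # qualities (80, 95): the 80 does not count, leaving 1 < 2 replicates
        peaks = pd.concat([
            _peaks([10.0], rep=1, quality=80),
            _peaks([10.0], rep=2, quality=95),
            _peaks([10.0], rep=3, quality=60),
        ])
        kept = ab.quality_replicate_filter(peaks)
        assert kept.empty

    def test_min_replicates_above_design_is_config_error(self, peak_frame):
        with pytest.raises(ConfigurationError):
            ab.quality_replicate_filter(peak_frame, min_replicates=4)


class TestAggregateReplicates:
    @staticmethod
    def _long(values, compound="c0", sample="S1"):
        return pd.DataFrame({
            "sample_id": sample,
            "replicate": range(1, len(values) + 1),
            "compound": compound,
            "pct": values,
        })

    def test_constant_replicates(self):
        pheno = ab.aggregate_replicates(self._long([10.0, 10.0, 10.0]))
        assert pheno.means.loc["S1", "c0"] == 10.0
        assert pheno.sds.loc["S1", "c0"] == 0.0

    def test_two_replicates_hand_arithmetic(self):
        pheno = ab.aggregate_replicates(self._long([0.0, 10.0]))
        assert pheno.means.loc["S1", "c0"] == 5.0
        assert pheno.sds.loc["S1", "c0"] == pytest.approx(7.0711, abs=1e-4)

    def test_single_replicate_flagged_sd_zero(self):
        pheno = ab.aggregate_replicates(self._long([4.8]))
        assert pheno.means.loc["S1", "c0"] == 4.8
        assert pheno.sds.loc["S1", "c0"] == 0.0
        assert bool(pheno.single_replicate.loc["S1", "c0"])

    def test_missing_compound_counts_as_zero(self):
        long = pd.concat([
            self._long([60.0], "c0"),
            pd.DataFrame({"sample_id": ["S1"], "replicate": [2],
                          "compound": ["c1"], "pct": [100.0]}),
        ])
        pheno = ab.aggregate_replicates(long)
        assert pheno.means.loc["S1", "c0"] == 30.0  # (60 + 0) / 2


def _tables_from_summary(row):
    """Phenotype + parent tables realising one published summary row."""
    f1 = ab.PhenotypeTable(
        means=pd.DataFrame({row.compound: [row.f1_min, row.f1_mean,
                                           row.f1_max]},
                           index=["a", "b", "c"]),
        sds=pd.DataFrame({row.compound: [0.0] * 3}, index=["a", "b", "c"]),
        counts=pd.DataFrame({row.compound: [3] * 3}, index=["a", "b", "c"]),
    )
    parents = ab.PhenotypeTable(
        means=pd.DataFrame({row.compound: [row.p1_mean, row.p2_mean]},
                           index=["07-102-41", "Juliette"]),
        sds=pd.DataFrame({row.compound: [row.p1_sd, row.p2_sd]},
                         index=["07-102-41", "Juliette"]),
        counts=pd.DataFrame({row.compound: [3, 3]},
                            index=["07-102-41", "Juliette"]),
    )
    return f1, parents


class TestSummarizeCompound:
    def test_all_zero_not_transgressive(self):
        f1 = ab.PhenotypeTable(
            means=pd.DataFrame({"c": [0.0, 0.0]}, index=["a", "b"]),
            sds=pd.DataFrame({"c": [0.0, 0.0]}, index=["a", "b"]),
            counts=pd.DataFrame({"c": [3, 3]}, index=["a", "b"]),
        )
        parents = ab.PhenotypeTable(
            means=pd.DataFrame({"c": [0.0, 0.0]}, index=["p1", "p2"]),
            sds=pd.DataFrame({"c": [0.0, 0.0]}, index=["p1", "p2"]),
            counts=pd.DataFrame({"c": [3, 3]}, index=["p1", "p2"]),
        )
        s = ab.summarize_compound(f1, parents, "c")
        assert s.f1_mean == 0.0
        assert not s.transgressive
        assert s.significance == "undefined"

    def test_methyl_butanoate_row_is_transgressive(self):
        summary = ab.studydata.phenotype_summary()
        row = summary[summary.compound == "methyl butanoate"].iloc[0]
        f1, parents = _tables_from_summary(row)
        s = ab.summarize_compound(f1, parents, row.compound)
        assert s.transgressive  # F1 max 34.3 above both parental means

    def test_nerolidol_row_is_not_transgressive(self):
        summary = ab.studydata.phenotype_summary()
        row = summary[summary.compound == "(E)-nerolidol"].iloc[0]
        f1, parents = _tables_from_summary(row)
        s = ab.summarize_compound(f1, parents, row.compound)
        assert not s.transgressive  # F1 range inside 17.4..60.6

    def test_missing_compound_raises(self, bundle):
        with pytest.raises(KeyError):
            ab.summarize_compound(bundle.pheno, bundle.parents, "nope")

    def test_widening_parental_interval_never_creates_transgression(self):
        summary = ab.studydata.phenotype_summary()
        for row in summary.itertuples():
            f1, parents = _tables_from_summary(row)
            base = ab.summarize_compound(f1, parents, row.compound)
            wider = parents.means.copy()
            wider.iloc[0, 0] = min(wider.iloc[0, 0], row.f1_min) - 1.0
            wider.iloc[0, 0] = max(wider.iloc[0, 0], 0.0)
            wider.iloc[1, 0] = min(wider.iloc[1, 0] + 20.0, 100.0)
            parents2 = ab.PhenotypeTable(means=wider, sds=parents.sds,
                                         counts=parents.counts)
            wide = ab.summarize_compound(f1, parents2, row.compound)
            assert base.transgressive or not wide.transgressive


class TestSelectTargetCompounds:
    @staticmethod
    def _summary(compound, mean, p):
        return ab.CompoundSummary(
            compound=compound, f1_mean=mean, f1_min=0.0, f1_max=mean * 2,
            parent1_mean=1.0, parent1_sd=0.1, parent2_mean=0.0,
            parent2_sd=0.0, t=None if p is None else 5.0, df=4.0, p=p,
            significance=ab.gcms.significance_class(p), transgressive=True)

    def test_low_mean_excluded(self):
        out = ab.select_target_compounds([self._summary("rare", 0.05, 0.001)])
        assert out == []

    def test_significant_abundant_compound_retained(self):
        out = ab.select_target_compounds([self._summary("mb", 9.4, 0.03)])
        assert out == ["mb"]

    def test_undefined_parental_contrast_excluded(self):
        out = ab.select_target_compounds([self._summary("x", 5.0, None)])
        assert out == []

    def test_empty_input(self):
        assert ab.select_target_compounds([]) == []

    def test_sorted_by_mean_descending(self):
        out = ab.select_target_compounds([
            self._summary("lo", 1.0, 0.01), self._summary("hi", 9.0, 0.01)])
        assert out == ["hi", "lo"]


class TestFrequencyHistogram:
    def test_all_zero_values_in_first_bin(self):
        edges, counts = ab.frequency_histogram([0, 0, 0], 5)
        assert counts[0] == 3

    def test_hand_binning(self):
        edges, counts = ab.frequency_histogram([1, 9, 11], 10)
        assert list(counts) == [2, 1]
        assert list(edges) == [0, 10, 20]

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ConfigurationError):
            ab.frequency_histogram([1.0], 0.0)

    @given(st.lists(st.floats(0, 100), max_size=60),
           st.floats(0.5, 30))
    def test_counts_conserved(self, values, width):
        _, counts = ab.frequency_histogram(values, width)
        assert counts.sum() == len(values)


def test_profile_peaks_end_to_end(peak_frame):
    pheno = ab.profile_peaks(peak_frame)
    assert set(pheno.individuals) == {"S1", "S2"}
    # S1 keeps methyl butanoate + linalool; each replicate sums to 100
    row = pheno.means.loc["S1"]
    assert row.sum() == pytest.approx(100.0, abs=1e-9)


def test_phenotype_table_tsv_roundtrip(tmp_path, bundle):
    path = tmp_path / "pheno.tsv"
    bundle.pheno.to_tsv(path)
    back = ab.PhenotypeTable.from_tsv(path)
    assert back.individuals == bundle.pheno.individuals
    assert np.allclose(back.means.to_numpy(), bundle.pheno.means.to_numpy(),
                       atol=1e-9)
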