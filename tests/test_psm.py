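"""GlycoPSM table dialects and Lewis spectral counting."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from glycoshock.errors import GlycoshockError
from glycoshock.psm import (
    GlycoPSMTable,
    lewis_level,
    narrow_filter,
    protein_lewis_distribution,
    protein_lewis_level,
    read_glycopsm_table,
    score_filter,
)
from glycoshock.spectra import DiagnosticIonConfig, SpectrumRecord
from glycoshock.synthetic import (
    CohortSpec,
    GlycoPSMSetSpec,
    generate_cohort,
    generate_glycopsm_table,
)


def _canonical_df(rows):
    return pd.DataFrame(
        rows,
        columns=["sample_id", "scan_id", "peptide", "protein", "site",
                 "composition", "fucose_type", "score"],
    )


@pytest.fixture()
def small_table():
    rows = []
    for i in range(10):
        ftype = "lewis" if i < 3 else ("core" if i < 6 else "none")
        comp = "HexNAc4Hex5Fuc1NeuAc1" if ftype != "none" else "HexNAc4Hex5NeuAc2"
        prot = "AGP1" if i < 2 else "HP"
        rows.append(("s1", f"scan{i}", "PEPK", prot, 100, comp, ftype, 200.0))
    return GlycoPSMTable(df=_canonical_df(rows)).validate()


class TestReadTable:
    def test_canonical_round_trip(self, small_table, tmp_path):
        path = tmp_path / "psms.tsv"
        small_table.df.to_csv(path, sep="\t", index=False)
        back = read_glycopsm_table(path)
        assert len(back) == 10
        assert back.dialect == "canonical"

    def test_igpa_like_fucose_class_mapped(self, tmp_path):
        df = pd.DataFrame(
            {
                "SampleID": ["s1", "s1"],
                "ScanNum": [1, 2],
                "PeptideSeq": ["PEPK", "PEPR"],
                "ProteinID": ["AGP1", "HP"],
                "GlySite": [75, 211],
                "GlycanComposition": ["HexNAc4Hex5Fuc1NeuAc1", "HexNAc4Hex5NeuAc2"],
                "FucoseClass": ["Lewis", "None"],
                "SScore": [99.1, 98.5],
            }
        )
        path = tmp_path / "igpa.tsv"
        df.to_csv(path, sep="\t", index=False)
        table = read_glycopsm_table(path, dialect="igpa_like")
        assert list(table.df["fucose_type"]) == ["lewis", "none"]

    def test_byonic_like_derives_fucose_type_from_composition(self, tmp_path):
        df = pd.DataFrame(
            {
                "Sample": ["s1", "s1"],
                "Scan #": [1, 2],
                "Peptide": ["PEPK", "PEPR"],
                "Protein Name": ["AGP1", "HP"],
                "Glycan Site": [75, 211],
                "Glycans": ["HexNAc4Hex5Fuc1NeuAc1", "HexNAc4Hex5NeuAc2"],
                "Score": [350.0, 200.0],
            }
        )
        path = tmp_path / "byo.tsv"
        df.to_csv(path, sep="\t", index=False)
        table = read_glycopsm_table(path, dialect="byonic_like")
        assert list(table.df["fucose_type"]) == ["ambiguous", "none"]

    def test_missing_protein_column_named_in_error(self, tmp_path):
        df = _canonical_df([("s1", "1", "PEPK", "AGP1", 1,
                             "HexNAc4Hex5NeuAc2", "none", 1.0)]).drop(columns="protein")
        path = tmp_path / "broken.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(GlycoshockError, match="protein"):
            read_glycopsm_table(path)

    def test_lewis_row_without_fucose_rejected(self):
        df = _canonical_df(
            [("s1", "1", "PEPK", "AGP1", 1, "HexNAc4Hex5NeuAc2", "lewis", 1.0)]
        )
        with pytest.raises(GlycoshockError):
            GlycoPSMTable(df=df).validate()


class TestLewisLevel:
    def test_fraction_of_lewis_rows(self, small_table):
        assert lewis_level(small_table)["s1"] == pytest.approx(0.3)

    def test_all_lewis(self):
        df = _canonical_df(
            [("s1", str(i), "PEPK", "AGP1", 1, "HexNAc4Hex5Fuc1NeuAc1", "lewis", 1.0)
             for i in range(4)]
        )
        assert lewis_level(GlycoPSMTable(df=df))["s1"] == 1.0

    def test_ambiguous_in_denominator_only_by_default(self):
        rows = [("s1", "1", "P", "A", 1, "HexNAc4Hex5Fuc1NeuAc1", "lewis", 1.0),
                ("s1", "2", "P", "A", 1, "HexNAc4Hex5Fuc1NeuAc1", "ambiguous", 1.0)]
        table = GlycoPSMTable(df=_canonical_df(rows))
        assert lewis_level(table)["s1"] == pytest.approx(0.5)
        assert lewis_level(table, include_ambiguous=True)["s1"] == 1.0

    def test_missing_sample_listed(self, small_table):
        with pytest.raises(GlycoshockError, match="s2"):
            lewis_level(small_table, samples=["s1", "s2"])

    def test_invariant_to_row_order_and_duplication(self, small_table):
        level = lewis_level(small_table)["s1"]
        shuffled = GlycoPSMTable(df=small_table.df.sample(frac=1, random_state=0))
        doubled = GlycoPSMTable(
            df=pd.concat([small_table.df, small_table.df], ignore_index=True)
        )
        assert lewis_level(shuffled)["s1"] == pytest.approx(level)
        assert lewis_level(doubled)["s1"] == pytest.approx(level)

    def test_configured_fraction_recovered_from_generator(self):
        cohort = generate_cohort(CohortSpec(n_survivors=2, n_nonsurvivors=1, seed=4))
        spec = GlycoPSMSetSpec(
            n_psms_per_sample=200,
            lewis_fraction_by_group_day={
                (g, d): 0.25
                for g in ("survivor", "nonsurvivor") for d in range(1, 10)
            },
            seed=4,
        )
        table, manifest = generate_glycopsm_table(cohort, spec)
        levels = lewis_level(table)
        for sid, truth in manifest["per_sample"].items():
            assert levels[sid] == pytest.approx(truth["lewis_fraction"])
            assert truth["lewis_fraction"] == pytest.approx(0.25)


class TestProteinDistribution:
    def test_hand_counts(self):
        rows = [("s1", str(i), "P", "AGP1", 1, "HexNAc4Hex5Fuc1NeuAc1", "lewis", 1.0)
                for i in range(3)]
        rows.append(("s1", "x", "P", "HP", 1, "HexNAc4Hex5Fuc1NeuAc1", "lewis", 1.0))
        shares = protein_lewis_distribution(GlycoPSMTable(df=_canonical_df(rows)))
        assert shares["AGP1"] == pytest.approx(0.75)
        assert shares["HP"] == pytest.approx(0.25)
        assert shares.sum() == pytest.approx(1.0)
        assert list(shares.index) == ["AGP1", "HP"]

    def test_single_protein(self):
        rows = [("s1", "1", "P", "AGP1", 1, "HexNAc4Hex5Fuc1NeuAc1", "lewis", 1.0)]
        shares = protein_lewis_distribution(GlycoPSMTable(df=_canonical_df(rows)))
        assert dict(shares) == {"AGP1": 1.0}

    def test_no_lewis_rows_rejected(self):
        rows = [("s1", "1", "P", "AGP1", 1, "HexNAc4Hex5NeuAc2", "none", 1.0)]
        with pytest.raises(GlycoshockError):
            protein_lewis_distribution(GlycoPSMTable(df=_canonical_df(rows)))

    def test_generator_shares_within_binomial_ci(self):
        """Multinomial protein assignment recovers configured shares (99% CI)."""
        cohort = generate_cohort(CohortSpec(n_survivors=8, n_nonsurvivors=4, seed=6))
        spec = GlycoPSMSetSpec(
            n_psms_per_sample=400,
            protein_shares_among_lewis={"AGP1": 0.75, "HP": 0.25},
            seed=6,
        )
        table, _ = generate_glycopsm_table(cohort, spec)
        lewis_rows = table.df[table.df["fucose_type"] == "lewis"]
        n = len(lewis_rows)
        count_agp1 = int((lewis_rows["protein"] == "AGP1").sum())
        lo, hi = binom.ppf([0.005, 0.995], n, 0.75)
        assert lo <= count_agp1 <= hi


class TestProteinLewisLevel:
    def test_per_sample_fraction_and_partition_identity(self, small_table):
        agp1 = protein_lewis_level(small_table, "AGP1")
        assert agp1["s1"] == pytest.approx(0.2)
        total = sum(
            protein_lewis_level(small_table, p)["s1"]
            for p in small_table.df["protein"].unique()
        )
        assert total == pytest.approx(lewis_level(small_table)["s1"])

    def test_absent_protein_warns_and_returns_zeros(self, small_table):
        with pytest.warns(UserWarning):
            levels = protein_lewis_level(small_table, "TF")
        assert (levels == 0).all()


def _spectra_with_hits(n, hit_indices, sample="s1"):
    records = {}
    for i in range(n):
        peaks = [(900.0, 100.0), (300.0, 20.0)]
        if i in hit_indices:
            peaks.append((512.205, 50.0))
        records[(sample, f"scan{i}")] = SpectrumRecord(
            sample_id=sample, scan_id=f"scan{i}", precursor_mz=900.0, charge=2,
            peaks=np.asarray(sorted(peaks)),
        )
    return records


class TestNarrowFilter:
    def test_retains_rows_whose_spectra_carry_the_ion(self, small_table):
        spectra = _spectra_with_hits(10, {0, 2, 5, 7})
        out = narrow_filter(small_table, spectra)
        assert len(out) == 4
        assert set(out.df["scan_id"]) == {"scan0", "scan2", "scan5", "scan7"}

    def test_no_ion_anywhere_empty_result(self, small_table):
        out = narrow_filter(small_table, _spectra_with_hits(10, set()))
        assert len(out) == 0

    def test_monotone_in_tolerance(self, small_table, rng):
        # jittered ion positions: widening the window only adds rows
        spectra = {}
        for i in range(10):
            mz = 512.20 + rng.uniform(-0.3, 0.3)
            spectra[("s1", f"scan{i}")] = SpectrumRecord(
                sample_id="s1", scan_id=f"scan{i}", precursor_mz=900.0, charge=2,
                peaks=np.asarray([(mz, 50.0), (900.0, 100.0)]),
            )
        narrow = narrow_filter(
            small_table, spectra,
            DiagnosticIonConfig(targets=(512.20,), tolerance_value=0.02),
        )
        wide = narrow_filter(
            small_table, spectra,
            DiagnosticIonConfig(targets=(512.20,), tolerance_value=0.5),
        )
        assert set(narrow.df["scan_id"]) <= set(wide.df["scan_id"])

    def test_unresolvable_scan_error_or_skip(self, small_table):
        spectra = _spectra_with_hits(5, {0})
        with pytest.raises(GlycoshockError):
            narrow_filter(small_table, spectra, on_missing="error")
        with pytest.warns(UserWarning):
            out = narrow_filter(small_table, spectra, on_missing="skip")
        assert len(out) == 1


def test_score_filter_thresholds(small_table):
    table = small_table
    table.df.loc[table.df.index[:4], "score"] = 50.0
    assert len(score_filter(table, 100.0)) == 6
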