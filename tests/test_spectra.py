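"""MGF I/O and diagnostic-ion scanning."""

import numpy as np
import pytest
from pyteomics import mgf as pyteomics_mgf

from glycoshock.errors import MalformedSpectrumError
from glycoshock.spectra import (
    DiagnosticIonConfig,
    SpectrumRecord,
    diagnostic_fraction,
    lex_lea_intensity_pairs,
    read_mgf,
    scan_spectrum,
    write_mgf,
)
from glycoshock.stats import wilcoxon_signed_rank
from glycoshock.synthetic import SpectrumSetSpec, generate_spectra


def _record(peaks, sample="S", scan="1", precursor=900.0):
    return SpectrumRecord(
        sample_id=sample, scan_id=scan, precursor_mz=precursor, charge=2,
        peaks=np.asarray(peaks, dtype=float),
    )


class TestMgfIO:
    def test_round_trip_preserves_counts_and_peaks(self, tmp_path):
        records = [
            _record([(300.1, 10.0), (512.205, 55.0), (900.0, 100.0)], scan="a"),
            _record([(250.0, 1.0)], scan="b"),
            _record([(100.0, 5.0), (200.0, 7.0)], scan="c"),
        ]
        path = tmp_path / "three.mgf"
        write_mgf(records, path)
        back = read_mgf(path)
        assert len(back) == 3
        for orig, rec in zip(records, back):
            assert rec.scan_id == orig.scan_id
            np.testing.assert_allclose(rec.peaks, orig.peaks)

    def test_round_trip_agrees_with_pyteomics(self, tmp_path):
        records = [_record([(300.1, 10.0), (512.2, 55.0)], scan="x")]
        path = tmp_path / "one.mgf"
        write_mgf(records, path)
        spectra = list(pyteomics_mgf.read(str(path)))
        assert len(spectra) == 1
        np.testing.assert_allclose(spectra[0]["m/z array"], [300.1, 512.2])

    def test_empty_file_yields_empty_stream(self, tmp_path):
        path = tmp_path / "empty.mgf"
        path.write_text("")
        assert read_mgf(path) == []

    def test_missing_end_ions_reports_block(self, tmp_path):
        path = tmp_path / "bad.mgf"
        path.write_text(
            "BEGIN IONS\nTITLE=s:1\nPEPMASS=900\n100 5\nEND IONS\n"
            "BEGIN IONS\nTITLE=s:2\nPEPMASS=901\n100 5\n"
        )
        with pytest.raises(MalformedSpectrumError) as err:
            read_mgf(path)
        assert err.value.block_index == 1

    def test_missing_pepmass_rejected(self, tmp_path):
        path = tmp_path / "nopm.mgf"
        path.write_text("BEGIN IONS\nTITLE=s:1\n100 5\nEND IONS\n")
        with pytest.raises(MalformedSpectrumError):
            read_mgf(path)

    def test_non_numeric_peak_line_rejected(self, tmp_path):
        path = tmp_path / "peak.mgf"
        path.write_text("BEGIN IONS\nTITLE=s:1\nPEPMASS=900\nabc def\nEND IONS\n")
        with pytest.raises(MalformedSpectrumError):
            read_mgf(path)

    def test_missing_charge_tolerated(self, tmp_path):
        path = tmp_path / "nocharge.mgf"
        path.write_text("BEGIN IONS\nTITLE=s:1\nPEPMASS=900\n100 5\nEND IONS\n")
        rec = read_mgf(path)[0]
        assert rec.charge is None
        assert rec.sample_id == "s" and rec.scan_id == "1"


class TestScanSpectrum:
    def test_peak_above_threshold_inside_window_hits(self):
        rec = _record([(512.205, 50.0), (900.0, 100.0)])
        report = scan_spectrum(rec, DiagnosticIonConfig.manual_hcd())
        hit = report.hits[512.20]
        assert hit.hit and hit.matched_mz == pytest.approx(512.205)
        assert hit.relative_intensity == pytest.approx(0.5)

    def test_intensity_threshold_is_strict(self):
        # exactly 1% of the base peak does not pass ">1%"
        rec = _record([(512.205, 1.0), (900.0, 100.0)])
        assert not scan_spectrum(rec, DiagnosticIonConfig.manual_hcd()).has_hit(512.20)

    def test_peak_outside_window_misses(self):
        rec = _record([(512.215, 99.0), (900.0, 100.0)])
        assert not scan_spectrum(rec, DiagnosticIonConfig.manual_hcd()).has_hit(512.20)

    def test_window_boundary_inclusive(self):
        rec = _record([(512.21, 50.0), (900.0, 100.0)])
        assert scan_spectrum(rec, DiagnosticIonConfig.manual_hcd()).has_hit(512.20)

    def test_most_intense_qualifying_peak_reported_tie_to_lower_mz(self):
        rec = _record([(512.195, 40.0), (512.205, 40.0), (900.0, 100.0)])
        hit = scan_spectrum(rec, DiagnosticIonConfig.manual_hcd()).hits[512.20]
        assert hit.matched_mz == pytest.approx(512.195)

    def test_empty_spectrum_rejected(self):
        rec = _record([(100.0, 1.0)])
        rec.peaks = np.empty((0, 2))
        with pytest.raises(ValueError):
            scan_spectrum(rec, DiagnosticIonConfig.manual_hcd())

    def test_ppm_and_absolute_modes_agree_at_matched_width(self, rng):
        # 0.01 Th at m/z 512.20 equals 512.20 * 19.527 ppm * 1e-6
        th_cfg = DiagnosticIonConfig(targets=(512.20,), tolerance_value=0.01)
        ppm_cfg = DiagnosticIonConfig(
            targets=(512.20,), tolerance_mode="ppm",
            tolerance_value=0.01 / 512.20 * 1e6,
        )
        for _ in range(200):
            mz = 512.20 + rng.uniform(-0.03, 0.03)
            rec = _record([(mz, 50.0), (900.0, 100.0)])
            assert scan_spectrum(rec, th_cfg).has_hit(512.20) == scan_spectrum(
                rec, ppm_cfg
            ).has_hit(512.20)

    def test_agrees_with_brute_force_scan(self, rng):
        """Randomized spectra: result identical to scanning every peak."""
        cfg = DiagnosticIonConfig(
            targets=(512.20, 803.29), tolerance_value=0.05,
            min_relative_intensity=0.01, min_absolute_intensity=2.0,
            top_n_restriction=20, snr_requirement=3.0,
        )
        for _ in range(100):
            n = rng.integers(5, 60)
            mz = rng.uniform(100, 1200, n)
            if rng.random() < 0.5:  # plant near-target peaks often
                mz[0] = 512.20 + rng.uniform(-0.1, 0.1)
            inten = rng.uniform(0.1, 100.0, n)
            rec = _record(np.column_stack([mz, inten]))
            report = scan_spectrum(rec, cfg)
            # brute force over all peaks
            base = rec.peaks[:, 1].max()
            med = np.median(rec.peaks[:, 1])
            order = np.argsort(-rec.peaks[:, 1], kind="stable")[:20]
            top = set(order.tolist())
            for target in cfg.targets:
                best = None
                for i, (m, it) in enumerate(rec.peaks):
                    if abs(m - target) > 0.05:
                        continue
                    if not (it > 0.01 * base and it >= 2.0 and it >= 3.0 * med):
                        continue
                    if i not in top:
                        continue
                    if best is None or it > best[1]:
                        best = (m, it)
                hit = report.hits[target]
                assert hit.hit == (best is not None)
                if best is not None:
                    assert hit.matched_intensity == pytest.approx(best[1])

    def test_tic_fraction_gate_clears_weak_hits(self):
        rec = _record([(512.205, 5.0), (900.0, 100.0)])
        gated = DiagnosticIonConfig(
            targets=(512.20,), tolerance_value=0.01, tic_fraction_cap=0.20
        )
        assert not scan_spectrum(rec, gated).has_hit(512.20)


class TestDiagnosticFraction:
    def test_engineered_fraction_recovered_exactly(self, tmp_path):
        spec = SpectrumSetSpec(n_spectra=100, target_ions=(512.20,),
                               hit_fraction_per_target=0.4, seed=3)
        path = tmp_path / "sim.mgf"
        manifest = generate_spectra(spec, path)
        records = read_mgf(path)
        frac = diagnostic_fraction(
            records, DiagnosticIonConfig(targets=(512.20,), tolerance_value=0.01)
        )
        assert frac[512.20] == pytest.approx(0.40)
        assert manifest["targets"]["512.2"]["engineered_hits"] == 40

    def test_zero_and_subthreshold_fractions(self, tmp_path):
        for kwargs, expected in [
            (dict(hit_fraction_per_target=0.0), 0.0),
            (dict(hit_fraction_per_target=0.5, hit_relative_intensity=0.005), 0.0),
            (dict(hit_fraction_per_target=1.0), 1.0),
        ]:
            spec = SpectrumSetSpec(n_spectra=40, target_ions=(512.20,), seed=5, **kwargs)
            path = tmp_path / "f.mgf"
            generate_spectra(spec, path)
            frac = diagnostic_fraction(
                read_mgf(path),
                DiagnosticIonConfig(targets=(512.20,), tolerance_value=0.01),
            )
            assert frac[512.20] == pytest.approx(expected)

    def test_invariant_to_spectrum_order(self, tmp_path):
        spec = SpectrumSetSpec(n_spectra=30, target_ions=(512.20,),
                               hit_fraction_per_target=0.3, seed=9)
        path = tmp_path / "o.mgf"
        generate_spectra(spec, path)
        records = read_mgf(path)
        cfg = DiagnosticIonConfig(targets=(512.20,), tolerance_value=0.01)
        assert diagnostic_fraction(records, cfg) == diagnostic_fraction(
            records[::-1], cfg
        )

    def test_no_spectra_rejected(self):
        with pytest.raises(ValueError):
            diagnostic_fraction([], DiagnosticIonConfig.manual_hcd())


class TestLexLeaPairs:
    def test_single_ion_and_absent_ion_pairs(self):
        cfg = DiagnosticIonConfig.manual_cid()
        only_lex = _record([(364.21, 30.0), (900.0, 100.0)])
        neither = _record([(500.0, 30.0), (900.0, 100.0)])
        pairs = lex_lea_intensity_pairs([only_lex, neither], cfg)
        np.testing.assert_allclose(pairs[0], [30.0, 0.0])
        np.testing.assert_allclose(pairs[1], [0.0, 0.0])

    def test_engineered_lex_dominance_detected_by_wilcoxon(self, rng):
        # Lewis x ion three times the Lewis a ion in every one of 6 spectra:
        # one-sided exact signed-rank p = 1/64 < 0.05
        records = [
            _record([
                (364.2 + rng.uniform(-0.05, 0.05), 30.0 * (1 + 0.1 * i)),
                (348.2 + rng.uniform(-0.05, 0.05), 10.0 * (1 + 0.1 * i)),
                (900.0, 100.0),
            ])
            for i in range(6)
        ]
        pairs = lex_lea_intensity_pairs(records, DiagnosticIonConfig.manual_cid())
        res = wilcoxon_signed_rank(pairs[:, 0], pairs[:, 1], alternative="greater")
        assert res.p_value == pytest.approx(1 / 64)
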