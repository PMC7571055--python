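"""Peak-list I/O, profile peak detection and external calibration."""

import numpy as np
import pytest

import glutencaller as gc
from glutencaller.errors import CalibrationError, ParseError, ValidationError
from glutencaller.simulate import SimulationSpec, simulate_peaklist, \
    simulate_profile
from glutencaller.spectra import calibrate_two_point


class TestReadWrite:
    def test_reads_sorted_peaklist(self, tmp_path):
        f = tmp_path / "p.tsv"
        f.write_text("83488\t1000\n69410\t800\n")
        pl = gc.read_peaklist(f)
        assert [p.mass for p in pl.peaks] == [69410, 83488]
        assert not pl.calibrated

    def test_duplicate_mass_keeps_max_intensity(self, tmp_path):
        f = tmp_path / "p.csv"
        f.write_text("83488,100\n83488,900\n")
        pl = gc.read_peaklist(f, dialect="csv")
        assert len(pl) == 1
        assert pl.peaks[0].intensity == 900

    def test_snr_column_preserved(self, tmp_path):
        f = tmp_path / "p.tsv"
        f.write_text("mass_da\tintensity\tsnr\n83488\t1000\t12.5\n")
        pl = gc.read_peaklist(f)
        assert pl.peaks[0].snr == 12.5

    def test_non_numeric_cell_reports_line(self, tmp_path):
        f = tmp_path / "p.tsv"
        f.write_text("83488\t1000\noops\t9\n")
        with pytest.raises(ParseError, match=":2"):
            gc.read_peaklist(f)

    def test_empty_file_rejected(self, tmp_path):
        f = tmp_path / "p.tsv"
        f.write_text("")
        with pytest.raises(ValidationError):
            gc.read_peaklist(f)

    def test_write_read_round_trip(self, tmp_path):
        pl = gc.PeakList([gc.Peak(75_886.25, 10.0, 3.0),
                          gc.Peak(83_488.5, 20.0, 8.0)])
        gc.write_peaklist(pl, tmp_path / "out.tsv")
        back = gc.read_peaklist(tmp_path / "out.tsv")
        assert np.allclose(back.masses, pl.masses)


class TestDetectPeaks:
    def test_noiseless_recovery_within_one_da(self, lib):
        spec = SimulationSpec(composition=("N", "7g2+8", "2+12"),
                              relative_mass_sd=0.0, noise_sd=0.0,
                              baseline_level=0.0)
        profile = simulate_profile(lib, spec)
        pl = gc.detect_peaks(profile, min_snr=3, min_spacing_da=500,
                             smooth_window_da=30)
        truth = sorted(m for _, m in simulate_peaklist(lib, spec)[1].subunits)
        assert len(pl) == 4
        assert np.allclose(pl.masses, truth, atol=1.0)

    def test_flat_spectrum_has_no_peaks(self):
        mz = np.linspace(60_000, 110_000, 5_000)
        flat = gc.ProfileSpectrum(mz, np.full_like(mz, 7.0))
        assert len(gc.detect_peaks(flat)) == 0

    def test_spacing_filter_merges_close_gaussians(self):
        mz = np.arange(60_000, 110_000, 5.0)
        inten = (100 * np.exp(-0.5 * ((mz - 80_000) / 150) ** 2)
                 + 90 * np.exp(-0.5 * ((mz - 80_200) / 150) ** 2))
        pl = gc.detect_peaks(gc.ProfileSpectrum(mz, inten), min_snr=3,
                             min_spacing_da=500, smooth_window_da=30)
        assert len(pl) == 1

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            gc.detect_peaks(gc.ProfileSpectrum(np.arange(10.0) + 60_000,
                                               np.ones(10)))

    def test_recovery_over_random_genotypes(self, lib):
        """Across seeded noisy simulations every injected peak is found
        within 3x the injected mass SD and nothing spurious is kept."""
        from glutencaller.simulate import table_compositions

        pools = table_compositions(lib, "korean")
        rng = np.random.default_rng(42)
        for _ in range(25):
            comp = pools[rng.integers(len(pools))]
            spec = SimulationSpec(composition=comp, relative_mass_sd=0.0005,
                                  seed=int(rng.integers(2**31)))
            profile = simulate_profile(lib, spec)
            found = gc.detect_peaks(profile).masses
            injected = simulate_peaklist(lib, spec)[0].masses
            for t in injected:
                assert min(abs(found - t)) <= 3 * 0.0005 * t
            for g in found:
                assert min(abs(injected - g)) <= 3 * 0.0005 * g


class TestCalibration:
    def test_identity(self):
        pl = gc.PeakList([gc.Peak(83_000.0, 1.0)])
        out, model = gc.calibrate(pl, 66_463.0)
        assert model.scale == 1.0
        assert out.peaks[0].mass == 83_000.0
        assert out.calibrated

    def test_scale_arithmetic(self):
        pl = gc.PeakList([gc.Peak(83_000.0, 1.0)])
        out, model = gc.calibrate(pl, 66_529.463)   # standard read 0.1% high
        assert out.peaks[0].mass == pytest.approx(82_917.1, abs=0.1)

    def test_out_of_tolerance_rejected(self):
        pl = gc.PeakList([gc.Peak(83_000.0, 1.0)])
        with pytest.raises(CalibrationError):
            gc.calibrate(pl, 70_000.0)

    def test_order_and_count_preserved(self):
        pl = gc.PeakList([gc.Peak(m, 1.0) for m in
                          (69_410.0, 75_886.0, 83_488.0)])
        out, _ = gc.calibrate(pl, 66_500.0)
        assert len(out) == 3
        assert np.all(np.diff(out.masses) > 0)

    def test_two_point_linear(self):
        pl = gc.PeakList([gc.Peak(66_463.0, 1.0), gc.Peak(90_000.0, 1.0)])
        out, model = calibrate_two_point(pl, (66_400.0, 89_900.0),
                                         (66_463.0, 90_000.0))
        assert model.kind == "two-point"
        # scale = 23,537/23,500; 66,463 x scale - 41.545 = 66,526.10
        assert out.peaks[0].mass == pytest.approx(66_526.10, abs=0.05)
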