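import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from specbind.spectra import (
    EEMatrix,
    Spectrum,
    SpectrumParseError,
    find_3d_peaks,
    peak_of,
    read_spectrum,
    shift_metrics,
    write_spectrum,
)
from specbind.synthetic import gen_eem


def gauss_spectrum(center, amp, grid=None, kind="emission"):
    if grid is None:
        grid = np.arange(220.0, 500.0 + 1e-9, 1.0)
    return Spectrum(grid, amp * np.exp(-((grid - center) ** 2) / (2 * 18.0**2)), kind)


class TestSpectrumContainer:
    def test_decreasing_axis_normalised(self):
        s = Spectrum(np.array([1700.0, 1650.0, 1600.0]), np.array([1.0, 2.0, 3.0]), "ftir")
        assert np.array_equal(s.axis, [1600.0, 1650.0, 1700.0])
        assert np.array_equal(s.signal, [3.0, 2.0, 1.0])

    @pytest.mark.parametrize(
        "axis, signal, err",
        [
            ([280.0], [1.0], "at least 2"),
            ([280.0, 280.0], [1.0, 2.0], "monotone"),
            ([280.0, 281.0, 280.5], [1.0, 2.0, 3.0], "monotone"),
            ([280.0, 281.0], [1.0], "lengths differ"),
        ],
    )
    def test_invalid_inputs_rejected(self, axis, signal, err):
        with pytest.raises(ValueError, match=err):
            Spectrum(np.array(axis), np.array(signal), "emission")

    def test_absorbance_must_be_nonnegative(self):
        with pytest.raises(ValueError, match="non-negative"):
            Spectrum(np.array([280.0, 281.0]), np.array([0.1, -0.1]), "absorbance")


class TestReadWrite:
    def test_two_line_file(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("280,100\n281,99\n")
        s = read_spectrum(p, "emission")
        assert len(s) == 2
        assert np.array_equal(s.axis, [280.0, 281.0])
        assert np.array_equal(s.signal, [100.0, 99.0])

    def test_decreasing_wavenumber_file_reversed(self, tmp_path):
        p = tmp_path / "ftir.csv"
        p.write_text("1700,0.1\n1650,0.5\n1600,0.2\n")
        s = read_spectrum(p, "ftir")
        assert np.array_equal(s.axis, [1600.0, 1650.0, 1700.0])
        assert np.array_equal(s.signal, [0.2, 0.5, 0.1])
        assert "reversed" in s.label

    def test_parse_error_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("280,100\n281,abc\n282,98\n")
        with pytest.raises(SpectrumParseError, match="line 2"):
            read_spectrum(p, "emission")

    def test_single_point_rejected(self, tmp_path):
        p = tmp_path / "short.csv"
        p.write_text("280,100\n")
        with pytest.raises(ValueError, match="fewer than 2"):
            read_spectrum(p, "emission")

    @settings(derandomize=True, max_examples=25)
    @given(
        values=arrays(
            np.float64,
            st.integers(5, 30),
            elements=st.floats(-1e6, 1e6, allow_nan=False),
        )
    )
    def test_round_trip_full_precision(self, values, tmp_path_factory):
        tmp = tmp_path_factory.mktemp("rt")
        axis = np.linspace(200.0, 500.0, values.size)
        s = Spectrum(axis, values, "emission", label="rt")
        write_spectrum(s, tmp / "s.csv")
        back = read_spectrum(tmp / "s.csv", "emission")
        assert np.array_equal(back.axis, s.axis)
        assert np.array_equal(back.signal, s.signal)


class TestPeakMetrics:
    def test_constructed_maximum(self, gaussian_emission):
        lam, intensity = peak_of(gaussian_emission)
        assert lam == 327.0
        assert intensity == pytest.approx(1000.0)

    def test_flat_signal_tie_breaks_to_smaller_axis(self):
        s = Spectrum(np.arange(300.0, 310.0), np.ones(10), "emission")
        lam, _ = peak_of(s, (302.0, 308.0))
        assert lam == 302.0

    def test_window_outside_axis_errors(self, gaussian_emission):
        with pytest.raises(ValueError):
            peak_of(gaussian_emission, (600.0, 700.0))

    def test_peak_belongs_to_grid(self, gaussian_emission):
        lam, _ = peak_of(gaussian_emission)
        assert lam in gaussian_emission.axis

    def test_shift_metrics_identity(self, gaussian_emission):
        assert shift_metrics(gaussian_emission, gaussian_emission) == (0.0, 0.0)

    def test_red_shift_and_intensity_decrease(self):
        # native peak (330 nm, 1539 a.u.) vs complexed (320 nm, 1291 a.u.)
        ref = gauss_spectrum(330.0, 1539.0)
        pert = gauss_spectrum(320.0, 1291.0)
        dlam, pct = shift_metrics(ref, pert)
        assert dlam == -10.0
        assert pct == pytest.approx(16.11, abs=0.01)

    def test_percent_decrease_backbone_peak(self):
        ref = gauss_spectrum(330.0, 623.2)
        pert = gauss_spectrum(330.0, 478.6)
        _, pct = shift_metrics(ref, pert)
        assert pct == pytest.approx(23.20, abs=0.01)

    def test_zero_reference_intensity_errors(self):
        grid = np.arange(300.0, 310.0)
        zero = Spectrum(grid, np.zeros(10), "emission")
        with pytest.raises(ValueError, match="zero"):
            shift_metrics(zero, zero)

    def test_kind_mismatch_errors(self, gaussian_emission):
        other = gauss_spectrum(330.0, 1.0, kind="ellipticity")
        with pytest.raises(ValueError, match="kind"):
            shift_metrics(gaussian_emission, other)


class TestEEMPeaks:
    def test_single_blob_stokes_shift(self):
        eem = gen_eem([(280.0, 330.0, 1539.0)])
        peaks = find_3d_peaks(eem)
        assert len(peaks) == 1
        p = peaks[0]
        assert (p.excitation_nm, p.emission_nm) == (280.0, 330.0)
        assert p.stokes_shift_nm == 50.0
        assert p.intensity == pytest.approx(1539.0)

    def test_blob_on_rayleigh_diagonal_excluded(self):
        eem = gen_eem([(300.0, 300.0, 1000.0)])
        assert find_3d_peaks(eem, scatter_exclusion_halfwidth=10.0) == []

    def test_two_blobs_descending_intensity(self):
        eem = gen_eem([(230.0, 330.0, 623.2), (280.0, 330.0, 1539.0)])
        peaks = find_3d_peaks(eem)
        assert [p.intensity for p in peaks] == sorted(
            (p.intensity for p in peaks), reverse=True
        )
        assert peaks[0].excitation_nm == 280.0
        assert peaks[1].stokes_shift_nm == 100.0

    def test_negative_halfwidth_rejected(self):
        eem = gen_eem([(280.0, 330.0, 1.0)])
        with pytest.raises(ValueError):
            find_3d_peaks(eem, -1.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            EEMatrix(np.arange(3.0), np.arange(4.0), np.zeros((4, 3)))
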