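import numpy as np
import pytest

from specbind.conformation import (
    BandSpec,
    CdParams,
    alpha_helix_fraction,
    amide1_band_fit,
    mean_residue_ellipticity,
    synchronous_profile,
)
from specbind.spectra import Spectrum
from specbind.synthetic import GroundTruth, gen_cd, gen_ftir, gen_synchronous


class TestSynchronousProfile:
    def test_recovers_generating_constant_and_shift(self, truth):
        spectra, q = gen_synchronous(truth, 60.0, ksv=5.0e4, shift_total_nm=5.0)
        profile = synchronous_profile(spectra, q, 60.0)
        assert profile.quench_slope == pytest.approx(5.0e4, rel=1e-6)
        assert profile.peak_shift_nm == pytest.approx(5.0, abs=0.5)

    def test_tryptophan_offset_quenches_faster_than_tyrosine(self, truth):
        s60, q = gen_synchronous(truth, 60.0, ksv=5.0e4, shift_total_nm=5.0)
        s15, _ = gen_synchronous(truth, 15.0, ksv=1.0e4, shift_total_nm=3.0)
        p60 = synchronous_profile(s60, q, 60.0)
        p15 = synchronous_profile(s15, q, 15.0)
        assert p15.quench_slope < p60.quench_slope
        assert p15.peak_shift_nm == pytest.approx(3.0, abs=0.5)

    def test_identical_spectra_give_zero_slope_and_shift(self, truth):
        spectra, q = gen_synchronous(truth, 60.0, ksv=0.0, shift_total_nm=0.0)
        profile = synchronous_profile(spectra, q, 60.0)
        assert profile.quench_slope == pytest.approx(0.0, abs=1e-9)
        assert profile.peak_shift_nm == 0.0

    def test_too_few_spectra_rejected(self, truth):
        spectra, q = gen_synchronous(truth, 60.0, ksv=1e4, shift_total_nm=0.0)
        with pytest.raises(ValueError, match=">= 3"):
            synchronous_profile(spectra[:2], q[:2], 60.0)


class TestCircularDichroism:
    def test_unit_identity(self):
        p = CdParams(theta_obs_mdeg=10.0 * 2.5e-6 * 585 * 0.1, cp_mol_L=2.5e-6)
        assert mean_residue_ellipticity(p) == pytest.approx(1.0)

    def test_published_helix_content_inverts(self):
        p = CdParams(theta_obs_mdeg=-30.98, cp_mol_L=2.5e-6)
        mre = mean_residue_ellipticity(p)
        assert mre == pytest.approx(-21180, abs=10)
        assert alpha_helix_fraction(mre) == pytest.approx(59.24, abs=0.05)

    def test_doubling_path_length_halves_mre(self):
        a = CdParams(-30.0, 2.5e-6, path_length_cm=0.1)
        b = CdParams(-30.0, 2.5e-6, path_length_cm=0.2)
        assert mean_residue_ellipticity(b) == pytest.approx(
            mean_residue_ellipticity(a) / 2.0
        )

    @pytest.mark.parametrize("mre, pct", [(-4000.0, 0.0), (-33000.0, 100.0)])
    def test_anchors_exact(self, mre, pct):
        assert alpha_helix_fraction(mre) == pct

    def test_affine_between_anchors(self):
        mid = alpha_helix_fraction((-4000.0 - 33000.0) / 2.0)
        assert mid == pytest.approx(50.0)

    def test_out_of_range_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert alpha_helix_fraction(-40000.0) == 100.0

    def test_generator_round_trip(self, truth):
        spec, theta208 = gen_cd(truth, alpha_helix_percent=59.24)
        mre = mean_residue_ellipticity(CdParams(theta208, truth.cp_mol_L))
        assert alpha_helix_fraction(mre) == pytest.approx(59.24, abs=1e-9)


class TestAmideOneDecomposition:
    def test_two_band_recovery(self, truth):
        spec, fr = gen_ftir(
            truth, fractions={"alpha_helix": 60.0, "beta_sheet": 40.0},
            noise=0.001, seed=11,
        )
        ss = amide1_band_fit(spec)
        assert ss.fractions["alpha_helix"] == pytest.approx(60.0, abs=2.0)
        assert ss.fractions["beta_sheet"] == pytest.approx(40.0, abs=2.0)

    def test_single_band_is_pure_helix(self, truth):
        spec, _ = gen_ftir(truth, fractions={"alpha_helix": 100.0})
        ss = amide1_band_fit(spec)
        assert ss.fractions["alpha_helix"] == pytest.approx(100.0, abs=0.1)

    def test_fractions_sum_to_hundred(self, truth):
        spec, _ = gen_ftir(truth, noise=0.002, seed=5)
        ss = amide1_band_fit(spec)
        assert sum(ss.fractions.values()) == pytest.approx(100.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_five_band_recovery_across_seeds(self, truth, seed):
        spec, fr = gen_ftir(truth, noise=0.001, seed=seed)
        ss = amide1_band_fit(spec)
        for name, target in fr.items():
            assert ss.fractions[name] == pytest.approx(target, abs=3.0)

    def test_baseline_offset_does_not_bias_fractions(self, truth):
        spec, fr = gen_ftir(truth, fractions={"alpha_helix": 70.0, "beta_turn": 30.0})
        tilted = spec.with_signal(spec.signal + 0.05 + 1e-4 * (spec.axis - 1600.0))
        ss = amide1_band_fit(tilted)
        assert ss.fractions["alpha_helix"] == pytest.approx(70.0, abs=2.0)

    def test_fewer_bands_allowed(self, truth):
        spec, _ = gen_ftir(truth, fractions={"alpha_helix": 100.0})
        bands = [BandSpec("alpha_helix", 1654.0, (1650.0, 1658.0))]
        ss = amide1_band_fit(spec, bands=bands)
        assert ss.fractions["alpha_helix"] == pytest.approx(100.0, abs=0.1)

    def test_region_not_covered_rejected(self):
        grid = np.arange(1650.0, 1660.0)
        spec = Spectrum(grid, np.ones(grid.size), "ftir")
        with pytest.raises(ValueError, match="region"):
            amide1_band_fit(spec)
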