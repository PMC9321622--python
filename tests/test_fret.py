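import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specbind.fret import (
    FretConfig,
    donor_acceptor_distance,
    forster_radius,
    fret_chain,
    fret_validity,
    overlap_integral,
    transfer_efficiency,
)
from specbind.spectra import Spectrum
from specbind.synthetic import GroundTruth, gen_fret_pair


def gaussian_pair(step=0.5, donor_amp=1000.0):
    return gen_fret_pair(GroundTruth(donor_amplitude=donor_amp), grid_step_nm=step)


class TestEfficiency:
    def test_published_ratio(self):
        assert transfer_efficiency(0.8426, 1.0) == pytest.approx(0.1574)

    @pytest.mark.parametrize("f, f0, e", [(1.0, 1.0, 0.0), (0.5, 1.0, 0.5)])
    def test_anchors(self, f, f0, e):
        assert transfer_efficiency(f, f0) == pytest.approx(e)

    def test_negative_efficiency_rejected(self):
        with pytest.raises(ValueError):
            transfer_efficiency(1.2, 1.0)


class TestOverlapIntegral:
    def test_agrees_with_fine_grid_oracle(self):
        donor, acceptor, j_ref = gaussian_pair()
        j = overlap_integral(donor, acceptor)
        assert j == pytest.approx(j_ref, rel=1e-3)

    def test_zero_acceptor_gives_zero(self):
        donor, acceptor, _ = gaussian_pair()
        zero = acceptor.with_signal(np.zeros(len(acceptor)))
        assert overlap_integral(donor, zero) == 0.0

    def test_narrow_donor_limit(self):
        # delta-like donor at lambda0: J -> eps(lambda0) * lambda0^4
        lam0, eps0 = 340.0, 1.0e4
        grid = np.arange(300.0, 380.0, 0.01)
        donor = Spectrum(grid, np.exp(-((grid - lam0) ** 2) / (2 * 0.05**2)), "emission")
        acceptor = Spectrum(grid, np.full(grid.size, eps0), "molar_absorptivity")
        assert overlap_integral(donor, acceptor) == pytest.approx(
            eps0 * lam0**4, rel=1e-4
        )

    @settings(derandomize=True, max_examples=20)
    @given(scale=st.floats(1e-3, 1e3))
    def test_invariant_under_donor_rescaling(self, scale):
        donor, acceptor, _ = gaussian_pair()
        scaled = donor.with_signal(donor.signal * scale)
        assert overlap_integral(scaled, acceptor) == pytest.approx(
            overlap_integral(donor, acceptor), rel=1e-12
        )

    def test_second_order_convergence(self):
        _, _, j_ref = gaussian_pair(step=0.5)
        errs = []
        for step in (4.0, 2.0, 1.0):
            donor, acceptor, _ = gaussian_pair(step=step)
            errs.append(abs(overlap_integral(donor, acceptor) - j_ref))
        # halving the grid spacing should shrink the error ~4x
        assert errs[1] < errs[0] / 2.5
        assert errs[2] < errs[1] / 2.5

    def test_disjoint_ranges_rejected(self):
        a = Spectrum(np.arange(300.0, 320.0), np.ones(20), "emission")
        b = Spectrum(np.arange(400.0, 420.0), np.ones(20), "molar_absorptivity")
        with pytest.raises(ValueError, match="disjoint"):
            overlap_integral(a, b)


class TestForsterRadius:
    def test_zero_overlap(self):
        assert forster_radius(0.0) == 0.0

    def test_closed_form_standard_convention(self):
        j = 1.0e13
        cfg = FretConfig()
        expected_angstrom = (8.79e-5 * (2.0 / 3.0) * 1.336**-4 * 0.118 * j) ** (1 / 6)
        assert forster_radius(j, cfg) == pytest.approx(expected_angstrom / 10.0)

    def test_quantum_yield_scaling_law(self):
        j = 5.0e12
        r1 = forster_radius(j, FretConfig(phi=0.118))
        r2 = forster_radius(j, FretConfig(phi=0.236))
        assert r2 / r1 == pytest.approx(2.0 ** (1.0 / 6.0))

    def test_negative_overlap_rejected(self):
        with pytest.raises(ValueError):
            forster_radius(-1.0)


class TestDistance:
    def test_published_inversion(self):
        assert donor_acceptor_distance(0.1574, 2.3749) == pytest.approx(
            3.1411, abs=5e-5
        )

    def test_half_transfer_point(self):
        assert donor_acceptor_distance(0.5, 3.0) == pytest.approx(3.0)

    @settings(derandomize=True, max_examples=50)
    @given(e=st.floats(1e-6, 1 - 1e-6), r0=st.floats(0.1, 10.0))
    def test_mutual_inverse_with_efficiency(self, e, r0):
        r = donor_acceptor_distance(e, r0)
        back = r0**6 / (r0**6 + r**6)
        assert back == pytest.approx(e, rel=1e-12)

    def test_strictly_decreasing_in_efficiency(self):
        es = np.linspace(0.05, 0.95, 19)
        rs = [donor_acceptor_distance(e, 2.5) for e in es]
        assert all(a > b for a, b in zip(rs, rs[1:]))

    @pytest.mark.parametrize("bad_e", [0.0, 1.0, -0.1, 1.5])
    def test_efficiency_domain(self, bad_e):
        with pytest.raises(ValueError):
            donor_acceptor_distance(bad_e, 2.0)


class TestValidity:
    def test_published_pair_valid(self):
        assert fret_validity(3.1411, 2.3749) == (True, True)

    def test_long_distance_invalid(self):
        assert fret_validity(8.0, 2.3749) == (False, False)

    def test_ratio_boundary_is_strict(self):
        r0 = 2.0
        assert fret_validity(1.5 * r0, r0)[1] is False


def test_full_chain_consistency():
    donor, acceptor, _ = gaussian_pair()
    result = fret_chain(donor, acceptor, f=0.8426, f0=1.0)
    assert result.efficiency == pytest.approx(0.1574)
    assert result.r_nm == pytest.approx(
        donor_acceptor_distance(result.efficiency, result.r0_nm)
    )
    e_back = result.r0_nm**6 / (result.r0_nm**6 + result.r_nm**6)
    assert e_back == pytest.approx(result.efficiency, rel=1e-9)
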