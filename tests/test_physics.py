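"""Phase steering, path lengths and lossy-medium wave parameters."""

import numpy as np
import pytest

from hypersar import (
    ApplicatorGeometry,
    PhaseVector,
    SteeringTarget,
    antenna_angles,
    lossy_wavelength,
    path_lengths,
    steering_phases,
)
from hypersar.errors import DegenerateGeometryError, InvalidArgumentError

BRAIN_WAVELENGTH = 4.8  # cm, averaged brain tissue


class TestAntennaAngles:
    @pytest.mark.parametrize(
        "n, expected", [(1, 0.0), (7, np.pi / 2), (13, np.pi), (24, 2 * np.pi * 23 / 24)]
    )
    def test_formula_positions(self, n, expected):
        """theta_n = 2 (n-1) pi / N for the 24-antenna ring."""
        assert antenna_angles(24)[n - 1] == pytest.approx(expected)

    def test_uniform_strictly_increasing(self):
        th = antenna_angles(24)
        assert th[0] == 0.0 and th[-1] < 2 * np.pi
        assert np.allclose(np.diff(th), 2 * np.pi / 24)

    def test_invalid_count_rejected(self):
        with pytest.raises(InvalidArgumentError):
            antenna_angles(0)


class TestPathLengths:
    def test_centered_target_equidistant(self, geometry):
        r_in, r_en = path_lengths(geometry, SteeringTarget(0, 0, 0))
        assert np.allclose(r_in, 13.0)
        assert np.allclose(r_en, np.sqrt(13.0**2 + 4.2**2))

    def test_ring_gap_in_quadrature(self, geometry):
        """R_en^2 = R_in^2 + g^2 for every antenna and any target."""
        r_in, r_en = path_lengths(geometry, SteeringTarget(3.0, -2.0, 0.0))
        assert np.allclose(r_en**2, r_in**2 + geometry.ring_gap**2)
        assert np.all(r_en > r_in)

    def test_target_on_antenna_is_degenerate(self, geometry):
        th = geometry.angles[0]
        target = SteeringTarget(13 * np.cos(th), 13 * np.sin(th), 0.0)
        with pytest.raises(DegenerateGeometryError):
            path_lengths(geometry, target)


class TestSteeringPhases:
    def test_centered_target_inner_zero(self, geometry):
        pv = steering_phases(geometry, SteeringTarget(0, 0, 0), BRAIN_WAVELENGTH)
        assert np.allclose(pv.inner, 0.0, atol=1e-12)

    def test_centered_target_outer_value(self, geometry):
        """Outer phase = (2 pi / lambda) (sqrt(13^2 + 4.2^2) - 13), same for all."""
        pv = steering_phases(geometry, SteeringTarget(0, 0, 0), BRAIN_WAVELENGTH)
        expected = 2 * np.pi / 4.8 * (np.sqrt(13**2 + 4.2**2) - 13.0)
        assert np.allclose(pv.outer, expected)
        assert pv.outer[0] == pytest.approx(0.866, abs=1e-3)

    @pytest.mark.parametrize("k", [1, 5, 12, 23])
    def test_rotational_equivariance(self, geometry, k):
        """Rotating the target by k*2pi/24 cyclically permutes the phases by k."""
        lam = BRAIN_WAVELENGTH
        x, y = 2.5, -1.0
        a = 2 * np.pi * k / 24
        xr = x * np.cos(a) - y * np.sin(a)
        yr = x * np.sin(a) + y * np.cos(a)
        base = steering_phases(geometry, SteeringTarget(x, y, 0), lam)
        rot = steering_phases(geometry, SteeringTarget(xr, yr, 0), lam)
        assert np.allclose(rot.inner, np.roll(base.inner, k), atol=1e-9)
        assert np.allclose(rot.outer, np.roll(base.outer, k), atol=1e-9)

    def test_nonnegative_and_zero_min_over_grid(self, geometry):
        """Every target of the steering grid yields unwrapped phases >= 0 with
        a zero inner minimum, and 48 independent values."""
        for x in (-4, -2, 0, 2, 4, 6):
            for y in (-4, -2, 0, 2, 4, 6):
                pv = steering_phases(geometry, SteeringTarget(x, y, 0), BRAIN_WAVELENGTH)
                assert pv.flat.size == 48
                assert np.all(pv.flat >= 0)
                assert pv.inner.min() == pytest.approx(0.0, abs=1e-12)
                # where the inner minimum is attained the outer phase is > 0
                n0 = np.argmin(pv.inner)
                assert pv.outer[n0] > 0

    def test_invalid_wavelength_rejected(self, geometry):
        with pytest.raises(InvalidArgumentError):
            steering_phases(geometry, SteeringTarget(0, 0, 0), 0.0)


class TestPhaseVector:
    def test_expand_duplicates_outer_rings(self):
        pv = PhaseVector(inner=np.zeros(24), outer=np.full(24, 0.5))
        full = pv.expand(3)
        assert full.shape == (72,)
        assert np.allclose(full[24:48], full[48:])

    def test_negative_phases_rejected(self):
        with pytest.raises(InvalidArgumentError):
            PhaseVector(inner=np.zeros(24), outer=np.full(24, -0.1))


class TestLossyWavelength:
    def test_vacuum_limit(self):
        assert lossy_wavelength(1.0, 0.0, 915e6) == pytest.approx(32.76, abs=0.01)

    def test_lossless_reduces_to_sqrt_permittivity(self):
        lam = lossy_wavelength(49.0, 0.0, 915e6)
        assert lam == pytest.approx(32.764 / 7.0, abs=0.01)

    @pytest.mark.parametrize(
        "er, sigma, table_cm",
        [
            (11.3, 0.11, 9.7),   # fat
            (12.4, 0.15, 9.2),   # bone
            (55.0, 0.95, 4.4),   # muscle
            (38.8, 0.60, 5.2),   # white matter
            (52.7, 0.95, 4.4),   # gray matter
            (45.8, 0.77, 4.8),   # average of gray & white
        ],
    )
    def test_tissue_table_round_trip(self, er, sigma, table_cm):
        """The dispersion relation reproduces the tabulated tissue wavelengths
        at 915 MHz to within 0.05 cm."""
        assert lossy_wavelength(er, sigma, 915e6) == pytest.approx(table_cm, abs=0.05)

    def test_bounded_by_free_space(self, registry):
        c_over_f = 2.9979e8 / 915e6 * 100
        for t in registry.values():
            assert t.wavelength <= c_over_f + 1e-9
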