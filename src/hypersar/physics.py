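"""Phased-array geometry, lossy-medium wave parameters and phase steering.

The applicator is a cylindrical three-ring array of 24 dipole antennas per
ring (72 total) at 915 MHz.  The two external rings share one phase set, so a
steering configuration has 48 independent phases.  Phases are computed by the
path-difference method: each antenna's phase is proportional to its extra
propagation distance to the steering focus, relative to the closest inner-ring
antenna, measured in brain-tissue wavelengths.

Conventions
-----------
* Lengths are centimetres, phases radians, frequency hertz.
* Antenna index ``n`` is 1-based in the steering formulas and 0-based in all
  stored arrays; ``antenna_angles(N)[i]`` is the angle of formula index
  ``n = i + 1``.
* Steering phases are unwrapped non-negative path-difference phases; they are
  only reduced modulo 2*pi where they enter a complex exponential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_FREQUENCY_HZ, SPEED_OF_LIGHT, VACUUM_PERMITTIVITY
from .errors import DegenerateGeometryError, InvalidArgumentError

__all__ = [
    "ApplicatorGeometry",
    "SteeringTarget",
    "PhaseVector",
    "antenna_angles",
    "path_lengths",
    "steering_phases",
    "lossy_wavelength",
    "propagation_constants",
]


def propagation_constants(
    rel_permittivity: float, conductivity: float, frequency: float
) -> tuple[float, float]:
    """Phase and attenuation constants of a plane wave in a lossy dielectric.

    Returns ``(beta, alpha)`` in rad/cm and Np/cm, from the standard
    low-loss-to-conductor dispersion

    .. math::

        \\beta = \\frac{\\omega}{c}\\sqrt{\\frac{\\epsilon_r}{2}
            \\left(\\sqrt{1 + \\tan^2\\delta} + 1\\right)}, \\qquad
        \\alpha = \\frac{\\omega}{c}\\sqrt{\\frac{\\epsilon_r}{2}
            \\left(\\sqrt{1 + \\tan^2\\delta} - 1\\right)}

    with loss tangent ``tan(delta) = sigma / (omega eps0 eps_r)``.
    """
    if rel_permittivity < 1:
        raise InvalidArgumentError(
            f"relative permittivity must be >= 1, got {rel_permittivity}"
        )
    if conductivity < 0:
        raise InvalidArgumentError(f"conductivity must be >= 0, got {conductivity}")
    if frequency <= 0:
        raise InvalidArgumentError(f"frequency must be > 0, got {frequency}")
    omega = 2.0 * np.pi * frequency
    tan_delta = conductivity / (omega * VACUUM_PERMITTIVITY * rel_permittivity)
    root = np.sqrt(1.0 + tan_delta**2)
    beta_m = (omega / SPEED_OF_LIGHT) * np.sqrt(rel_permittivity * (root + 1.0) / 2.0)
    alpha_m = (omega / SPEED_OF_LIGHT) * np.sqrt(rel_permittivity * (root - 1.0) / 2.0)
    return beta_m / 100.0, alpha_m / 100.0  # per metre -> per cm


def lossy_wavelength(
    rel_permittivity: float, conductivity: float, frequency: float = DEFAULT_FREQUENCY_HZ
) -> float:
    """Wavelength ``2*pi/beta`` in a lossy dielectric, cm.

    For ``sigma = 0`` this reduces to ``c / (f * sqrt(eps_r))``; it is always
    bounded above by the free-space wavelength ``c/f``.
    """
    beta, _ = propagation_constants(rel_permittivity, conductivity, frequency)
    return 2.0 * np.pi / beta


def antenna_angles(n_ring: int) -> np.ndarray:
    """Angular positions ``theta_n = 2*(n-1)*pi/N`` of one antenna ring.

    Returns ``n_ring`` strictly increasing angles in ``[0, 2*pi)`` with
    uniform spacing ``2*pi/n_ring``.
    """
    if n_ring < 1:
        raise InvalidArgumentError(f"n_ring must be >= 1, got {n_ring}")
    return 2.0 * np.pi * np.arange(n_ring) / n_ring


@dataclass(frozen=True)
class ApplicatorGeometry:
    """Three-ring cylindrical phased-array applicator.

    Parameters
    ----------
    ring_radius
        Radius ``a`` of every ring from the z-axis, cm.
    ring_gap
        Axial spacing ``g`` between the central and each external ring, cm.
    antennas_per_ring
        Number of antennas per ring (default 24).
    n_rings
        Number of rings (default 3: central at z=0, external at z=+-g).
    frequency
        Operating frequency, Hz.
    """

    ring_radius: float = 13.0
    ring_gap: float = 4.2
    antennas_per_ring: int = 24
    n_rings: int = 3
    frequency: float = DEFAULT_FREQUENCY_HZ

    def __post_init__(self) -> None:
        if self.ring_radius <= 0 or self.ring_gap <= 0:
            raise InvalidArgumentError("ring_radius and ring_gap must be > 0")
        if self.antennas_per_ring < 1 or self.n_rings < 1:
            raise InvalidArgumentError("antennas_per_ring and n_rings must be >= 1")
        if self.n_rings != 1 and self.n_rings != 3:
            raise InvalidArgumentError("only 1 or 3 rings are supported")
        if self.frequency <= 0:
            raise InvalidArgumentError("frequency must be > 0")

    @property
    def n_antennas(self) -> int:
        return self.antennas_per_ring * self.n_rings

    @property
    def angles(self) -> np.ndarray:
        return antenna_angles(self.antennas_per_ring)

    @property
    def antenna_positions(self) -> np.ndarray:
        """All antenna positions, shape (n_antennas, 3), cm.

        Ordered central ring (z=0) first, then the upper (z=+g) and lower
        (z=-g) external rings, each in increasing angle order.
        """
        theta = self.angles
        ring = np.column_stack(
            [self.ring_radius * np.cos(theta), self.ring_radius * np.sin(theta), np.zeros_like(theta)]
        )
        if self.n_rings == 1:
            return ring
        upper = ring.copy()
        upper[:, 2] = self.ring_gap
        lower = ring.copy()
        lower[:, 2] = -self.ring_gap
        return np.vstack([ring, upper, lower])


@dataclass(frozen=True)
class SteeringTarget:
    """Steering focus coordinates (x0, y0, z0), cm."""

    x0: float
    y0: float
    z0: float = 0.0

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x0, self.y0, self.z0])


@dataclass(frozen=True)
class PhaseVector:
    """48 independent antenna phases: 24 inner-ring + 24 shared external-ring.

    All entries are non-negative unwrapped radians and at least one inner
    entry is exactly zero (the inner-ring minimum path is subtracted).
    """

    inner: np.ndarray
    outer: np.ndarray

    def __post_init__(self) -> None:
        inner = np.asarray(self.inner, dtype=float)
        outer = np.asarray(self.outer, dtype=float)
        object.__setattr__(self, "inner", inner)
        object.__setattr__(self, "outer", outer)
        if inner.shape != outer.shape or inner.ndim != 1:
            raise InvalidArgumentError("inner and outer must be 1-D of equal length")
        if np.any(inner < 0) or np.any(outer < 0):
            raise InvalidArgumentError("phases must be non-negative")
        if not np.isclose(inner.min(), 0.0, atol=1e-12):
            raise InvalidArgumentError("minimum inner phase must be zero")

    @property
    def flat(self) -> np.ndarray:
        """Concatenated (inner, outer) vector — length 48 for the default array."""
        return np.concatenate([self.inner, self.outer])

    def expand(self, n_rings: int = 3) -> np.ndarray:
        """Per-antenna phases in applicator order (central, upper, lower).

        The shared external phase set is duplicated onto both external rings,
        expanding 48 independent phases to 72 antenna phases.
        """
        if n_rings == 1:
            return self.inner.copy()
        return np.concatenate([self.inner, self.outer, self.outer])


def path_lengths(
    geometry: ApplicatorGeometry, target: SteeringTarget
) -> tuple[np.ndarray, np.ndarray]:
    """In-plane path lengths from each ring to the steering focus, cm.

    ``R_in[n]`` is the axial-plane distance from central-ring antenna ``n`` to
    ``(x0, y0)``; ``R_en[n]`` adds the ring gap in quadrature,
    ``R_en^2 = R_in^2 + g^2`` (the 3-D distance from an external-ring antenna
    to the in-plane focus).  The focus z-coordinate does not enter.
    """
    theta = geometry.angles
    dx = geometry.ring_radius * np.cos(theta) - target.x0
    dy = geometry.ring_radius * np.sin(theta) - target.y0
    r_in = np.hypot(dx, dy)
    if np.any(r_in < 1e-9):
        raise DegenerateGeometryError(
            "steering target coincides with an antenna position"
        )
    r_en = np.sqrt(r_in**2 + geometry.ring_gap**2)
    return r_in, r_en


def steering_phases(
    geometry: ApplicatorGeometry,
    target: SteeringTarget,
    brain_wavelength: float,
) -> PhaseVector:
    """Path-difference steering phases for a focus at ``target``.

    .. math::

        \\psi^{in}_n = \\frac{2\\pi}{\\lambda_{brain}}(R^{in}_n - \\min_m R^{in}_m),
        \\qquad
        \\psi^{en}_n = \\frac{2\\pi}{\\lambda_{brain}}(R^{en}_n - \\min_m R^{in}_m)

    so waves launched with these phase advances arrive in phase at the focus.
    """
    if brain_wavelength <= 0:
        raise InvalidArgumentError(
            f"brain wavelength must be > 0, got {brain_wavelength}"
        )
    r_in, r_en = path_lengths(geometry, target)
    k = 2.0 * np.pi / brain_wavelength
    r_min = r_in.min()
    return PhaseVector(inner=k * (r_in - r_min), outer=k * (r_en - r_min))
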