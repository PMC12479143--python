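"""Analytic electromagnetic forward surrogate.

Ground-truth SAR fields are produced by coherent superposition of attenuated
spherical waves: each antenna contributes

.. math::

    E_k(r) = A_k \\, \\frac{e^{-\\alpha(r)\\,d_k}}{d_k} \\,
             e^{-i(\\beta(r)\\, d_k - \\psi_k)}, \\qquad d_k = |r - r_k|

with the phase and attenuation constants ``beta, alpha`` evaluated from the
*local* tissue at the observation point, and SAR computed from the total
field as ``sigma |E|^2 / (2 rho)``.  The field is then rescaled globally so
the absorbed power ``sum_i rho_i SAR_i V_i`` equals the stated input power
(100 W by default).

This single-scatter model ignores reflection and refraction at layer
boundaries; it is a fast stand-in for a full-wave solver that preserves the
interference structure that makes phase steering (and hence the learning
task) meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError, ZeroFieldError
from .phantom import HeadPhantom
from .physics import ApplicatorGeometry, PhaseVector, propagation_constants

__all__ = ["SARField", "simulate_sar", "focus_location"]

#: Distance floor (cm) guarding the 1/d singularity at an antenna position.
DISTANCE_FLOOR_CM = 0.1


@dataclass
class SARField:
    """Per-point SAR values (W/kg) tied to a phantom.

    ``values[i]`` is the SAR at ``phantom.points[i]``; values are finite and
    non-negative, and sum (mass-weighted) to ``input_power`` watts when
    produced by :func:`simulate_sar`.
    """

    values: np.ndarray
    phantom: HeadPhantom
    input_power: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.shape[0] != self.phantom.n_points:
            raise InvalidArgumentError("values length must match phantom size")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("SAR values must be finite")
        if np.any(self.values < 0):
            raise InvalidArgumentError("SAR values must be non-negative")

    def absorbed_power(self) -> float:
        """Total absorbed power sum_i rho_i SAR_i V_i, watts."""
        rho = self.phantom.properties[:, 2]
        v_m3 = self.phantom.cell_volume * 1e-6  # cm^3 -> m^3
        return float(np.sum(rho * self.values * v_m3))


def simulate_sar(
    phantom: HeadPhantom,
    geometry: ApplicatorGeometry,
    phases: PhaseVector,
    amplitudes: np.ndarray | None = None,
    input_power: float = 100.0,
) -> SARField:
    """Synthetic ground-truth SAR field for one steering configuration.

    Parameters
    ----------
    phantom
        Head phantom providing points and local (eps_r, sigma, rho).
    geometry
        Applicator; the 48 independent phases are expanded to its 72 antennas
        by duplicating the shared external set onto both external rings.
    phases
        Steering phase vector.
    amplitudes
        Per-antenna weights (default: uniform 1).
    input_power
        Power the absorbed SAR integral is normalised to, W.
    """
    positions = geometry.antenna_positions  # (K, 3)
    psi = phases.expand(geometry.n_rings)  # (K,)
    if psi.shape[0] != positions.shape[0]:
        raise InvalidArgumentError(
            f"phase vector expands to {psi.shape[0]} antennas, geometry has "
            f"{positions.shape[0]}"
        )
    if amplitudes is None:
        amplitudes = np.ones(positions.shape[0])
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.shape != psi.shape:
        raise InvalidArgumentError("amplitudes must have one weight per antenna")
    if input_power <= 0:
        raise InvalidArgumentError("input_power must be > 0")

    pts = phantom.points
    eps_r = phantom.properties[:, 0]
    sigma = phantom.properties[:, 1]
    rho = phantom.properties[:, 2]

    # Local wave parameters per point (vectorised over the few unique tissues).
    beta = np.empty(phantom.n_points)
    alpha = np.empty(phantom.n_points)
    for er, sg in {(e, s) for e, s in zip(eps_r, sigma)}:
        sel = (eps_r == er) & (sigma == sg)
        b, a = propagation_constants(er, sg, geometry.frequency)
        beta[sel] = b
        alpha[sel] = a

    # Distances point -> antenna, (N, K), with singularity floor.
    d = np.linalg.norm(pts[:, None, :] - positions[None, :, :], axis=2)
    d = np.maximum(d, DISTANCE_FLOOR_CM)

    phase = beta[:, None] * d - psi[None, :]
    e_field = np.sum(
        amplitudes[None, :] * np.exp(-alpha[:, None] * d) * np.exp(-1j * phase) / d,
        axis=1,
    )
    sar = sigma * np.abs(e_field) ** 2 / (2.0 * rho)

    v_m3 = phantom.cell_volume * 1e-6
    raw_power = float(np.sum(rho * sar * v_m3))
    if raw_power <= 0.0:
        raise ZeroFieldError(
            "field deposits no power (all conductivities zero?); cannot normalise"
        )
    sar *= input_power / raw_power
    return SARField(values=sar, phantom=phantom, input_power=input_power)


def focus_location(
    field: SARField, top_fraction: float = 0.05, capture_radius: float = 2.5
) -> np.ndarray:
    """Location of the SAR focus in the brain, cm.

    Returns the SAR-weighted centroid of the top ``top_fraction`` of
    brain-compartment points, restricted to within ``capture_radius`` cm of
    the hottest brain point.  The restriction keeps the locator anchored to
    the interference focus: steered fields also carry bright peripheral
    points near the closest antennas and secondary lobes, and a centroid
    over a *global* top fraction mixes those clusters and can land between
    them.  ``capture_radius=inf`` recovers the unrestricted centroid.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise InvalidArgumentError("top_fraction must be in (0, 1]")
    if capture_radius <= 0.0:
        raise InvalidArgumentError("capture_radius must be > 0")
    mask = field.phantom.brain_mask
    if not mask.any():
        raise InvalidArgumentError("phantom has an empty brain mask")
    vals = field.values[mask]
    if not np.any(vals > 0):
        raise ZeroFieldError("SAR is zero on the brain mask")
    pts = field.phantom.points[mask]
    near = np.linalg.norm(pts - pts[np.argmax(vals)], axis=1) <= capture_radius
    vals, pts = vals[near], pts[near]
    k = max(1, int(np.ceil(top_fraction * mask.sum())))
    top = np.argsort(vals)[-min(k, vals.size):]
    w = vals[top]
    return np.asarray((pts[top] * w[:, None]).sum(axis=0) / w.sum())
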