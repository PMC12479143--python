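"""Field-comparison metrics: MAE, RMSE, PSNR, SSIM and the gamma index.

All metrics compare a predicted SAR field with the ground truth on a region
mask — the whole brain (WB) or a spherical target region (TR) around the
steering focus.  The gamma index is evaluated on the point cloud itself:
for each reference (truth) point ``s``,

    gamma(s) = min over evaluated points s' of
               sqrt( (|r_s - r_s'| / dta_crit)^2 + (DeltaD / dose_crit)^2 )

with the dose difference ``DeltaD = 100 * (pred(s') - truth(s)) / max truth``
normalised globally to the truth maximum on the mask, the spatial search
capped at ``3 * dta_crit``, and a point passing when ``gamma <= 1``.  The
truth field is always the reference; the comparison is directional.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidArgumentError, ZeroFieldError
from .losses import ssim_1d
from .phantom import HeadPhantom
from .physics import SteeringTarget
from .surrogate import SARField

__all__ = [
    "GammaCriteria",
    "RegionMask",
    "field_metrics",
    "gamma_index",
    "make_region_masks",
    "STANDARD_GAMMA_CRITERIA",
]


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma-index acceptance criteria.

    ``dose_crit`` is the dose-difference criterion in percent of the
    normalisation (global truth maximum on the mask); ``dta_crit`` the
    distance-to-agreement criterion in millimetres.
    """

    dose_crit: float
    dta_crit: float
    search_cap_factor: float = 3.0

    def __post_init__(self) -> None:
        if self.dose_crit <= 0 or self.dta_crit <= 0:
            raise InvalidArgumentError("gamma criteria must be > 0")

    @property
    def label(self) -> str:
        return f"{self.dose_crit:g}%/{self.dta_crit:g}mm"


#: The conventional reporting criteria: 2%/2mm, 3%/3mm, 3%/5mm.
STANDARD_GAMMA_CRITERIA = (
    GammaCriteria(2.0, 2.0),
    GammaCriteria(3.0, 3.0),
    GammaCriteria(3.0, 5.0),
)


@dataclass(frozen=True)
class RegionMask:
    """Point-index mask restricted to the brain compartment."""

    indices: np.ndarray
    kind: str  # "whole-brain" | "target-region"
    target_radius: float | None = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices)
        object.__setattr__(self, "indices", idx)
        if idx.size == 0:
            raise InvalidArgumentError("region mask is empty")
        if self.kind not in ("whole-brain", "target-region"):
            raise InvalidArgumentError(f"unknown mask kind {self.kind!r}")


def make_region_masks(
    phantom: HeadPhantom, target: SteeringTarget, radius: float = 1.5
) -> tuple[RegionMask, RegionMask]:
    """Whole-brain and target-region masks for a steering target.

    The target region is every brain point within ``radius`` cm of the
    target; it is a subset of the whole-brain mask by construction.
    """
    if not phantom.contains_brain(target.xyz)[0]:
        raise InvalidArgumentError("target must lie inside the brain compartment")
    wb = np.flatnonzero(phantom.brain_mask)
    d = np.linalg.norm(phantom.points[wb] - target.xyz, axis=1)
    tr = wb[d <= radius]
    if tr.size == 0:
        raise InvalidArgumentError(
            f"no brain points within {radius} cm of the target; increase the radius"
        )
    return (
        RegionMask(indices=wb, kind="whole-brain"),
        RegionMask(indices=tr, kind="target-region", target_radius=radius),
    )


def _field_values(field) -> np.ndarray:
    return field.values if isinstance(field, SARField) else np.asarray(field, float)


def field_metrics(pred, truth, mask: RegionMask) -> dict[str, float]:
    """MAE, RMSE, relative RMSE, PSNR (dB) and SSIM on the masked points.

    ``relRMSE = RMSE / max(truth)`` and ``PSNR = 20 log10(max(truth)/RMSE)``
    with the maximum taken on the mask; identical fields report ``PSNR = inf``.
    """
    p = _field_values(pred)[mask.indices]
    t = _field_values(truth)[mask.indices]
    if p.shape != t.shape:
        raise InvalidArgumentError("fields must live on the same phantom")
    diff = p - t
    mae = float(np.mean(np.abs(diff)))
    rmse = float(np.sqrt(np.mean(diff**2)))
    tmax = float(t.max())
    if tmax <= 0:
        raise ZeroFieldError("truth maximum on the mask is zero")
    psnr = np.inf if rmse == 0 else 20.0 * np.log10(tmax / rmse)
    return {
        "MAE": mae,
        "RMSE": rmse,
        "relRMSE": rmse / tmax,
        "PSNR": float(psnr),
        "SSIM": ssim_1d(p, t),
    }


def gamma_index(
    pred,
    truth,
    criteria: GammaCriteria,
    mask: RegionMask,
    points: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Per-point gamma values and the pass rate (% of points with gamma <= 1).

    ``pred`` and ``truth`` are SAR fields on the same phantom (or plain value
    arrays plus explicit ``points`` in cm).  Reference points are the masked
    truth points; evaluated points are the masked prediction points within
    ``criteria.search_cap_factor * dta_crit`` of each reference.
    """
    if points is None:
        ref = pred if isinstance(pred, SARField) else truth
        if not isinstance(ref, SARField):
            raise InvalidArgumentError("pass `points` when fields are plain arrays")
        points = ref.phantom.points
    pts_mm = np.asarray(points, float)[mask.indices] * 10.0  # cm -> mm
    p = _field_values(pred)[mask.indices]
    t = _field_values(truth)[mask.indices]
    tmax = float(t.max())
    if tmax <= 0:
        raise ZeroFieldError("truth maximum on the mask is zero; gamma undefined")

    dose_p = 100.0 * p / tmax  # percent of global normalisation
    dose_t = 100.0 * t / tmax
    cap = criteria.search_cap_factor * criteria.dta_crit
    tree = cKDTree(pts_mm)
    neighbours = tree.query_ball_point(pts_mm, cap)

    gamma = np.empty(p.size)
    for i, idx in enumerate(neighbours):
        idx = np.asarray(idx)
        dd = np.linalg.norm(pts_mm[idx] - pts_mm[i], axis=1) / criteria.dta_crit
        dD = (dose_p[idx] - dose_t[i]) / criteria.dose_crit
        gamma[i] = np.sqrt(np.min(dd**2 + dD**2))
    # boundary rule: gamma <= 1 passes, with a tolerance absorbing round-off
    # when a dose difference sits exactly on the criterion
    pass_rate = 100.0 * float(np.mean(gamma <= 1.0 + 1e-9))
    return gamma, pass_rate
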