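"""Procedural five-layer head phantom as a labelled point cloud.

The phantom emulates a simplified layered head: nested ellipsoidal shells
(outside-in: fat, bone, muscle) around a brain compartment, with an
intranasal air pocket carved near the front (+x) of the brain.  Each point
carries the dielectric properties of its tissue from the shipped registry.
It deliberately does not reproduce any particular anatomical model; its role
is to give the electromagnetic surrogate a head-like stratified medium.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidArgumentError
from .tissues import BRAIN_VARIANTS, TissueProperties, load_tissue_registry

__all__ = ["LayerSpec", "HeadPhantom", "build_head_phantom"]

# Canonical shell order, outside-in, matching the registry table order.
SHELL_ORDER = ("fat", "bone", "muscle")


@dataclass(frozen=True)
class LayerSpec:
    """Geometry of the layered phantom.

    Parameters
    ----------
    brain_radii
        Semi-axes (cm) of the ellipsoidal brain compartment.
    thicknesses
        Shell thicknesses (cm) for fat, bone, muscle, outside-in.
    air_pocket_center, air_pocket_radius
        Sphere carved out of the head and labelled intranasal air, cm.
    """

    brain_radii: tuple[float, float, float] = (7.0, 7.0, 6.0)
    thicknesses: dict[str, float] = field(
        default_factory=lambda: {"fat": 0.5, "bone": 0.7, "muscle": 0.5}
    )
    air_pocket_center: tuple[float, float, float] = (6.0, 0.0, -3.0)
    air_pocket_radius: float = 1.2

    @property
    def total_shell(self) -> float:
        return sum(self.thicknesses.values())

    @property
    def outer_radii(self) -> np.ndarray:
        return np.asarray(self.brain_radii) + self.total_shell

    def homogeneous(self) -> bool:
        return self.total_shell == 0.0 and self.air_pocket_radius == 0.0


@dataclass
class HeadPhantom:
    """Point-cloud head model with per-point tissue labels and properties.

    Attributes
    ----------
    points
        (N, 3) coordinates, cm, in a fixed canonical order (this order also
        defines the 1-D signal layout used by SSIM and the enhancement net).
    tissue_label
        (N,) tissue name per point.
    properties
        (N, 3) columns (eps_r, sigma, rho) matching each point's registry row.
    brain_mask
        (N,) boolean, True on brain-compartment points.
    cell_volume
        Representative per-point volume, cm^3: bounding-box volume / N.
    layer_spec
        Generating geometry; used for analytic point-in-brain tests.
    brain_variant
        Registry label of the brain tissue ('white_matter', 'gray_matter' or
        'brain_average').
    """

    points: np.ndarray
    tissue_label: np.ndarray
    properties: np.ndarray
    brain_mask: np.ndarray
    cell_volume: float
    layer_spec: LayerSpec
    brain_variant: str
    seed: int | None = None

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def contains_brain(self, xyz: np.ndarray) -> np.ndarray:
        """Analytic test of whether coordinates lie in the brain compartment."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        r = np.asarray(self.layer_spec.brain_radii)
        inside = np.sum((xyz / r) ** 2, axis=1) <= 1.0
        c = np.asarray(self.layer_spec.air_pocket_center)
        if self.layer_spec.air_pocket_radius > 0:
            in_air = (
                np.linalg.norm(xyz - c, axis=1) <= self.layer_spec.air_pocket_radius
            )
            inside &= ~in_air
        return inside

    def with_brain_variant(self, variant: str) -> "HeadPhantom":
        """Copy of this phantom with the brain compartment's tissue swapped."""
        if variant not in BRAIN_VARIANTS:
            raise InvalidArgumentError(
                f"unknown brain variant {variant!r}; expected one of {BRAIN_VARIANTS}"
            )
        registry = load_tissue_registry()
        t = registry[variant]
        props = self.properties.copy()
        props[self.brain_mask] = (t.rel_permittivity, t.conductivity, t.density)
        labels = self.tissue_label.copy()
        labels[self.brain_mask] = variant
        return replace(
            self, properties=props, tissue_label=labels, brain_variant=variant
        )

    @property
    def normalized_points(self) -> np.ndarray:
        """Coordinates affinely mapped to [0, 1] per axis (min -> 0, max -> 1)."""
        lo = self.points.min(axis=0)
        hi = self.points.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        return (self.points - lo) / span

    def brain_tissue(self) -> TissueProperties:
        return load_tissue_registry()[self.brain_variant]


def _morton_codes(pts: np.ndarray, half_extent: np.ndarray, bits: int = 10) -> np.ndarray:
    """Morton (bit-interleaved) codes of points quantised inside +-half_extent."""
    q = np.clip(
        ((pts + half_extent) / (2 * half_extent) * (2**bits - 1)).astype(np.uint64),
        0,
        2**bits - 1,
    )
    codes = np.zeros(pts.shape[0], dtype=np.uint64)
    for b in range(bits):
        for axis in range(3):
            codes |= ((q[:, axis] >> np.uint64(b)) & np.uint64(1)) << np.uint64(3 * b + axis)
    return codes


def build_head_phantom(
    n_points: int,
    seed: int,
    layer_spec: LayerSpec | None = None,
    brain_variant: str = "brain_average",
    max_radius: float = 13.0,
) -> HeadPhantom:
    """Sample a layered head phantom with ``n_points`` points.

    Points are drawn uniformly inside the outer ellipsoid with a seeded
    generator (deterministic for a fixed seed) and labelled by the ellipsoidal
    shell they fall in.  The phantom must fit strictly inside the applicator:
    ``max(outer radii) < max_radius``.

    Parameters
    ----------
    n_points
        Number of points, >= 100.
    seed
        Seed for the point sampler.
    layer_spec
        Phantom geometry; defaults to a 7 cm brain with 0.5/0.7/0.5 cm
        fat/bone/muscle shells and a frontal air pocket.  Use
        ``LayerSpec(brain_radii=(9, 9, 9), thicknesses={}, air_pocket_radius=0)``
        for a homogeneous all-brain sphere.
    brain_variant
        Tissue used for the brain compartment.
    max_radius
        Applicator radius bound, cm.
    """
    if n_points < 100:
        raise InvalidArgumentError(f"n_points must be >= 100, got {n_points}")
    spec = layer_spec if layer_spec is not None else LayerSpec()
    if any(t <= 0 for t in spec.thicknesses.values()):
        raise InvalidArgumentError("layer thicknesses must be positive")
    outer = spec.outer_radii
    if outer.max() >= max_radius:
        raise InvalidArgumentError(
            f"phantom outer radius {outer.max():.2f} cm must be < {max_radius} cm"
        )
    if brain_variant not in BRAIN_VARIANTS:
        raise InvalidArgumentError(
            f"unknown brain variant {brain_variant!r}; expected one of {BRAIN_VARIANTS}"
        )

    rng = np.random.default_rng(seed)
    pts = np.empty((0, 3))
    # Rejection-sample uniform points in the outer ellipsoid.
    while pts.shape[0] < n_points:
        cand = rng.uniform(-outer, outer, size=(2 * n_points, 3))
        keep = np.sum((cand / outer) ** 2, axis=1) <= 1.0
        pts = np.vstack([pts, cand[keep]])
    pts = pts[:n_points]
    # Canonical point order: Morton (Z-order) curve, so that nearby indices
    # are nearby in space.  The 1-D treatments of the field (SSIM windows,
    # the enhancement U-Net's convolutions) then operate on spatially
    # coherent neighbourhoods.
    pts = pts[np.argsort(_morton_codes(pts, outer))]

    # Normalised ellipsoidal radius relative to the brain surface: u <= 1 is
    # brain; shells are bands of constant metric thickness outside it.
    brain_r = np.asarray(spec.brain_radii)
    u = np.sqrt(np.sum((pts / brain_r) ** 2, axis=1))
    # Metric distance outside the brain surface along the radial direction,
    # approximated with the direction-dependent local radius.
    local_r = np.linalg.norm(pts, axis=1) / np.maximum(u, 1e-12)
    depth = (u - 1.0) * local_r  # cm outside the brain surface (negative inside)

    labels = np.empty(n_points, dtype=object)
    labels[:] = brain_variant
    edges = np.cumsum([spec.thicknesses.get(k, 0.0) for k in SHELL_ORDER[::-1]])
    # inside-out: muscle, bone, fat
    names_in_out = list(SHELL_ORDER[::-1])
    prev = 0.0
    for name, edge in zip(names_in_out, edges):
        sel = (depth > prev) & (depth <= edge)
        labels[sel] = name
        prev = edge
    labels[depth > prev] = SHELL_ORDER[0]  # numerical stragglers -> outermost

    if spec.air_pocket_radius > 0:
        c = np.asarray(spec.air_pocket_center)
        in_air = np.linalg.norm(pts - c, axis=1) <= spec.air_pocket_radius
        labels[in_air] = "air"

    registry = load_tissue_registry()
    props = np.empty((n_points, 3))
    for name in np.unique(labels.astype(str)):
        t = registry[name]
        sel = labels == name
        props[sel] = (t.rel_permittivity, t.conductivity, t.density)

    brain_mask = labels == brain_variant
    if not brain_mask.any():
        raise InvalidArgumentError("phantom has an empty brain compartment")

    bbox = pts.max(axis=0) - pts.min(axis=0)
    cell_volume = float(np.prod(bbox)) / n_points

    return HeadPhantom(
        points=pts,
        tissue_label=labels.astype(str),
        properties=props,
        brain_mask=np.asarray(brain_mask, dtype=bool),
        cell_volume=cell_volume,
        layer_spec=spec,
        brain_variant=brain_variant,
        seed=seed,
    )
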