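"""Experimental-design enumeration, sample generation and dataset splits.

The study design steers the focus over a 2 cm grid in [-4, 6] cm along x and
y, at axial planes z in {-2, 0, +2} cm, for three brain-tissue variants
(white matter, gray matter and their average).  Each sample pairs the
phantom's per-point inputs and the 48 steering phases with the surrogate's
ground-truth SAR field normalised to 100 W.  The full design product is
filtered to targets inside the brain compartment; a dataset draws
``n_samples`` of the remaining configurations seed-deterministically
(201 by default) and splits them 160/21/20.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from .errors import InvalidArgumentError
from .phantom import HeadPhantom
from .physics import ApplicatorGeometry, PhaseVector, SteeringTarget, steering_phases
from .surrogate import SARField, simulate_sar
from .tissues import BRAIN_VARIANTS, load_tissue_registry

__all__ = [
    "DesignGrid",
    "SampleRecord",
    "enumerate_design",
    "generate_dataset",
    "split_dataset",
    "kfold_splits",
    "save_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class DesignGrid:
    """Steering-target grid crossed with brain-tissue variants."""

    xy_values: tuple[float, ...] = (-4.0, -2.0, 0.0, 2.0, 4.0, 6.0)
    z_values: tuple[float, ...] = (-2.0, 0.0, 2.0)
    tissue_variants: tuple[str, ...] = BRAIN_VARIANTS

    def __post_init__(self) -> None:
        if not self.xy_values or not self.z_values or not self.tissue_variants:
            raise InvalidArgumentError("design grid must be nonempty")
        for v in self.tissue_variants:
            if v not in BRAIN_VARIANTS:
                raise InvalidArgumentError(f"unknown tissue variant {v!r}")


@dataclass
class SampleRecord:
    """One training sample: brain-mesh inputs, steering phases and ground truth.

    The learning task is defined on the brain compartment: ``brain_inputs``
    is the N_b x 6 array (x, y, z, eps_r, sigma, rho) over the phantom's
    brain points (in canonical phantom order), and ``normalized_inputs``
    carries the same rows with coordinates affinely mapped to [0, 1] per
    axis over the brain points.  ``sar_truth`` is the surrogate field on the
    *full* phantom (the physics needs the outer layers); ``brain_sar``
    restricts it to the brain rows the network predicts.
    """

    brain_inputs: np.ndarray
    normalized_inputs: np.ndarray
    phases: PhaseVector
    target: SteeringTarget
    tissue_variant: str
    sar_truth: SARField

    @property
    def n_points(self) -> int:
        return self.brain_inputs.shape[0]

    @property
    def brain_sar(self) -> np.ndarray:
        """Ground-truth SAR on the brain points, W/kg."""
        return self.sar_truth.values[self.sar_truth.phantom.brain_mask]


def enumerate_design(
    grid: DesignGrid, phantom: HeadPhantom
) -> list[tuple[SteeringTarget, str]]:
    """All (target, variant) configurations with the target inside the brain.

    Ordering is deterministic: lexicographic by variant (grid order), then
    z, y, x (grid order).  Emits a warning and returns an empty list if every
    target falls outside the brain compartment.
    """
    configs: list[tuple[SteeringTarget, str]] = []
    for variant in grid.tissue_variants:
        for z in grid.z_values:
            for y in grid.xy_values:
                for x in grid.xy_values:
                    t = SteeringTarget(x, y, z)
                    if phantom.contains_brain(t.xyz)[0]:
                        configs.append((t, variant))
    if not configs:
        warnings.warn("no design targets fall inside the brain compartment")
    return configs


def generate_dataset(
    grid: DesignGrid,
    phantom: HeadPhantom,
    geometry: ApplicatorGeometry,
    n_samples: int,
    seed: int,
    input_power: float = 100.0,
) -> list[SampleRecord]:
    """Generate ``n_samples`` surrogate samples from a seed-shuffled design.

    For each drawn (target, variant) configuration the steering phases are
    computed from the variant's brain wavelength and the ground-truth SAR
    from the surrogate on the variant-adjusted phantom.  Deterministic for a
    fixed seed.
    """
    design = enumerate_design(grid, phantom)
    if n_samples > len(design):
        raise InvalidArgumentError(
            f"n_samples={n_samples} exceeds design size {len(design)}"
        )
    order = np.random.default_rng(seed).permutation(len(design))[:n_samples]

    registry = load_tissue_registry(geometry.frequency)
    variant_phantoms = {v: phantom.with_brain_variant(v) for v in grid.tissue_variants}
    bm = phantom.brain_mask
    brain_pts = phantom.points[bm]
    lo, hi = brain_pts.min(axis=0), brain_pts.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    norm_coords = (brain_pts - lo) / span

    records: list[SampleRecord] = []
    for idx in order:
        target, variant = design[idx]
        ph = variant_phantoms[variant]
        lam = registry[variant].wavelength
        psi = steering_phases(geometry, target, lam)
        truth = simulate_sar(ph, geometry, psi, input_power=input_power)
        raw = np.column_stack([brain_pts, ph.properties[bm]])
        norm = np.column_stack([norm_coords, ph.properties[bm]])
        records.append(
            SampleRecord(
                brain_inputs=raw,
                normalized_inputs=norm,
                phases=psi,
                target=target,
                tissue_variant=variant,
                sar_truth=truth,
            )
        )
    return records


def split_dataset(
    records: list[SampleRecord],
    sizes: tuple[int, int, int] = (160, 21, 20),
    seed: int = 0,
) -> tuple[list[SampleRecord], list[SampleRecord], list[SampleRecord]]:
    """Disjoint train/validation/test split of the first ``sum(sizes)`` records.

    The membership is a seeded permutation; the three folds are disjoint and
    exhaust the first ``sum(sizes)`` records.
    """
    n_train, n_val, n_test = sizes
    total = n_train + n_val + n_test
    if min(sizes) < 0:
        raise InvalidArgumentError("split sizes must be non-negative")
    if total > len(records):
        raise InvalidArgumentError(
            f"split sizes sum to {total} but only {len(records)} records exist"
        )
    perm = np.random.default_rng(seed).permutation(total)
    train = [records[i] for i in perm[:n_train]]
    val = [records[i] for i in perm[n_train : n_train + n_val]]
    test = [records[i] for i in perm[n_train + n_val : total]]
    return train, val, test


def kfold_splits(
    records: list[SampleRecord], k: int = 5, seed: int = 0
) -> list[tuple[list[SampleRecord], list[SampleRecord]]]:
    """K disjoint (train, held-out) folds over all records, seed-shuffled."""
    if k < 2 or k > len(records):
        raise InvalidArgumentError("k must be in [2, len(records)]")
    perm = np.random.default_rng(seed).permutation(len(records))
    folds = np.array_split(perm, k)
    out = []
    for i in range(k):
        held = [records[j] for j in folds[i]]
        rest = [records[j] for f in folds[:i] + folds[i + 1 :] for j in f]
        out.append((rest, held))
    return out


# ---------------------------------------------------------------------------
# HDF5 container


def save_dataset(path: str, records: list[SampleRecord], phantom: HeadPhantom) -> None:
    """Write records to an HDF5 file, one group per sample plus the phantom."""
    with h5py.File(path, "w") as f:
        g = f.create_group("phantom")
        g.create_dataset("points", data=phantom.points)
        g.create_dataset("properties", data=phantom.properties)
        g.create_dataset("brain_mask", data=phantom.brain_mask)
        g.create_dataset(
            "tissue_label",
            data=np.array([s.encode() for s in phantom.tissue_label]),
        )
        g.attrs["cell_volume"] = phantom.cell_volume
        g.attrs["brain_variant"] = phantom.brain_variant
        g.attrs["brain_radii"] = phantom.layer_spec.brain_radii
        g.attrs["air_pocket_center"] = phantom.layer_spec.air_pocket_center
        g.attrs["air_pocket_radius"] = phantom.layer_spec.air_pocket_radius
        g.attrs["thickness_names"] = list(phantom.layer_spec.thicknesses)
        g.attrs["thickness_values"] = list(phantom.layer_spec.thicknesses.values())
        for i, r in enumerate(records):
            s = f.create_group(f"samples/{i:05d}")
            s.create_dataset("inputs", data=r.brain_inputs)
            s.create_dataset("normalized_inputs", data=r.normalized_inputs)
            s.create_dataset("phases_inner", data=r.phases.inner)
            s.create_dataset("phases_outer", data=r.phases.outer)
            s.create_dataset("sar", data=r.sar_truth.values)
            s.attrs["target"] = r.target.xyz
            s.attrs["tissue_variant"] = r.tissue_variant
            s.attrs["input_power"] = r.sar_truth.input_power


def load_dataset(path: str) -> tuple[list[SampleRecord], HeadPhantom]:
    """Inverse of :func:`save_dataset`."""
    from .phantom import LayerSpec

    with h5py.File(path, "r") as f:
        g = f["phantom"]
        spec = LayerSpec(
            brain_radii=tuple(g.attrs["brain_radii"]),
            thicknesses=dict(
                zip(list(g.attrs["thickness_names"]), list(g.attrs["thickness_values"]))
            ),
            air_pocket_center=tuple(g.attrs["air_pocket_center"]),
            air_pocket_radius=float(g.attrs["air_pocket_radius"]),
        )
        phantom = HeadPhantom(
            points=g["points"][()],
            tissue_label=np.array([b.decode() for b in g["tissue_label"][()]]),
            properties=g["properties"][()],
            brain_mask=g["brain_mask"][()].astype(bool),
            cell_volume=float(g.attrs["cell_volume"]),
            layer_spec=spec,
            brain_variant=str(g.attrs["brain_variant"]),
        )
        records = []
        for key in sorted(f["samples"]):
            s = f[f"samples/{key}"]
            variant = str(s.attrs["tissue_variant"])
            ph = phantom if variant == phantom.brain_variant else phantom.with_brain_variant(variant)
            x0, y0, z0 = s.attrs["target"]
            records.append(
                SampleRecord(
                    brain_inputs=s["inputs"][()],
                    normalized_inputs=s["normalized_inputs"][()],
                    phases=PhaseVector(
                        inner=s["phases_inner"][()], outer=s["phases_outer"][()]
                    ),
                    target=SteeringTarget(float(x0), float(y0), float(z0)),
                    tissue_variant=variant,
                    sar_truth=SARField(
                        values=s["sar"][()],
                        phantom=ph,
                        input_power=float(s.attrs["input_power"]),
                    ),
                )
            )
    return records, phantom
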