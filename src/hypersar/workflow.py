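"""End-to-end pipeline: phantom -> dataset -> two-stage training -> evaluation.

:func:`run_two_stage` wires the whole method together at a configurable
scale.  The default :class:`ExperimentConfig` is the package's scaled-down
study: a 500-point layered phantom, the in-plane (z = 0) steering grid
crossed with the three brain-tissue variants, 52 samples split 40/6/6, and
50 epochs per stage at learning rate 1e-3 (a few hundred optimiser steps;
see docs/methods.md for the scaling rationale).  The full-scale design
(100k points, 201 samples, 160/21/20, 500 epochs at 1e-4) is reached by
overriding the same fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import DesignGrid, SampleRecord, generate_dataset, split_dataset
from .metrics import STANDARD_GAMMA_CRITERIA, field_metrics, gamma_index, make_region_masks
from .nn.autodiff import default_dtype
from .phantom import LayerSpec, build_head_phantom
from .physics import ApplicatorGeometry
from .sarpnet import SarpNet, SarpNetConfig
from .surrogate import focus_location
from .train import TrainConfig, enhance_field, predict_field, train_stage
from .unet import UNet1D, UNet1DConfig

__all__ = ["ExperimentConfig", "ExperimentResult", "run_two_stage"]

logger = logging.getLogger("hypersar")


@dataclass
class ExperimentConfig:
    """Conditions of one two-stage experiment."""

    n_points: int = 500
    n_samples: int = 52
    split_sizes: tuple[int, int, int] = (40, 6, 6)
    grid: DesignGrid = field(default_factory=lambda: DesignGrid(z_values=(0.0,)))
    layer_spec: LayerSpec = field(default_factory=LayerSpec)
    geometry: ApplicatorGeometry = field(default_factory=ApplicatorGeometry)
    predict_train: TrainConfig = field(
        default_factory=lambda: TrainConfig(lr=1e-3, epochs=50)
    )
    enhance_train: TrainConfig = field(
        default_factory=lambda: TrainConfig(lr=1e-3, epochs=50, select_on="val_rmse")
    )
    sarpnet: SarpNetConfig = field(default_factory=SarpNetConfig)
    unet: UNet1DConfig = field(default_factory=UNet1DConfig)
    target_region_radius: float = 1.5
    focus_top_fraction: float = 0.05


@dataclass
class ExperimentResult:
    """Outputs of :func:`run_two_stage`."""

    predict_history: list[dict]
    enhance_history: list[dict]
    test_metrics: dict[str, dict[str, float]]
    focus_distances: dict[str, np.ndarray]
    records: tuple[list[SampleRecord], list[SampleRecord], list[SampleRecord]]
    models: tuple[SarpNet, UNet1D]

    def focus_hit_rate(self, stage: str = "enhance", tolerance: float = 2.0) -> float:
        """Fraction of held-out samples whose predicted focus lies within
        ``tolerance`` cm of the true steering target."""
        d = self.focus_distances[stage]
        return float(np.mean(d <= tolerance))


def _mean_test_metrics(
    fields: list, records: list[SampleRecord], radius: float, with_gamma: bool
) -> dict[str, dict[str, float]]:
    """Average WB / TR metrics over the test samples."""
    out: dict[str, list[dict[str, float]]] = {"WB": [], "TR": []}
    for fld, rec in zip(fields, records):
        wb, tr = make_region_masks(rec.sar_truth.phantom, rec.target, radius)
        for name, mask in (("WB", wb), ("TR", tr)):
            m = field_metrics(fld, rec.sar_truth, mask)
            if with_gamma:
                for crit in STANDARD_GAMMA_CRITERIA:
                    _, rate = gamma_index(fld, rec.sar_truth, crit, mask)
                    m[f"GI {crit.label}"] = rate
            out[name].append(m)
    return {
        region: {
            k: float(np.mean([m[k] for m in ms])) for k in ms[0]
        }
        for region, ms in out.items()
    }


def run_two_stage(
    seed: int, config: ExperimentConfig | None = None, with_gamma: bool = False
) -> ExperimentResult:
    """Run the full prediction + enhancement experiment at the configured scale.

    ``seed`` drives every random element (phantom sampling, design draw,
    split membership, parameter initialisation, batch shuffling) through a
    fixed offset scheme, so a run is reproducible from the seed alone.
    """
    cfg = config if config is not None else ExperimentConfig()
    seeds = np.random.SeedSequence(seed).generate_state(6) % (2**31)

    logger.info("building phantom (N=%d)", cfg.n_points)
    phantom = build_head_phantom(
        cfg.n_points, seed=int(seeds[0]), layer_spec=cfg.layer_spec
    )
    logger.info("generating %d surrogate samples", cfg.n_samples)
    records = generate_dataset(
        cfg.grid, phantom, cfg.geometry, cfg.n_samples, seed=int(seeds[1])
    )
    train, val, test = split_dataset(records, cfg.split_sizes, seed=int(seeds[2]))

    # Networks train in float32: memory-bandwidth bound on CPU, and single
    # precision is ample for SAR regression.  Metrics stay in float64.
    with default_dtype(np.float32):
        predictor = SarpNet(cfg.sarpnet, seed=int(seeds[3]))
        predict_cfg = replace(cfg.predict_train, seed=int(seeds[4]))
        logger.info("training prediction stage (%d epochs)", predict_cfg.epochs)
        predict_history = train_stage(predictor, train, val, predict_cfg)

        # Enhancement trains on the prediction stage's outputs (brain signal).
        bm = phantom.brain_mask

        def signals(rs: list[SampleRecord]):
            return [
                (predict_field(predictor, r).values[bm], r.brain_sar) for r in rs
            ]

        enhancer = UNet1D(cfg.unet, seed=int(seeds[5]))
        enhance_cfg = replace(cfg.enhance_train, seed=int(seeds[4]))
        logger.info("training enhancement stage (%d epochs)", enhance_cfg.epochs)
        enhance_history = train_stage(enhancer, signals(train), signals(val), enhance_cfg)

        predicted = [predict_field(predictor, r) for r in test]
        enhanced = [enhance_field(enhancer, f) for f in predicted]

    test_metrics = {
        "predict": _mean_test_metrics(
            predicted, test, cfg.target_region_radius, with_gamma
        ),
        "enhance": _mean_test_metrics(
            enhanced, test, cfg.target_region_radius, with_gamma
        ),
    }
    focus_distances = {
        stage: np.array(
            [
                np.linalg.norm(
                    focus_location(f, cfg.focus_top_fraction) - r.target.xyz
                )
                for f, r in zip(fields, test)
            ]
        )
        for stage, fields in (("predict", predicted), ("enhance", enhanced))
    }
    return ExperimentResult(
        predict_history=predict_history,
        enhance_history=enhance_history,
        test_metrics=test_metrics,
        focus_distances=focus_distances,
        records=(train, val, test),
        models=(predictor, enhancer),
    )
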