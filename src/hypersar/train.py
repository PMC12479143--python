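"""Training loops for the prediction and enhancement stages.

Both stages use Adam with a step learning-rate schedule (reduced by a fixed
factor every ``decay_every`` epochs; defaults 1e-4, 0.2, 100, 500 epochs).
The prediction stage minimises the combined SSIM + L2 loss; the enhancement
stage minimises the 30 W/kg threshold loss on the prediction network's
outputs.  The best-validation parameter set is retained and restored at the
end of training.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .dataset import SampleRecord
from .errors import InvalidArgumentError, TrainingDivergedError
from .losses import combined_loss, threshold_loss
from .nn import Adam, Tensor, step_lr
from .sarpnet import SarpNet, SarpNetConfig
from .surrogate import SARField
from .unet import UNet1D, UNet1DConfig

__all__ = [
    "TrainConfig",
    "train_stage",
    "predict_field",
    "enhance_field",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    """Optimisation schedule and loss weights."""

    lr: float = 1e-4
    lr_decay_factor: float = 0.2
    decay_every: int = 100
    epochs: int = 500
    alpha1: float = 1.0
    beta1: float = 1.0
    enhancement_threshold: float = 30.0
    batch_size: int = 4
    seed: int = 0
    #: Metric for best-validation checkpoint selection: the stage's own loss
    #: ("val_loss") or the validation RMSE ("val_rmse").  The initial state
    #: is always a candidate, so a stage whose training never validates as
    #: an improvement keeps its initialisation (for the residual enhancer
    #: that is the identity map).
    select_on: str = "val_loss"

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise InvalidArgumentError("lr must be > 0")
        if self.epochs < 1:
            raise InvalidArgumentError("epochs must be >= 1")
        if self.batch_size < 1:
            raise InvalidArgumentError("batch_size must be >= 1")


def _predict_batch_arrays(records: list[SampleRecord]):
    x = np.stack([r.normalized_inputs for r in records])
    psi = np.stack([r.phases.flat for r in records])
    y = np.stack([r.brain_sar for r in records])
    return x, psi, y


def _stage_of(model) -> str:
    if isinstance(model, SarpNet):
        return "predict"
    if isinstance(model, UNet1D):
        return "enhance"
    raise InvalidArgumentError(f"unsupported model type {type(model).__name__}")


def train_stage(
    model,
    train_data,
    val_data,
    config: TrainConfig,
) -> list[dict]:
    """Train one stage in place; returns the per-epoch loss history.

    ``train_data``/``val_data`` are lists of :class:`SampleRecord` for the
    prediction stage (:class:`SarpNet` model) or of ``(signal, truth)`` array
    pairs for the enhancement stage (:class:`UNet1D` model).  The model is
    left holding the parameters of the best-validation epoch.
    """
    if not train_data:
        raise InvalidArgumentError("training set is empty")
    stage = _stage_of(model)
    rng = np.random.default_rng(config.seed)
    params = model.parameters()
    optimizer = Adam(params, lr=config.lr)

    def batch_loss(batch) -> Tensor:
        if stage == "predict":
            x, psi, y = _predict_batch_arrays(batch)
            pred = model(x, psi)
            return combined_loss(pred, Tensor(y), config.alpha1, config.beta1)
        signals = np.stack([s for s, _ in batch])
        truths = np.stack([t for _, t in batch])
        out = model(signals)
        return threshold_loss(out, Tensor(truths), config.enhancement_threshold)

    def batch_pred_truth(batch):
        if stage == "predict":
            x, psi, y = _predict_batch_arrays(batch)
            return model(x, psi).data, y
        signals = np.stack([s for s, _ in batch])
        truths = np.stack([t for _, t in batch])
        return model(signals).data, truths

    def eval_scores(data) -> tuple[float, float]:
        """(mean loss, RMSE) over a dataset."""
        if not data:
            return np.nan, np.nan
        total = 0.0
        sq = 0.0
        count = 0
        for i in range(0, len(data), config.batch_size):
            chunk = data[i : i + config.batch_size]
            total += float(batch_loss(chunk).data) * len(chunk)
            pred, truth = batch_pred_truth(chunk)
            sq += float(np.sum((pred - truth) ** 2))
            count += truth.size
        return total / len(data), float(np.sqrt(sq / count))

    if config.select_on not in ("val_loss", "val_rmse"):
        raise InvalidArgumentError("select_on must be 'val_loss' or 'val_rmse'")

    def select_score(val_loss: float, val_rmse: float, train_loss: float) -> float:
        score = val_loss if config.select_on == "val_loss" else val_rmse
        return score if np.isfinite(score) else train_loss

    history: list[dict] = []
    init_val_loss, init_val_rmse = eval_scores(val_data)
    best_val = select_score(init_val_loss, init_val_rmse, np.inf)
    best_state = model.state_arrays()
    n = len(train_data)
    for epoch in range(1, config.epochs + 1):
        lr = step_lr(config.lr, epoch, config.lr_decay_factor, config.decay_every)
        optimizer.lr = lr
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, config.batch_size):
            batch = [train_data[j] for j in order[i : i + config.batch_size]]
            optimizer.zero_grad()
            loss = batch_loss(batch)
            value = float(loss.data)
            if not np.isfinite(value):
                raise TrainingDivergedError(
                    f"non-finite {stage} loss at epoch {epoch}"
                )
            loss.backward()
            optimizer.step()
            epoch_loss += value * len(batch)
        train_loss = epoch_loss / n
        val_loss, val_rmse = eval_scores(val_data)
        history.append(
            {
                "epoch": epoch,
                "lr": lr,
                "train_loss": train_loss,
                "val_loss": val_loss,
                "val_rmse": val_rmse,
            }
        )
        score = select_score(val_loss, val_rmse, train_loss)
        if score < best_val:
            best_val = score
            best_state = model.state_arrays()
    model.load_state_arrays(best_state)
    return history


def predict_field(model: SarpNet, record: SampleRecord) -> SARField:
    """Prediction-stage SAR field for one sample.

    The network predicts on the brain points; the returned field lives on
    the full phantom with zeros outside the brain compartment and values
    clamped to be non-negative.
    """
    phantom = record.sar_truth.phantom
    values = np.zeros(phantom.n_points)
    brain = model.predict(record.normalized_inputs, record.phases.flat)
    values[phantom.brain_mask] = np.maximum(brain, 0.0)
    return SARField(
        values=values,
        phantom=phantom,
        input_power=record.sar_truth.input_power,
    )


def enhance_field(model: UNet1D, field: SARField) -> SARField:
    """Enhancement-stage refinement of a predicted SAR field (brain signal)."""
    mask = field.phantom.brain_mask
    refined = field.values.copy()
    refined[mask] = np.maximum(model.refine(field.values[mask]), 0.0)
    return SARField(
        values=refined,
        phantom=field.phantom,
        input_power=field.input_power,
    )


# ---------------------------------------------------------------------------
# Checkpoints


def save_checkpoint(path: str, model, train_config: TrainConfig | None = None) -> None:
    """Save model parameters and configuration to a single ``.npz`` file."""
    stage = _stage_of(model)
    cfg = asdict(model.config) if not isinstance(model.config, dict) else model.config
    meta = {"stage": stage, "model_config": cfg}
    if train_config is not None:
        meta["train_config"] = asdict(train_config)
    arrays = {f"param_{i:04d}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str):
    """Load a checkpoint; returns the reconstructed model."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        arrays = [data[k] for k in sorted(k for k in data.files if k.startswith("param_"))]
    if meta["stage"] == "predict":
        cfg = meta["model_config"]
        cfg["decoder_widths"] = tuple(cfg["decoder_widths"])
        model = SarpNet(SarpNetConfig(**cfg))
    else:
        model = UNet1D(UNet1DConfig(**meta["model_config"]))
    model.load_state_arrays(arrays)
    return model
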