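"""Training losses: SSIM + L2 combined loss and the threshold loss.

SSIM on a point cloud is made well-defined by treating the SAR values as a
1-D signal in the phantom's fixed canonical point order, with a sliding
Gaussian window (length 11, sigma 1.5) and the standard stabilising
constants ``C1 = (0.01 L)^2``, ``C2 = (0.03 L)^2`` scaled to the data range
``L``.  The same definition serves the training loss (differentiable, on
:class:`~hypersar.nn.Tensor`) and the evaluation metric (numpy).

The prediction stage trains with ``alpha1 * (1 - SSIM) + beta1 * MSE``;
the enhancement stage with a per-point partitioned loss: L1 where the
ground truth is below 30 W/kg (fine-grained refinement of the low-intensity
background) and L2 where it is above (large errors near the focus).
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidArgumentError
from .nn import Tensor, conv1d

__all__ = ["gaussian_window", "ssim_1d", "combined_loss", "threshold_loss"]

SSIM_WIN_SIZE = 11
SSIM_SIGMA = 1.5
_K1, _K2 = 0.01, 0.03


def gaussian_window(win_size: int = SSIM_WIN_SIZE, sigma: float = SSIM_SIGMA) -> np.ndarray:
    """Normalised truncated Gaussian window."""
    r = (win_size - 1) // 2
    x = np.arange(-r, r + 1, dtype=float)
    w = np.exp(-0.5 * (x / sigma) ** 2)
    return w / w.sum()


def _resolve_window(n: int) -> np.ndarray:
    """Gaussian window, falling back to a full-length uniform window for short signals."""
    if n >= SSIM_WIN_SIZE:
        return gaussian_window()
    return np.full(n, 1.0 / n)


def _resolve_range(truth: np.ndarray, data_range: float | None) -> float:
    if data_range is not None:
        if data_range <= 0:
            raise InvalidArgumentError("data_range must be > 0")
        return float(data_range)
    span = float(truth.max() - truth.min())
    return span if span > 0 else 1.0


def _ssim_tensor(pred: Tensor, truth: Tensor, data_range: float) -> Tensor:
    """Mean SSIM of batched 1-D signals (B, N); differentiable in ``pred``."""
    b, n = pred.shape
    w = Tensor(_resolve_window(n)[None, None, :])
    x = pred.reshape(b, 1, n)
    y = truth.reshape(b, 1, n)
    ux = conv1d(x, w)
    uy = conv1d(y, w)
    uxx = conv1d(x * x, w)
    uyy = conv1d(y * y, w)
    uxy = conv1d(x * y, w)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    cov = uxy - ux * uy
    c1 = (_K1 * data_range) ** 2
    c2 = (_K2 * data_range) ** 2
    s = ((ux * uy * 2.0 + c1) * (cov * 2.0 + c2)) / (
        (ux * ux + uy * uy + c1) * (vx + vy + c2)
    )
    return s.mean()


def ssim_1d(
    pred: np.ndarray, truth: np.ndarray, data_range: float | None = None
) -> float:
    """Mean structural similarity of two 1-D signals in canonical order.

    Local means, variances and covariance come from a sliding Gaussian
    window (length 11, sigma 1.5) evaluated where the window fully overlaps
    the signal; signals shorter than the window use a single full-length
    uniform window.  Returns a value in [-1, 1]; 1 iff the signals are equal.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise InvalidArgumentError("ssim_1d expects two equal-length 1-D signals")
    rng = _resolve_range(truth, data_range)
    return float(
        _ssim_tensor(Tensor(pred[None, :]), Tensor(truth[None, :]), rng).data
    )


def _as_batch(t: Tensor) -> Tensor:
    if t.ndim == 1:
        return t.reshape(1, t.shape[0])
    if t.ndim != 2:
        raise InvalidArgumentError("expected a 1-D signal or a (B, N) batch")
    return t


def combined_loss(
    pred,
    truth,
    alpha1: float = 1.0,
    beta1: float = 1.0,
    data_range: float | None = None,
):
    """Prediction-stage loss ``alpha1 * (1 - SSIM) + beta1 * MSE``.

    Accepts numpy arrays (returns a float) or Tensors (returns a scalar
    Tensor differentiable in ``pred``).  Non-negative, and zero iff
    ``pred == truth``.
    """
    was_numpy = not isinstance(pred, Tensor)
    p = _as_batch(pred if isinstance(pred, Tensor) else Tensor(np.asarray(pred, float)))
    t = _as_batch(truth if isinstance(truth, Tensor) else Tensor(np.asarray(truth, float)))
    if p.shape != t.shape:
        raise InvalidArgumentError(
            f"prediction shape {p.shape} does not match truth shape {t.shape}"
        )
    if not (np.all(np.isfinite(p.data)) and np.all(np.isfinite(t.data))):
        raise InvalidArgumentError("loss inputs must be finite")
    rng = _resolve_range(t.data, data_range)
    d = p - t
    mse = (d * d).mean()
    loss = alpha1 * (1.0 - _ssim_tensor(p, t, rng)) + beta1 * mse
    return float(loss.data) if was_numpy else loss


def threshold_loss(pred, truth, threshold: float = 30.0):
    """Enhancement-stage loss: L1 below the SAR threshold, L2 above it.

    The partition depends only on the ground truth, so the loss is
    continuous (though not smooth) in the prediction.
    """
    was_numpy = not isinstance(pred, Tensor)
    p = pred if isinstance(pred, Tensor) else Tensor(np.asarray(pred, float))
    t = truth if isinstance(truth, Tensor) else Tensor(np.asarray(truth, float))
    if p.shape != t.shape:
        raise InvalidArgumentError(
            f"prediction shape {p.shape} does not match truth shape {t.shape}"
        )
    if not (np.all(np.isfinite(p.data)) and np.all(np.isfinite(t.data))):
        raise InvalidArgumentError("loss inputs must be finite")
    below = Tensor((t.data < threshold).astype(float))
    d = p - t
    loss = (d.abs() * below + d * d * (1.0 - below)).mean()
    return float(loss.data) if was_numpy else loss
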