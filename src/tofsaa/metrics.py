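"""Image/data error metrics and ensemble bias-variance summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "normalized_rmse",
    "data_rmse",
    "line_profile",
    "EnsembleResult",
    "bias_std_curve",
]


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


def normalized_rmse(img: np.ndarray, truth: np.ndarray) -> float:
    """Root-mean-square error normalised by the mean of the truth image."""
    img = np.asarray(img, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if img.shape != truth.shape:
        raise ValueError(f"shape mismatch: {img.shape} vs {truth.shape}")
    m = truth.mean()
    if m == 0:
        raise ValueError("truth has zero mean; normalized RMSE undefined")
    return _rms(img - truth) / m


def data_rmse(c_est: np.ndarray, C: np.ndarray) -> float:
    """RMSE between model and measured data, normalised by the data mean."""
    return normalized_rmse(c_est, C)


def line_profile(img: np.ndarray, row: int | None = None) -> np.ndarray:
    """Values of one image row left to right (default: the middle row)."""
    img = np.asarray(img)
    if row is None:
        row = img.shape[0] // 2
    if not 0 <= row < img.shape[0]:
        raise IndexError(f"row {row} out of range for {img.shape[0]} rows")
    return img[row, :].copy()


@dataclass
class EnsembleResult:
    """Per-checkpoint stacks of reconstructions over noise realizations.

    ``activity[it]`` and ``attenuation[it]`` are arrays of shape
    (n_realizations, n, n) for each checkpoint iteration ``it``.
    """

    checkpoints: tuple[int, ...]
    n_realizations: int
    algo: str
    activity: dict = field(default_factory=dict)
    attenuation: dict = field(default_factory=dict)

    def stack(self, quantity: str, checkpoint: int) -> np.ndarray:
        return getattr(self, quantity)[checkpoint]

    def mean_image(self, quantity: str, checkpoint: int) -> np.ndarray:
        return self.stack(quantity, checkpoint).mean(axis=0)

    def std_image(self, quantity: str, checkpoint: int) -> np.ndarray:
        return self.stack(quantity, checkpoint).std(axis=0, ddof=1)


def bias_std_curve(
    ensemble: EnsembleResult, truth: np.ndarray, quantity: str = "activity"
) -> list[tuple[float, float]]:
    """Normalised (bias, std) per checkpoint from an ensemble.

    bias = RMSE(mean image, truth) / mean(truth); std = root-mean pixel
    standard deviation / mean(truth).  One tuple per checkpoint, in
    checkpoint order.
    """
    if ensemble.n_realizations < 2:
        raise ValueError("need at least 2 realizations for bias/std")
    truth = np.asarray(truth, dtype=float)
    m = truth.mean()
    if m == 0:
        raise ValueError("truth has zero mean")
    out = []
    for it in ensemble.checkpoints:
        mean_img = ensemble.mean_image(quantity, it)
        std_img = ensemble.std_image(quantity, it)
        out.append((_rms(mean_img - truth) / m, _rms(std_img) / m))
    return out
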