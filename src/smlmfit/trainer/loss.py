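"""Masked L1 image loss.

A support mask is derived from the target image (pixels above a small
fraction of its maximum); both images are compared only inside the mask,
with the sum reduction.  Prediction values outside the mask cannot affect
the loss or its gradient.
"""

from __future__ import annotations

import numpy as np

__all__ = ["masked_l1", "masked_l1_with_grad", "target_mask"]


def target_mask(target: np.ndarray, threshold: float = 0.01) -> np.ndarray:
    """Support mask: target pixels above ``threshold`` times the target max."""
    return target > threshold * float(target.max())


def masked_l1(pred: np.ndarray, target: np.ndarray, threshold: float = 0.01) -> float:
    loss, _ = masked_l1_with_grad(pred, target, threshold)
    return loss


def masked_l1_with_grad(
    pred: np.ndarray, target: np.ndarray, threshold: float = 0.01
) -> tuple[float, np.ndarray]:
    """Sum of absolute differences inside the target-support mask, plus its
    (sub)gradient with respect to the prediction."""
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    mask = target_mask(target, threshold)
    diff = np.where(mask, pred - target, 0.0)
    return float(np.abs(diff).sum()), np.sign(diff)
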