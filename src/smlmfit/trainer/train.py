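"""Joint optimisation of per-image pose (via the CNN) and the shared 3D
model matrix through the differentiable renderer.

Per step: render the current model with each image's predicted pose and
predicted output-sigma, take the masked L1 loss against the (normalised)
target image, and backpropagate through splat, projection and rotation into
both the network weights and the model-matrix coordinates.  The direct
ablation (:func:`train_direct`) replaces the CNN with a per-image
5-parameter pose table optimised the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..geometry import PointCloud3D, axis_angle_jacobian, axis_angle_to_matrix
from ..renderer import RenderConfig, normalise_image_vjp, splat_with_grad
from ..simulator import SyntheticDataset
from .layers import Adam, Param
from .loss import masked_l1_with_grad
from .network import NetworkSpec, PoseNet, head_transform
from .schedule import SigmaSchedule

__all__ = [
    "TrainConfig",
    "TrainResult",
    "TrainingDivergedError",
    "evaluate_loss",
    "train",
    "train_direct",
]


class TrainingDivergedError(RuntimeError):
    """Non-finite loss or gradients encountered."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimiser and run settings (defaults follow the baseline runs)."""

    learning_rate: float = 0.0004
    batch_size: int = 32
    epochs: int = 40
    model_size: int = 350
    normalisation_scalar: float = 100.0
    seed: int = 0
    test_fraction: float = 0.1
    mask_threshold: float = 0.01
    dtype: str = "float64"
    sigma_head: str = "free"  # "free" or "bounded" output-sigma head
    # Adam moves each coordinate by at most ~lr per step, so short runs can
    # leave the model matrix too little travel; scaled-down runs raise this.
    verts_learning_rate: float | None = None

    @property
    def verts_lr(self) -> float:
        return self.verts_learning_rate or self.learning_rate

    def __post_init__(self) -> None:
        for name in ("learning_rate", "batch_size", "epochs", "model_size",
                     "normalisation_scalar"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in [0, 1)")


@dataclass
class TrainResult:
    reconstruction: PointCloud3D
    net: PoseNet | None
    trace: list[tuple[float, float]]  # per-epoch (train loss, test loss)
    pose_table: np.ndarray | None = None
    rejected_samples: int = 0
    extras: dict = field(default_factory=dict)


def _split_indices(dataset: SyntheticDataset, test_fraction: float,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """90/10-style split by base structure so augmented copies of one base
    sample never straddle the split."""
    bases = rng.permutation(dataset.n_base)
    n_test = int(round(test_fraction * dataset.n_base))
    test_bases = set(bases[:n_test].tolist())
    a = dataset.augment_factor
    idx = np.arange(len(dataset))
    is_test = np.isin(idx // a, list(test_bases)) if test_bases else np.zeros(len(idx), bool)
    return idx[~is_test], idx[is_test]


def _render_target(dataset: SyntheticDataset, i: int, sigma: float, scalar: float,
                   dtype) -> np.ndarray:
    img = dataset.render(i, sigma)
    total = float(img.pixels.sum())
    if total <= 0:
        raise TrainingDivergedError(f"sample {i} rendered with no intensity")
    return (img.pixels * (scalar / total)).astype(dtype)


def _sample_loss_and_grads(verts, rot, trans, sigma, target, config, render_config):
    """Loss of one rendered sample and its gradients.

    Returns (loss, grad_verts, grad_rot, grad_trans, grad_sigma); gradients
    flow through masked L1, image normalisation, the Gaussian splat and the
    axis-angle rotation.
    """
    R = axis_angle_to_matrix(rot)
    proj = (verts @ R[:2, :].T + trans).astype(np.dtype(config.dtype))
    img, splat_vjp = splat_with_grad(proj, sigma, render_config)
    total = float(img.pixels.sum())
    if total <= 0:
        # every Gaussian fell fully outside the frame: no usable gradient
        return None
    pred, norm_vjp = normalise_image_vjp(img.pixels, config.normalisation_scalar)
    loss, g_pred = masked_l1_with_grad(pred, target, config.mask_threshold)
    g_pts, g_sigma = splat_vjp(norm_vjp(g_pred))
    g_verts = g_pts @ R[:2, :]
    g_trans = g_pts.sum(axis=0)
    J = axis_angle_jacobian(rot)
    g_rot = np.array([
        float((g_pts * (verts @ J[k][:2, :].T)).sum()) for k in range(3)
    ])
    return loss, g_verts, g_rot, g_trans, g_sigma


def evaluate_loss(net: PoseNet, dataset: SyntheticDataset, indices, sigma: float,
                  config: TrainConfig, verts: np.ndarray,
                  render_config: RenderConfig) -> float:
    """Mean masked loss of the current model + network on given samples."""
    dtype = np.dtype(config.dtype)
    net.sigma_ref = sigma
    total, count = 0.0, 0
    for start in range(0, len(indices), config.batch_size):
        batch = indices[start : start + config.batch_size]
        targets = np.stack([
            _render_target(dataset, int(i), sigma, config.normalisation_scalar, dtype)
            for i in batch
        ])
        raw = net.forward(targets)
        rot, trans, sig, _, _ = head_transform(
            raw, net.sigma_ref, net.sigma_span, net.trans_limit, net.sigma_mode
        )
        for b in range(len(batch)):
            out = _sample_loss_and_grads(
                verts, rot[b], trans[b], float(sig[b]), targets[b], config, render_config
            )
            if out is not None:
                total += out[0]
                count += 1
    return total / max(count, 1)


def train(
    dataset: SyntheticDataset,
    net_spec: NetworkSpec,
    config: TrainConfig,
    schedule: SigmaSchedule,
    rng: np.random.Generator | None = None,
    max_steps_per_epoch: int | None = None,
    callback=None,
    init_verts: np.ndarray | None = None,
) -> TrainResult:
    """Fit the model matrix and pose network to a dataset.

    Fully reproducible from ``config.seed`` when ``rng`` is not supplied.
    ``max_steps_per_epoch`` truncates epochs (used by diagnostics and
    tests); ``callback(epoch, verts, trace)`` runs after every epoch;
    ``init_verts`` warm-starts the model matrix instead of the default
    uniform draw.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    if schedule.epochs < config.epochs:
        raise ValueError("schedule covers fewer epochs than the run")
    rng = rng or np.random.default_rng(config.seed)
    dtype = np.dtype(config.dtype)
    render_config = dataset.render_config

    net = PoseNet(net_spec, rng, dtype=dtype)
    net.sigma_ref = schedule.sigma_start
    net.sigma_mode = config.sigma_head
    if init_verts is not None:
        if init_verts.shape != (config.model_size, 3):
            raise ValueError("init_verts shape must match (model_size, 3)")
        verts = Param(np.array(init_verts, dtype=np.float64))
    else:
        verts = Param(rng.uniform(-0.5, 0.5, size=(config.model_size, 3)))
    opt = Adam(net.params, lr=config.learning_rate)
    opt_verts = Adam([verts], lr=config.verts_lr)

    train_idx, test_idx = _split_indices(dataset, config.test_fraction, rng)
    trace: list[tuple[float, float]] = []

    for epoch in range(config.epochs):
        sigma_in = schedule.sigma_at_epoch(epoch)
        net.sigma_ref = sigma_in
        order = rng.permutation(train_idx)
        if max_steps_per_epoch is not None:
            order = order[: max_steps_per_epoch * config.batch_size]
        epoch_loss, n_seen = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            targets = np.stack([
                _render_target(dataset, int(i), sigma_in, config.normalisation_scalar, dtype)
                for i in batch
            ])
            raw = net.forward(targets)
            rot, trans, sig, dtrans, dsig = head_transform(
                raw, net.sigma_ref, net.sigma_span, net.trans_limit, net.sigma_mode
            )
            dout = np.zeros_like(raw)
            opt.zero_grad()
            opt_verts.zero_grad()
            for b in range(len(batch)):
                out = _sample_loss_and_grads(
                    verts.value, rot[b], trans[b], float(sig[b]), targets[b],
                    config, render_config,
                )
                if out is None:
                    continue
                loss, g_verts, g_rot, g_trans, g_sigma = out
                epoch_loss += loss
                n_seen += 1
                verts.grad += g_verts
                dout[b, 0:3] = g_rot
                dout[b, 3:5] = g_trans * dtrans[b]
                dout[b, 5] = g_sigma * dsig[b]
            net.backward(dout)
            if not np.isfinite(epoch_loss):
                raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
            opt.step()
            opt_verts.step()
        mean_train = epoch_loss / max(n_seen, 1)
        mean_test = (
            evaluate_loss(net, dataset, test_idx, sigma_in, config, verts.value, render_config)
            if len(test_idx)
            else float("nan")
        )
        trace.append((mean_train, mean_test))
        if callback is not None:
            callback(epoch, verts.value.copy(), trace)

    recon = PointCloud3D(verts.value.copy(), label="reconstruction")
    return TrainResult(recon, net, trace)


def train_direct(
    dataset: SyntheticDataset,
    config: TrainConfig,
    schedule: SigmaSchedule,
    rng: np.random.Generator | None = None,
) -> TrainResult:
    """Ablation: optimise a per-image 5-parameter pose table (no network)
    jointly with the model matrix through the same renderer and loss.

    The renderer uses the current input-sigma directly, since there is no
    head to predict an output-sigma.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    rng = rng or np.random.default_rng(config.seed)
    dtype = np.dtype(config.dtype)
    render_config = dataset.render_config

    n = len(dataset)
    poses = Param(np.zeros((n, 5)))
    poses.value[:, 0:3] = rng.normal(scale=0.1, size=(n, 3))
    verts = Param(rng.uniform(-0.5, 0.5, size=(config.model_size, 3)))
    opt = Adam([poses], lr=config.learning_rate)
    opt_verts = Adam([verts], lr=config.verts_lr)

    train_idx, test_idx = _split_indices(dataset, config.test_fraction, rng)
    trace: list[tuple[float, float]] = []
    trans_limit = 0.5

    for epoch in range(config.epochs):
        sigma_in = schedule.sigma_at_epoch(epoch)
        order = rng.permutation(train_idx)
        epoch_loss, n_seen = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            opt.zero_grad()
            opt_verts.zero_grad()
            for i in batch:
                i = int(i)
                target = _render_target(dataset, i, sigma_in, config.normalisation_scalar, dtype)
                rot = poses.value[i, 0:3]
                th = np.tanh(poses.value[i, 3:5])
                out = _sample_loss_and_grads(
                    verts.value, rot, trans_limit * th, sigma_in, target,
                    config, render_config,
                )
                if out is None:
                    continue
                loss, g_verts, g_rot, g_trans, _ = out
                epoch_loss += loss
                n_seen += 1
                verts.grad += g_verts
                poses.grad[i, 0:3] = g_rot
                poses.grad[i, 3:5] = g_trans * trans_limit * (1.0 - th**2)
            if not np.isfinite(epoch_loss):
                raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
            opt.step()
            opt_verts.step()
        mean_train = epoch_loss / max(n_seen, 1)
        trace.append((mean_train, float("nan")))

    recon = PointCloud3D(verts.value.copy(), label="direct_reconstruction")
    return TrainResult(recon, None, trace, pose_table=poses.value.copy())
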