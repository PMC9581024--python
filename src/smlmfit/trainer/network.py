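"""The pose-regression CNN: strided 3x3 convolutions with leaky rectifier
activations, closed by two fully connected layers that reduce each image to
six numbers — three axis-angle rotation components, two in-plane
translations and one output-sigma."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ..geometry import Pose
from .layers import Conv2d, Flatten, LeakyReLU, Linear, Param

__all__ = ["NetworkSpec", "PoseNet", "PosePrediction", "predict"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of the pose-regression CNN.

    Channel widths double every other layer from ``base_channels`` up to
    ``max_channels``; enough stride-2 layers are placed (interleaved with
    stride-1 layers) to reduce the input to 1x1 spatially.
    """

    image_size: int = 128
    in_channels: int = 1
    n_conv: int = 10
    leaky_slope: float = 0.1
    base_channels: int = 16
    max_channels: int = 512
    fc_hidden: tuple[int, ...] = (256,)
    out_dim: int = 6

    def __post_init__(self) -> None:
        if self.out_dim != 6:
            raise ValueError("the pose head has exactly 6 outputs")
        n2 = int(np.log2(self.image_size))
        if 2**n2 != self.image_size:
            raise ValueError("image_size must be a power of two")
        if n2 > self.n_conv:
            raise ValueError(f"need at least {n2} conv layers for {self.image_size}px input")

    def strides(self) -> list[int]:
        n2 = int(np.log2(self.image_size))
        n1 = self.n_conv - n2
        pattern = [2, 1] * min(n1, n2) + [2] * max(n2 - n1, 0) + [1] * max(n1 - n2, 0)
        return pattern[: self.n_conv]

    def channels(self) -> list[int]:
        return [
            min(self.base_channels * 2 ** ((i + 1) // 2), self.max_channels)
            for i in range(self.n_conv)
        ]


@dataclass
class PosePrediction:
    """One network output: a pose plus the sigma the renderer should use."""

    pose: Pose
    output_sigma: float

    def __post_init__(self) -> None:
        if self.output_sigma <= 0:
            raise ValueError("output_sigma must be positive")


class PoseNet:
    """Manual-backprop CNN mapping a batch of images to (B, 6) raw outputs.

    The network holds no stochastic layers, so evaluation is deterministic.
    """

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator, dtype=np.float64) -> None:
        self.spec = spec
        self.dtype = dtype
        # pose-head shaping; the trainer keeps sigma_ref at the current
        # scheduled input-sigma, and the head predicts a bounded multiplier
        # of it (an unbounded output-sigma lets the network blur its render
        # into an uninformative blob, killing the pose gradients)
        self.sigma_ref = 3.0
        self.sigma_span = 2.0
        self.sigma_mode = "free"
        self.trans_limit = 0.5
        self.layers: list = []
        cin = spec.in_channels
        size = spec.image_size
        for cout, stride in zip(spec.channels(), spec.strides()):
            self.layers.append(Conv2d(cin, cout, stride, rng, dtype))
            self.layers.append(LeakyReLU(spec.leaky_slope))
            cin = cout
            size //= stride
        self.layers.append(Flatten())
        self._flat_dim = cin * size * size
        nin = self._flat_dim
        for nh in spec.fc_hidden:
            self.layers.append(Linear(nin, nh, rng, dtype))
            self.layers.append(LeakyReLU(spec.leaky_slope))
            nin = nh
        self.layers.append(Linear(nin, spec.out_dim, rng, dtype))

    @property
    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params]

    def forward(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=self.dtype)
        if x.ndim == 3:
            x = x[:, None, :, :]
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        g = np.asarray(dout, dtype=self.dtype)
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def head_transform(raw: np.ndarray, sigma_ref: float = 3.0, sigma_span: float = 2.0,
                   trans_limit: float = 0.5, sigma_mode: str = "free"):
    """Map raw network outputs to pose parameters.

    Rotations pass through unbounded; translations are squashed with tanh to
    keep the structure in frame.  The output-sigma is referenced to the
    current input-sigma ``sigma_ref``: in ``free`` mode it is
    ``0.1 + softplus(raw + c)`` with ``c`` chosen so a zero raw output
    predicts ``sigma_ref`` (unbounded above — the network may over-blur its
    render, which in practice protects the model matrix while poses are
    still wrong); in ``bounded`` mode it is ``sigma_ref * span**tanh(raw)``,
    within a factor ``span`` of the input-sigma.  Returns (rot, trans,
    sigma) plus the derivatives of the squashed components for backprop.
    """
    rot = raw[:, 0:3]
    th = np.tanh(raw[:, 3:5])
    trans = trans_limit * th
    dtrans = trans_limit * (1.0 - th**2)
    if sigma_mode == "fixed":
        # output-sigma tied to the input-sigma (sanctioned for clean data);
        # removes the "blur everything" gradient channel entirely
        sigma = np.full(raw.shape[0], float(sigma_ref))
        dsigma = np.zeros(raw.shape[0])
    elif sigma_mode == "free":
        floor = 0.1
        c = _softplus_inverse(max(sigma_ref - floor, 1e-3))
        z = raw[:, 5] + c
        sigma = floor + np.logaddexp(0.0, z)
        dsigma = 1.0 / (1.0 + np.exp(-z))
    elif sigma_mode == "bounded":
        ts = np.tanh(raw[:, 5])
        sigma = sigma_ref * sigma_span**ts
        dsigma = sigma * np.log(sigma_span) * (1.0 - ts**2)
    else:
        raise ValueError(f"unknown sigma_mode {sigma_mode!r}")
    return rot, trans, sigma, dtrans, dsigma


def _softplus_inverse(y: float) -> float:
    return float(np.log(np.expm1(y))) if y < 30 else float(y)


def predict(
    net: PoseNet, images: np.ndarray, normalisation_scalar: float | None = None
) -> list[PosePrediction]:
    """Evaluate the network on a batch of images.

    When ``normalisation_scalar`` is given, images whose integrated
    intensity deviates from it by more than 1% trigger a warning log,
    since the network was trained on normalised inputs.
    """
    x = np.asarray(images, dtype=net.dtype)
    if x.ndim == 2:
        x = x[None]
    if normalisation_scalar is not None:
        sums = x.reshape(x.shape[0], -1).sum(axis=1)
        off = np.abs(sums - normalisation_scalar) > 0.01 * normalisation_scalar
        if off.any():
            logger.warning(
                "%d of %d input images are not normalised to %g",
                int(off.sum()), len(sums), normalisation_scalar,
            )
    raw = net.forward(x)
    rot, trans, sigma, _, _ = head_transform(
        raw, net.sigma_ref, net.sigma_span, net.trans_limit, net.sigma_mode
    )
    return [
        PosePrediction(Pose(rot[i], trans[i]), float(sigma[i])) for i in range(len(raw))
    ]
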