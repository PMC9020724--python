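"""The 1D CNN classifier/regressor and its multi-task variant.

Architecture (encoder): two convolutional blocks — Conv1d + BatchNorm + ReLU
with 16 then 32 filters, both kernel size 8 and same padding — followed by
average pooling (window 4, stride 3), flattening, and two fully connected
layers (hidden 64, then 3 class logits or 1 regression output) with dropout
0.2 before each.

The multi-task variant adds a spectral-reconstruction decoder branching from
the flattened pooled features: a fully connected layer whose width is derived
from the encoder's pooled length, reshaped to (32, L0), then two blocks of
Conv + BatchNorm + ReLU + nearest upsampling (x2) with 32 then 16 filters
(kernel 8), and a final 1-filter convolution (kernel 4) cropped to the input
length.  Its output reconstructs the standardized input spectrum, which
regularizes the shared encoder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .layers import (
    Adam, AvgPool1d, BatchNorm1d, Conv1d, Dense, Dropout, Flatten, Layer,
    Reshape, Upsample, softmax,
)

logger = logging.getLogger(__name__)


class ModelError(ValueError):
    pass


@dataclass
class ModelConfig:
    input_channels: int = 186
    conv1_filters: int = 16
    conv1_kernel: int = 8
    conv2_filters: int = 32
    conv2_kernel: int = 8
    pool_window: int = 4
    pool_stride: int = 3
    fc_hidden: int = 64        # swept 32..1024 when tuning
    n_classes: int = 3
    dropout_rate: float = 0.2
    multitask: bool = False
    recon_weight: float = 0.5
    head: str = "classify"     # or "regress"
    dtype: str = "float32"     # float64 available for gradient checking
    seed: int = 0

    def validate(self) -> None:
        for name in ("input_channels", "conv1_filters", "conv1_kernel",
                     "conv2_filters", "conv2_kernel", "pool_window",
                     "pool_stride", "fc_hidden", "n_classes"):
            if getattr(self, name) < 1:
                raise ModelError(f"{name} must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ModelError("dropout_rate must be in [0, 1)")
        if self.recon_weight < 0:
            raise ModelError("recon_weight must be >= 0")
        if self.head not in ("classify", "regress"):
            raise ModelError(f"unknown head '{self.head}'")


# ---------------------------------------------------------------------------
# loss functions (sum-over-samples conventions)
# ---------------------------------------------------------------------------

_EPS = 1e-12


def classification_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Categorical cross-entropy, -sum_i y_i log p_i, summed over samples.

    ``probs`` rows must lie on the simplex; a zero probability at the true
    class is clamped at 1e-12 and logged.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    labels = np.atleast_1d(np.asarray(labels))
    if np.any(probs < -1e-9) or np.any(np.abs(probs.sum(axis=1) - 1) > 1e-6):
        raise ModelError("probability rows must lie on the simplex")
    p_true = probs[np.arange(len(labels)), labels]
    if np.any(p_true <= 0):
        logger.warning("classification_loss: clamping %d zero probabilities",
                       int((p_true <= 0).sum()))
    return float(-np.log(np.clip(p_true, _EPS, 1.0)).sum())


def reconstruction_loss(observed: np.ndarray, reconstructed: np.ndarray) -> float:
    """Sum over samples of the per-sample mean squared channel error."""
    observed = np.atleast_2d(np.asarray(observed, dtype=float))
    reconstructed = np.atleast_2d(np.asarray(reconstructed, dtype=float))
    if observed.shape != reconstructed.shape:
        raise ModelError(
            f"shape mismatch {observed.shape} vs {reconstructed.shape}"
        )
    return float(((observed - reconstructed) ** 2).mean(axis=1).sum())


def combined_loss(class_loss: float, recon_loss: float,
                  recon_weight: float = 0.5) -> float:
    """Multi-task objective: 1.0 * classification + recon_weight * reconstruction."""
    return float(class_loss + recon_weight * recon_loss)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class SpectralCNN:
    """Encoder + task head (+ optional reconstruction decoder).

    Inputs are (batch, input_channels) standardized spectra.  ``forward``
    returns a dict with ``probs``/``logits`` (classify) or ``output``
    (regress) and, for the multi-task variant, ``recon``.
    """

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        L = config.input_channels
        dt = np.dtype(config.dtype).type

        self.conv1 = Conv1d(1, config.conv1_filters, config.conv1_kernel, rng, dtype=dt)
        self.bn1 = BatchNorm1d(config.conv1_filters, dtype=dt)
        self.relu1 = _relu()
        self.conv2 = Conv1d(config.conv1_filters, config.conv2_filters,
                            config.conv2_kernel, rng, dtype=dt)
        self.bn2 = BatchNorm1d(config.conv2_filters, dtype=dt)
        self.relu2 = _relu()
        self.pool = AvgPool1d(config.pool_window, config.pool_stride)
        try:
            self.pooled_len = self.pool.out_length(L)
        except ValueError as exc:
            raise ModelError(f"pooling layer: {exc}") from exc
        self.flatten = Flatten()
        flat_dim = config.conv2_filters * self.pooled_len

        self.drop1 = Dropout(config.dropout_rate, rng)
        self.fc1 = Dense(flat_dim, config.fc_hidden, rng, dtype=dt)
        self.relu_fc = _relu()
        self.drop2 = Dropout(config.dropout_rate, rng)
        out_dim = config.n_classes if config.head == "classify" else 1
        self.fc2 = Dense(config.fc_hidden, out_dim, rng, dtype=dt)

        self.decoder: list[Layer] | None = None
        if config.multitask:
            # decoder width derived from the encoder: two x2 upsamplings must
            # reach at least the input length
            L0 = int(np.ceil(L / 4))
            self.dec_len0 = L0
            self.dec_fc = Dense(flat_dim, config.conv2_filters * L0, rng, dtype=dt)
            self.decoder = [
                Reshape(config.conv2_filters, L0),
                Conv1d(config.conv2_filters, 32, 8, rng, dtype=dt),
                BatchNorm1d(32, dtype=dt), _relu(),
                Upsample(2),
                Conv1d(32, 16, 8, rng, dtype=dt), BatchNorm1d(16, dtype=dt), _relu(),
                Upsample(2),
                Conv1d(16, 1, 4, rng, dtype=dt),
            ]
            self._crop_left = (4 * L0 - L) // 2

        self._encoder_chain = [self.conv1, self.bn1, self.relu1,
                               self.conv2, self.bn2, self.relu2]

    # -- plumbing ----------------------------------------------------------

    def params(self):
        layers: list[Layer] = (self._encoder_chain
                               + [self.fc1, self.fc2])
        if self.decoder is not None:
            layers = layers + [self.dec_fc] + self.decoder
        out = []
        for lay in layers:
            out.extend(lay.params())
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (p, _), w in zip(self.params(), weights):
            p[:] = w

    # -- forward/backward --------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> dict:
        x = np.asarray(x, dtype=np.dtype(self.config.dtype))
        if x.ndim != 2 or x.shape[1] != self.config.input_channels:
            raise ModelError(
                f"expected (batch, {self.config.input_channels}) input, got {x.shape}"
            )
        h = x[:, None, :]
        for lay in self._encoder_chain:
            h = lay.forward(h, train)
        self.conv_features = h          # (N, 32, L): Grad-CAM anchor
        p = self.pool.forward(h, train)
        z = self.flatten.forward(p, train)
        self._flat = z

        hd = self.drop1.forward(z, train)
        hd = self.fc1.forward(hd, train)
        hd = self.relu_fc.forward(hd, train)
        hd = self.drop2.forward(hd, train)
        logits = self.fc2.forward(hd, train)

        out: dict = {}
        if self.config.head == "classify":
            out["logits"] = logits
            out["probs"] = softmax(logits)
        else:
            out["output"] = logits[:, 0]

        if self.decoder is not None:
            d = self.dec_fc.forward(z, train)
            for lay in self.decoder:
                d = lay.forward(d, train)
            L = self.config.input_channels
            self._dec_full_len = d.shape[2]
            out["recon"] = d[:, 0, self._crop_left:self._crop_left + L]
        return out

    def backward(self, grad_head: np.ndarray,
                 grad_recon: np.ndarray | None = None) -> None:
        """Accumulate parameter gradients.

        ``grad_head``: gradient w.r.t. logits (classify) or the scalar output
        column (regress), shape (N, out_dim).  ``grad_recon``: gradient
        w.r.t. the cropped reconstruction, shape (N, input_channels).
        """
        g = self.fc2.backward(grad_head)
        g = self.drop2.backward(g)
        g = self.relu_fc.backward(g)
        g = self.fc1.backward(g)
        gz = self.drop1.backward(g)

        if grad_recon is not None and self.decoder is not None:
            L = self.config.input_channels
            gd = np.zeros((grad_recon.shape[0], 1, self._dec_full_len))
            gd[:, 0, self._crop_left:self._crop_left + L] = grad_recon
            for lay in reversed(self.decoder):
                gd = lay.backward(gd)
            gz = gz + self.dec_fc.backward(gd)

        gp = self.flatten.backward(gz)
        gh = self.pool.backward(gp)
        for lay in reversed(self._encoder_chain):
            gh = lay.backward(gh)

    def head_gradient_to_conv(self, grad_head: np.ndarray) -> np.ndarray:
        """Gradient of a head functional w.r.t. the last conv-block output.

        Used by Grad-CAM; runs the head-only backward chain without touching
        parameter gradients' consumers (gradients are overwritten next step).
        """
        g = self.fc2.backward(grad_head)
        g = self.drop2.backward(g)
        g = self.relu_fc.backward(g)
        g = self.fc1.backward(g)
        g = self.drop1.backward(g)
        gp = self.flatten.backward(g)
        return self.pool.backward(gp)

    def make_optimizer(self, lr: float = 1e-3) -> Adam:
        return Adam(self.params(), lr=lr)


def _relu():
    from .layers import ReLU
    return ReLU()


def build_model(config: ModelConfig) -> SpectralCNN:
    """Construct the network; raises ModelError naming the offending layer."""
    return SpectralCNN(config)
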