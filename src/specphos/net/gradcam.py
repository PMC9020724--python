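"""Grad-CAM attribution for 1D spectral models.

Gradient-weighted class activation mapping: the gradient of the target
signal (a class logit, or the regression output) with respect to the last
convolution block's output is averaged over positions per filter; the
filter maps, weighted by those averages, are summed, rectified (only
positively contributing regions kept), linearly interpolated to the input
wavelength resolution, and normalized to sum to 1 per sample.
"""

from __future__ import annotations

import logging

import numpy as np

from .models import ModelError, SpectralCNN

logger = logging.getLogger(__name__)


def grad_cam(model: SpectralCNN, spectra: np.ndarray,
             target: int | str = 0) -> np.ndarray:
    """Per-channel attribution maps, shape (n_samples, input_channels).

    ``target``: class index for a classifier; ignored (the scalar output is
    used) for a regressor.  Dropout and batch-norm run in eval mode, so two
    identical inputs give identical maps.  All-zero maps fall back to
    uniform attribution, logged.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    out = model.forward(spectra, train=False)

    n = spectra.shape[0]
    if model.config.head == "classify":
        if not isinstance(target, (int, np.integer)):
            raise ModelError(f"classifier target must be a class index, got {target!r}")
        if not 0 <= int(target) < model.config.n_classes:
            raise ModelError(f"class index {target} out of range")
        grad_head = np.zeros_like(out["logits"])
        grad_head[:, int(target)] = 1.0
    else:
        grad_head = np.ones((n, 1))

    dA = model.head_gradient_to_conv(grad_head)   # (N, F, L_conv)
    A = model.conv_features
    alpha = dA.mean(axis=2)                        # (N, F)
    cam = np.maximum((alpha[:, :, None] * A).sum(axis=1), 0.0)  # (N, L_conv)

    L_in = model.config.input_channels
    if cam.shape[1] != L_in:
        xi = np.linspace(0.0, 1.0, cam.shape[1])
        xo = np.linspace(0.0, 1.0, L_in)
        cam = np.vstack([np.interp(xo, xi, row) for row in cam])

    totals = cam.sum(axis=1)
    flat = totals <= 0
    if flat.any():
        logger.info("grad_cam: %d all-zero maps replaced by uniform", int(flat.sum()))
        cam[flat] = 1.0
        totals[flat] = L_in
    return cam / totals[:, None]
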