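"""Small shared numerics helpers."""

from __future__ import annotations

import numpy as np


def nrmse(reference: np.ndarray, test: np.ndarray,
          normalization: str = "euclidean") -> float:
    """Normalised root-mean-square error between two volumes.

    ``euclidean`` divides by the reference's L2 norm (used for the MR
    consistency checks, where both volumes share support); ``peak`` divides
    the RMSE by the reference's maximum, the usual choice for emission
    images whose activity is concentrated in a small fraction of the volume.
    """
    a = np.abs(np.asarray(reference)).astype(float)
    b = np.abs(np.asarray(test)).astype(float)
    diff = np.sqrt(np.mean((a - b) ** 2))
    if normalization == "euclidean":
        return float(np.linalg.norm(a - b) / np.linalg.norm(a))
    if normalization == "peak":
        return float(diff / a.max())
    raise ValueError(f"unknown normalization {normalization!r}")
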