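"""Norm-power basis expansion and the shared error/gradient primitives.

The risk predictor is linear in parameters, y_hat = b @ w, where each of the
five analyte columns x is expanded through seven fixed maps

    1,  |x|^1/2,  |x|^1,  |x|^1.2,  |x|^2,  |x|^3,  |x|^4

giving a 35-column basis (analyte-major order: all seven maps of HTC first).
Absolute values keep the fractional powers real for held-out rows that land
below 0 on the training scale.  The five duplicate bias columns make b^T b
rank-deficient by construction; solvers downstream must tolerate this.

Labels enter fitting on the unit scale (percent / 100), which conditions the
optimization; reporting converts back to percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import ANALYTES

#: Exponents of the seven basis maps; None marks the bias (constant 1) column.
BASIS_EXPONENTS = (None, 0.5, 1.0, 1.2, 2.0, 3.0, 4.0)

#: Basis dimensionality: 7 maps x 5 analytes.
N_BASIS = len(BASIS_EXPONENTS) * len(ANALYTES)

#: Column names, analyte-major: htc_bias, htc_pow0.5, ..., mpv_pow4.
BASIS_COLUMN_NAMES = tuple(
    f"{a}_bias" if p is None else f"{a}_pow{p:g}"
    for a in ANALYTES
    for p in BASIS_EXPONENTS
)


@dataclass
class BasisMatrix:
    """M x 35 basis expansion of an M x 5 analyte matrix."""

    b: np.ndarray
    column_names: tuple = BASIS_COLUMN_NAMES

    @property
    def m(self) -> int:
        return self.b.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Basis as a labelled DataFrame (debugging / export)."""
        return pd.DataFrame(self.b, columns=list(self.column_names))


@dataclass
class PredictionError:
    """Residual vector e = y - y_hat and its squared norm."""

    e: np.ndarray

    @property
    def sq(self) -> float:
        return float(self.e @ self.e)


def build_basis(d_e: np.ndarray) -> BasisMatrix:
    """Expand an M x 5 analyte matrix into the M x 35 power basis."""
    d_e = np.asarray(d_e, dtype=float)
    if d_e.ndim != 2 or d_e.shape[1] != len(ANALYTES):
        raise ValueError(f"expected an M x {len(ANALYTES)} matrix, got {d_e.shape}")
    if not np.all(np.isfinite(d_e)):
        raise ValueError("analyte matrix contains non-finite values")
    cols = []
    for j in range(d_e.shape[1]):
        x = np.abs(d_e[:, j])
        for p in BASIS_EXPONENTS:
            cols.append(np.ones_like(x) if p is None else x**p)
    return BasisMatrix(b=np.column_stack(cols))


def predict(w: np.ndarray, b: BasisMatrix) -> np.ndarray:
    """Model output y_hat = b @ w per row."""
    w = np.asarray(w, dtype=float)
    if w.shape != (b.b.shape[1],):
        raise ValueError(f"weight vector must have length {b.b.shape[1]}, got {w.shape}")
    return b.b @ w


def prediction_error(y: np.ndarray, y_hat: np.ndarray) -> PredictionError:
    """Residual e = y - y_hat."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    return PredictionError(e=y - y_hat)


def squared_error_gradient(b: BasisMatrix, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Gradient of the squared residual norm: -2 b^T y + 2 b^T b w."""
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if y.shape != (b.m,) or w.shape != (b.b.shape[1],):
        raise ValueError("dimension mismatch between basis, labels and weights")
    return -2.0 * (b.b.T @ y) + 2.0 * (b.b.T @ (b.b @ w))
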