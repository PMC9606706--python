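"""Depth-weighted minimum-norm source estimation with dSPM and sLORETA.

The estimator is formulated after whitening. With noise covariance C
(diagonally loaded by a factor of 0.1 of its mean diagonal), whitener
W = C'^(-1/2), whitened gain G~ = W G, and depth-weight prior
R = diag(||g~_j||^(-2*gamma)) rescaled so trace(G~ R G~') equals the number
of sensors, the minimum-norm kernel is

    K = R G~' (G~ R G~' + lambda^2 I)^(-1) W,      lambda^2 = 1 / SNR^2

with defaults gamma = 0.5 and SNR = 3 (amplitude ratio). Raw minimum-norm
currents K x are standardized per source:

  * dSPM divides by the noise-propagated standard deviation, the row norm of
    R G~' M^(-1) (unit variance under whitened noise);
  * sLORETA divides by the square root of the model data-covariance diagonal,
    diag(R G~' M^(-1) G~ R)^(1/2), which gives exact peak localization for a
    single noiseless source;
  * MNE-raw divides by nothing (A.m units, superficially biased).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .forward import Leadfield
from .simulate import SensorEpochs

__all__ = [
    "NoiseCovariance",
    "InverseOperator",
    "SourceEstimate",
    "estimate_noise_covariance",
    "make_inverse_operator",
    "apply_inverse",
]

METHODS = ("dSPM", "sLORETA", "MNE-raw")


class ProvenanceError(ValueError):
    """Mismatched channels between data and operator."""


@dataclass(frozen=True)
class NoiseCovariance:
    """Regularized sensor noise covariance (V^2)."""

    matrix: np.ndarray
    n_samples_used: int
    regularization_factor: float
    channel_labels: tuple[str, ...]

    def __post_init__(self):
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(m, m.T, atol=1e-18 + 1e-10 * np.abs(m).max()):
            raise ValueError("covariance must be symmetric")


@dataclass(frozen=True)
class InverseOperator:
    """Linear kernel plus per-source standardization divisors."""

    kernel: np.ndarray  # V x n_sensors, includes the whitener
    norm_factors: np.ndarray  # V, strictly positive
    method: str
    depth_order: float
    snr: float
    channel_labels: tuple[str, ...]
    sourcespace_ref: str

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if not np.all(np.isfinite(self.kernel)):
            raise ValueError("kernel must be finite")
        if not (np.all(self.norm_factors > 0) and np.all(np.isfinite(self.norm_factors))):
            raise ValueError("norm factors must be strictly positive and finite")


@dataclass(frozen=True)
class SourceEstimate:
    """Vertices x time standardized current-density scores."""

    values: np.ndarray
    times: np.ndarray
    method: str
    sourcespace_ref: str


def estimate_noise_covariance(
    epochs: SensorEpochs,
    window: tuple[float, float] = (-0.200, 0.0),
    reg: float = 0.1,
) -> NoiseCovariance:
    """Empirical covariance over pooled pre-stimulus baseline samples.

    The per-trial, per-channel baseline mean is removed before pooling;
    the regularized form is C' = C + reg * mean(diag(C)) * I.
    """
    if epochs.n_trials < 2:
        raise ValueError("need at least two trials")
    mask = (epochs.times >= window[0]) & (epochs.times <= window[1])
    n_win = int(mask.sum())
    if n_win < 2:
        raise ValueError("baseline window is degenerate")
    base = epochs.data[:, :, mask]
    base = base - base.mean(axis=2, keepdims=True)
    x = np.concatenate([base[k] for k in range(base.shape[0])], axis=1)
    n_total = x.shape[1]
    c = (x @ x.T) / (n_total - epochs.n_trials)  # dof lost to per-trial demeaning
    c_reg = c + reg * np.mean(np.diag(c)) * np.eye(c.shape[0])
    return NoiseCovariance(
        matrix=c_reg,
        n_samples_used=n_total,
        regularization_factor=reg,
        channel_labels=epochs.channel_labels,
    )


def _symmetric_inv_sqrt(m: np.ndarray) -> np.ndarray:
    vals, vecs = scipy.linalg.eigh(m)
    if vals.min() <= 0:
        raise np.linalg.LinAlgError("covariance is not positive definite")
    return (vecs * (1.0 / np.sqrt(vals))) @ vecs.T


def make_inverse_operator(
    leadfield: Leadfield,
    noisecov: NoiseCovariance,
    method: str,
    depth_order: float = 0.5,
    snr: float = 3.0,
) -> InverseOperator:
    """Assemble the whitened, depth-weighted minimum-norm kernel and the
    method-specific standardization factors."""
    if leadfield.channel_labels != noisecov.channel_labels:
        raise ProvenanceError("leadfield and covariance sensor sets differ")
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    G = leadfield.gain
    n_sensors = G.shape[0]
    W = _symmetric_inv_sqrt(noisecov.matrix)
    Gw = W @ G
    col_norm2 = np.sum(Gw**2, axis=0)
    if np.any(col_norm2 == 0):
        raise ValueError("degenerate (all-zero) leadfield column")
    r = col_norm2 ** (-depth_order)
    r *= n_sensors / np.sum(r * col_norm2)  # trace(Gw R Gw') = n_sensors
    lam2 = 1.0 / snr**2
    GR = Gw * r[None, :]  # Gw @ R
    M = GR @ Gw.T + lam2 * np.eye(n_sensors)
    Minv = scipy.linalg.inv(M)
    A = GR.T @ Minv  # R Gw' M^-1, V x n_sensors
    if method == "dSPM":
        norm = np.sqrt(np.sum(A**2, axis=1))
    elif method == "sLORETA":
        norm = np.sqrt(np.sum(A * GR.T, axis=1))  # diag(R Gw' M^-1 Gw R)
    else:
        norm = np.ones(G.shape[1])
    return InverseOperator(
        kernel=A @ W,
        norm_factors=norm,
        method=method,
        depth_order=depth_order,
        snr=snr,
        channel_labels=leadfield.channel_labels,
        sourcespace_ref=leadfield.sourcespace_ref,
    )


def apply_inverse(
    data: np.ndarray | SensorEpochs,
    operator: InverseOperator,
    times: np.ndarray | None = None,
    channel_labels: tuple[str, ...] | None = None,
) -> SourceEstimate:
    """Map average-referenced sensor data (sensors x time) to source scores."""
    if isinstance(data, SensorEpochs):
        if data.channel_labels != operator.channel_labels:
            raise ProvenanceError("channel labels do not match the operator")
        x = data.data.mean(axis=0)
        t = data.times
    else:
        if channel_labels is not None and tuple(channel_labels) != operator.channel_labels:
            raise ProvenanceError("channel labels do not match the operator")
        x = np.atleast_2d(np.asarray(data, dtype=float))
        t = np.arange(x.shape[1], dtype=float) if times is None else np.asarray(times)
    values = (operator.kernel @ x) / operator.norm_factors[:, None]
    return SourceEstimate(
        values=values, times=t, method=operator.method, sourcespace_ref=operator.sourcespace_ref
    )
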