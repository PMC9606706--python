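"""Analytic EEG forward solution for a dipole in concentric spherical shells.

The scalp potential of a current dipole inside a layered spherical conductor
separates into spherical harmonics. Writing ``x = f/R`` for the dipole
eccentricity (source distance f over scalp radius R) and ``u`` for the cosine
of the angle between the dipole position and the electrode, the surface
potential is

    V = 1/(4 pi sigma_1 R^2) * sum_n tau_n x^(n-1)
        [ n q_r P_n(u) + (q.e_hat - u q_r) P_n'(u) ]

where ``q_r`` is the radial moment component, ``P_n`` the Legendre
polynomials, and ``tau_n`` a per-degree shell factor obtained from the
boundary conditions (continuity of potential and radial current at the two
skull interfaces, zero current through the scalp). For a homogeneous sphere
``tau_n = (2n+1)/n`` and the series has a closed form, used as the test
oracle. The skull's low relative conductivity (0.0125) shrinks ``tau_n``,
i.e. smears and attenuates the scalp topography.

Leadfields are assembled with unit dipoles (1 A.m) along each source normal
(constrained orientation) and are average-referenced, so forward and inverse
share one reference convention.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .geometry import ElectrodeMontage, SphericalHeadModel, SourceSpace

__all__ = [
    "Leadfield",
    "shell_potential",
    "homogeneous_sphere_potential",
    "compute_leadfield",
]

MAX_TERMS = 2000
MIN_TERMS = 60


class DomainError(ValueError):
    """Source or sensor outside its admissible region."""


class ConvergenceError(RuntimeError):
    """Harmonic series failed to converge within the term cap."""


@dataclass(frozen=True)
class Leadfield:
    """Sensors x sources gain matrix, V per (A.m), average-referenced."""

    gain: np.ndarray
    channel_labels: tuple[str, ...]
    n_sources: int
    head_ref: str
    montage_ref: str
    sourcespace_ref: str

    def __post_init__(self):
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("leadfield contains non-finite entries")


def _digest(*arrays) -> str:
    h = hashlib.sha1()
    for a in arrays:
        h.update(np.ascontiguousarray(np.asarray(a, dtype=float)).tobytes())
    return h.hexdigest()[:12]


# ---------------------------------------------------------------------------
# shell factors

_tau_cache: dict[tuple, np.ndarray] = {}


def shell_factors(head: SphericalHeadModel, n_max: int) -> np.ndarray:
    """Dimensionless per-degree transfer factors tau_n, n = 1..n_max.

    Derived by propagating the harmonic-n solution outward: the insulating
    scalp boundary fixes the outer-region mixing ratio, the two skull
    interfaces are eliminated analytically, leaving a scalar relation
    between the (unit) source coefficient and the scalp-surface value.
    """
    key = (head.radii, head.conductivities)
    cached = _tau_cache.get(key)
    if cached is not None and len(cached) >= n_max:
        return cached[:n_max]

    s1, s2, s3 = head.conductivities
    R = head.scalp_radius
    a1, a2 = head.radii[0] / R, head.radii[1] / R
    n = np.arange(1, n_max + 1, dtype=float)

    # outer region (scalp layer): V3 = A3 [rho^n + n/(n+1) rho^-(n+1)]
    phi_a2 = a2**n + (n / (n + 1)) * a2 ** -(n + 1)
    psi_a2 = n * (a2 ** (n - 1) - a2 ** -(n + 2))
    # skull layer coefficients per unit A3, pre-multiplied by their radial term
    A2p = ((n + 1) * phi_a2 + a2 * (s3 / s2) * psi_a2) / (2 * n + 1)  # A2 a2^n
    B2q = (n * phi_a2 - a2 * (s3 / s2) * psi_a2) / (2 * n + 1)  # B2 a2^-(n+1)
    t = a1 / a2
    v = A2p * t**n + B2q * t ** -(n + 1)  # V2(a1) per unit A3
    w = (n / a1) * A2p * t**n - ((n + 1) / a1) * B2q * t ** -(n + 1)  # V2'(a1)

    denom = s1 * n * v - s2 * a1 * w
    A3 = s1 * (2 * n + 1) * a1 ** -(n + 1) / denom
    tau = A3 * (2 * n + 1) / (n + 1)
    _tau_cache[key] = tau
    return tau


# ---------------------------------------------------------------------------
# potentials


def _check_on_scalp(pos: np.ndarray, head: SphericalHeadModel, atol: float = 1e-6):
    r = np.linalg.norm(np.atleast_2d(pos) - head.center, axis=1)
    if np.any(np.abs(r - head.scalp_radius) > atol):
        raise DomainError("electrode not on the scalp sphere")


def shell_potential(
    dipole_pos: np.ndarray,
    dipole_moment: np.ndarray,
    electrode_pos: np.ndarray,
    head: SphericalHeadModel,
    tol: float = 1e-8,
) -> float:
    """Scalp potential (volts) of one dipole (A.m) at one electrode.

    The harmonic series is truncated once the last term's relative
    contribution drops below ``tol`` (at least MIN_TERMS terms are summed);
    exceeding MAX_TERMS raises ConvergenceError.
    """
    dipole_pos = np.asarray(dipole_pos, dtype=float)
    q = np.asarray(dipole_moment, dtype=float)
    electrode_pos = np.asarray(electrode_pos, dtype=float)
    _check_on_scalp(electrode_pos, head)

    R = head.scalp_radius
    p = dipole_pos - head.center
    f = np.linalg.norm(p)
    if f >= head.inner_skull_radius:
        raise DomainError("dipole must lie strictly inside the inner skull")
    e_hat = (electrode_pos - head.center) / np.linalg.norm(electrode_pos - head.center)
    if f == 0.0:
        # radial decomposition degenerates; only n=1 survives (x^(n-1) -> 0^0)
        qn = np.linalg.norm(q)
        p_hat = e_hat if qn == 0 else q / qn
    else:
        p_hat = p / f
    x = f / R
    u = float(np.clip(p_hat @ e_hat, -1.0, 1.0))
    q_r = float(q @ p_hat)
    q_tan = float(q @ e_hat) - u * q_r  # equals q_t * sin(gamma)

    tau = shell_factors(head, MAX_TERMS)
    total = 0.0
    P_nm1, P_n = 1.0, u  # P_0, P_1
    dP_nm1, dP_n = 0.0, 1.0
    xpow = 1.0  # x^(n-1)
    for n in range(1, MAX_TERMS + 1):
        term = tau[n - 1] * xpow * (n * q_r * P_n + q_tan * dP_n)
        total += term
        if n >= MIN_TERMS and abs(term) <= tol * max(abs(total), np.finfo(float).tiny):
            break
        # Legendre recurrences for P_{n+1}, P'_{n+1}
        P_np1 = ((2 * n + 1) * u * P_n - n * P_nm1) / (n + 1)
        dP_np1 = (2 * n + 1) * P_n + dP_nm1
        P_nm1, P_n = P_n, P_np1
        dP_nm1, dP_n = dP_n, dP_np1
        xpow *= x
    else:
        raise ConvergenceError("series did not converge within MAX_TERMS")
    return total / (4.0 * np.pi * head.conductivities[0] * R**2)


def homogeneous_sphere_potential(
    dipole_pos: np.ndarray,
    dipole_moment: np.ndarray,
    electrode_pos: np.ndarray,
    radius: float,
    sigma: float = 1.0,
    center: np.ndarray | None = None,
) -> float:
    """Closed-form surface potential of a dipole in a homogeneous sphere.

    Independent of the series solution: obtained by summing the harmonic
    expansion with the known generating functions of the Legendre
    polynomials. Serves as the oracle for the equal-conductivity limit.
    """
    c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    p = np.asarray(dipole_pos, dtype=float) - c
    q = np.asarray(dipole_moment, dtype=float)
    e = np.asarray(electrode_pos, dtype=float) - c
    R = float(radius)
    f = np.linalg.norm(p)
    e_hat = e / np.linalg.norm(e)
    if f == 0.0:
        return 3.0 * float(q @ e_hat) / (4.0 * np.pi * sigma * R**2)
    p_hat = p / f
    x = f / R
    u = float(np.clip(p_hat @ e_hat, -1.0, 1.0))
    q_r = float(q @ p_hat)
    q_tan = float(q @ e_hat) - u * q_r
    rho = np.sqrt(1.0 - 2.0 * x * u + x * x)
    radial = q_r * (2.0 * (u - x) / rho**3 + (1.0 / rho - 1.0) / x)
    tangential = q_tan * (2.0 / rho**3 + (1.0 + rho) / (rho * (1.0 - x * u + rho)))
    return (radial + tangential) / (4.0 * np.pi * sigma * R**2)


# ---------------------------------------------------------------------------
# leadfield assembly


def compute_leadfield(
    head: SphericalHeadModel,
    montage: ElectrodeMontage,
    sourcespace: SourceSpace,
    tol: float = 1e-8,
) -> Leadfield:
    """Average-referenced gain matrix for unit dipoles along source normals.

    Vectorized over all sensor-vertex pairs; the series length is fixed from
    the most eccentric source so every pair converges to ``tol``.
    """
    _check_on_scalp(montage.positions, head)
    R = head.scalp_radius
    pv = sourcespace.vertices - head.center
    f = np.linalg.norm(pv, axis=1)
    if np.any(f >= head.inner_skull_radius):
        raise DomainError("source vertices must lie strictly inside the inner skull")
    with np.errstate(invalid="ignore"):
        p_hat = np.where(f[:, None] > 0, pv / np.where(f[:, None] == 0, 1.0, f[:, None]), 0.0)
    x = f / R
    x_max = float(x.max())
    if x_max > 0:
        n_terms = int(np.ceil(np.log(tol) / np.log(x_max))) + 30
    else:
        n_terms = MIN_TERMS
    n_terms = int(np.clip(n_terms, MIN_TERMS, MAX_TERMS))
    tau = shell_factors(head, n_terms)

    e_rel = montage.positions - head.center
    e_hat = e_rel / np.linalg.norm(e_rel, axis=1)[:, None]
    q = sourcespace.normals  # unit moments, 1 A.m

    u = np.clip(e_hat @ p_hat.T, -1.0, 1.0)  # (n_e, n_v)
    q_r = np.sum(q * p_hat, axis=1)  # (n_v,)
    qe = e_hat @ q.T  # (n_e, n_v)
    q_tan = qe - u * q_r[None, :]

    total = np.zeros_like(u)
    P_nm1 = np.ones_like(u)
    P_n = u.copy()
    dP_nm1 = np.zeros_like(u)
    dP_n = np.ones_like(u)
    xpow = np.ones_like(x)  # x^(n-1), per vertex
    for n in range(1, n_terms + 1):
        total += tau[n - 1] * xpow[None, :] * (n * q_r[None, :] * P_n + q_tan * dP_n)
        if n < n_terms:
            P_np1 = ((2 * n + 1) * u * P_n - n * P_nm1) / (n + 1)
            dP_np1 = (2 * n + 1) * P_n + dP_nm1
            P_nm1, P_n = P_n, P_np1
            dP_nm1, dP_n = dP_n, dP_np1
            xpow *= x
    gain = total / (4.0 * np.pi * head.conductivities[0] * R**2)
    gain -= gain.mean(axis=0, keepdims=True)  # average reference
    return Leadfield(
        gain=gain,
        channel_labels=montage.labels,
        n_sources=sourcespace.n_vertices,
        head_ref=_digest(head.center, head.radii, head.conductivities),
        montage_ref=_digest(montage.positions),
        sourcespace_ref=_digest(sourcespace.vertices, sourcespace.normals),
    )
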