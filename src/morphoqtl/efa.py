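"""Elliptic Fourier description of closed outlines (Kuhl–Giardina).

A closed outline is expanded as a sum of ellipses: with ``t`` the
cumulative chord (arc) length and ``T`` the perimeter,

    x(t) = A0 + sum_k a_k cos(2*pi*k*t/T) + b_k sin(2*pi*k*t/T)
    y(t) = C0 + sum_k c_k cos(2*pi*k*t/T) + d_k sin(2*pi*k*t/T)

The analysis vector is the 4H harmonic coefficients (a, b, c, d per
harmonic, harmonic-major order); the DC terms (A0, C0) encode location
only and are kept out of it.  No first-ellipse normalization of rotation,
scale or starting point is applied here: orientation and size are already
standardized by Procrustes superimposition on control points, and the
starting point by the rostral-midline anchor.

Symmetrization follows the object-symmetry idea adapted to outlines: the
outline is reflected about the midline-landmark axis, re-ordered to remain
counter-clockwise with the homologous starting point, rotationally aligned
to the original, and the two copies averaged.  The average is rotated by
half the aligning angle so that the result is *exactly* symmetric about
the midline axis, which makes symmetrization an exact projection
(idempotent, and the identity on symmetric outlines).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from morphoqtl.tps import CP_CAUDAL, CP_ROSTRAL, Outline
from morphoqtl.geometry import _optimal_rotation, _rot


@dataclass
class EFDCoefficients:
    """Per-harmonic quadruples (a, b, c, d) plus DC terms.

    ``coeffs`` has shape ``(H, 4)`` in (a, b, c, d) column order.  The
    analysis vector excludes (A0, C0); with 30 harmonics it has 120
    entries.
    """

    coeffs: np.ndarray
    A0: float = 0.0
    C0: float = 0.0

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 2 or self.coeffs.shape[1] != 4:
            raise ValueError("coeffs must be (H, 4)")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("non-finite Fourier coefficients")

    @property
    def n_harmonics(self) -> int:
        return self.coeffs.shape[0]

    @property
    def vector(self) -> np.ndarray:
        """Length-4H analysis vector, harmonic-major (a1,b1,c1,d1,a2,...)."""
        return self.coeffs.ravel().copy()

    @classmethod
    def from_vector(cls, vec, A0: float = 0.0, C0: float = 0.0) -> "EFDCoefficients":
        vec = np.asarray(vec, dtype=float)
        if vec.size % 4:
            raise ValueError("vector length must be a multiple of 4")
        return cls(vec.reshape(-1, 4), A0, C0)


def _as_points(outline) -> np.ndarray:
    if isinstance(outline, Outline):
        return outline.points
    return np.asarray(outline, dtype=float)


def efd(outline, n_harmonics: int) -> EFDCoefficients:
    """Elliptic Fourier coefficients of a closed outline.

    The outline is treated as a piecewise-linear closed curve
    parameterized by cumulative chord length, starting at its first
    vertex.  ``n_harmonics`` above the Nyquist limit (n_points/2) only
    triggers a warning: the extra harmonics alias.
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    pts = _as_points(outline)
    n = pts.shape[0]
    if n_harmonics > n / 2:
        warnings.warn(
            f"{n_harmonics} harmonics from {n} points exceeds the Nyquist "
            "limit; higher harmonics alias",
            stacklevel=2,
        )
    closed = np.vstack([pts, pts[:1]])
    dxy = np.diff(closed, axis=0)  # (n, 2)
    dt = np.sqrt(np.sum(dxy**2, axis=1))
    if np.any(dt == 0.0):
        raise ValueError("repeated consecutive points give zero-length segments")
    T = dt.sum()
    t = np.concatenate([[0.0], np.cumsum(dt)])  # (n+1,)

    k = np.arange(1, n_harmonics + 1)[:, None]  # (H, 1)
    phi = 2.0 * np.pi * k * t[None, :] / T  # (H, n+1)
    dcos = np.diff(np.cos(phi), axis=1)  # (H, n)
    dsin = np.diff(np.sin(phi), axis=1)
    slope = dxy / dt[:, None]  # (n, 2)
    const = T / (2.0 * (k.ravel() ** 2) * np.pi**2)  # (H,)
    a = const * (dcos @ slope[:, 0])
    b = const * (dsin @ slope[:, 0])
    c = const * (dcos @ slope[:, 1])
    d = const * (dsin @ slope[:, 1])

    # DC terms: mean of the piecewise-linear curve over one period
    xi = np.concatenate([[0.0], np.cumsum(dxy[:-1, 0])])
    eta = np.concatenate([[0.0], np.cumsum(dxy[:-1, 1])])
    A0 = pts[0, 0] + float(np.sum(dt * (xi + dxy[:, 0] / 2.0))) / T
    C0 = pts[0, 1] + float(np.sum(dt * (eta + dxy[:, 1] / 2.0))) / T

    return EFDCoefficients(np.column_stack([a, b, c, d]), A0, C0)


def inverse_efd(coeffs: EFDCoefficients, n_points: int = 100, ts=None) -> np.ndarray:
    """Reconstruct a closed outline from Fourier coefficients.

    Samples the truncated Fourier series at ``n_points`` equal parameter
    steps (the first vertex corresponds to the source outline's starting
    point), or at explicit normalized parameters ``ts`` in [0, 1) — e.g.
    the source outline's cumulative-arc-length fractions, at which the
    series converges to the source vertices as H grows.
    """
    H = coeffs.n_harmonics
    if ts is not None:
        t = np.asarray(ts, dtype=float)
    else:
        t = np.arange(n_points) / n_points  # t/T in [0, 1)
    k = np.arange(1, H + 1)[:, None]
    cos_kt = np.cos(2.0 * np.pi * k * t[None, :])  # (H, n)
    sin_kt = np.sin(2.0 * np.pi * k * t[None, :])
    a, b, c, d = coeffs.coeffs.T
    x = coeffs.A0 + a @ cos_kt + b @ sin_kt
    y = coeffs.C0 + c @ cos_kt + d @ sin_kt
    return np.column_stack([x, y])


def _axis_frame(outline: Outline):
    """Rotation+origin putting the midline-landmark axis on the x-axis."""
    a = outline.control_points[CP_ROSTRAL]
    b = outline.control_points[CP_CAUDAL]
    axis = b - a
    norm = np.hypot(*axis)
    if norm < 1e-12 * (1.0 + np.abs(outline.points).max()):
        raise ValueError("midline control points coincide: symmetry axis undefined")
    u = axis / norm
    R = np.array([[u[0], u[1]], [-u[1], u[0]]])  # world -> axis frame
    return a, R


def _reflect_sequence(pts: np.ndarray) -> np.ndarray:
    """Reflect about the x-axis, reverse to restore CCW order, re-anchor
    the start at the reflection of the original start."""
    m = pts * np.array([1.0, -1.0])
    return np.roll(m[::-1], 1, axis=0)


def symmetrize(outline: Outline, n_harmonics: int, return_outline: bool = False):
    """Symmetric component of an outline about its midline-landmark axis.

    Reflects the outline about the axis through the rostral and caudal
    midline control points, restores counter-clockwise order and the
    homologous start, finds the rotation best aligning the reflected copy
    to the original, and averages the two copies with a half-angle
    correction so the result is exactly mirror-symmetric about the axis.
    Returns the :class:`EFDCoefficients` of the symmetrized outline (and,
    with ``return_outline=True``, also the symmetrized :class:`Outline`
    with symmetrized control points).
    """
    origin, R = _axis_frame(outline)
    X = (outline.points - origin) @ R.T
    RX = _reflect_sequence(X)
    theta = _optimal_rotation(RX, X)
    half = _rot(theta / 2.0)
    # rot(-θ/2)·X averaged with rot(+θ/2)·RX: exactly symmetric about the axis
    S = (X @ half + RX @ half.T) / 2.0

    # control points: midline pair reflects onto itself, lateral pair swaps
    cp = (outline.control_points - origin) @ R.T
    cp_ref = cp * np.array([1.0, -1.0])
    cp_ref = cp_ref[[CP_ROSTRAL, CP_CAUDAL, 3, 2]]
    cp_sym = (cp @ half + cp_ref @ half.T) / 2.0

    back = lambda p: p @ R + origin
    sym_outline = Outline(
        back(S), back(cp_sym), outline.specimen_id, dict(outline.metadata)
    )
    coeffs = efd(sym_outline.points, n_harmonics)
    if return_outline:
        return coeffs, sym_outline
    return coeffs


def shape_along_axis(
    coeff_matrix: np.ndarray,
    axis_scores: np.ndarray,
    level_low: float,
    level_high: float,
    n_points: int = 100,
):
    """Outline pair visualizing shape change along a statistical axis.

    Each Fourier coefficient is regressed (ordinary least squares) on the
    per-specimen score; the fitted coefficient vectors predicted at
    ``level_low`` and ``level_high`` are reconstructed into outlines.  No
    amplification factor is applied.
    """
    coeff_matrix = np.asarray(coeff_matrix, dtype=float)
    scores = np.asarray(axis_scores, dtype=float).ravel()
    if coeff_matrix.shape[0] != scores.size:
        raise ValueError("one score per specimen required")
    if np.ptp(scores) == 0.0:
        raise ValueError("constant scores: regression undefined")
    X = np.column_stack([np.ones_like(scores), scores])
    beta, *_ = np.linalg.lstsq(X, coeff_matrix, rcond=None)  # (2, 4H)
    shapes = []
    for level in (level_low, level_high):
        vec = beta[0] + beta[1] * level
        shapes.append(inverse_efd(EFDCoefficients.from_vector(vec), n_points))
    return shapes[0], shapes[1]
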