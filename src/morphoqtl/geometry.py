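"""Generalized Procrustes analysis on control points and outline transforms.

The superimposition strategy separates two size measures on purpose: the
four control points are centered and scaled to unit *centroid size* during
GPA, while each outline is centered on its own centroid and scaled by the
square root of its *area* before receiving the control-point rotation.
Landmark size and outline size are never conflated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from morphoqtl.tps import Outline, _signed_area

log = logging.getLogger(__name__)

GPA_TOL = 1e-10
GPA_MAX_ITER = 100


class ConvergenceError(RuntimeError):
    def __init__(self, msg, residual=None):
        super().__init__(msg)
        self.residual = residual


def centroid_size(config: np.ndarray) -> float:
    """Square root of the summed squared distances from the landmarks to
    their centroid.

    Translation- and rotation-invariant; homogeneous of degree 1 in scale.
    """
    config = np.asarray(config, dtype=float)
    centered = config - config.mean(axis=0)
    size = float(np.sqrt(np.sum(centered**2)))
    if size == 0.0:
        raise ValueError("all landmarks coincident: centroid size is zero")
    return size


def _optimal_rotation(config: np.ndarray, target: np.ndarray) -> float:
    """Angle of the proper rotation minimizing ||R(config) - target||²."""
    num = float(np.sum(config[:, 0] * target[:, 1] - config[:, 1] * target[:, 0]))
    den = float(np.sum(config[:, 0] * target[:, 0] + config[:, 1] * target[:, 1]))
    return float(np.arctan2(num, den))


def _rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


@dataclass
class ProcrustesFit:
    """Result of a GPA over landmark configurations.

    ``translations[i]``, ``scales[i]`` and ``rotations[i]`` give the fitted
    transform of specimen ``i``: ``aligned = R(rotations[i]) @ (x -
    translations[i]).T * scales[i]``.  ``consensus`` is the mean of the
    aligned configurations.
    """

    specimen_ids: list
    translations: np.ndarray  # (m, 2) per-specimen centroid
    scales: np.ndarray  # (m,) multiplicative, 1/centroid size
    rotations: np.ndarray  # (m,) radians
    consensus: np.ndarray  # (k, 2)
    aligned: np.ndarray  # (m, k, 2)
    residual_ss: float
    n_iter: int

    def index(self, specimen_id) -> int:
        try:
            return self.specimen_ids.index(specimen_id)
        except ValueError as exc:
            raise KeyError(f"specimen {specimen_id!r} not in fit") from exc


def gpa(
    configs,
    specimen_ids=None,
    tol: float = GPA_TOL,
    max_iter: int = GPA_MAX_ITER,
) -> ProcrustesFit:
    """Generalized least-squares Procrustes superimposition.

    Each configuration is centered, scaled to unit centroid size and
    rotated (proper rotations only, no reflection) to minimize the overall
    sum of squared distances to the consensus, iterating until the
    consensus moves by less than ``tol``.  Consensus is initialized from
    the first specimen; the converged fit does not depend on input order.
    """
    configs = np.asarray(configs, dtype=float)
    if configs.ndim != 3 or configs.shape[0] < 2:
        raise ValueError("need >= 2 configurations of identical landmark count")
    m = configs.shape[0]
    if specimen_ids is None:
        specimen_ids = list(range(m))
    specimen_ids = list(specimen_ids)

    translations = configs.mean(axis=1)
    centered = configs - translations[:, None, :]
    sizes = np.sqrt(np.sum(centered**2, axis=(1, 2)))
    if np.any(sizes == 0.0):
        bad = specimen_ids[int(np.argmin(sizes))]
        raise ValueError(f"specimen {bad!r}: zero centroid size")
    scales = 1.0 / sizes
    scaled = centered * scales[:, None, None]

    consensus = scaled[0].copy()
    rotations = np.zeros(m)
    aligned = scaled.copy()
    for it in range(1, max_iter + 1):
        for i in range(m):
            rotations[i] = _optimal_rotation(scaled[i], consensus)
            aligned[i] = scaled[i] @ _rot(rotations[i]).T
        new_consensus = aligned.mean(axis=0)
        shift = float(np.sqrt(np.sum((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        residual = float(np.sum((aligned - consensus) ** 2))
        log.debug("gpa iter %d: consensus shift %.3e residual %.3e", it, shift, residual)
        if shift < tol:
            return ProcrustesFit(
                specimen_ids,
                translations,
                scales,
                rotations,
                consensus,
                aligned,
                residual,
                it,
            )
    raise ConvergenceError(
        f"GPA did not converge in {max_iter} iterations", residual=residual
    )


def outline_area(outline) -> float:
    """Absolute shoelace area of a closed outline (array or Outline)."""
    pts = outline.points if isinstance(outline, Outline) else np.asarray(outline, float)
    area = abs(_signed_area(pts))
    if area == 0.0:
        raise ValueError("degenerate outline with zero area")
    return area


def apply_transform(outline: Outline, fit: ProcrustesFit, specimen_id=None) -> Outline:
    """Center an outline on its own centroid, scale by 1/sqrt(area), and
    rotate by the specimen's fitted GPA rotation.

    The outline's size normalizer is the square root of its surface, not
    the control-point centroid size.  Control points are carried through
    the same transform so they stay attached to the outline.
    """
    if specimen_id is None:
        specimen_id = outline.specimen_id
    i = fit.index(specimen_id)
    pts = outline.points
    centroid = pts.mean(axis=0)
    scale = 1.0 / np.sqrt(outline_area(pts))
    R = _rot(fit.rotations[i])
    out = outline.copy()
    out.points = (pts - centroid) * scale @ R.T
    out.control_points = (outline.control_points - centroid) * scale @ R.T
    return out


def resample_equal_arclength(outline, n_points: int):
    """Resample a closed outline to ``n_points`` vertices at exactly equal
    arc-length spacing by linear interpolation along the perimeter.

    The start point is preserved.  Accepts an ``Outline`` (returned as an
    ``Outline``) or a bare ``(n, 2)`` array.
    """
    if n_points < 8:
        raise ValueError("n_points must be >= 8")
    is_outline = isinstance(outline, Outline)
    pts = outline.points if is_outline else np.asarray(outline, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.sqrt(np.sum(np.diff(closed, axis=0) ** 2, axis=1))
    perimeter = seg.sum()
    if perimeter == 0.0:
        raise ValueError("zero-perimeter outline cannot be resampled")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(n_points) * (perimeter / n_points)
    x = np.interp(targets, cum, closed[:, 0])
    y = np.interp(targets, cum, closed[:, 1])
    new_pts = np.column_stack([x, y])
    if not is_outline:
        return new_pts
    out = outline.copy()
    out.points = new_pts
    return out
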