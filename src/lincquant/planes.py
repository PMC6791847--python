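"""PCA plane fit to the filament origins of one attachment plate.

The origins of the filaments over one plate form a roughly planar patch
parallel to the nuclear envelope.  Fitting a plane by principal component
analysis yields the patch's in-plane extents — the long side is the
length of membrane over which the filaments concentrate, which downstream
feeds the motor-packing arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ValidationError

__all__ = ["PlaneFit", "fit_plane_pca"]


class PlaneFitError(ValidationError):
    """The points do not determine a plane (too few or collinear)."""


@dataclass
class PlaneFit:
    """Least-squares plane through a point patch, via PCA.

    ``axis1``/``axis2`` span the plane in descending-variance order,
    ``normal`` completes a right-handed orthonormal triad.  ``extent1 >=
    extent2`` are the min–max ranges of the point projections onto the
    in-plane axes — physical side lengths of the patch, not variance
    multiples.  ``rms_residual`` is the RMS out-of-plane distance.
    """

    plate_id: int
    centroid: np.ndarray
    axis1: np.ndarray
    axis2: np.ndarray
    normal: np.ndarray
    extent1: float
    extent2: float
    rms_residual: float
    n_points: int


def fit_plane_pca(origins, plate_id: int = 0) -> PlaneFit:
    """Fit a plane to >= 3 non-collinear points by PCA.

    The plane passes through the centroid; its axes are the first two
    principal directions of the centred points.  Sign conventions are
    deterministic: each axis has its largest-magnitude component
    positive, and the normal is axis1 x axis2.
    """
    pts = np.asarray(origins, dtype=float).reshape(-1, 3)
    if len(pts) < 3:
        raise PlaneFitError(f"plane fit needs >= 3 points, got {len(pts)}")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # SVD of the centred cloud: right singular vectors are the principal axes
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] <= max(1e-9, 1e-9 * svals[0]):
        raise PlaneFitError("points are collinear; the plane is undetermined")

    def _orient(v):
        return v if v[np.argmax(np.abs(v))] >= 0 else -v

    axis1, axis2 = _orient(vt[0]), _orient(vt[1])
    normal = np.cross(axis1, axis2)
    proj1 = centered @ axis1
    proj2 = centered @ axis2
    out = centered @ normal
    return PlaneFit(
        plate_id=plate_id,
        centroid=centroid,
        axis1=axis1,
        axis2=axis2,
        normal=normal,
        extent1=float(np.ptp(proj1)),
        extent2=float(np.ptp(proj2)),
        rms_residual=float(np.sqrt(np.mean(out**2))),
        n_points=len(pts),
    )
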