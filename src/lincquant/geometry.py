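"""Per-filament geometry: arc length, end-to-end distance, stretch factor,
origin extraction and attachment-plate assignment.

The stretch factor (end-to-end distance divided by polyline arc length) is
the tortuosity measure used throughout: 1 for a straight filament, smaller
the more rippled it is.  A filament's *origin* is its anchor point at the
inner nuclear membrane, operationalised as the filament vertex with the
minimum Euclidean distance to the lateral-element point set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .model import Filament, StructurePointSet, ValidationError

__all__ = [
    "path_length",
    "linear_distance",
    "stretch_factor",
    "find_origin",
    "OriginResult",
    "assign_plates",
]


def _points_of(filament) -> np.ndarray:
    pts = filament.points if isinstance(filament, Filament) else np.asarray(filament, float)
    if len(pts) < 2:
        raise ValidationError("a filament needs at least 2 points")
    return pts


def path_length(filament) -> float:
    """Polyline arc length in nm: sum of consecutive segment lengths."""
    pts = _points_of(filament)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def linear_distance(filament) -> float:
    """End-to-end distance in nm between the first and last stored point."""
    pts = _points_of(filament)
    return float(np.linalg.norm(pts[-1] - pts[0]))


def stretch_factor(filament) -> float:
    """linear_distance / path_length, in (0, 1] (0 for a closed path)."""
    length = path_length(filament)
    if not length > 0:
        raise ValidationError("stretch factor undefined for zero path length")
    return linear_distance(filament) / length


@dataclass
class OriginResult:
    """Outcome of origin extraction for one filament."""

    origin: np.ndarray        #: the origin coordinate (nm)
    origin_index: int         #: index of the origin in the *input* point order
    filament: Filament        #: filament re-oriented so the origin leads, when possible
    distance: float           #: distance from the origin to the reference structure


def find_origin(
    filament: Filament,
    reference: StructurePointSet,
    reorient: bool = True,
) -> OriginResult:
    """Locate a filament's nuclear-envelope anchor point.

    The origin is the filament vertex minimising the minimum Euclidean
    distance to any point of ``reference`` — normally the lateral-element
    point set; passing the inner-membrane set instead gives the
    membrane-intersection variant for sensitivity checks.  Ties break to
    the lowest vertex index.  With ``reorient=True`` the returned filament
    is flipped when the origin is its last vertex, so the origin leads.
    """
    if reference is None or len(reference) == 0:
        raise ValidationError("origin extraction needs a non-empty reference point set")
    pts = filament.points
    d = cdist(pts, reference.points).min(axis=1)
    idx = int(np.argmin(d))  # argmin takes the first minimum: lowest-index tie-break
    out = filament
    if reorient and idx == len(pts) - 1:
        out = filament.reversed()
    return OriginResult(pts[idx].copy(), idx, out, float(d[idx]))


def assign_plates(
    origins: np.ndarray,
    plate_points: Optional[StructurePointSet] = None,
    random_state: int = 0,
) -> np.ndarray:
    """Partition filament origins between the two attachment plates.

    Each synapsed telomere pair presents two attachment plates, and the
    filaments cluster over them.  When the plates themselves were
    segmented, each origin goes to the nearer plate centroid (the two
    centroids are found by 2-means on the plate points, which are
    well-separated blobs).  Without plate points, 2-means on the origins
    with a fixed seed is used.  Labels are deterministic: plate 0 is the
    cluster whose centroid is smaller along the axis of largest
    centroid separation.

    A single origin cannot be split; it is assigned plate 0.
    """
    origins = np.asarray(origins, dtype=float).reshape(-1, 3)
    if len(origins) < 2:
        import warnings

        warnings.warn("fewer than 2 origins; assigning all to plate 0", stacklevel=2)
        return np.zeros(len(origins), dtype=int)

    if plate_points is not None and len(plate_points) >= 2:
        km = KMeans(n_clusters=2, n_init=10, random_state=random_state)
        km.fit(plate_points.points)
        centroids = km.cluster_centers_
        labels = cdist(origins, centroids).argmin(axis=1)
    else:
        km = KMeans(n_clusters=2, n_init=10, random_state=random_state)
        labels = km.fit_predict(origins)
        centroids = km.cluster_centers_

    # label convention: sort the two centroids along the axis where they
    # differ most, so plate ids are stable under jitter in the other axes
    split_axis = int(np.argmax(np.abs(centroids[1] - centroids[0])))
    order = np.argsort(centroids[:, split_axis])
    relabel = np.empty(2, dtype=int)
    relabel[order] = np.arange(2)
    return relabel[labels]
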