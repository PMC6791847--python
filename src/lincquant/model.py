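"""Core data containers for attachment-site models.

An attachment site is the unit of analysis: one electron tomogram of a
meiotic telomere pair anchored to the nuclear envelope.  Its segmentation
is represented here as labeled 3D point clouds (membranes, synaptonemal
complex elements, attachment plates) plus an ordered polyline per traced
LINC-complex filament, all in nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Structure classes a segmented object may be assigned to.
STRUCTURE_CLASSES = (
    "lateral_element",
    "central_element",
    "attachment_plate",
    "inner_membrane",
    "outer_membrane",
    "linc_filament",
    "microtubule",
    "other",
)


class ValidationError(ValueError):
    """A model object violates one of its structural invariants."""


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError(f"expected an (n, 3) coordinate array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValidationError("coordinates must be finite")
    return pts


@dataclass
class Filament:
    """One traced LINC complex: an ordered 3D polyline in nm.

    Parameters
    ----------
    filament_id : str
        Identifier unique within a site (e.g. ``"6:12"`` for object 6,
        contour 12 of the source point file).
    points : (n, 3) array of float
        Ordered polyline vertices in nm, ``n >= 2``, with positive total
        path length.
    recorded_width : float, optional
        Manually measured filament width in nm.  Carried through as
        metadata only; never recomputed.
    """

    filament_id: str
    points: np.ndarray
    recorded_width: Optional[float] = None

    def __post_init__(self) -> None:
        self.points = _as_points(self.points)
        if len(self.points) < 2:
            raise ValidationError(
                f"filament {self.filament_id!r} needs >= 2 points, got {len(self.points)}"
            )
        seg = np.diff(self.points, axis=0)
        if not np.linalg.norm(seg, axis=1).sum() > 0:
            raise ValidationError(f"filament {self.filament_id!r} has zero path length")

    def reversed(self) -> "Filament":
        """The same filament with point order flipped."""
        return Filament(self.filament_id, self.points[::-1].copy(), self.recorded_width)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class StructurePointSet:
    """Point cloud of one structure class, with its contour grouping."""

    structure_class: str
    points: np.ndarray
    contour_ids: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.structure_class not in STRUCTURE_CLASSES:
            raise ValidationError(f"unknown structure class {self.structure_class!r}")
        self.points = _as_points(self.points)
        if len(self.points) == 0:
            raise ValidationError(f"structure {self.structure_class!r} has no points")
        if self.contour_ids is None:
            self.contour_ids = np.ones(len(self.points), dtype=int)
        else:
            self.contour_ids = np.asarray(self.contour_ids, dtype=int)
            if self.contour_ids.shape != (len(self.points),):
                raise ValidationError("contour_ids must be one integer per point")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class AttachmentSiteModel:
    """Full segmentation model of one telomere attachment site.

    All coordinates are in nm (pixel scaling is applied at load time).
    ``has_microtubule`` is true iff a microtubule object was segmented;
    ``microtubule_axis`` then holds its centre-line polyline.
    """

    site_id: str
    pixel_size: float
    structures: dict = field(default_factory=dict)
    filaments: list = field(default_factory=list)
    has_microtubule: bool = False
    microtubule_axis: Optional[np.ndarray] = None
    label_map: Optional[dict] = None  # object_id -> structure class, kept for round-trips

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValidationError("pixel_size must be > 0")
        if self.has_microtubule != (self.microtubule_axis is not None):
            raise ValidationError("has_microtubule must mirror the presence of a microtubule axis")
        if self.microtubule_axis is not None:
            self.microtubule_axis = _as_points(self.microtubule_axis)

    @property
    def n_filaments(self) -> int:
        return len(self.filaments)


def validate_for_quantification(model: AttachmentSiteModel) -> None:
    """Check that a site carries what the downstream analysis needs.

    Origin extraction anchors every filament to the lateral-element point
    set, so quantification requires at least one lateral-element structure
    and at least one filament.
    """
    if "lateral_element" not in model.structures:
        raise ValidationError(f"site {model.site_id!r}: no lateral_element structure")
    if model.n_filaments == 0:
        raise ValidationError(f"site {model.site_id!r}: no LINC filaments")
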