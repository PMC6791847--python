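"""Reading and writing attachment-site models as IMOD-style point files.

The supported dialect is the text export produced by IMOD's ``model2point
-object``: one point per line, five whitespace-separated numeric columns
``object contour x y z`` with coordinates in pixels.  A label map assigns
each object id to a structure class, and a per-tomogram pixel size converts
pixels to nm on load.  Binary IMOD model files are deliberately out of
scope.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import yaml

from .model import (
    STRUCTURE_CLASSES,
    AttachmentSiteModel,
    Filament,
    StructurePointSet,
    ValidationError,
)

__all__ = [
    "ParseError",
    "LabelMapError",
    "read_point_model",
    "write_point_model",
    "read_cohort_config",
    "load_cohort",
]


class ParseError(ValueError):
    """A point file line could not be parsed; carries the 1-based line number."""

    def __init__(self, path, line_number: int, message: str):
        self.path = path
        self.line_number = line_number
        super().__init__(f"{path}:{line_number}: {message}")


class LabelMapError(ValueError):
    """An object id in the file is missing from the label map, or a label is invalid."""


def _check_label_map(label_map: Mapping[int, str]) -> dict:
    checked = {}
    for obj, cls in label_map.items():
        obj = int(obj)
        if obj < 1:
            raise LabelMapError(f"object ids must be >= 1, got {obj}")
        if cls not in STRUCTURE_CLASSES:
            raise LabelMapError(
                f"object {obj}: unknown structure class {cls!r}; "
                f"expected one of {STRUCTURE_CLASSES}"
            )
        checked[obj] = cls
    return checked


def _scale_vector(pixel_size) -> np.ndarray:
    scale = np.atleast_1d(np.asarray(pixel_size, dtype=float))
    if scale.size == 1:
        scale = np.repeat(scale, 3)
    if scale.shape != (3,):
        raise ValidationError("pixel_size must be a scalar or an (sx, sy, sz) triple")
    if not np.all(scale > 0):
        raise ValidationError("pixel_size must be > 0")
    return scale


def read_point_model(
    path,
    label_map: Mapping[int, str],
    pixel_size: Union[float, Sequence[float]],
    site_id: Optional[str] = None,
) -> AttachmentSiteModel:
    """Read a 5-column point file into an :class:`AttachmentSiteModel`.

    Parameters
    ----------
    path : path or file-like
        Source of ``object contour x y z`` lines.  Blank lines and ``#``
        comment lines are ignored.
    label_map : mapping of int -> structure class
        Every object id appearing in the file must be mapped.
    pixel_size : float or (sx, sy, sz)
        nm per pixel; a triple allows anisotropic tomograms.  All
        coordinates are multiplied by it on load.
    site_id : str, optional
        Defaults to the file stem.

    Each contour of a ``linc_filament`` object becomes one
    :class:`~lincquant.model.Filament`, point order as in the file.
    """
    label_map = _check_label_map(label_map)
    scale = _scale_vector(pixel_size)

    if hasattr(path, "read"):
        lines = path.read().splitlines()
        name = getattr(path, "name", "<stream>")
    else:
        path = Path(path)
        lines = path.read_text().splitlines()
        name = str(path)
    if site_id is None:
        site_id = Path(name).stem if name != "<stream>" else "site"

    records = []  # (object, contour, xyz)
    for ln, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        cols = stripped.split()
        if len(cols) != 5:
            raise ParseError(name, ln, f"expected 5 columns, got {len(cols)}")
        try:
            obj, cont = int(float(cols[0])), int(float(cols[1]))
            xyz = np.array([float(c) for c in cols[2:5]])
        except ValueError as exc:
            raise ParseError(name, ln, f"non-numeric field: {exc}") from None
        if not np.all(np.isfinite(xyz)):
            raise ParseError(name, ln, "non-finite coordinate")
        if obj not in label_map:
            raise LabelMapError(f"{name}:{ln}: object {obj} not present in label map")
        records.append((obj, cont, xyz * scale))

    # group by (object, contour) preserving file order
    grouped: dict = {}
    for obj, cont, xyz in records:
        grouped.setdefault((obj, cont), []).append(xyz)

    filaments = []
    class_points: dict = {}
    mt_axis = None
    for (obj, cont), pts in grouped.items():
        cls = label_map[obj]
        arr = np.vstack(pts)
        if cls == "linc_filament":
            if len(arr) < 2:
                raise ValidationError(
                    f"{name}: filament contour {obj}:{cont} has {len(arr)} point(s); "
                    "a filament needs at least 2"
                )
            filaments.append(Filament(f"{obj}:{cont}", arr))
        else:
            bucket = class_points.setdefault(cls, ([], []))
            bucket[0].append(arr)
            bucket[1].append(np.full(len(arr), cont, dtype=int))
            if cls == "microtubule" and mt_axis is None:
                mt_axis = arr

    structures = {
        cls: StructurePointSet(cls, np.vstack(p), np.concatenate(c))
        for cls, (p, c) in class_points.items()
    }
    has_mt = any(label_map[o] == "microtubule" for o, _, _ in records)
    return AttachmentSiteModel(
        site_id=site_id,
        pixel_size=float(scale[0]),
        structures=structures,
        filaments=filaments,
        has_microtubule=has_mt,
        microtubule_axis=mt_axis,
        label_map=dict(label_map),
    )


def write_point_model(model: AttachmentSiteModel, path, decimals: int = 3) -> dict:
    """Write a model back to the 5-column text dialect (coordinates in nm).

    Returns the label map used, so that ``read_point_model(path,
    label_map, pixel_size=1.0)`` round-trips the model.  Object ids come
    from ``model.label_map`` when present; otherwise ids are assigned in
    :data:`~lincquant.model.STRUCTURE_CLASSES` order.
    """
    if model.label_map:
        class_to_obj = {}
        for obj, cls in sorted(model.label_map.items()):
            class_to_obj.setdefault(cls, obj)
        next_id = max(model.label_map) + 1
    else:
        class_to_obj = {}
        next_id = 1

    def obj_for(cls: str) -> int:
        nonlocal next_id
        if cls not in class_to_obj:
            class_to_obj[cls] = next_id
            next_id += 1
        return class_to_obj[cls]

    fmt = f"%d %d %.{decimals}f %.{decimals}f %.{decimals}f"
    buf = _io.StringIO()
    for cls in STRUCTURE_CLASSES:
        if cls == "linc_filament" or cls not in model.structures:
            continue
        st = model.structures[cls]
        obj = obj_for(cls)
        for pt, cont in zip(st.points, st.contour_ids):
            buf.write(fmt % (obj, cont, pt[0], pt[1], pt[2]) + "\n")
    if model.filaments:
        obj = obj_for("linc_filament")
        for cont, fil in enumerate(model.filaments, start=1):
            for pt in fil.points:
                buf.write(fmt % (obj, cont, pt[0], pt[1], pt[2]) + "\n")

    text = buf.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        try:
            Path(path).write_text(text)
        except OSError as exc:
            raise IOError(f"cannot write point model to {path}: {exc}") from exc
    return {obj: cls for cls, obj in class_to_obj.items()}


def read_cohort_config(config_path) -> list:
    """Parse a cohort YAML config into a list of site entry dicts.

    Expected layout::

        sites:
          - site_id: site_01        # optional, defaults to file stem
            path: site_01.txt      # relative to the config file
            pixel_size_nm: 1.0
            labels: {1: lateral_element, 6: linc_filament, ...}
            has_microtubule: true  # optional, cross-checked after load
    """
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    if not isinstance(cfg, dict) or "sites" not in cfg:
        raise ValidationError(f"{config_path}: config must contain a 'sites' list")
    entries = []
    for i, entry in enumerate(cfg["sites"]):
        for key in ("path", "pixel_size_nm", "labels"):
            if key not in entry:
                raise ValidationError(f"{config_path}: site #{i + 1} is missing {key!r}")
        entry = dict(entry)
        entry["path"] = (config_path.parent / entry["path"]).resolve()
        entries.append(entry)
    return entries


def load_cohort(config_path) -> list:
    """Load every site listed in a cohort config; returns models in file order."""
    models = []
    for entry in read_cohort_config(config_path):
        model = read_point_model(
            entry["path"],
            entry["labels"],
            entry["pixel_size_nm"],
            site_id=entry.get("site_id"),
        )
        expected_mt = entry.get("has_microtubule")
        if expected_mt is not None and bool(expected_mt) != model.has_microtubule:
            raise ValidationError(
                f"site {model.site_id!r}: config declares has_microtubule="
                f"{expected_mt} but the file {'has' if model.has_microtubule else 'lacks'} "
                "a microtubule object"
            )
        models.append(model)
    return models
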