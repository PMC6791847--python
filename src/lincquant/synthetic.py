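"""Seeded generator of synthetic attachment-site models.

The original tomograms are not publicly deposited, so every pipeline
stage is exercised on synthetic sites that emulate the reported
statistical structure: two attachment-plate filament clusters per site,
per-site filament counts near the observed ones, filament lengths around
91 ± 18 nm, a hard >= 5 nm spacing between origins, >= 2 nm clearance
between filaments, rippled polylines with stretch factor < 1, and an
optional single microtubule running parallel to the plate long axis near
which filaments are straighter.  Ground truth (plate labels, target
lengths and stretch factors, near-microtubule flags) is emitted alongside
each model so recovery can be checked exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .distances import min_pair_distance
from .geometry import path_length, stretch_factor
from .io import write_point_model
from .model import AttachmentSiteModel, Filament, StructurePointSet, ValidationError

__all__ = [
    "TABLE1_FILAMENT_COUNTS",
    "TABLE1_HAS_MICROTUBULE",
    "SyntheticConfig",
    "GenerationError",
    "poisson_disk_origins",
    "rippled_polyline",
    "generate_site",
    "generate_cohort",
    "CohortResult",
]

#: Observed per-site filament counts across the 11 reconstructed attachment
#: sites the generator emulates (sites listed without-microtubule first).
TABLE1_FILAMENT_COUNTS = (69, 104, 77, 64, 63, 80, 80, 67, 79, 88, 61)
#: Which of those 11 sites carried a microtubule.
TABLE1_HAS_MICROTUBULE = (
    False, False, False, False, False, False, True, True, True, True, True,
)

#: Object-id labeling used for every generated site.
_LABEL_MAP = {
    1: "lateral_element",
    2: "central_element",
    3: "attachment_plate",
    4: "inner_membrane",
    5: "outer_membrane",
    6: "linc_filament",
    7: "microtubule",
}


class GenerationError(RuntimeError):
    """The requested site could not be generated under the constraints."""


@dataclass
class SyntheticConfig:
    """Study conditions for synthetic cohorts.

    Defaults reproduce the observed cohort: 11 sites, counts drawn from
    the observed per-site counts, lengths ~ N(91, 18^2) truncated at 3
    SD, >= 5 nm origin spacing, >= 2 nm filament clearance, 150 x 60 nm
    plates 250 nm apart, 5/11 of sites with a microtubule, and stretch
    targets 0.77 (no/far microtubule) vs 0.80 (origin within 100 nm of
    the axis).
    """

    n_sites: int = 11
    filament_counts: Union[str, Sequence[int]] = "table1"  # "table1" | "normal" | explicit
    count_mean: float = 76.0
    count_sd: float = 12.0
    length_mean: float = 91.0
    length_sd: float = 18.0
    min_origin_spacing: float = 5.0
    min_filament_clearance: float = 2.0
    plate_length: float = 150.0
    plate_width: float = 60.0
    plate_separation: float = 250.0
    stretch_no_mt: float = 0.77
    stretch_near_mt: float = 0.80
    stretch_jitter_sd: float = 0.02
    mt_fraction: float = 5.0 / 11.0
    mt_influence_radius: float = 100.0
    mt_height: float = 60.0
    point_spacing: float = 4.0
    direction_tilt_deg: float = 15.0
    membrane_gap: float = 45.0
    pixel_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "length_mean", "length_sd", "min_origin_spacing", "min_filament_clearance",
            "plate_length", "plate_width", "plate_separation", "mt_influence_radius",
            "mt_height", "point_spacing", "membrane_gap", "pixel_size",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("stretch_no_mt", "stretch_near_mt"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValidationError(f"{name} must be in (0, 1]")
        if not (0 <= self.mt_fraction <= 1):
            raise ValidationError("mt_fraction must be in [0, 1]")
        if self.n_sites < 0:
            raise ValidationError("n_sites must be >= 0")


def poisson_disk_origins(
    n: int,
    plate_length: float,
    plate_width: float,
    min_spacing: float,
    rng: np.random.Generator,
    center=(0.0, 0.0, 0.0),
    max_tries_per_point: int = 2000,
) -> np.ndarray:
    """Dart-throwing Poisson-disk sample of ``n`` origins on one plate.

    Points lie in the z = center_z plane on a ``plate_length x
    plate_width`` rectangle around ``center``; all pairwise distances are
    >= ``min_spacing``.  Raises :class:`GenerationError` when the
    requested density is infeasible (disk packing above ~50% coverage)
    or when dart throwing exhausts its retry budget.
    """
    if n < 0:
        raise ValidationError("n must be >= 0")
    area = plate_length * plate_width
    if n * np.pi * (min_spacing / 2.0) ** 2 > 0.5 * area:
        raise GenerationError(
            f"{n} origins with {min_spacing} nm spacing exceed the plate capacity; "
            "enlarge the plate or relax the spacing"
        )
    center = np.asarray(center, dtype=float)
    pts: list = []
    for _ in range(n):
        for _attempt in range(max_tries_per_point):
            cand = center + np.array(
                [
                    rng.uniform(-plate_length / 2.0, plate_length / 2.0),
                    rng.uniform(-plate_width / 2.0, plate_width / 2.0),
                    0.0,
                ]
            )
            if not pts or np.linalg.norm(np.vstack(pts) - cand, axis=1).min() >= min_spacing:
                pts.append(cand)
                break
        else:
            raise GenerationError(
                "dart throwing exhausted retries; relax min_origin_spacing or density"
            )
    return np.vstack(pts) if pts else np.empty((0, 3))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def rippled_polyline(
    origin,
    direction,
    target_length: float,
    stretch_target: float,
    point_spacing: float,
    rng: np.random.Generator,
    tol: float = 1e-3,
    max_iter: int = 80,
) -> Filament:
    """A polyline of given arc length whose stretch factor hits a target.

    A straight backbone from ``origin`` along ``direction`` is perturbed
    by a transverse random walk (zero at both endpoints, so the chord is
    preserved); the perturbation amplitude is found by bisection so that
    chord / arc-length equals ``stretch_target``, then the whole polyline
    is rescaled about the origin to the requested arc length.  Scaling
    preserves the stretch factor, so both posts hold simultaneously.
    """
    if not (0 < stretch_target <= 1):
        raise ValidationError("stretch_target must be in (0, 1]")
    if not target_length > 0 or not point_spacing > 0:
        raise ValidationError("target_length and point_spacing must be > 0")
    origin = np.asarray(origin, dtype=float)
    d = _unit(np.asarray(direction, dtype=float))
    n_seg = max(2, int(round(target_length / point_spacing)))
    t = np.linspace(0.0, 1.0, n_seg + 1)

    if stretch_target >= 1.0:
        pts = origin + np.outer(t * target_length, d)
        return Filament("synthetic", pts)

    # orthonormal transverse frame
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(d, helper))
    v = np.cross(d, u)

    def _walk():
        w = np.cumsum(rng.standard_normal(n_seg + 1))
        return w - w[0] - t * (w[-1] - w[0])  # pinned to zero at both ends

    wu, wv = _walk(), _walk()
    if np.allclose(wu, 0) and np.allclose(wv, 0):  # measure-zero degenerate draw
        wu = np.sin(np.pi * t)

    base = np.outer(t, d)  # unit-chord backbone

    def _stretch(alpha: float) -> float:
        pts = base + alpha * (np.outer(wu, u) + np.outer(wv, v))
        return 1.0 / np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()

    lo, hi = 0.0, 0.1
    for _ in range(max_iter):
        if _stretch(hi) < stretch_target:
            break
        hi *= 2.0
    else:
        raise GenerationError(f"stretch target {stretch_target} unattainable")
    alpha = None
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if abs(_stretch(mid) - stretch_target) < tol:
            alpha = mid
            break
        if _stretch(mid) > stretch_target:
            lo = mid
        else:
            hi = mid
    if alpha is None:
        alpha = 0.5 * (lo + hi)
    pts = base + alpha * (np.outer(wu, u) + np.outer(wv, v))
    arclen = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
    pts = origin + pts * (target_length / arclen)
    return Filament("synthetic", pts)


def _grid(x0, x1, y0, y1, z, spacing, rng, jitter=1.0):
    xs = np.arange(x0, x1 + spacing / 2, spacing)
    ys = np.arange(y0, y1 + spacing / 2, spacing)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, float(z))])
    pts[:, :2] += rng.uniform(-jitter, jitter, size=(len(pts), 2))
    return pts


def _truncated_normal(mean, sd, rng, lower=None, upper=None):
    lo = max(1e-6, mean - 3 * sd) if lower is None else lower
    hi = mean + 3 * sd if upper is None else upper
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise GenerationError("truncated-normal rejection failed")


def _scaffolds(cfg: SyntheticConfig, rng: np.random.Generator) -> dict:
    """Coarse planar/ribbon point scaffolds for membranes, plates and SC."""
    hl, hw, sep = cfg.plate_length / 2, cfg.plate_width / 2, cfg.plate_separation
    structures = {}
    plate_pts, plate_cont = [], []
    le_pts, le_cont = [], []
    for k, cy in enumerate((0.0, sep)):
        plate = _grid(-hl, hl, cy - hw, cy + hw, -4.0, 10.0, rng)
        plate_pts.append(plate)
        plate_cont.append(np.full(len(plate), k + 1))
        # lateral-element ribbon descending into the nucleoplasm below its
        # plate; it spans the plate footprint so that every filament's
        # closest vertex to it is the anchor point at the membrane
        for z in np.arange(-15.0, -121.0, -12.0):
            row = _grid(-hl, hl, cy - hw, cy + hw, z, 12.0, rng)
            le_pts.append(row)
            le_cont.append(np.full(len(row), k + 1))
    structures["attachment_plate"] = StructurePointSet(
        "attachment_plate", np.vstack(plate_pts), np.concatenate(plate_cont)
    )
    structures["lateral_element"] = StructurePointSet(
        "lateral_element", np.vstack(le_pts), np.concatenate(le_cont)
    )
    ce = []
    for z in np.arange(-20.0, -121.0, -15.0):
        ce.append(_grid(-hl, hl, sep / 2 - 5, sep / 2 + 5, z, 15.0, rng))
    structures["central_element"] = StructurePointSet("central_element", np.vstack(ce))
    span_y = (-hw - 60.0, sep + hw + 60.0)
    inner = _grid(-hl - 60, hl + 60, span_y[0], span_y[1], 0.0, 20.0, rng)
    outer = _grid(-hl - 60, hl + 60, span_y[0], span_y[1], cfg.membrane_gap, 20.0, rng)
    structures["inner_membrane"] = StructurePointSet("inner_membrane", inner)
    structures["outer_membrane"] = StructurePointSet("outer_membrane", outer)
    return structures


def _sample_count(cfg: SyntheticConfig, rng: np.random.Generator, site_index: int) -> int:
    rule = cfg.filament_counts
    if isinstance(rule, str):
        if rule == "table1":
            return int(rng.choice(TABLE1_FILAMENT_COUNTS))
        if rule == "normal":
            return max(2, int(round(rng.normal(cfg.count_mean, cfg.count_sd))))
        raise ValidationError(f"unknown filament_counts rule {rule!r}")
    seq = list(rule)
    return int(seq[site_index % len(seq)])


def _mt_axis(cfg: SyntheticConfig) -> np.ndarray:
    # single microtubule parallel to the plate long axis, above plate 0
    xs = np.arange(-1.5 * cfg.plate_length, 1.5 * cfg.plate_length + 1, 25.0)
    return np.column_stack(
        [xs, np.zeros_like(xs), np.full_like(xs, cfg.mt_height)]
    )


def _origin_axis_distance(origin: np.ndarray, axis: np.ndarray) -> float:
    from .proximity import _point_segments_min

    return _point_segments_min(origin[None, :], axis[:-1], axis[1:])


def generate_site(
    config: SyntheticConfig,
    has_microtubule: bool,
    rng: np.random.Generator,
    site_id: str = "site_01",
    n_filaments: Optional[int] = None,
    site_index: int = 0,
    max_clearance_retries: int = 100,
):
    """Generate one synthetic attachment site and its ground truth.

    Returns ``(AttachmentSiteModel, ground_truth DataFrame)`` with one
    truth row per filament: plate label, target length/stretch and
    near-microtubule flag.  Deterministic for a given rng state.
    """
    cfg = config
    if n_filaments is None:
        n_filaments = _sample_count(cfg, rng, site_index)
    if n_filaments < 2:
        raise ValidationError("a site needs at least 2 filaments")

    structures = _scaffolds(cfg, rng)
    axis = _mt_axis(cfg) if has_microtubule else None

    n0 = n_filaments // 2 + (rng.random() < 0.5 if n_filaments % 2 else 0)
    plate_ns = (int(n0), n_filaments - int(n0))
    filaments, truth_rows = [], []
    fil_idx = 0
    for plate_id, (n_plate, cy) in enumerate(zip(plate_ns, (0.0, cfg.plate_separation))):
        area = cfg.plate_length * cfg.plate_width
        if n_plate * np.pi * (cfg.min_origin_spacing / 2.0) ** 2 > 0.5 * area:
            raise GenerationError(
                f"{site_id}: {n_plate} origins exceed the plate capacity at "
                f"{cfg.min_origin_spacing} nm spacing"
            )
        center = np.array([0.0, cy, 0.0])
        plate_origins: list = []
        for _k in range(n_plate):
            fil_idx += 1
            fid = f"f{fil_idx:03d}"
            placed = placed_origin = None
            # filaments are placed sequentially; when ripple redraws cannot
            # clear the neighbours, the origin itself is re-thrown (still
            # respecting the minimum spacing) rather than failing the site
            for _otry in range(max_clearance_retries):
                origin = center + np.array(
                    [
                        rng.uniform(-cfg.plate_length / 2.0, cfg.plate_length / 2.0),
                        rng.uniform(-cfg.plate_width / 2.0, cfg.plate_width / 2.0),
                        0.0,
                    ]
                )
                if plate_origins and (
                    np.linalg.norm(np.vstack(plate_origins) - origin, axis=1).min()
                    < cfg.min_origin_spacing
                ):
                    continue
                near_mt = bool(
                    has_microtubule
                    and _origin_axis_distance(origin, axis) < cfg.mt_influence_radius
                )
                target_stretch = cfg.stretch_near_mt if near_mt else cfg.stretch_no_mt
                if cfg.stretch_jitter_sd > 0:
                    target_stretch = float(
                        np.clip(rng.normal(target_stretch, cfg.stretch_jitter_sd), 0.3, 1.0)
                    )
                target_length = _truncated_normal(cfg.length_mean, cfg.length_sd, rng)
                for _try in range(10):
                    tilt = np.deg2rad(rng.uniform(0.0, cfg.direction_tilt_deg))
                    az = rng.uniform(0.0, 2 * np.pi)
                    direction = np.array(
                        [np.sin(tilt) * np.cos(az), np.sin(tilt) * np.sin(az), np.cos(tilt)]
                    )
                    cand = rippled_polyline(
                        origin, direction, target_length, target_stretch,
                        cfg.point_spacing, rng,
                    )
                    cand = Filament(fid, cand.points)
                    clear = all(
                        min_pair_distance(cand, other) >= cfg.min_filament_clearance
                        for other in filaments
                    )
                    if clear:
                        placed, placed_origin = cand, origin
                        break
                if placed is not None:
                    break
            if placed is None:
                raise GenerationError(
                    f"{site_id}/{fid}: could not satisfy the "
                    f"{cfg.min_filament_clearance} nm clearance after "
                    f"{max_clearance_retries} origin redraws"
                )
            plate_origins.append(placed_origin)
            filaments.append(placed)
            truth_rows.append(
                {
                    "site_id": site_id,
                    "filament_id": fid,
                    "plate_id": plate_id,
                    "target_length_nm": target_length,
                    "target_stretch": target_stretch,
                    "near_mt": near_mt,
                    "realized_length_nm": path_length(placed),
                    "realized_stretch": stretch_factor(placed),
                }
            )

    if has_microtubule:
        structures["microtubule"] = StructurePointSet("microtubule", axis)
    model = AttachmentSiteModel(
        site_id=site_id,
        pixel_size=cfg.pixel_size,
        structures=structures,
        filaments=filaments,
        has_microtubule=has_microtubule,
        microtubule_axis=axis,
        label_map=dict(_LABEL_MAP),
    )
    return model, pd.DataFrame(truth_rows)


@dataclass
class CohortResult:
    models: list
    ground_truth: pd.DataFrame
    manifest: dict
    config: SyntheticConfig = field(repr=False, default=None)  # type: ignore[assignment]


def _config_hash(cfg: SyntheticConfig) -> str:
    payload = asdict(cfg)
    if not isinstance(payload["filament_counts"], str):
        payload["filament_counts"] = list(payload["filament_counts"])
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def generate_cohort(
    config: SyntheticConfig,
    out_dir: Optional[Union[str, Path]] = None,
    mt_pattern: Optional[Sequence[bool]] = None,
) -> CohortResult:
    """Generate a cohort of sites, optionally writing it to disk.

    ``round(mt_fraction * n_sites)`` sites carry a microtubule, assigned
    to the last sites of the cohort (matching the observed layout where
    microtubule-bearing sites are listed last); ``mt_pattern`` overrides
    this explicitly.  When ``out_dir`` is given, point files, a cohort
    YAML config, the ground-truth CSV and a manifest JSON are written.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    if mt_pattern is None:
        k = int(round(cfg.mt_fraction * cfg.n_sites))
        mt_pattern = [i >= cfg.n_sites - k for i in range(cfg.n_sites)]
    else:
        mt_pattern = [bool(b) for b in mt_pattern]
        if len(mt_pattern) != cfg.n_sites:
            raise ValidationError("mt_pattern length must equal n_sites")

    models, truths = [], []
    for i, has_mt in enumerate(mt_pattern):
        site_id = f"site_{i + 1:02d}"
        model, truth = generate_site(cfg, has_mt, rng, site_id=site_id, site_index=i)
        models.append(model)
        truths.append(truth)
    truth = (
        pd.concat(truths, ignore_index=True)
        if truths
        else pd.DataFrame(
            columns=[
                "site_id", "filament_id", "plate_id", "target_length_nm",
                "target_stretch", "near_mt", "realized_length_nm", "realized_stretch",
            ]
        )
    )
    manifest = {
        "seed": cfg.seed,
        "n_sites": cfg.n_sites,
        "config_hash": _config_hash(cfg),
        "sites": [
            {"site_id": m.site_id, "has_microtubule": m.has_microtubule,
             "n_filaments": m.n_filaments}
            for m in models
        ],
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        site_entries = []
        for m in models:
            fname = f"{m.site_id}.txt"
            label_map = write_point_model(m, out_dir / fname)
            site_entries.append(
                {
                    "site_id": m.site_id,
                    "path": fname,
                    "pixel_size_nm": 1.0,  # files are written in nm
                    "has_microtubule": m.has_microtubule,
                    "labels": {int(k): v for k, v in label_map.items()},
                }
            )
        (out_dir / "cohort.yaml").write_text(
            yaml.safe_dump({"sites": site_entries}, sort_keys=False)
        )
        truth.to_csv(out_dir / "ground_truth.csv", index=False)
        manifest["files"] = [e["path"] for e in site_entries] + [
            "cohort.yaml", "ground_truth.csv"
        ]
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return CohortResult(models=models, ground_truth=truth, manifest=manifest, config=cfg)
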