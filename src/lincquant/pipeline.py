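"""End-to-end orchestration: per-site quantification and cohort comparison.

``quantify_sites`` runs origin extraction, plate assignment, geometry,
nearest-neighbour distances, plane fits and microtubule proximity for
each site and returns a per-filament metrics table plus per-site
summaries.  ``compare_cohorts`` runs the cohort-level battery: counts KS,
lengths t, nearest-neighbour KS, stretch rank-sum, the proximity cutoff
scan, and the force model evaluated at the measured mean plane extent.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import distances as dist
from . import geometry as geom
from . import proximity as prox
from . import stats as st
from .force import ForceModelParams, evaluate as evaluate_force
from .model import AttachmentSiteModel, ValidationError, validate_for_quantification
from .planes import PlaneFitError, fit_plane_pca

logger = logging.getLogger("lincquant")

__all__ = ["quantify_sites", "compare_cohorts", "METRICS_COLUMNS"]

METRICS_COLUMNS = [
    "site_id", "filament_id", "plate_id",
    "origin_x", "origin_y", "origin_z",
    "path_length_nm", "linear_distance_nm", "stretch_factor",
    "nn_origin_nm", "nn_filament_nm", "mt_distance_nm", "has_microtubule",
]


def quantify_sites(
    models: Sequence[AttachmentSiteModel],
    origin_reference: str = "lateral_element",
    nn_method: str = "points",
):
    """Quantify a list of site models.

    Returns ``(metrics, site_summaries)``: a per-filament DataFrame with
    :data:`METRICS_COLUMNS` and a list of per-site summary dicts
    (filament count, length/stretch summaries, plane fits, minimum
    spacings).  ``origin_reference`` may be ``"inner_membrane"`` for the
    membrane-intersection origin variant.
    """
    frames, summaries = [], []
    for model in models:
        validate_for_quantification(model)
        ref = model.structures.get(origin_reference)
        if ref is None:
            raise ValidationError(
                f"site {model.site_id!r}: no {origin_reference!r} structure for origins"
            )
        origins, oriented = [], []
        for fil in model.filaments:
            res = geom.find_origin(fil, ref)
            origins.append(res.origin)
            oriented.append(res.filament)
        origins = np.vstack(origins)
        plate_ids = geom.assign_plates(origins, model.structures.get("attachment_plate"))

        ids = [f.filament_id for f in oriented]
        df = pd.DataFrame(
            {
                "site_id": model.site_id,
                "filament_id": ids,
                "plate_id": plate_ids,
                "origin_x": origins[:, 0],
                "origin_y": origins[:, 1],
                "origin_z": origins[:, 2],
                "path_length_nm": [geom.path_length(f) for f in oriented],
                "linear_distance_nm": [geom.linear_distance(f) for f in oriented],
                "stretch_factor": [geom.stretch_factor(f) for f in oriented],
            }
        )
        nn_o = dist.nn_origin_distances(origins, ids, site_id=model.site_id)
        nn_f = dist.nn_filament_distances(oriented, site_id=model.site_id, method=nn_method)
        df = df.merge(
            nn_o[["filament_id", "distance"]].rename(columns={"distance": "nn_origin_nm"}),
            on="filament_id", how="left",
        ).merge(
            nn_f[["filament_id", "distance"]].rename(columns={"distance": "nn_filament_nm"}),
            on="filament_id", how="left",
        )
        if model.has_microtubule:
            df["mt_distance_nm"] = [
                prox.distance_to_microtubule(f, model.microtubule_axis) for f in oriented
            ]
        else:
            df["mt_distance_nm"] = np.nan
        df["has_microtubule"] = model.has_microtubule
        frames.append(df)

        plane_fits = []
        for pid in (0, 1):
            pts = origins[plate_ids == pid]
            try:
                fit = fit_plane_pca(pts, plate_id=pid)
            except PlaneFitError as exc:
                logger.info("site %s plate %d: %s", model.site_id, pid, exc)
                continue
            plane_fits.append(
                {
                    "plate_id": pid,
                    "n_points": fit.n_points,
                    "extent1_nm": fit.extent1,
                    "extent2_nm": fit.extent2,
                    "rms_residual_nm": fit.rms_residual,
                }
            )
        lengths = df["path_length_nm"].to_numpy()
        summaries.append(
            {
                "site_id": model.site_id,
                "has_microtubule": model.has_microtubule,
                "n_filaments": int(len(df)),
                "length": st.summarize(lengths).as_dict(),
                "mean_stretch": float(df["stretch_factor"].mean()),
                "mean_linear_nm": float(df["linear_distance_nm"].mean()),
                "min_origin_nn_nm": float(df["nn_origin_nm"].min()),
                "min_filament_nn_nm": float(df["nn_filament_nm"].min()),
                "plane_fits": plane_fits,
            }
        )
        logger.info(
            "site %s: %d filaments, mean length %.1f nm, %s microtubule",
            model.site_id, len(df), lengths.mean(),
            "with" if model.has_microtubule else "no",
        )
    metrics = (
        pd.concat(frames, ignore_index=True)[METRICS_COLUMNS]
        if frames
        else pd.DataFrame(columns=METRICS_COLUMNS)
    )
    return metrics, summaries


def _group(metrics: pd.DataFrame, with_mt: bool) -> pd.DataFrame:
    return metrics[metrics["has_microtubule"] == with_mt]


def compare_cohorts(
    metrics: pd.DataFrame,
    site_summaries: Optional[list] = None,
    force_params: Optional[ForceModelParams] = None,
    cutoffs=None,
) -> dict:
    """Full with- vs without-microtubule comparison battery.

    Produces a JSON-ready dict.  When only one group is present the
    comparisons are skipped with an explicit notice while summaries are
    still emitted.
    """
    report: dict = {}
    counts = metrics.groupby("site_id", sort=False).agg(
        n=("filament_id", "size"), has_mt=("has_microtubule", "first")
    )
    report["per_site_counts"] = {
        site: int(n) for site, n in zip(counts.index, counts["n"])
    }
    report["overall"] = {
        "n_sites": int(len(counts)),
        "total_filaments": int(counts["n"].sum()),
        "mean_filaments_per_site": float(counts["n"].mean()) if len(counts) else np.nan,
        "length": st.summarize(metrics["path_length_nm"]).as_dict() if len(metrics) else None,
    }
    o_shift = dist.global_minimum_shift(metrics["nn_origin_nm"].dropna()) if len(metrics) else None
    f_shift = dist.global_minimum_shift(metrics["nn_filament_nm"].dropna()) if len(metrics) else None
    report["origin_nn"] = (
        {"min_nm": o_shift.shift, "rate_per_nm": o_shift.rate, "n": o_shift.n}
        if o_shift else None
    )
    report["filament_nn"] = (
        {"min_nm": f_shift.shift, "rate_per_nm": f_shift.rate, "n": f_shift.n}
        if f_shift else None
    )

    with_mt, without_mt = _group(metrics, True), _group(metrics, False)
    if with_mt.empty or without_mt.empty:
        report["comparisons"] = None
        report["notice"] = "only one cohort present; group comparisons skipped"
        return report

    counts_w = counts[counts["has_mt"]]["n"].to_numpy(float)
    counts_wo = counts[~counts["has_mt"]]["n"].to_numpy(float)
    comp: dict = {}
    if len(counts_w) and len(counts_wo):
        comp["counts_ks"] = st.ks_two_sample(counts_wo, counts_w, mode="exact").as_dict()
        comp["counts_ks_asymptotic"] = st.ks_two_sample(
            counts_wo, counts_w, mode="asymptotic"
        ).as_dict()
    comp["lengths_t"] = st.t_two_sample(
        with_mt["path_length_nm"], without_mt["path_length_nm"]
    ).as_dict()
    comp["length_mean_with_mt"] = st.summarize(with_mt["path_length_nm"]).as_dict()
    comp["length_mean_without_mt"] = st.summarize(without_mt["path_length_nm"]).as_dict()
    comp["origin_nn_ks"] = st.ks_two_sample(
        without_mt["nn_origin_nm"].dropna(), with_mt["nn_origin_nm"].dropna(),
        mode="asymptotic",
    ).as_dict()
    comp["filament_nn_ks"] = st.ks_two_sample(
        without_mt["nn_filament_nm"].dropna(), with_mt["nn_filament_nm"].dropna(),
        mode="asymptotic",
    ).as_dict()
    stretch_cmp = prox.stretch_cohort_compare(
        with_mt["stretch_factor"], without_mt["stretch_factor"]
    )
    comp["stretch"] = stretch_cmp.as_dict()
    comp["linear_mean_with_mt_nm"] = float(with_mt["linear_distance_nm"].mean())
    comp["linear_mean_without_mt_nm"] = float(without_mt["linear_distance_nm"].mean())
    report["comparisons"] = comp

    mt_rows = with_mt.dropna(subset=["mt_distance_nm"])
    if len(mt_rows) >= 4:
        scan = prox.cutoff_scan(
            mt_rows["mt_distance_nm"], mt_rows["linear_distance_nm"], cutoffs=cutoffs
        )
        report["cutoff_scan"] = scan.to_dict(orient="records")
    else:
        report["cutoff_scan"] = None

    params = force_params or ForceModelParams()
    if site_summaries:
        extents = [
            pf["extent1_nm"] for s in site_summaries for pf in s.get("plane_fits", [])
        ]
        if extents:
            params = ForceModelParams(
                **{
                    **params.__dict__,
                    "interaction_length_per_plate": float(np.mean(extents)),
                }
            )
            report["mean_plane_extent_nm"] = float(np.mean(extents))
    report["force_model"] = evaluate_force(
        report["overall"]["mean_filaments_per_site"], params
    ).as_dict()
    return report
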