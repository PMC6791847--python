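"""Microtubule-proximity analysis.

At attachment sites bearing a microtubule, filaments engaging the motor
system are expected to be pulled straighter.  This module measures each
filament's distance to the microtubule axis, splits filaments into
close/far groups at a cutoff, scans cutoffs with a rank-sum test on the
end-to-end (linear) distances, and compares stretch-factor cohorts
between sites with and without a microtubule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .distances import density_curve
from .model import Filament, ValidationError
from .stats import TestResult, wilcoxon_rank_sum

__all__ = [
    "distance_to_microtubule",
    "classify_by_cutoff",
    "cutoff_scan",
    "default_cutoff_grid",
    "stretch_cohort_compare",
]


def _point_segments_min(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Min distance from any of ``points`` to any segment [a_i, b_i]."""
    d = b - a  # (m,3)
    len2 = np.einsum("ij,ij->i", d, d)
    len2 = np.where(len2 > 0, len2, 1.0)
    # t[i,j]: projection parameter of point i on segment j
    diff = points[:, None, :] - a[None, :, :]          # (n,m,3)
    t = np.clip(np.einsum("nmj,mj->nm", diff, d) / len2, 0.0, 1.0)
    closest = a[None, :, :] + t[..., None] * d[None, :, :]
    dist = np.linalg.norm(points[:, None, :] - closest, axis=2)
    return float(dist.min())


def distance_to_microtubule(filament, mt_axis: Optional[np.ndarray]) -> Optional[float]:
    """Minimum distance from a filament to the microtubule axis polyline.

    Point-to-segment, i.e. the axis is treated as a continuous polyline
    while the filament contributes its stored vertices.  Returns ``None``
    when the site has no microtubule — absence is not zero distance.  A
    configurable radius is deliberately not subtracted; distances are to
    the segmented centre line.
    """
    if mt_axis is None:
        return None
    pts = filament.points if isinstance(filament, Filament) else np.asarray(filament, float)
    axis = np.asarray(mt_axis, dtype=float).reshape(-1, 3)
    if len(axis) == 1:
        return float(np.linalg.norm(pts - axis[0], axis=1).min())
    return _point_segments_min(np.asarray(pts, float), axis[:-1], axis[1:])


def classify_by_cutoff(mt_distances, cutoff: float) -> np.ndarray:
    """Boolean mask of filaments *close* to the microtubule (< cutoff, strict)."""
    if not cutoff > 0:
        raise ValidationError("cutoff must be > 0")
    d = np.asarray(mt_distances, dtype=float)
    close = d < cutoff
    if not close.any():
        warnings.warn(f"no filament closer than {cutoff} nm", stacklevel=2)
    return close


def default_cutoff_grid() -> np.ndarray:
    """Cutoff grid for proximity scans: 20–300 nm in 2 nm steps."""
    return np.arange(20.0, 302.0, 2.0)


def cutoff_scan(
    mt_distances,
    linear_distances,
    cutoffs: Optional[Sequence[float]] = None,
    min_group: int = 2,
) -> pd.DataFrame:
    """Close-vs-far mean linear-distance difference across cutoff values.

    For each cutoff, filaments at microtubule-bearing sites are split at
    the cutoff; the row records group sizes, group means of the
    end-to-end distance, their difference (close − far) and the rank-sum
    p-value.  Cutoffs leaving a group below ``min_group`` yield rows with
    NaN means/p (undefined, not dropped).
    """
    if cutoffs is None:
        cutoffs = default_cutoff_grid()
    cutoffs = np.asarray(cutoffs, dtype=float).ravel()
    if cutoffs.size == 0:
        raise ValidationError("empty cutoff list")
    d = np.asarray(mt_distances, dtype=float).ravel()
    lin = np.asarray(linear_distances, dtype=float).ravel()
    if d.shape != lin.shape:
        raise ValidationError("mt_distances and linear_distances must align")
    rows = []
    for c in cutoffs:
        close = d < c
        n_close, n_far = int(close.sum()), int((~close).sum())
        row = {
            "cutoff": float(c),
            "n_close": n_close,
            "n_far": n_far,
            "mean_linear_close": np.nan,
            "mean_linear_far": np.nan,
            "mean_difference": np.nan,
            "wilcoxon_p": np.nan,
        }
        if n_close >= min_group and n_far >= min_group:
            mc, mf = float(lin[close].mean()), float(lin[~close].mean())
            row.update(
                mean_linear_close=mc,
                mean_linear_far=mf,
                mean_difference=mc - mf,
                wilcoxon_p=wilcoxon_rank_sum(lin[close], lin[~close]).p_value,
            )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class StretchComparison:
    """Stretch-factor contrast between with-MT and without-MT cohorts."""

    mean_with_mt: float
    mean_without_mt: float
    mean_difference: float  # with − without
    test: Optional[TestResult]
    density_with_mt: Optional[tuple]
    density_without_mt: Optional[tuple]

    def as_dict(self) -> dict:
        return {
            "mean_with_mt": self.mean_with_mt,
            "mean_without_mt": self.mean_without_mt,
            "mean_difference": self.mean_difference,
            "test": self.test.as_dict() if self.test else None,
        }


def stretch_cohort_compare(stretch_with_mt, stretch_without_mt) -> StretchComparison:
    """Compare stretch factors of filaments at sites with vs without a microtubule."""
    a = np.asarray(stretch_with_mt, dtype=float).ravel()
    b = np.asarray(stretch_without_mt, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValidationError("both cohorts must be non-empty")

    def _density(x):
        if x.size < 2 or x.std() == 0:
            warnings.warn("cohort too small/degenerate for a density curve", stacklevel=3)
            return None
        return density_curve(x)

    test = wilcoxon_rank_sum(a, b) if (a.size > 1 and b.size > 1) else None
    return StretchComparison(
        mean_with_mt=float(a.mean()),
        mean_without_mt=float(b.mean()),
        mean_difference=float(a.mean() - b.mean()),
        test=test,
        density_with_mt=_density(a),
        density_without_mt=_density(b),
    )
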