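"""Dynein–dynactin force and stoichiometry arithmetic.

Telomere movement forces are generated by dynein–dynactin complexes
walking on microtubules and transmitted through the LINC filaments.  The
model packs motor complexes (~43 nm footprint each) at maximum density
onto the microtubule segment over which the filaments of each attachment
plate concentrate (~150 nm, measured as the plane-fit long extent), twice
per site.  Each dynein contributes ~5 pN; a dynactin can engage one or
two dyneins, so per-site force estimates come in a single-dynein and a
dual-dynein variant.  Nucleus-wide totals follow from the mean filament
count per site, the number of attachment sites, and the trimeric SUN/KASH
stoichiometry of a LINC complex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from .model import ValidationError

__all__ = [
    "ForceModelParams",
    "ForceModelResult",
    "NucleusTotals",
    "max_dynein_complexes",
    "site_force",
    "nucleus_totals",
    "evaluate",
]


@dataclass
class ForceModelParams:
    """Constants of the packing/force model.

    interaction_length_per_plate : nm of microtubule engaged per plate
        (default 150, the plane-fit long side).
    plates_per_site : attachment plates per telomere attachment site (2).
    complex_length : footprint of a microtubule-bound dynein–dynactin
        complex along the microtubule, nm (43).
    force_per_dynein : stall force of one dynein motor, pN (~5).
    dyneins_per_dynactin : 1 or 2 motors per dynactin scaffold.
    sites_per_nucleus : telomere attachment sites per meiotic nucleus
        (40 = 80 telomeres paired two-by-two; the partially synapsed XY
        bivalent adds one more — pass 41 for that variant).
    subunits_per_complex : SUN (and KASH) monomers per LINC complex (3,
        trimeric coiled-coils).
    packing : "ceil" packs partial footprints (maximum-density reading),
        "floor" is the conservative whole-footprint bound.
    """

    interaction_length_per_plate: float = 150.0
    plates_per_site: int = 2
    complex_length: float = 43.0
    force_per_dynein: float = 5.0
    dyneins_per_dynactin: int = 1
    sites_per_nucleus: int = 40
    subunits_per_complex: int = 3
    packing: str = "ceil"

    def __post_init__(self) -> None:
        for name in (
            "interaction_length_per_plate",
            "plates_per_site",
            "complex_length",
            "sites_per_nucleus",
            "subunits_per_complex",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if self.force_per_dynein < 0:
            raise ValidationError("force_per_dynein must be >= 0")
        if self.dyneins_per_dynactin not in (1, 2):
            raise ValidationError("dyneins_per_dynactin must be 1 or 2")
        if self.packing not in ("ceil", "floor"):
            raise ValidationError("packing must be 'ceil' or 'floor'")


def max_dynein_complexes(params: ForceModelParams = ForceModelParams()) -> int:
    """Maximum dynein–dynactin complexes accommodated per attachment site.

    Per plate, the number of ~43 nm footprints fitting on the engaged
    microtubule length; "ceil" counts a partial footprint as reachable
    (maximum density), "floor" does not.  Summed over both plates.
    """
    ratio = params.interaction_length_per_plate / params.complex_length
    per_plate = math.ceil(ratio) if params.packing == "ceil" else max(1, math.floor(ratio))
    return params.plates_per_site * per_plate


def site_force(params: ForceModelParams = ForceModelParams()) -> float:
    """Upper-bound force per attachment site in pN."""
    return max_dynein_complexes(params) * params.dyneins_per_dynactin * params.force_per_dynein


@dataclass
class NucleusTotals:
    filaments: float
    filaments_rounded_thousand: int
    sun_monomers: float
    kash_monomers: float


def nucleus_totals(
    mean_filaments_per_site: float,
    params: ForceModelParams = ForceModelParams(),
) -> NucleusTotals:
    """Nucleus-wide filament and SUN/KASH monomer totals."""
    if mean_filaments_per_site < 0:
        raise ValidationError("mean filament count must be >= 0")
    filaments = params.sites_per_nucleus * mean_filaments_per_site
    monomers = params.subunits_per_complex * filaments
    return NucleusTotals(
        filaments=filaments,
        filaments_rounded_thousand=int(round(filaments / 1000.0)) * 1000,
        sun_monomers=monomers,
        kash_monomers=monomers,
    )


@dataclass
class ForceModelResult:
    params: ForceModelParams
    complexes_per_site: int
    force_per_site: float
    totals: NucleusTotals

    def as_dict(self) -> dict:
        return {
            "params": asdict(self.params),
            "complexes_per_site": self.complexes_per_site,
            "force_per_site_pN": self.force_per_site,
            "filaments_per_nucleus": self.totals.filaments,
            "filaments_per_nucleus_rounded": self.totals.filaments_rounded_thousand,
            "sun_monomers_per_nucleus": self.totals.sun_monomers,
            "kash_monomers_per_nucleus": self.totals.kash_monomers,
        }


def evaluate(
    mean_filaments_per_site: float,
    params: ForceModelParams = ForceModelParams(),
) -> ForceModelResult:
    """Evaluate the full model for a measured mean filament count."""
    return ForceModelResult(
        params=params,
        complexes_per_site=max_dynein_complexes(params),
        force_per_site=site_force(params),
        totals=nucleus_totals(mean_filaments_per_site, params),
    )
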