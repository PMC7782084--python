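"""Equivalent-circle diameters and the nucleus/cytoplasm ratio.

The computed diameter (CD) of a signal is the diameter of the circle with
the same area, ``CD = 2·sqrt(A/π)``. The nucleus/cytoplasm ratio (NCR) is
by default the area ratio ``A_DAPI / A_CK`` — the convention that
reproduces the published per-cohort values — with the diameter-ratio
variant ``sqrt(A_DAPI / A_CK)`` available behind a switch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .features import EventRecord

__all__ = [
    "EventMorphometry",
    "equivalent_diameter",
    "nucleus_cytoplasm_ratio",
    "morphometry_table",
    "morphometry_frame",
]


@dataclass
class EventMorphometry:
    """Cytoplasm and (when evaluable) nucleus morphometry of one event.

    ``dapi_area``, ``dapi_diameter`` and ``ncr`` are ``None`` unless the
    event passed the nucleus-evaluability cascade.
    """

    event_id: str
    group: str
    material: str
    ck_area: float
    ck_diameter: float
    dapi_area: float | None = None
    dapi_diameter: float | None = None
    ncr: float | None = None


def equivalent_diameter(area: float) -> float:
    """Diameter (μm) of the circle with the given area (μm²); 0 maps to 0."""
    if area < 0:
        raise ValueError(f"area must be >= 0, got {area}")
    return 2.0 * math.sqrt(area / math.pi)


def nucleus_cytoplasm_ratio(dapi_area: float, ck_area: float, *, convention: str = "area") -> float:
    """NCR of one event; requires ``0 < dapi_area < ck_area``.

    ``convention="area"`` returns the area ratio, ``"diameter"`` the ratio
    of equivalent diameters (its square root). Either way the result lies
    in (0, 1).
    """
    if not (0 < dapi_area < ck_area):
        raise ValueError(
            f"need 0 < dapi_area < ck_area, got dapi_area={dapi_area}, ck_area={ck_area}"
        )
    ratio = dapi_area / ck_area
    if convention == "area":
        return ratio
    if convention == "diameter":
        return math.sqrt(ratio)
    raise ValueError(f"convention must be 'area' or 'diameter', got {convention!r}")


def morphometry_table(
    records: Iterable[EventRecord], *, convention: str = "area"
) -> list[EventMorphometry]:
    """One morphometry row per size-eligible event.

    Nucleus fields are populated only for events flagged ``ncr_eligible``
    by the selection cascade.
    """
    out = []
    for r in records:
        if "size_eligible" not in r.flags:
            continue
        row = EventMorphometry(
            event_id=r.event_id,
            group=r.group,
            material=r.material,
            ck_area=r.ck.area,
            ck_diameter=equivalent_diameter(r.ck.area),
        )
        if "ncr_eligible" in r.flags:
            row.dapi_area = r.dapi.area
            row.dapi_diameter = equivalent_diameter(r.dapi.area)
            row.ncr = nucleus_cytoplasm_ratio(r.dapi.area, r.ck.area, convention=convention)
        out.append(row)
    return out


def morphometry_frame(rows: list[EventMorphometry]) -> pd.DataFrame:
    """Morphometry rows as a DataFrame (for CSV export and statistics)."""
    return pd.DataFrame(
        [
            {
                "event_id": m.event_id,
                "group": m.group,
                "material": m.material,
                "ck_area_um2": m.ck_area,
                "ck_diameter_um": m.ck_diameter,
                "dapi_area_um2": m.dapi_area,
                "dapi_diameter_um": m.dapi_diameter,
                "ncr": m.ncr,
            }
            for m in rows
        ],
        columns=[
            "event_id",
            "group",
            "material",
            "ck_area_um2",
            "ck_diameter_um",
            "dapi_area_um2",
            "dapi_diameter_um",
            "ncr",
        ],
    )
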