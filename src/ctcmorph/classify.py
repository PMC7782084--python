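"""P2A singularity classification and the nested selection cascade.

Events are binned by the P2A shape ratio of their cytokeratin signal into
single / doublet / small cluster / large cluster (half-open bins, defaults
1.5 / 2.5 / 4.0; a circle scores 1). The cascade then selects, in order:

1. ``size_eligible`` — CK-positive events classified *single*; only these
   enter the size analysis.
2. ``dapi_evaluable`` — size-eligible events with a positive DAPI signal
   (> 0 μm²) whose nucleus is intact (DAPI area strictly smaller than CK
   area).
3. ``ncr_eligible`` — DAPI-evaluable events whose DAPI signal is itself
   classified single; only these enter the nucleus/cytoplasm analysis.
4. ``leukocyte`` — CD45+/DAPI+/CK− events whose CD45 signal is single
   (the CK singularity rule applied to the CD45 channel).

The same bins are reused on the DAPI signal with the three nucleus labels
single / double / clustered (both cluster bins collapse to *clustered*).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .features import EventRecord
from .io import CohortManifest

__all__ = [
    "P2ABins",
    "SINGULARITY_CLASSES",
    "classify_singularity",
    "annotate_records",
    "select_ctc_events",
    "select_nucleus_evaluable",
    "select_leukocytes",
    "apply_selection_cascade",
    "tabulate_counts",
    "counts_with_total",
    "compare_to_expert_counts",
]

SINGULARITY_CLASSES = ("single", "doublet", "small_cluster", "large_cluster")

#: mapping of the event bins onto the three nucleus-singularity labels
_DAPI_LABEL = {
    "single": "single",
    "doublet": "double",
    "small_cluster": "clustered",
    "large_cluster": "clustered",
}

COUNT_COLUMNS = [
    "detected",
    "ck_positive",
    "single",
    "doublet",
    "small_cluster",
    "large_cluster",
    "dapi_evaluable",
    "dapi_single",
    "dapi_double",
    "dapi_clustered",
]


@dataclass(frozen=True)
class P2ABins:
    """Ascending P2A thresholds defining the four singularity classes."""

    t1: float = 1.5
    t2: float = 2.5
    t3: float = 4.0

    def __post_init__(self) -> None:
        if not (0 < self.t1 < self.t2 < self.t3):
            raise ValueError(f"P2A edges must satisfy 0 < t1 < t2 < t3, got {self}")

    @classmethod
    def from_edges(cls, edges: Sequence[float]) -> "P2ABins":
        return cls(*edges)


def classify_singularity(p2a: float | None, bins: P2ABins = P2ABins()) -> str:
    """Bin a P2A value: [0,t1) single, [t1,t2) doublet, [t2,t3) small_cluster, [t3,∞) large_cluster.

    An undefined P2A (``None``) yields ``"undefined"`` rather than an error.
    """
    if p2a is None:
        return "undefined"
    if p2a < 0:
        raise ValueError(f"p2a must be >= 0, got {p2a}")
    if p2a < bins.t1:
        return "single"
    if p2a < bins.t2:
        return "doublet"
    if p2a < bins.t3:
        return "small_cluster"
    return "large_cluster"


def annotate_records(records: Iterable[EventRecord], bins: P2ABins = P2ABins()) -> list[EventRecord]:
    """Fill the CK and DAPI singularity labels of each record in place."""
    records = list(records)
    for r in records:
        r.singularity_class = (
            classify_singularity(r.ck.p2a, bins) if r.ck.positive else "undefined"
        )
        r.dapi_singularity_class = (
            _DAPI_LABEL[classify_singularity(r.dapi.p2a, bins)] if r.dapi.positive else "undefined"
        )
    return records


def select_ctc_events(records: Iterable[EventRecord], bins: P2ABins = P2ABins()) -> list[EventRecord]:
    """Flag ``size_eligible``: CK-positive events whose CK signal is single."""
    records = annotate_records(records, bins)
    for r in records:
        if r.ck.positive and r.singularity_class == "single":
            r.flags.add("size_eligible")
        else:
            r.flags.discard("size_eligible")
    return records


def select_nucleus_evaluable(
    records: Iterable[EventRecord], bins: P2ABins = P2ABins()
) -> list[EventRecord]:
    """Flag ``dapi_evaluable`` (DAPI > 0 μm² and DAPI < CK within the
    size-eligible events) and ``ncr_eligible`` (additionally a single DAPI
    signal)."""
    records = list(records)
    for r in records:
        r.flags.discard("dapi_evaluable")
        r.flags.discard("ncr_eligible")
        if "size_eligible" not in r.flags:
            continue
        if r.dapi.area > 0 and r.dapi.area < r.ck.area:
            r.flags.add("dapi_evaluable")
            if _DAPI_LABEL[classify_singularity(r.dapi.p2a, bins)] == "single":
                r.flags.add("ncr_eligible")
    return records


def select_leukocytes(records: Iterable[EventRecord], bins: P2ABins = P2ABins()) -> list[EventRecord]:
    """Flag ``leukocyte``: CD45+/DAPI+/CK− events with a single CD45 signal."""
    records = list(records)
    for r in records:
        is_leuko = (
            r.cd45.positive
            and r.dapi.positive
            and not r.ck.positive
            and classify_singularity(r.cd45.p2a, bins) == "single"
        )
        if is_leuko:
            r.flags.add("leukocyte")
        else:
            r.flags.discard("leukocyte")
    return records


def apply_selection_cascade(
    records: Iterable[EventRecord], bins: P2ABins = P2ABins()
) -> list[EventRecord]:
    """Run the full cascade: singularity labels, size, nucleus and leukocyte flags."""
    records = select_ctc_events(records, bins)
    records = select_nucleus_evaluable(records, bins)
    return select_leukocytes(records, bins)


def tabulate_counts(records: Iterable[EventRecord]) -> pd.DataFrame:
    """Count events per (group, material) by detection, CK class and nucleus class.

    Columns: detected, ck_positive, single, doublet, small_cluster,
    large_cluster (partitioning the CK-positive events), dapi_evaluable and
    its nucleus-singularity partition dapi_single / dapi_double /
    dapi_clustered.
    """
    rows: dict[tuple[str, str], dict[str, int]] = {}
    for r in records:
        key = (r.group, r.material)
        c = rows.setdefault(key, {col: 0 for col in COUNT_COLUMNS})
        c["detected"] += 1
        if r.ck.positive:
            c["ck_positive"] += 1
            c[r.singularity_class] += 1
        if "dapi_evaluable" in r.flags:
            c["dapi_evaluable"] += 1
            c[f"dapi_{r.dapi_singularity_class}"] += 1
    index = pd.MultiIndex.from_tuples(sorted(rows), names=["group", "material"])
    return pd.DataFrame([rows[k] for k in sorted(rows)], index=index, columns=COUNT_COLUMNS)


def counts_with_total(counts: pd.DataFrame) -> pd.DataFrame:
    """Append a grand-total row (column sums) to a counts table."""
    total = counts.sum(axis=0).to_frame().T
    total.index = pd.MultiIndex.from_tuples([("total", "")], names=counts.index.names)
    return pd.concat([counts, total])


def compare_to_expert_counts(
    records: Iterable[EventRecord], manifest: CohortManifest
) -> pd.DataFrame:
    """Per-cartridge ratio of re-detected events to the expert CTC count.

    The ratio is NaN (undefined) when the expert count is zero. Every
    cartridge appearing in the records must be covered by the manifest.
    """
    detected: dict[str, int] = {}
    for r in records:
        detected[r.cartridge_id] = detected.get(r.cartridge_id, 0) + 1
    known = {e.cartridge_id for e in manifest}
    unknown = sorted(set(detected) - known)
    if unknown:
        raise ValueError(f"cartridges absent from manifest: {unknown}")
    rows = []
    for entry in manifest:
        n = detected.get(entry.cartridge_id, 0)
        expert = entry.expert_ctc_count
        ratio = n / expert if expert > 0 else np.nan
        rows.append(
            {
                "cartridge_id": entry.cartridge_id,
                "group": entry.group,
                "material": entry.material,
                "detected": n,
                "expert": expert,
                "ratio": ratio,
            }
        )
    return pd.DataFrame(rows, columns=["cartridge_id", "group", "material", "detected", "expert", "ratio"])
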