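"""On-disk artifacts: galleries, marker files, manifests and feature tables.

The vendor cartridge format is proprietary, so this module defines a
minimal open layout instead:

* a gallery directory holds one subdirectory per cartridge;
* each cartridge directory holds a marker file (``markers.xml`` — one
  ``<event id=... row=... col=...>`` element per marked event — or a
  ``markers.csv`` fallback with columns ``event_id,row,col``) plus one
  grayscale TIFF per channel per event named ``<event_id>_<channel>.tif``;
* a cohort manifest CSV maps cartridges to cohort labels and the expert
  CTC count (``cartridge_id,group,material,expert_ctc_count``).

Coordinates are 0-based ``(row, col)`` positions of the event center in
the cartridge frame; thumbnails are centered crops. Pixel size is read
from TIFF resolution tags where present, otherwise a configurable default
applies. Numeric fields that are undefined (e.g. P2A of an empty channel)
are serialized as empty cells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from lxml import etree

from .config import CHANNELS
from .features import ChannelImage, ChannelMeasurement, EventRecord

__all__ = [
    "MarkedEvent",
    "ManifestEntry",
    "CohortManifest",
    "MarkerParseError",
    "GalleryValidationError",
    "read_marker_file",
    "write_marker_file",
    "read_manifest",
    "write_manifest",
    "read_gallery",
    "write_feature_table",
    "read_feature_table",
]


class MarkerParseError(ValueError):
    """A marker file entry could not be parsed."""


class GalleryValidationError(ValueError):
    """A gallery artifact violates a structural invariant."""


@dataclass
class MarkedEvent:
    """One expert-marked event: aligned thumbnails plus cohort labels."""

    event_id: str
    cartridge_id: str
    coordinates: tuple[int, int]
    thumbnails: dict[str, ChannelImage]
    group: str
    material: str = "blood"

    def __post_init__(self) -> None:
        if set(self.thumbnails) != set(CHANNELS):
            raise GalleryValidationError(
                f"event {self.event_id}: expected exactly one thumbnail per channel "
                f"{CHANNELS}, got {sorted(self.thumbnails)}"
            )
        shapes = {img.pixels.shape for img in self.thumbnails.values()}
        sizes = {img.pixel_size for img in self.thumbnails.values()}
        if len(shapes) != 1 or len(sizes) != 1:
            raise GalleryValidationError(
                f"event {self.event_id}: thumbnails must share dimensions and pixel size "
                f"(shapes {shapes}, pixel sizes {sizes})"
            )


@dataclass
class ManifestEntry:
    cartridge_id: str
    group: str
    material: str = "blood"
    expert_ctc_count: int = 0


@dataclass
class CohortManifest:
    """Cartridge → (cohort, material, expert count) mapping."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.cartridge_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise GalleryValidationError("cartridge_ids in a manifest must be unique")
        for e in self.entries:
            if e.expert_ctc_count < 0:
                raise GalleryValidationError(
                    f"cartridge {e.cartridge_id}: expert_ctc_count must be >= 0"
                )

    def __iter__(self):
        return iter(self.entries)

    def lookup(self, cartridge_id: str) -> ManifestEntry:
        for e in self.entries:
            if e.cartridge_id == cartridge_id:
                return e
        raise KeyError(cartridge_id)


# ---------------------------------------------------------------------------
# marker files


def read_marker_file(path: str | Path) -> list[tuple[str, tuple[int, int]]]:
    """Read marked-event coordinates, in file order.

    Dispatches on extension: ``.xml`` for the open XML dialect, anything
    else is treated as the two-column CSV fallback.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".xml":
        return _read_marker_xml(path)
    return _read_marker_csv(path)


def _read_marker_xml(path: Path) -> list[tuple[str, tuple[int, int]]]:
    try:
        root = etree.parse(str(path)).getroot()
    except etree.XMLSyntaxError as exc:
        raise MarkerParseError(f"{path}: {exc}") from exc
    out = []
    for el in root.iter("event"):
        attrs = el.attrib
        if "id" not in attrs or "row" not in attrs or "col" not in attrs:
            raise MarkerParseError(
                f"{path}:{el.sourceline}: <event> needs id, row and col attributes, got {dict(attrs)}"
            )
        try:
            coord = (int(attrs["row"]), int(attrs["col"]))
        except ValueError as exc:
            raise MarkerParseError(
                f"{path}:{el.sourceline}: non-integer coordinate in event {attrs['id']!r}: "
                f"row={attrs['row']!r} col={attrs['col']!r}"
            ) from exc
        out.append((attrs["id"], coord))
    return out


def _read_marker_csv(path: Path) -> list[tuple[str, tuple[int, int]]]:
    out = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    body = [(i + 1, ln) for i, ln in enumerate(lines) if ln]
    if body and body[0][1].lower().replace(" ", "") in ("event_id,row,col", "id,row,col"):
        body = body[1:]
    for lineno, ln in body:
        parts = [p.strip() for p in ln.split(",")]
        if len(parts) != 3:
            raise MarkerParseError(f"{path}:{lineno}: expected 'event_id,row,col', got {ln!r}")
        try:
            coord = (int(parts[1]), int(parts[2]))
        except ValueError as exc:
            raise MarkerParseError(
                f"{path}:{lineno}: non-integer coordinate in event {parts[0]!r}"
            ) from exc
        out.append((parts[0], coord))
    return out


def write_marker_file(entries: list[tuple[str, tuple[int, int]]], path: str | Path) -> None:
    """Write the open XML marker dialect."""
    root = etree.Element("events")
    for event_id, (row, col) in entries:
        etree.SubElement(root, "event", id=str(event_id), row=str(int(row)), col=str(int(col)))
    Path(path).write_bytes(etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8"))


# ---------------------------------------------------------------------------
# manifest


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "cartridge_id": e.cartridge_id,
                "group": e.group,
                "material": e.material,
                "expert_ctc_count": e.expert_ctc_count,
            }
            for e in manifest
        ],
        columns=["cartridge_id", "group", "material", "expert_ctc_count"],
    ).to_csv(path, index=False)


def read_manifest(path: str | Path) -> CohortManifest:
    df = pd.read_csv(path, dtype={"cartridge_id": str, "group": str, "material": str})
    entries = []
    for row in df.itertuples(index=False):
        material = row.material if isinstance(row.material, str) and row.material else "blood"
        entries.append(
            ManifestEntry(
                cartridge_id=row.cartridge_id,
                group=row.group,
                material=material,
                expert_ctc_count=int(row.expert_ctc_count),
            )
        )
    return CohortManifest(entries)


# ---------------------------------------------------------------------------
# gallery


def _pixel_size_from_tiff(page) -> float | None:
    """Physical pixel size (μm) from TIFF resolution tags, if stored."""
    tags = page.tags
    if "XResolution" not in tags or "ResolutionUnit" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    per_unit = num / den
    unit = tags["ResolutionUnit"].value
    unit_um = {2: 25400.0, 3: 10000.0}.get(int(unit))
    if unit_um is None:
        return None
    return unit_um / per_unit


def read_gallery(
    gallery_dir: str | Path,
    manifest: CohortManifest,
    *,
    default_pixel_size: float = 0.64,
) -> list[MarkedEvent]:
    """Load every complete marked event of every cartridge in the manifest.

    Events missing a channel raster are reported via ``warnings.warn`` and
    skipped; a shape mismatch between channels of one event raises
    :class:`GalleryValidationError`. The returned event count never exceeds
    the marker-file count.
    """
    gallery_dir = Path(gallery_dir)
    events: list[MarkedEvent] = []
    for entry in manifest:
        cart_dir = gallery_dir / entry.cartridge_id
        marker_path = cart_dir / "markers.xml"
        if not marker_path.exists():
            marker_path = cart_dir / "markers.csv"
        markers = read_marker_file(marker_path)
        for event_id, coord in markers:
            paths = {ch: cart_dir / f"{event_id}_{ch}.tif" for ch in CHANNELS}
            missing = [ch for ch, p in paths.items() if not p.exists()]
            if missing:
                warnings.warn(
                    f"event {event_id} in cartridge {entry.cartridge_id}: missing channel(s) "
                    f"{missing}; event skipped"
                )
                continue
            thumbnails = {}
            for ch, p in paths.items():
                with tifffile.TiffFile(p) as tif:
                    pixels = tif.pages[0].asarray()
                    ps = _pixel_size_from_tiff(tif.pages[0]) or default_pixel_size
                thumbnails[ch] = ChannelImage(pixels=pixels, pixel_size=ps, channel=ch)
            events.append(
                MarkedEvent(
                    event_id=event_id,
                    cartridge_id=entry.cartridge_id,
                    coordinates=coord,
                    thumbnails=thumbnails,
                    group=entry.group,
                    material=entry.material,
                )
            )
    return events


# ---------------------------------------------------------------------------
# feature tables

_CHANNEL_FIELDS = ("area_um2", "perimeter_um", "p2a", "mean_intensity", "positive")

FEATURE_COLUMNS = (
    ["event_id", "cartridge_id", "group", "material"]
    + [f"{ch}_{f}" for ch in CHANNELS for f in _CHANNEL_FIELDS]
    + ["singularity_class", "dapi_singularity_class", "flags"]
)


def _measurement_to_row(m: ChannelMeasurement) -> list:
    return [
        m.area,
        m.perimeter,
        m.p2a if m.p2a is not None else None,
        m.mean_intensity if m.mean_intensity is not None else None,
        "true" if m.positive else "false",
    ]


def write_feature_table(records: list[EventRecord], path: str | Path) -> None:
    """Serialize per-event measurements to CSV (empty cell = undefined)."""
    rows = []
    for r in records:
        row = [r.event_id, r.cartridge_id, r.group, r.material]
        for ch in CHANNELS:
            row.extend(_measurement_to_row(r.channel(ch)))
        row.extend([r.singularity_class, r.dapi_singularity_class, ";".join(sorted(r.flags))])
        rows.append(row)
    pd.DataFrame(rows, columns=FEATURE_COLUMNS).to_csv(path, index=False)


def _parse_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def read_feature_table(path: str | Path) -> list[EventRecord]:
    """Inverse of :func:`write_feature_table`."""
    df = pd.read_csv(path, dtype=object)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise GalleryValidationError(f"{path}: feature table missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        channels = {}
        for ch in CHANNELS:
            positive = str(d[f"{ch}_positive"]).lower() == "true"
            channels[ch] = ChannelMeasurement(
                area=_parse_float(d[f"{ch}_area_um2"]) or 0.0,
                perimeter=_parse_float(d[f"{ch}_perimeter_um"]) or 0.0,
                p2a=_parse_float(d[f"{ch}_p2a"]),
                mean_intensity=_parse_float(d[f"{ch}_mean_intensity"]),
                positive=positive,
            )
        flags_raw = d["flags"]
        flags = (
            set(str(flags_raw).split(";"))
            if isinstance(flags_raw, str) and flags_raw
            else set()
        )
        material = d["material"] if isinstance(d["material"], str) and d["material"] else "blood"
        records.append(
            EventRecord(
                event_id=str(d["event_id"]),
                cartridge_id=str(d["cartridge_id"]),
                group=str(d["group"]),
                material=material,
                dapi=channels["dapi"],
                ck=channels["ck"],
                cd45=channels["cd45"],
                singularity_class=str(d["singularity_class"]),
                dapi_singularity_class=str(d["dapi_singularity_class"]),
                flags=flags,
            )
        )
    return records
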