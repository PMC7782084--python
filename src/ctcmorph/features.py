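"""Per-event fluorescence measurement.

Each marked event arrives as three spatially aligned thumbnails (DAPI, CK,
CD45). This module segments the signal in each channel and measures the
quantities the downstream analysis consumes: area (μm²), perimeter (μm),
the normalized perimeter-to-area shape ratio

    P2A = P² / (4·π·A)

(1 for a circle, larger for anything else), and the mean foreground
intensity. Segmentation is deterministic and parameter-light: median-filter
denoising, Otsu's global threshold, a minimum component size, and retention
of the component(s) at the thumbnail center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure
from skimage.filters import threshold_otsu

from .config import CHANNELS

__all__ = [
    "ChannelImage",
    "ChannelMeasurement",
    "EventRecord",
    "segment_channel",
    "measure_channel",
    "measure_event",
]


@dataclass
class ChannelImage:
    """A single fluorescence channel raster with its physical pixel size.

    ``pixels`` is a 2-D array of nonnegative intensities (arbitrary units);
    ``pixel_size`` is the micrometer edge length of one pixel; ``channel``
    is one of ``("dapi", "ck", "cd45")``.
    """

    pixels: np.ndarray
    pixel_size: float
    channel: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError(f"pixels must be a 2-D grid, got shape {self.pixels.shape}")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be nonnegative")
        if not (math.isfinite(self.pixel_size) and self.pixel_size > 0):
            raise ValueError(f"pixel_size must be finite and > 0, got {self.pixel_size}")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")


@dataclass
class ChannelMeasurement:
    """Measured signal of one channel of one event.

    ``p2a`` and ``mean_intensity`` are ``None`` (undefined) when the
    segmented area is zero; ``positive`` means a nonempty signal was found.
    """

    area: float = 0.0
    perimeter: float = 0.0
    p2a: float | None = None
    mean_intensity: float | None = None
    positive: bool = False


@dataclass
class EventRecord:
    """All measurements and classification labels of one marked event."""

    event_id: str
    cartridge_id: str
    group: str
    material: str = "blood"
    dapi: ChannelMeasurement = field(default_factory=ChannelMeasurement)
    ck: ChannelMeasurement = field(default_factory=ChannelMeasurement)
    cd45: ChannelMeasurement = field(default_factory=ChannelMeasurement)
    singularity_class: str = "undefined"
    dapi_singularity_class: str = "undefined"
    flags: set[str] = field(default_factory=set)

    def channel(self, name: str) -> ChannelMeasurement:
        return {"dapi": self.dapi, "ck": self.ck, "cd45": self.cd45}[name]


def segment_channel(
    image: ChannelImage,
    *,
    min_component_area_um2: float = 4.0,
    merge_distance_um: float = 3.2,
    median_filter_size: int = 3,
) -> np.ndarray:
    """Segment the event signal in one channel.

    Returns a boolean foreground mask containing the connected
    component(s) at or nearest the thumbnail center. Degenerate inputs
    (constant images, pure noise with no component above the minimum
    size) yield an empty mask, never an exception.
    """
    px = image.pixels.astype(float)
    smoothed = ndimage.median_filter(px, size=median_filter_size)
    if smoothed.max() == smoothed.min():
        return np.zeros(image.pixels.shape, dtype=bool)
    threshold = threshold_otsu(smoothed)

    # Background guard: on a signal-free thumbnail Otsu merely splits the
    # noise, so require the threshold to clear the background level (median
    # of the border ring) by 4 robust standard deviations.
    ring = np.concatenate(
        [smoothed[:2].ravel(), smoothed[-2:].ravel(), smoothed[2:-2, :2].ravel(), smoothed[2:-2, -2:].ravel()]
    ) if min(smoothed.shape) > 4 else smoothed.ravel()
    bg_level = float(np.median(ring))
    bg_sigma = 1.4826 * float(np.median(np.abs(ring - bg_level)))
    if threshold <= bg_level + 4.0 * bg_sigma:
        return np.zeros(image.pixels.shape, dtype=bool)
    fg = smoothed > threshold

    min_px = max(1, int(round(min_component_area_um2 / image.pixel_size**2)))
    labels, n = ndimage.label(fg)
    if n == 0:
        return np.zeros_like(fg)

    # distance of each component's closest pixel to the thumbnail center
    center = ((fg.shape[0] - 1) / 2.0, (fg.shape[1] - 1) / 2.0)
    rr, cc = np.nonzero(fg)
    dist = np.hypot(rr - center[0], cc - center[1])
    comp = labels[rr, cc]
    sizes = np.bincount(comp, minlength=n + 1)
    min_dist = np.full(n + 1, np.inf)
    np.minimum.at(min_dist, comp, dist)

    big = set((np.flatnonzero(sizes[1:] >= min_px) + 1).tolist())
    if not big:
        return np.zeros_like(fg)

    # Grow the event from the component nearest the center, agglomerating
    # any component within the merge distance of the kept set, so the
    # touching-or-near blobs of a doublet/cluster are measured as one
    # region while distant debris is dropped.
    merge_px = merge_distance_um / image.pixel_size
    nearest = min(big, key=lambda c: min_dist[c])
    kept = {nearest}
    candidates = big - kept
    while candidates:
        kept_mask = np.isin(labels, sorted(kept))
        gap = ndimage.distance_transform_edt(~kept_mask)
        added = {c for c in candidates if gap[labels == c].min() <= merge_px}
        if not added:
            break
        kept |= added
        candidates -= added
    return np.isin(labels, sorted(kept))


def _contour_perimeter_px(mask: np.ndarray) -> float:
    """Boundary length of a binary mask in pixel units.

    Marching-squares contours at the 0.5 level, regularized with a
    circular moving average before summing segment lengths. The raw
    staircase contour overestimates smooth boundaries by ~5%; the
    smoothing removes that bias for the round objects measured here
    while only mildly rounding true corners.
    """
    padded = np.pad(mask.astype(float), 1)
    total = 0.0
    for contour in skmeasure.find_contours(padded, 0.5):
        closed = np.array_equal(contour[0], contour[-1])
        pts = contour[:-1] if closed else contour
        n = len(pts)
        w = 3 if n >= 6 else 1
        if closed and w > 1:
            kernel = np.ones(w) / w
            ext = np.vstack([pts[-(w // 2):], pts, pts[: w - 1 - w // 2]])
            pts = np.column_stack(
                [np.convolve(ext[:, 0], kernel, "valid"), np.convolve(ext[:, 1], kernel, "valid")]
            )
        loop = np.vstack([pts, pts[:1]]) if closed else pts
        seg = np.diff(loop, axis=0)
        total += float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    return total


def measure_channel(image: ChannelImage, mask: np.ndarray) -> ChannelMeasurement:
    """Measure area, perimeter, P2A and mean intensity of a segmented signal."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.pixels.shape:
        raise ValueError(f"mask shape {mask.shape} does not match image shape {image.pixels.shape}")
    n_px = int(mask.sum())
    if n_px == 0:
        return ChannelMeasurement()
    ps = image.pixel_size
    area = n_px * ps * ps
    perimeter = _contour_perimeter_px(mask) * ps
    return ChannelMeasurement(
        area=area,
        perimeter=perimeter,
        p2a=perimeter * perimeter / (4.0 * math.pi * area),
        mean_intensity=float(image.pixels[mask].mean()),
        positive=True,
    )


def measure_event(event, **segment_kwargs) -> EventRecord:
    """Segment and measure all three channels of a marked event.

    Classification labels are initialized to ``"undefined"``; they are
    filled in by the classification stage.
    """
    measurements = {}
    for name in CHANNELS:
        img = event.thumbnails[name]
        measurements[name] = measure_channel(img, segment_channel(img, **segment_kwargs))
    return EventRecord(
        event_id=event.event_id,
        cartridge_id=event.cartridge_id,
        group=event.group,
        material=event.material,
        dapi=measurements["dapi"],
        ck=measurements["ck"],
        cd45=measurements["cd45"],
    )
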