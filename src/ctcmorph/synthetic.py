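"""Synthetic cartridge cohorts with known ground truth.

The patient image archive behind the published cohort summaries is not
deposited, so every stage of the pipeline is exercised on synthetic
cohorts instead. The generator draws per-event cytoplasm areas from a
lognormal calibrated to a target median and IQR (the minimal right-skewed
two-parameter family matching both), nucleus/cytoplasm ratios from a Beta
distribution with a target median, singularity classes from the published
class-mix frequencies, and renders each event as anti-aliased disks in
three channels: CK cytoplasm (1 disk for singles; 2, 3 or 5 narrowly
separated disks for doublets and clusters), a DAPI nucleus enclosed in
the cytoplasm, and CD45 for leukocyte events (CK left empty). Gaussian
read noise on a constant background emulates imaging noise.

A single seed drives all sampling; exports are readable by
:mod:`ctcmorph.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.stats import norm

from .config import CHANNELS
from .features import ChannelImage
from .io import CohortManifest, ManifestEntry, MarkedEvent, write_manifest, write_marker_file

__all__ = [
    "CohortSpec",
    "GroundTruthEvent",
    "lognormal_from_median_iqr",
    "beta_from_median",
    "sample_cohort",
    "render_event",
    "export_synthetic_gallery",
    "reference_cohorts",
]

_Z75 = norm.ppf(0.75)

#: edge-to-edge gap (μm) between the member disks of a doublet/cluster.
#: The gap is kept below the measurement stage's merge distance, so the k
#: member cells are measured as one event whose P2A is ≈ k (k disjoint
#: circles), i.e. mid-bin for every class; it is wide enough that the
#: median filter does not fuse the cells into one rounded blob.
DEFAULT_GAP_UM = 2.0

#: events per cartridge in exported galleries (the platform's gallery limit)
EVENTS_PER_CARTRIDGE = 175


def lognormal_from_median_iqr(median: float, iqr: float) -> tuple[float, float]:
    """Lognormal (mu, sigma) whose median and Q3−Q1 width match the targets.

    For ``X = exp(mu + sigma·Z)``: median = exp(mu) and
    IQR = median·(exp(z75·sigma) − exp(−z75·sigma)) = 2·median·sinh(z75·sigma),
    so sigma = asinh(IQR / (2·median)) / z75 in closed form.
    """
    if not (median > 0 and iqr > 0):
        raise ValueError(f"median and IQR must be > 0, got median={median}, iqr={iqr}")
    return math.log(median), math.asinh(iqr / (2.0 * median)) / _Z75


def beta_from_median(median: float, concentration: float = 20.0) -> tuple[float, float]:
    """Beta (a, b) with the given approximate median and total concentration.

    Uses the median ≈ (a − 1/3) / (a + b − 2/3) approximation.
    """
    if not (0 < median < 1):
        raise ValueError(f"median must lie in (0, 1), got {median}")
    a = median * (concentration - 2.0 / 3.0) + 1.0 / 3.0
    b = concentration - a
    if a <= 0 or b <= 0:
        raise ValueError(f"concentration {concentration} too small for median {median}")
    return a, b


@dataclass
class CohortSpec:
    """Generative description of one cohort.

    ``area_median_um2`` / ``area_iqr_um2`` calibrate the lognormal
    cytoplasm-area distribution; ``ncr_median`` the Beta NCR distribution;
    ``class_mix`` the singularity frequencies (single, doublet, small
    cluster, large cluster). ``dapi_positive_rate`` is the fraction of
    events in which a nucleus is detected at all, ``oversized_nucleus_rate``
    the fraction rendered with a DAPI signal larger than the CK signal
    (rejected downstream as non-intact), and ``dapi_doublet_rate`` the
    fraction with a fragmented (two-lobe) nucleus. Leukocyte events carry
    their signal in CD45 + DAPI with an empty CK channel.
    """

    group: str
    n_events: int
    area_median_um2: float
    area_iqr_um2: float
    material: str = "blood"
    ncr_median: float = 0.55
    ncr_concentration: float = 20.0
    class_mix: tuple[float, float, float, float] = (0.95, 0.04, 0.009, 0.001)
    leukocyte_fraction: float = 0.0
    dapi_positive_rate: float = 0.85
    oversized_nucleus_rate: float = 0.02
    dapi_doublet_rate: float = 0.015
    area_cap_um2: float = 2000.0
    background_level: float = 60.0
    foreground_level: float = 500.0
    noise_sigma: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1, got {self.class_mix}")
        for p in (*self.class_mix, self.leukocyte_fraction, self.dapi_positive_rate,
                  self.oversized_nucleus_rate, self.dapi_doublet_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probabilities must lie in [0, 1], got {p}")
        # validates the (median, IQR) pair
        lognormal_from_median_iqr(self.area_median_um2, self.area_iqr_um2)
        beta_from_median(self.ncr_median, self.ncr_concentration)


@dataclass
class GroundTruthEvent:
    """True (pre-rendering) properties of one synthetic event."""

    event_id: str
    group: str
    material: str
    true_class: str
    true_ck_area: float
    true_dapi_area: float
    true_cd45_area: float
    true_ncr: float | None
    is_leukocyte: bool
    dapi_lobes: int = 1


_CLASSES = ("single", "doublet", "small_cluster", "large_cluster")


def sample_cohort(spec: CohortSpec, rng: np.random.Generator | None = None) -> list[GroundTruthEvent]:
    """Draw a cohort of ground-truth events; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    mu, sigma = lognormal_from_median_iqr(spec.area_median_um2, spec.area_iqr_um2)
    a, b = beta_from_median(spec.ncr_median, spec.ncr_concentration)
    events = []
    for i in range(spec.n_events):
        area = float(min(rng.lognormal(mu, sigma), spec.area_cap_um2))
        ncr = float(np.clip(rng.beta(a, b), 0.02, 0.98))
        is_leuko = bool(rng.random() < spec.leukocyte_fraction)
        dapi_lobes = 1
        if is_leuko:
            cls = "single"
            ck_area, cd45_area = 0.0, area
            dapi_area = ncr * cd45_area
            true_ncr = None
        else:
            cls = _CLASSES[int(rng.choice(4, p=spec.class_mix))]
            ck_area, cd45_area = area, 0.0
            if rng.random() >= spec.dapi_positive_rate:
                dapi_area = 0.0
            elif rng.random() < spec.oversized_nucleus_rate:
                dapi_area = ck_area * float(rng.uniform(1.05, 1.3))
            else:
                dapi_area = ncr * ck_area
                if rng.random() < spec.dapi_doublet_rate:
                    dapi_lobes = 2
            true_ncr = dapi_area / ck_area if 0 < dapi_area < ck_area else None
        events.append(
            GroundTruthEvent(
                event_id=f"{spec.group}-{spec.material}-{i:06d}",
                group=spec.group,
                material=spec.material,
                true_class=cls,
                true_ck_area=ck_area,
                true_dapi_area=dapi_area,
                true_cd45_area=cd45_area,
                true_ncr=true_ncr,
                is_leukocyte=is_leuko,
                dapi_lobes=dapi_lobes,
            )
        )
    return events


# ---------------------------------------------------------------------------
# rendering


_N_DISKS = {"single": 1, "doublet": 2, "small_cluster": 3, "large_cluster": 5}


def _disk_layout(cls: str, area: float, gap_um: float) -> list[tuple[float, float, float]]:
    """Disk centers (dy, dx) and radius realizing one event, in μm.

    The event's total area is split over k equal disks (k = 1, 2, 3, 5 for
    single, doublet, small cluster, large cluster) laid out as a chain
    (cross for the large cluster, to stay compact) with a fixed
    edge-to-edge gap.
    """
    if cls not in _N_DISKS:
        raise ValueError(f"unknown class {cls!r}")
    k = _N_DISKS[cls]
    r = math.sqrt(area / (k * math.pi))
    d = 2.0 * r + gap_um  # center-to-center distance
    if cls == "single":
        return [(0.0, 0.0, r)]
    if cls == "doublet":
        return [(0.0, -d / 2, r), (0.0, d / 2, r)]
    if cls == "small_cluster":
        return [(0.0, -d, r), (0.0, 0.0, r), (0.0, d, r)]
    return [(0.0, 0.0, r), (0.0, -d, r), (0.0, d, r), (-d, 0.0, r), (d, 0.0, r)]


def _coverage(shape: tuple[int, int], disks, pixel_size: float, supersample: int = 4) -> np.ndarray:
    """Anti-aliased union coverage of disks given in μm coordinates.

    ``disks`` are (cy_um, cx_um, r_um) with the origin at the frame center.
    Supersampling is restricted to each disk's bounding box for speed.
    """
    h, w = shape
    ss = supersample
    cy0, cx0 = (h - 1) / 2.0, (w - 1) / 2.0
    out = np.zeros((h, w))
    for cy, cx, r in disks:
        # pixel-index bounding box with a 1-px margin
        y_lo = max(0, int(math.floor(cy0 + (cy - r) / pixel_size)) - 1)
        y_hi = min(h, int(math.ceil(cy0 + (cy + r) / pixel_size)) + 2)
        x_lo = max(0, int(math.floor(cx0 + (cx - r) / pixel_size)) - 1)
        x_hi = min(w, int(math.ceil(cx0 + (cx + r) / pixel_size)) + 2)
        if y_lo >= y_hi or x_lo >= x_hi:
            continue
        ys = y_lo + (np.arange((y_hi - y_lo) * ss) + 0.5) / ss - 0.5
        xs = x_lo + (np.arange((x_hi - x_lo) * ss) + 0.5) / ss - 0.5
        yy = (ys[:, None] - cy0) * pixel_size - cy
        xx = (xs[None, :] - cx0) * pixel_size - cx
        hit = yy**2 + xx**2 <= r * r
        local = hit.reshape(y_hi - y_lo, ss, x_hi - x_lo, ss).mean(axis=(1, 3))
        patch = out[y_lo:y_hi, x_lo:x_hi]
        np.maximum(patch, local, out=patch)
    return out


def render_event(
    truth: GroundTruthEvent,
    *,
    pixel_size: float = 0.64,
    frame_px: int = 128,
    gap_um: float = DEFAULT_GAP_UM,
    background_level: float = 60.0,
    foreground_level: float = 500.0,
    noise_sigma: float = 15.0,
    rng: np.random.Generator | None = None,
    cartridge_id: str = "synthetic",
) -> MarkedEvent:
    """Render one ground-truth event as a three-channel thumbnail set."""
    rng = np.random.default_rng(0) if rng is None else rng
    shape = (frame_px, frame_px)
    half_um = (frame_px - 1) / 2.0 * pixel_size
    jitter = tuple(rng.uniform(-0.8, 0.8, 2) * pixel_size)

    cell_area = truth.true_cd45_area if truth.is_leukocyte else truth.true_ck_area
    cell_channel = "cd45" if truth.is_leukocyte else "ck"
    disks = [
        (cy + jitter[0], cx + jitter[1], r)
        for cy, cx, r in _disk_layout(truth.true_class, cell_area, gap_um)
    ]
    for cy, cx, r in disks:
        if max(abs(cy), abs(cx)) + r > half_um - pixel_size:
            raise ValueError(
                f"event {truth.event_id}: area {cell_area:.1f} μm² does not fit a "
                f"{frame_px}px frame at {pixel_size} μm/px"
            )

    coverages = {ch: np.zeros(shape) for ch in CHANNELS}
    coverages[cell_channel] = _coverage(shape, disks, pixel_size)

    if truth.true_dapi_area > 0:
        cy0, cx0, r_cell = disks[0]
        if truth.dapi_lobes == 2:
            r_d = math.sqrt(truth.true_dapi_area / (2.0 * math.pi))
            d = 2.0 * r_d + gap_um
            dapi_disks = [(cy0, cx0 - d / 2, r_d), (cy0, cx0 + d / 2, r_d)]
        else:
            r_d = math.sqrt(truth.true_dapi_area / math.pi)
            # nucleus sits inside the first cytoplasm disk when it fits
            max_off = max(0.0, r_cell - r_d)
            off = rng.uniform(-0.3, 0.3, 2) * max_off
            dapi_disks = [(cy0 + off[0], cx0 + off[1], r_d)]
        for cy, cx, r in dapi_disks:
            if max(abs(cy), abs(cx)) + r > half_um - pixel_size:
                raise ValueError(
                    f"event {truth.event_id}: DAPI area {truth.true_dapi_area:.1f} μm² "
                    f"does not fit a {frame_px}px frame"
                )
        coverages["dapi"] = _coverage(shape, dapi_disks, pixel_size)

    thumbnails = {}
    for ch in CHANNELS:
        img = background_level + foreground_level * coverages[ch]
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma, shape)
        pixels = np.clip(np.round(img), 0, 65535).astype(np.uint16)
        thumbnails[ch] = ChannelImage(pixels=pixels, pixel_size=pixel_size, channel=ch)

    center = ((frame_px - 1) // 2, (frame_px - 1) // 2)
    return MarkedEvent(
        event_id=truth.event_id,
        cartridge_id=cartridge_id,
        coordinates=center,
        thumbnails=thumbnails,
        group=truth.group,
        material=truth.material,
    )


def render_cohort(
    truths: list[GroundTruthEvent],
    spec: CohortSpec,
    *,
    pixel_size: float = 0.64,
    frame_px: int = 128,
    rng: np.random.Generator | None = None,
) -> list[MarkedEvent]:
    """Render a sampled cohort, splitting it into gallery-sized cartridges."""
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    out = []
    for i, truth in enumerate(truths):
        cart = f"{spec.group}-{spec.material}-c{i // EVENTS_PER_CARTRIDGE:03d}"
        out.append(
            render_event(
                truth,
                pixel_size=pixel_size,
                frame_px=frame_px,
                background_level=spec.background_level,
                foreground_level=spec.foreground_level,
                noise_sigma=spec.noise_sigma,
                rng=rng,
                cartridge_id=cart,
            )
        )
    return out


# ---------------------------------------------------------------------------
# export


def truth_frame(truths: list[GroundTruthEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event_id": t.event_id,
                "group": t.group,
                "material": t.material,
                "true_class": t.true_class,
                "true_ck_area": t.true_ck_area,
                "true_dapi_area": t.true_dapi_area,
                "true_cd45_area": t.true_cd45_area,
                "true_ncr": t.true_ncr,
                "is_leukocyte": t.is_leukocyte,
                "dapi_lobes": t.dapi_lobes,
            }
            for t in truths
        ]
    )


def export_synthetic_gallery(
    specs: list[CohortSpec],
    out_dir: str | Path,
    *,
    pixel_size: float = 0.64,
    frame_px: int = 128,
) -> tuple[CohortManifest, pd.DataFrame]:
    """Sample, render and write cohorts as a gallery readable by ``read_gallery``.

    Writes per-cartridge marker files and channel TIFFs (with resolution
    tags carrying the pixel size), a cohort manifest (the expert count per
    cartridge is the number of true non-leukocyte events), and a
    ground-truth CSV beside the gallery.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    all_truths: list[GroundTruthEvent] = []
    entries: list[ManifestEntry] = []
    resolution = (1e4 / pixel_size, 1e4 / pixel_size)
    for spec in specs:
        truths = sample_cohort(spec)
        all_truths.extend(truths)
        events = render_cohort(truths, spec, pixel_size=pixel_size, frame_px=frame_px)
        by_cart: dict[str, list[tuple[GroundTruthEvent, MarkedEvent]]] = {}
        for t, ev in zip(truths, events):
            by_cart.setdefault(ev.cartridge_id, []).append((t, ev))
        for cart_id, pairs in by_cart.items():
            cart_dir = out_dir / cart_id
            cart_dir.mkdir(exist_ok=True)
            write_marker_file([(ev.event_id, ev.coordinates) for _, ev in pairs], cart_dir / "markers.xml")
            for _, ev in pairs:
                for ch, img in ev.thumbnails.items():
                    tifffile.imwrite(
                        cart_dir / f"{ev.event_id}_{ch}.tif",
                        img.pixels,
                        resolution=resolution,
                        resolutionunit="CENTIMETER",
                    )
            expert = sum(0 if t.is_leukocyte else 1 for t, _ in pairs)
            entries.append(
                ManifestEntry(
                    cartridge_id=cart_id,
                    group=spec.group,
                    material=spec.material,
                    expert_ctc_count=expert,
                )
            )
    manifest = CohortManifest(entries)
    write_manifest(manifest, out_dir / "manifest.csv")
    truths_df = truth_frame(all_truths)
    truths_df.to_csv(out_dir / "ground_truth.csv", index=False)
    return manifest, truths_df


# ---------------------------------------------------------------------------
# calibrated preset


def reference_cohorts(scale: float = 1.0, seed: int = 0) -> list[CohortSpec]:
    """Cohort specs calibrated to the published summaries.

    Area medians/IQRs, class mixes and DAPI-evaluability rates follow the
    per-cohort values of the study this generator emulates; ``scale``
    shrinks every cohort proportionally (minimum 30 events) so smaller
    reproductions stay tractable. The leukocyte NCR target is a realistic
    choice (lymphocytes have scant cytoplasm); it is not a published value.
    """

    def n(full: int) -> int:
        return max(30, int(round(full * scale)))

    def mix(single, doublet, small, large):
        total = single + doublet + small + large
        return (single / total, doublet / total, small / total, large / total)

    common = dict(oversized_nucleus_rate=0.02, dapi_doublet_rate=0.015)
    return [
        CohortSpec(
            group="breast", material="blood", n_events=n(45695),
            area_median_um2=120.4, area_iqr_um2=104.9, ncr_median=0.47,
            class_mix=mix(44232, 1172, 68, 1), dapi_positive_rate=0.79,
            seed=seed + 1, **common,
        ),
        CohortSpec(
            group="breast", material="liquor", n_events=n(5327),
            area_median_um2=141.3, area_iqr_um2=113.1, ncr_median=0.46,
            class_mix=mix(4702, 513, 104, 3), dapi_positive_rate=0.98,
            seed=seed + 2, **common,
        ),
        CohortSpec(
            group="prostate", material="blood", n_events=n(20624),
            area_median_um2=83.6, area_iqr_um2=63.5, ncr_median=0.62,
            class_mix=mix(19117, 916, 63, 4), dapi_positive_rate=0.71,
            seed=seed + 3, **common,
        ),
        CohortSpec(
            group="colorectal", material="blood", n_events=n(934),
            area_median_um2=44.6, area_iqr_um2=53.3, ncr_median=0.60,
            class_mix=mix(503, 12, 3, 1), dapi_positive_rate=0.52,
            seed=seed + 4, **common,
        ),
        CohortSpec(
            group="bladder", material="blood", n_events=n(260),
            area_median_um2=57.8, area_iqr_um2=111.5, ncr_median=0.75,
            class_mix=mix(182, 15, 1, 0.001), dapi_positive_rate=0.56,
            seed=seed + 5, **common,
        ),
        CohortSpec(
            group="breast_cell_line", material="blood", n_events=n(3395),
            area_median_um2=265.4, area_iqr_um2=127.38, ncr_median=0.37,
            class_mix=(0.95, 0.04, 0.009, 0.001), dapi_positive_rate=0.95,
            seed=seed + 6, **common,
        ),
        CohortSpec(
            group="prostate_cell_line", material="blood", n_events=n(1054),
            area_median_um2=337.9, area_iqr_um2=142.5, ncr_median=0.48,
            class_mix=(0.95, 0.04, 0.009, 0.001), dapi_positive_rate=0.95,
            seed=seed + 7, **common,
        ),
        CohortSpec(
            group="leukocyte", material="blood", n_events=n(130),
            area_median_um2=69.6, area_iqr_um2=25.6, ncr_median=0.80,
            class_mix=(1.0, 0.0, 0.0, 0.0), leukocyte_fraction=1.0,
            dapi_positive_rate=1.0, seed=seed + 8, **common,
        ),
    ]
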