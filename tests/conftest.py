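import numpy as np
import pytest

from ctcmorph.config import CHANNELS
from ctcmorph.features import ChannelImage, ChannelMeasurement, EventRecord
from ctcmorph.io import MarkedEvent
from ctcmorph.synthetic import GroundTruthEvent, render_event


def make_record(
    event_id="e0",
    group="g",
    material="blood",
    ck=None,
    dapi=None,
    cd45=None,
    cartridge_id="c0",
):
    """EventRecord with explicit per-channel (area, p2a) measurements."""

    def meas(spec):
        if spec is None:
            return ChannelMeasurement()
        area, p2a = spec
        if area <= 0:
            return ChannelMeasurement()
        perimeter = float(np.sqrt(p2a * 4 * np.pi * area))
        return ChannelMeasurement(
            area=area, perimeter=perimeter, p2a=p2a, mean_intensity=100.0, positive=True
        )

    return EventRecord(
        event_id=event_id,
        cartridge_id=cartridge_id,
        group=group,
        material=material,
        dapi=meas(dapi),
        ck=meas(ck),
        cd45=meas(cd45),
    )


def disk_image(radius_px, *, shape=(64, 64), pixel_size=0.64, channel="ck",
               center=None, level=500.0, background=0.0, supersample=8):
    """Anti-aliased disk rendered at a generic subpixel center."""
    h, w = shape
    if center is None:
        center = ((h - 1) / 2 + 0.39, (w - 1) / 2 + 0.89)
    ss = supersample
    ys = (np.arange(h * ss) + 0.5) / ss - 0.5
    xs = (np.arange(w * ss) + 0.5) / ss - 0.5
    yy = ys[:, None] - center[0]
    xx = xs[None, :] - center[1]
    hit = yy**2 + xx**2 <= radius_px**2
    coverage = hit.reshape(h, ss, w, ss).mean(axis=(1, 3))
    return ChannelImage(
        pixels=background + level * coverage, pixel_size=pixel_size, channel=channel
    )


def synthetic_marked_event(truth: GroundTruthEvent, seed=0, noise_sigma=0.0, **kwargs) -> MarkedEvent:
    return render_event(truth, noise_sigma=noise_sigma, rng=np.random.default_rng(seed), **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
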