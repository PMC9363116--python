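"""Shared fixtures: small rasters and sessions built programmatically."""

import numpy as np
import pytest

from pupdyn import ActivityRaster, MovementEpochs, SessionBundle, raster_from_transients


def make_null_raster(seed, n_cells=100, n_frames=5000, rate_per_min=1.0, frame_rate=10.0):
    """Independent-cell raster: Bernoulli transient onsets, short rises."""
    rng = np.random.default_rng(seed)
    h = rate_per_min / 60.0 / frame_rate
    transients = []
    for _ in range(n_cells):
        onsets = np.flatnonzero(rng.random(n_frames) < h)
        cell, last = [], -1
        for o in onsets:
            if o <= last:
                continue
            p = min(n_frames - 1, o + int(rng.integers(2, 6)))
            cell.append((int(o), int(p)))
            last = p
        transients.append(cell)
    return ActivityRaster(
        raster_from_transients(transients, n_frames),
        frame_rate=frame_rate,
    )


@pytest.fixture
def toy_raster():
    """3 cells x 30 frames with hand-placed transients."""
    transients = [
        [(2, 4), (10, 12), (20, 22)],
        [(5, 8)],
        [],
    ]
    return ActivityRaster(
        raster_from_transients(transients, 30),
        frame_rate=10.0,
        cell_types=np.array(["pyramidal", "interneuron", "pyramidal"], dtype=object),
        transients=transients,
    )


@pytest.fixture
def toy_bundle(toy_raster):
    movements = MovementEpochs(epochs=[(6, 9, "twitch"), (18, 24, "complex")], n_frames=30)
    return SessionBundle(raster=toy_raster, movements=movements,
                         meta={"animal_id": "toy", "age_days": 7, "session_id": "toy-1"})
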