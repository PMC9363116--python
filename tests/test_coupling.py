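"""PMTHs, movement-related inhibition, epoch-associated cells, trend fits."""

import numpy as np
import pytest

from pupdyn import (
    ActivityRaster,
    MovementEpochs,
    SessionBundle,
    epoch_associated_cells,
    fit_trend,
    inhibiting_movement_proportion,
    pmth_group,
    pmth_session,
    post_movement_activity,
    raster_from_transients,
)
from pupdyn.coupling import sigmoid
from conftest import make_null_raster


def bundle_from(transients, n_frames, onsets, frame_rate=10.0, dur=5):
    raster = ActivityRaster(
        raster_from_transients(transients, n_frames), frame_rate=frame_rate
    )
    movements = MovementEpochs(
        epochs=[(o, o + dur, "twitch") for o in onsets], n_frames=n_frames
    )
    return SessionBundle(raster=raster, movements=movements)


class TestPMTHSession:
    def test_all_cells_at_onset_give_100_percent(self):
        """Every cell transient starts at each movement onset -> median 100%
        at the onset bin."""
        onsets = [150, 300, 450]
        transients = [[(o, o + 3) for o in onsets] for _ in range(4)]
        b = bundle_from(transients, 600, onsets)
        p = pmth_session(b, n_surrogates=20, seed=0)
        onset_bin = np.argmin(np.abs(p.bin_centers))
        assert p.median[onset_bin] == pytest.approx(100.0)

    def test_hand_enumerated_fractions(self):
        """2 cells, 3 movements: per-bin medians match hand counting."""
        onsets = [150, 300, 450]
        # cell 0 active at +1 frame after every onset; cell 1 after 2 of 3
        transients = [
            [(o + 1, o + 1) for o in onsets],
            [(o + 1, o + 1) for o in onsets[:2]],
        ]
        b = bundle_from(transients, 600, onsets)
        p = pmth_session(b, n_surrogates=10, seed=0)
        plus1 = np.argmin(np.abs(p.bin_centers - 0.1))
        # counts across movements at +0.1 s: [2, 2, 1] -> median 2 of 2 cells
        assert p.median[plus1] == pytest.approx(100.0)
        assert p.q25[plus1] == pytest.approx(75.0)  # 25th pct of [2,2,1]/2

    def test_null_raster_median_inside_envelope(self):
        """On an independent-cell raster the observed median stays within the
        surrogate envelope for >= 90% of bins."""
        raster = make_null_raster(11, n_cells=80, n_frames=4000, rate_per_min=2.0)
        onsets = np.arange(200, 3800, 240)
        movements = MovementEpochs(
            epochs=[(int(o), int(o) + 5, "twitch") for o in onsets], n_frames=4000
        )
        b = SessionBundle(raster=raster, movements=movements)
        p = pmth_session(b, n_surrogates=200, seed=12)
        inside = (p.median <= p.surrogate_p95) & (p.median >= p.surrogate_p5)
        assert inside.mean() >= 0.90

    def test_cell_permutation_invariance(self):
        raster = make_null_raster(13, n_cells=30, n_frames=2000)
        onsets = [300, 900, 1500]
        movements = MovementEpochs(
            epochs=[(o, o + 5, "twitch") for o in onsets], n_frames=2000
        )
        perm = np.random.default_rng(1).permutation(30)
        b1 = SessionBundle(raster=raster, movements=movements)
        b2 = SessionBundle(
            raster=ActivityRaster(
                raster.activity[perm],
                transients=[raster.transients[c] for c in perm],
            ),
            movements=movements,
        )
        p1 = pmth_session(b1, n_surrogates=5, seed=3)
        p2 = pmth_session(b2, n_surrogates=5, seed=3)
        assert np.allclose(p1.median, p2.median)

    def test_no_usable_movements_errors(self):
        b = bundle_from([[(5, 6)]], 150, [10])  # 20-s window never fits
        with pytest.raises(ValueError):
            pmth_session(b, n_surrogates=5, seed=0)


class TestPMTHGroup:
    def test_single_session_identity(self):
        b = bundle_from([[(150, 153)], [(300, 302)]], 600, [150, 300, 450])
        p = pmth_session(b, n_surrogates=10, seed=1)
        g = pmth_group([p])
        assert np.allclose(g.median, p.median)

    def test_two_identical_sessions_unchanged(self):
        b = bundle_from([[(150, 153)]], 600, [150, 300, 450])
        p = pmth_session(b, n_surrogates=10, seed=1)
        g = pmth_group([p, p])
        assert np.allclose(g.median, p.median)

    def test_three_sessions_percentile_oracle(self):
        sessions = []
        for seed in range(3):
            raster = make_null_raster(seed + 20, n_cells=20, n_frames=1200)
            movements = MovementEpochs(
                epochs=[(300, 305, "twitch"), (700, 705, "twitch")], n_frames=1200
            )
            sessions.append(
                pmth_session(SessionBundle(raster=raster, movements=movements),
                             n_surrogates=5, seed=seed)
            )
        g = pmth_group(sessions)
        stack = np.stack([s.median for s in sessions])
        assert np.allclose(g.median, np.percentile(stack, 50, axis=0))
        assert np.allclose(g.q25, np.percentile(stack, 25, axis=0))

    def test_envelope_widens_with_fewer_movements(self):
        """The surrogate envelope widens as the number of movements drops."""
        raster = make_null_raster(40, n_cells=60, n_frames=6000, rate_per_min=2.0)
        widths = {}
        for n_mov in (25, 6):
            onsets = np.linspace(250, 5750, n_mov).astype(int)
            movements = MovementEpochs(
                epochs=[(int(o), int(o) + 5, "twitch") for o in onsets], n_frames=6000
            )
            p = pmth_session(SessionBundle(raster=raster, movements=movements),
                             n_surrogates=150, seed=41)
            widths[n_mov] = float(np.mean(p.surrogate_p95 - p.surrogate_p5))
        assert widths[6] > widths[25]

    def test_mixed_binning_rejected(self):
        b1 = bundle_from([[(150, 153)]], 600, [150, 300], frame_rate=10.0)
        b2 = bundle_from([[(150, 153)]], 600, [150, 300], frame_rate=5.0)
        p1 = pmth_session(b1, n_surrogates=5, seed=0)
        p2 = pmth_session(b2, n_surrogates=5, seed=0)
        with pytest.raises(ValueError):
            pmth_group([p1, p2])


class TestPostMovementActivity:
    def _raster(self, cells):
        return ActivityRaster(raster_from_transients(cells, 200), frame_rate=10.0)

    def test_all_post_gives_one(self):
        raster = self._raster([[(101, 105)], [(110, 112)]])
        assert post_movement_activity(raster, 100) == 1.0

    def test_all_pre_gives_zero(self):
        raster = self._raster([[(85, 90)], [(92, 95)]])
        assert post_movement_activity(raster, 100) == 0.0

    def test_three_of_ten(self):
        cells = [[(85, 90)] for _ in range(7)] + [[(105, 108)] for _ in range(3)]
        raster = self._raster(cells)
        assert post_movement_activity(raster, 100) == pytest.approx(0.30)

    def test_empty_window_undefined(self):
        raster = self._raster([[(5, 8)]])
        assert np.isnan(post_movement_activity(raster, 100))

    def test_symmetric_raster_gives_half(self):
        cells = [[(80, 90)] for _ in range(5)] + [[(110, 119)] for _ in range(5)]
        raster = self._raster(cells)
        assert post_movement_activity(raster, 100) == pytest.approx(0.5)


class TestInhibitingProportion:
    @pytest.mark.parametrize(
        "ratios,expected",
        [([1.0, 1.0], 0.0), ([0.0, 0.0], 1.0), ([0.3, 0.5, 0.39, 0.41], 0.5)],
    )
    def test_proportion_arithmetic(self, ratios, expected):
        """The 40% rule is a strict inequality on the per-movement ratios."""
        n_frames = 400 + 300 * len(ratios)
        cells, onsets = [], []
        for i, r in enumerate(ratios):
            onset = 200 + 300 * i
            onsets.append(onset)
            n_post = int(round(r * 100))
            for _ in range(n_post):
                cells.append([(onset + 2, onset + 4)])
            for _ in range(100 - n_post):
                cells.append([(onset - 10, onset - 5)])
        # every movement has exactly 100 window-active cells, and each cell
        # is active around exactly one movement
        b = bundle_from(cells, n_frames, onsets)
        assert inhibiting_movement_proportion(b) == pytest.approx(expected)


class TestEpochAssociatedCells:
    def test_concentrated_cell_flagged(self):
        """30 onsets all inside a 20%-of-session epoch set are far above the
        shifted 99th percentile."""
        # aperiodic epoch set covering 20% of the session; the cell's 30
        # onsets all fall inside it, so shifted counts concentrate near 6
        rng = np.random.default_rng(0)
        epochs = np.sort(rng.choice(4900, size=1000, replace=False))
        onsets = np.sort(rng.choice(epochs, size=30, replace=False))
        transients = [[(int(o), int(o) + 2) for o in onsets]]
        raster = ActivityRaster(raster_from_transients(transients, 5000))
        flags, frac = epoch_associated_cells(raster, epochs, n_shifts=100, seed=0)
        assert flags[0]

    def test_all_frames_epoch_never_flagged(self):
        raster = make_null_raster(30, n_cells=20, n_frames=1000)
        flags, frac = epoch_associated_cells(raster, np.arange(1000), seed=1)
        assert not flags.any()

    def test_cell_without_transients_not_flagged(self):
        raster = ActivityRaster(np.zeros((3, 500), dtype=np.uint8))
        flags, frac = epoch_associated_cells(raster, np.arange(100), seed=2)
        assert not flags.any()


class TestFitTrend:
    def test_linear_exact(self):
        x = np.arange(5, 13, dtype=float)
        fit = fit_trend(x, 2 * x + 1, "linear")
        assert fit.params["slope"] == pytest.approx(2.0)
        assert fit.params["intercept"] == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_sigmoid_recovery(self):
        x = np.linspace(5, 13, 30)
        y = sigmoid(x, 0.1, 0.6, 9.0, 3.0)
        fit = fit_trend(x, y, "sigmoid")
        assert abs(fit.params["v50"] - 9.0) < 1e-3
        assert fit.r2 > 0.999

    def test_constant_y_r2_zero(self):
        fit = fit_trend(np.arange(8), np.full(8, 2.0), "sigmoid")
        assert fit.r2 == 0.0
        assert np.allclose(fit.predict(np.arange(8)), 2.0)

    def test_poly4_noiseless(self):
        x = np.linspace(0, 10, 20)
        y = 0.1 * (x - 5) ** 4 - x
        fit = fit_trend(x, y, "poly4")
        assert fit.r2 == pytest.approx(1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_trend([1, 2], [1, 2], "linear")
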