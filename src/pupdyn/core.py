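"""Core domain types and session I/O.

The central analysis substrate is a binary activity raster (cells x frames)
in which a neuron is marked active from the onset to the peak of each of its
calcium transients, together with per-cell type labels (pyramidal cell vs
GABAergic interneuron) and the animal's movement epochs.  A session bundle
groups the raster, the movement epochs, optional dF/F fluorescence traces
and minimal metadata (animal id, postnatal age in days, session id).

Bundles are stored as a directory of small CSV tables plus a JSON metadata
file, so that sessions round-trip exactly and remain human-inspectable:

    transients.csv   cell,onset,peak
    movements.csv    onset,offset,category
    cells.csv        cell,type
    meta.json        {"animal_id": ..., "age_days": ..., "session_id": ...,
                      "n_frames": ..., "frame_rate": ...}
    traces.csv       optional, n_cells rows x n_frames columns, no header
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("pupdyn")

#: recognised cell-type labels
CELL_TYPES = ("pyramidal", "interneuron", "noise")
#: recognised movement categories
MOVEMENT_CATEGORIES = ("twitch", "complex", "unclassified")

#: default imaging frame rate in frames/s (5 frames = 500 ms in the
#: synchrony-merge rule); the true per-session rate is carried as data.
DEFAULT_FRAME_RATE = 10.0


class ValidationError(ValueError):
    """A domain invariant was violated when constructing or loading data."""


# ---------------------------------------------------------------------------
# raster construction
# ---------------------------------------------------------------------------

def raster_from_transients(
    transients: Sequence[Sequence[tuple[int, int]]], n_frames: int
) -> np.ndarray:
    """Binary (n_cells x n_frames) matrix with ones on closed [onset, peak].

    Overlapping transients within a cell are merged (a warning is logged);
    out-of-bounds indices or peak < onset raise :class:`ValidationError`.
    """
    n_frames = int(n_frames)
    raster = np.zeros((len(transients), n_frames), dtype=np.uint8)
    for c, cell_transients in enumerate(transients):
        seen_end = -1
        for onset, peak in cell_transients:
            onset, peak = int(onset), int(peak)
            if peak < onset:
                raise ValidationError(
                    f"cell {c}: transient peak {peak} precedes onset {onset}"
                )
            if onset < 0 or peak >= n_frames:
                raise ValidationError(
                    f"cell {c}: transient ({onset}, {peak}) outside [0, {n_frames})"
                )
            if onset <= seen_end:
                logger.warning("cell %d: overlapping transients merged", c)
            seen_end = max(seen_end, peak)
            raster[c, onset : peak + 1] = 1
    return raster


def transients_from_raster(raster: np.ndarray) -> list[list[tuple[int, int]]]:
    """Extract maximal runs of ones per row as (onset, peak) intervals."""
    out: list[list[tuple[int, int]]] = []
    for row in np.asarray(raster, dtype=bool):
        padded = np.diff(np.concatenate(([0], row.view(np.uint8), [0])))
        onsets = np.flatnonzero(padded == 1)
        offsets = np.flatnonzero(padded == -1) - 1
        out.append(list(zip(onsets.tolist(), offsets.tolist())))
    return out


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ActivityRaster:
    """Binary activity matrix with cell types and the defining transients.

    ``activity[c, f] == 1`` iff frame ``f`` lies within the closed
    ``[onset, peak]`` interval of some calcium transient of cell ``c``.
    """

    activity: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE
    cell_types: np.ndarray = field(default=None)  # type: ignore[assignment]
    transients: list[list[tuple[int, int]]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=np.uint8)
        if self.activity.ndim != 2:
            raise ValidationError("activity must be a 2-D (cells x frames) matrix")
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")
        if self.cell_types is None:
            self.cell_types = np.array(["pyramidal"] * self.n_cells, dtype=object)
        self.cell_types = np.asarray(self.cell_types, dtype=object)
        if len(self.cell_types) != self.n_cells:
            raise ValidationError("cell_types length does not match activity rows")
        unknown = set(self.cell_types) - set(CELL_TYPES)
        if unknown:
            raise ValidationError(f"unknown cell types: {sorted(unknown)}")
        if self.transients is None:
            self.transients = transients_from_raster(self.activity)
        self._validate_transients()

    def _validate_transients(self) -> None:
        if len(self.transients) != self.n_cells:
            raise ValidationError("transients length does not match activity rows")
        rebuilt = raster_from_transients(self.transients, self.n_frames)
        for c, tr in enumerate(self.transients):
            onsets = [o for o, _ in tr]
            if any(b < a for a, b in zip(onsets, onsets[1:])) or len(set(onsets)) != len(onsets):
                raise ValidationError(f"cell {c}: transient onsets not strictly increasing")
        if not np.array_equal(rebuilt, self.activity):
            raise ValidationError("activity matrix inconsistent with transient list")

    @property
    def n_cells(self) -> int:
        return self.activity.shape[0]

    @property
    def n_frames(self) -> int:
        return self.activity.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def cells_of_type(self, cell_type: str) -> np.ndarray:
        """Indices of cells with the given type label."""
        return np.flatnonzero(self.cell_types == cell_type)

    def onsets(self) -> list[np.ndarray]:
        """Per-cell array of transient onset frames."""
        return [np.array([o for o, _ in tr], dtype=int) for tr in self.transients]

    def subset(self, cells: np.ndarray) -> "ActivityRaster":
        cells = np.asarray(cells, dtype=int)
        return ActivityRaster(
            activity=self.activity[cells],
            frame_rate=self.frame_rate,
            cell_types=self.cell_types[cells],
            transients=[self.transients[c] for c in cells],
        )


@dataclass
class MovementEpochs:
    """Non-overlapping movement intervals [onset, offset) with categories."""

    epochs: list[tuple[int, int, str]]
    n_frames: int

    def __post_init__(self) -> None:
        cleaned = []
        for onset, offset, cat in self.epochs:
            onset, offset = int(onset), int(offset)
            if offset <= onset:
                raise ValidationError(f"epoch ({onset}, {offset}) has offset <= onset")
            if onset < 0 or offset > self.n_frames:
                raise ValidationError(f"epoch ({onset}, {offset}) outside [0, {self.n_frames}]")
            if cat not in MOVEMENT_CATEGORIES:
                raise ValidationError(f"unknown movement category {cat!r}")
            cleaned.append((onset, offset, cat))
        cleaned.sort()
        for (a0, b0, _), (a1, _, _) in zip(cleaned, cleaned[1:]):
            if a1 < b0:
                raise ValidationError("movement epochs overlap")
        self.epochs = cleaned

    def __len__(self) -> int:
        return len(self.epochs)

    def onsets(self, categories: Optional[Sequence[str]] = None) -> np.ndarray:
        """Movement onset frames, optionally restricted to given categories."""
        return np.array(
            [o for o, _, c in self.epochs if categories is None or c in categories],
            dtype=int,
        )

    def movement_frames(self) -> np.ndarray:
        """Sorted array of frames covered by any movement epoch."""
        mask = np.zeros(self.n_frames, dtype=bool)
        for onset, offset, _ in self.epochs:
            mask[onset:offset] = True
        return np.flatnonzero(mask)


@dataclass
class FluorescenceTraces:
    """Unitless dF/F traces, same (cells x frames) shape as the raster."""

    dff: np.ndarray

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        if self.dff.ndim != 2:
            raise ValidationError("dff must be 2-D")


@dataclass
class SessionBundle:
    """One imaging session: raster + movements (+ optional traces) + metadata."""

    raster: ActivityRaster
    movements: MovementEpochs
    traces: Optional[FluorescenceTraces] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.movements.n_frames != self.raster.n_frames:
            raise ValidationError("movements.n_frames does not match raster")
        if self.traces is not None and self.traces.dff.shape != self.raster.activity.shape:
            raise ValidationError("traces shape does not match raster")
        age = self.meta.get("age_days")
        if age is not None and not (3 <= float(age) <= 15):
            raise ValidationError(f"age_days {age} outside the postnatal range [3, 15]")

    @property
    def age_days(self) -> Optional[float]:
        age = self.meta.get("age_days")
        return None if age is None else float(age)


# ---------------------------------------------------------------------------
# immobility
# ---------------------------------------------------------------------------

def immobility_frames(movements: MovementEpochs, buffer_frames: int = 0) -> np.ndarray:
    """Frames outside every movement epoch dilated by ``buffer_frames``.

    Returns the sorted array of immobility frame indices: the complement of
    the union of [onset - buffer, offset + buffer) over all epochs.
    """
    if buffer_frames < 0:
        raise ValueError("buffer_frames must be >= 0")
    mask = np.ones(movements.n_frames, dtype=bool)
    for onset, offset, _ in movements.epochs:
        a = max(0, onset - buffer_frames)
        b = min(movements.n_frames, offset + buffer_frames)
        mask[a:b] = False
    return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# bundle I/O
# ---------------------------------------------------------------------------

def save_session(bundle: SessionBundle, path: str | Path) -> Path:
    """Write a session bundle to a directory of CSV tables + meta.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = [
        (c, onset, peak)
        for c, tr in enumerate(bundle.raster.transients)
        for onset, peak in tr
    ]
    pd.DataFrame(rows, columns=["cell", "onset", "peak"]).to_csv(
        path / "transients.csv", index=False
    )
    pd.DataFrame(bundle.movements.epochs, columns=["onset", "offset", "category"]).to_csv(
        path / "movements.csv", index=False
    )
    pd.DataFrame(
        {"cell": np.arange(bundle.raster.n_cells), "type": bundle.raster.cell_types}
    ).to_csv(path / "cells.csv", index=False)
    meta = dict(bundle.meta)
    meta["n_frames"] = bundle.raster.n_frames
    meta["frame_rate"] = bundle.raster.frame_rate
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    if bundle.traces is not None:
        np.savetxt(path / "traces.csv", bundle.traces.dff, delimiter=",", fmt="%.6g")
    return path


def load_session(path: str | Path, format: str = "bundle", drop_noise: bool = True) -> SessionBundle:
    """Load and validate a session bundle.

    Parameters
    ----------
    path:
        Directory written by :func:`save_session`.
    format:
        Only the ``"bundle"`` CSV dialect is supported; ``"nwb"`` is reserved.
    drop_noise:
        Remove cells labelled ``"noise"`` before analysis (default, matching
        the preprocessing applied to the in-vivo dataset).
    """
    if format == "nwb":
        raise NotImplementedError(
            "NWB reading requires pynwb; export the session to the CSV bundle dialect"
        )
    if format != "bundle":
        raise ValueError(f"unknown format {format!r}")
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(path)
    try:
        meta = json.loads((path / "meta.json").read_text())
    except json.JSONDecodeError as err:
        raise ValidationError(f"meta.json is not valid JSON: {err}") from err
    for key in ("n_frames", "frame_rate"):
        if key not in meta:
            raise ValidationError(f"meta.json missing required field {key!r}")
    n_frames = int(meta.pop("n_frames"))
    frame_rate = float(meta.pop("frame_rate"))

    cells = pd.read_csv(path / "cells.csv")
    _require_columns(cells, ("cell", "type"), "cells.csv")
    n_cells = len(cells)
    if not np.array_equal(np.sort(cells["cell"].to_numpy()), np.arange(n_cells)):
        raise ValidationError("cells.csv: 'cell' must enumerate 0..n_cells-1")
    cell_types = cells.sort_values("cell")["type"].to_numpy(dtype=object)

    tr_table = pd.read_csv(path / "transients.csv")
    _require_columns(tr_table, ("cell", "onset", "peak"), "transients.csv")
    transients: list[list[tuple[int, int]]] = [[] for _ in range(n_cells)]
    for cell, onset, peak in tr_table.itertuples(index=False):
        if not 0 <= cell < n_cells:
            raise ValidationError(f"transients.csv: cell {cell} not in cells.csv")
        transients[int(cell)].append((int(onset), int(peak)))
    for tr in transients:
        tr.sort()
    raster = ActivityRaster(
        activity=raster_from_transients(transients, n_frames),
        frame_rate=frame_rate,
        cell_types=cell_types,
        transients=transients,
    )

    mv_table = pd.read_csv(path / "movements.csv")
    _require_columns(mv_table, ("onset", "offset", "category"), "movements.csv")
    movements = MovementEpochs(
        epochs=[(int(a), int(b), str(c)) for a, b, c in mv_table.itertuples(index=False)],
        n_frames=n_frames,
    )

    traces = None
    if (path / "traces.csv").exists():
        dff = np.loadtxt(path / "traces.csv", delimiter=",", ndmin=2)
        traces = FluorescenceTraces(dff=dff)

    bundle = SessionBundle(raster=raster, movements=movements, traces=traces, meta=meta)
    if drop_noise:
        keep = np.flatnonzero(bundle.raster.cell_types != "noise")
        if len(keep) != bundle.raster.n_cells:
            logger.info("dropping %d noise cells", bundle.raster.n_cells - len(keep))
            traces = (
                FluorescenceTraces(bundle.traces.dff[keep]) if bundle.traces else None
            )
            bundle = SessionBundle(
                raster=bundle.raster.subset(keep),
                movements=bundle.movements,
                traces=traces,
                meta=bundle.meta,
            )
    return bundle


def _require_columns(df: pd.DataFrame, columns: Sequence[str], name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{name}: missing column(s) {missing}")
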