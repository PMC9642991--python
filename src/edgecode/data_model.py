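"""Canonical data types and I/O for drum-scanned edge stimulation recordings.

A recording session scans raised, finely oriented lines (±5°, ±10° relative to
the axis perpendicular to the scan direction) across the receptive field of a
single first-order tactile afferent (FA-1 or SA-1), at a set of constant drum
speeds.  The drum carries 5 physical copies of each of the 4 orientations and
is rotated 3 times per speed, giving 15 trials per orientation × speed.

This module defines the canonical in-memory representation (``NeuronRecord``
and friends), a plain-text dataset format (one directory per neuron with
``meta.json``, ``spikes.csv`` and ``drum.csv``), trial segmentation into 8 mm
response windows, and the time→space conversion that references every action
potential to the position of the stimulus on the skin.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "RecordValidationError",
    "OutOfRangeError",
    "StimulusLayout",
    "DrumTrace",
    "SpikeTrain",
    "NeuronRecord",
    "TrialResponse",
    "default_layout",
    "spikes_to_positions",
    "segment_trials",
    "load_dataset",
    "save_dataset",
]

#: length of the response window around each line, µm (minimum line spacing)
WINDOW_UM = 8000.0

#: minimum pooled spike count required to align a window on the response
#: centre of mass; below this the nominal line position is used instead
MIN_SPIKES_FOR_ALIGNMENT = 10


class SchemaError(ValueError):
    """A canonical file is missing a required field or column."""


class RecordValidationError(ValueError):
    """A neuron record violates an invariant of the canonical format."""


class OutOfRangeError(ValueError):
    """A spike time falls outside the support of the drum position trace."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusLayout:
    """Geometry of the stimulus drum.

    ``line_positions_mm`` holds the nominal drum position at which each raised
    line crosses the scan axis, with ``line_orientations_deg`` giving the
    orientation of the line at each position.  Orientations are measured
    relative to the axis perpendicular to the scan direction.
    """

    orientations_deg: tuple[float, ...] = (-10.0, -5.0, 5.0, 10.0)
    repetitions_per_rotation: int = 5
    rotations: int = 3
    line_span_mm: float = 12.0
    line_height_mm: float = 0.5
    line_width_top_mm: float = 0.5
    line_width_base_mm: float = 0.8
    min_line_spacing_mm: float = 8.0
    drum_diameter_mm: float = 59.0
    line_positions_mm: tuple[float, ...] = ()
    line_orientations_deg: tuple[float, ...] = ()

    @property
    def circumference_mm(self) -> float:
        return math.pi * self.drum_diameter_mm

    @property
    def trials_per_condition(self) -> int:
        return self.repetitions_per_rotation * self.rotations

    def validate(self) -> None:
        n_lines = len(self.orientations_deg) * self.repetitions_per_rotation
        if len(self.line_positions_mm) != n_lines:
            raise RecordValidationError(
                f"expected {n_lines} line positions, got {len(self.line_positions_mm)}"
            )
        if len(self.line_orientations_deg) != n_lines:
            raise RecordValidationError("line_orientations_deg length mismatch")
        pos = np.sort(np.asarray(self.line_positions_mm, dtype=float))
        gaps = np.diff(pos)
        # wrap-around gap between last line and first line of the next rotation
        wrap = pos[0] + self.circumference_mm - pos[-1]
        if gaps.size and (gaps.min() < self.min_line_spacing_mm - 1e-9):
            raise RecordValidationError("line spacing below minimum")
        if wrap < self.min_line_spacing_mm - 1e-9:
            raise RecordValidationError("wrap-around line spacing below minimum")
        for theta in self.orientations_deg:
            n = sum(1 for t in self.line_orientations_deg if t == theta)
            if n != self.repetitions_per_rotation:
                raise RecordValidationError(
                    f"orientation {theta} has {n} lines per rotation, "
                    f"expected {self.repetitions_per_rotation}"
                )

    def line_position_mm(self, orientation_deg: float, presentation: int) -> float:
        """Nominal drum position of a given line (presentation index 1-based)."""
        k = 0
        for p, t in zip(self.line_positions_mm, self.line_orientations_deg):
            if t == orientation_deg:
                k += 1
                if k == presentation:
                    return p
        raise KeyError(f"no line with orientation {orientation_deg}, presentation {presentation}")


def default_layout(
    orientations_deg: Sequence[float] = (-10.0, -5.0, 5.0, 10.0),
    repetitions_per_rotation: int = 5,
    rotations: int = 3,
) -> StimulusLayout:
    """Evenly spaced layout interleaving the orientations around the drum."""
    orientations_deg = tuple(float(t) for t in orientations_deg)
    n_lines = len(orientations_deg) * repetitions_per_rotation
    circumference = math.pi * 59.0
    spacing = circumference / n_lines
    positions = tuple((k + 0.5) * spacing for k in range(n_lines))
    line_orients = tuple(orientations_deg[k % len(orientations_deg)] for k in range(n_lines))
    layout = StimulusLayout(
        orientations_deg=orientations_deg,
        repetitions_per_rotation=repetitions_per_rotation,
        rotations=rotations,
        line_positions_mm=positions,
        line_orientations_deg=line_orients,
    )
    layout.validate()
    return layout


@dataclass
class DrumTrace:
    """Drum position trace for one speed condition.

    Positions are in µm along the scan direction, monotone non-decreasing and
    0-based; times in seconds from the start of the condition.
    """

    time_s: np.ndarray
    position_um: np.ndarray
    speed_mm_s: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.position_um = np.asarray(self.position_um, dtype=float)

    def validate(self) -> None:
        if self.time_s.shape != self.position_um.shape or self.time_s.ndim != 1:
            raise RecordValidationError("drum trace arrays must be 1-D and matched")
        if np.any(np.diff(self.position_um) < 0):
            raise RecordValidationError("drum position must be monotone non-decreasing")
        dt = np.diff(self.time_s)
        if np.any(dt <= 0):
            raise RecordValidationError("drum trace times must be strictly increasing")
        inst = np.diff(self.position_um) / dt / 1000.0  # mm/s
        med = float(np.median(inst))
        if abs(med - self.speed_mm_s) > 0.05 * self.speed_mm_s:
            raise RecordValidationError(
                f"median instantaneous speed {med:.2f} mm/s deviates >5% "
                f"from label {self.speed_mm_s} mm/s"
            )

    @classmethod
    def constant_speed(
        cls, speed_mm_s: float, duration_s: float, sample_hz: float = 2400.0
    ) -> "DrumTrace":
        n = max(2, int(round(duration_s * sample_hz)) + 1)
        t = np.linspace(0.0, duration_s, n)
        return cls(time_s=t, position_um=t * speed_mm_s * 1000.0, speed_mm_s=speed_mm_s)

    def position_at(self, times_s: np.ndarray) -> np.ndarray:
        times_s = np.asarray(times_s, dtype=float)
        if times_s.size and (
            times_s.min() < self.time_s[0] - 1e-12 or times_s.max() > self.time_s[-1] + 1e-12
        ):
            raise OutOfRangeError("spike time outside drum trace support")
        return np.interp(times_s, self.time_s, self.position_um)

    def time_at(self, positions_um: np.ndarray) -> np.ndarray:
        """Inverse mapping (first time at which each position is reached)."""
        positions_um = np.asarray(positions_um, dtype=float)
        if positions_um.size and (
            positions_um.min() < self.position_um[0] - 1e-9
            or positions_um.max() > self.position_um[-1] + 1e-9
        ):
            raise OutOfRangeError("position outside drum trace support")
        return np.interp(positions_um, self.position_um, self.time_s)


@dataclass
class SpikeTrain:
    """Spikes of one edge passage (one trial), in absolute condition time."""

    times_s: np.ndarray
    neuron_id: str
    orientation_deg: float
    speed_mm_s: float
    rotation: int  # 0-based drum rotation index
    presentation: int  # 1-based line copy index within a rotation

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)

    def validate(self) -> None:
        if self.times_s.ndim != 1:
            raise RecordValidationError("spike times must be a 1-D array")
        if self.times_s.size > 1 and np.any(np.diff(self.times_s) <= 0):
            raise RecordValidationError(
                f"spike times not strictly increasing for neuron {self.neuron_id}"
            )


@dataclass
class NeuronRecord:
    """One afferent with all its trials, drum traces and the stimulus layout."""

    neuron_id: str
    neuron_type: str  # 'FA-1' | 'SA-1'
    spike_trains: list[SpikeTrain]
    drum_traces: dict[float, DrumTrace]
    layout: StimulusLayout

    def validate(self) -> None:
        if self.neuron_type not in ("FA-1", "SA-1"):
            raise RecordValidationError(f"unknown neuron type {self.neuron_type!r}")
        self.layout.validate()
        for tr in self.spike_trains:
            tr.validate()
        for v, trace in self.drum_traces.items():
            trace.validate()
            if trace.speed_mm_s != v:
                raise RecordValidationError("drum trace keyed under wrong speed")
        counts: dict[tuple[float, float], int] = {}
        for tr in self.spike_trains:
            counts[(tr.orientation_deg, tr.speed_mm_s)] = (
                counts.get((tr.orientation_deg, tr.speed_mm_s), 0) + 1
            )
        expected = self.layout.trials_per_condition
        for (theta, v), n in counts.items():
            if n != expected:
                raise RecordValidationError(
                    f"neuron {self.neuron_id}: orientation {theta} at {v} mm/s has "
                    f"{n} trials, expected {expected}"
                )

    @property
    def speeds(self) -> tuple[float, ...]:
        return tuple(sorted(self.drum_traces))

    @property
    def orientations(self) -> tuple[float, ...]:
        return self.layout.orientations_deg


@dataclass
class TrialResponse:
    """Spikes of one edge passage inside its 8 mm response window.

    Times are relative to the moment the drum enters the window; positions are
    relative to the window start, in [0, 8000] µm (both ends closed).
    """

    times_s: np.ndarray
    positions_um: np.ndarray
    window_um: float
    duration_s: float
    orientation_deg: float
    speed_mm_s: float
    rotation: int
    presentation: int
    neuron_id: str
    neuron_type: str
    flagged: bool = False  # zero spikes in window, or nominal-position fallback

    @property
    def n_spikes(self) -> int:
        return int(self.times_s.size)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def spikes_to_positions(spike_times_s: np.ndarray, trace: DrumTrace) -> np.ndarray:
    """Reference each spike to the drum position at its time of occurrence.

    Linear interpolation of the position trace; raises :class:`OutOfRangeError`
    for spikes outside the trace support.
    """
    return trace.position_at(spike_times_s)


def segment_trials(rec: NeuronRecord, window_um: float = WINDOW_UM) -> list[TrialResponse]:
    """Cut each line passage into an 8 mm response window.

    The window for a given physical line is centred, per neuron, on the drum
    position of the spike-density centre of mass of the pooled response to
    that line (all speeds and rotations).  When fewer than
    ``MIN_SPIKES_FOR_ALIGNMENT`` pooled spikes are available the nominal line
    position is used and the resulting trials are flagged.  Window boundaries
    are closed at both ends.
    """
    circ_um = rec.layout.circumference_mm * 1000.0

    # positions of every spike, relative to the nominal crossing of its line
    rel_positions: dict[tuple[float, int], list[np.ndarray]] = {}
    abs_pos: dict[int, np.ndarray] = {}
    for k, tr in enumerate(rec.spike_trains):
        trace = rec.drum_traces[tr.speed_mm_s]
        pos = spikes_to_positions(tr.times_s, trace)
        abs_pos[k] = pos
        nominal = (
            rec.layout.line_position_mm(tr.orientation_deg, tr.presentation) * 1000.0
            + tr.rotation * circ_um
        )
        rel_positions.setdefault((tr.orientation_deg, tr.presentation), []).append(pos - nominal)

    # per-line alignment offset: pooled centre of mass, or 0 (nominal) fallback
    half = window_um / 2.0
    centers: dict[tuple[float, int], tuple[float, bool]] = {}
    for key, parts in rel_positions.items():
        pooled = np.concatenate(parts) if parts else np.empty(0)
        pooled = pooled[(pooled >= -1.5 * window_um) & (pooled <= 1.5 * window_um)]
        if pooled.size >= MIN_SPIKES_FOR_ALIGNMENT:
            centers[key] = (float(pooled.mean()), False)
        else:
            centers[key] = (0.0, True)

    trials: list[TrialResponse] = []
    for k, tr in enumerate(rec.spike_trains):
        trace = rec.drum_traces[tr.speed_mm_s]
        nominal = (
            rec.layout.line_position_mm(tr.orientation_deg, tr.presentation) * 1000.0
            + tr.rotation * circ_um
        )
        center, fallback = centers[(tr.orientation_deg, tr.presentation)]
        start_abs = nominal + center - half
        # keep the window inside the recorded trace (first/last line of a
        # recording); clamped trials are flagged
        lo, hi = trace.position_um[0], trace.position_um[-1] - window_um
        clamped = not (lo <= start_abs <= hi)
        start_abs = min(max(start_abs, lo), hi)
        end_abs = start_abs + window_um
        pos = abs_pos[k]
        in_window = (pos >= start_abs) & (pos <= end_abs)  # closed interval
        t0, t1 = trace.time_at(np.array([start_abs, end_abs]))
        trials.append(
            TrialResponse(
                times_s=tr.times_s[in_window] - t0,
                positions_um=pos[in_window] - start_abs,
                window_um=window_um,
                duration_s=float(t1 - t0),
                orientation_deg=tr.orientation_deg,
                speed_mm_s=tr.speed_mm_s,
                rotation=tr.rotation,
                presentation=tr.presentation,
                neuron_id=rec.neuron_id,
                neuron_type=rec.neuron_type,
                flagged=fallback or clamped or not np.any(in_window),
            )
        )
    return trials


# ---------------------------------------------------------------------------
# canonical dataset I/O
# ---------------------------------------------------------------------------

_SPIKE_COLUMNS = [
    "neuron_id",
    "speed_mm_s",
    "rotation",
    "presentation",
    "orientation_deg",
    "spike_time_s",
]
_DRUM_COLUMNS = ["speed_mm_s", "time_s", "position_um"]
_META_FIELDS = ["neuron_id", "neuron_type", "speeds_mm_s", "layout"]


def save_dataset(records: Sequence[NeuronRecord], path: str | Path) -> None:
    """Write records in the canonical format (one directory per neuron)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for rec in records:
        d = path / rec.neuron_id
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "neuron_id": rec.neuron_id,
            "neuron_type": rec.neuron_type,
            "speeds_mm_s": list(rec.speeds),
            "layout": asdict(rec.layout),
        }
        (d / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
        rows = []
        for tr in rec.spike_trains:
            for t in tr.times_s:
                rows.append(
                    (rec.neuron_id, tr.speed_mm_s, tr.rotation, tr.presentation,
                     tr.orientation_deg, t)
                )
            if tr.times_s.size == 0:  # keep empty trials representable
                rows.append(
                    (rec.neuron_id, tr.speed_mm_s, tr.rotation, tr.presentation,
                     tr.orientation_deg, np.nan)
                )
        pd.DataFrame(rows, columns=_SPIKE_COLUMNS).to_csv(
            d / "spikes.csv", index=False, float_format="%.17g"
        )
        drum_rows = []
        for v in rec.speeds:
            trace = rec.drum_traces[v]
            drum_rows.append(
                pd.DataFrame(
                    {"speed_mm_s": v, "time_s": trace.time_s, "position_um": trace.position_um}
                )
            )
        pd.concat(drum_rows, ignore_index=True).to_csv(
            d / "drum.csv", index=False, float_format="%.17g"
        )


def _layout_from_meta(obj: dict) -> StimulusLayout:
    kwargs = dict(obj)
    for key in ("orientations_deg", "line_positions_mm", "line_orientations_deg"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return StimulusLayout(**kwargs)


def load_dataset(path: str | Path) -> list[NeuronRecord]:
    """Load a canonical dataset directory.

    Every loaded record is validated; an invalid record raises a
    :class:`RecordValidationError` naming the neuron rather than being
    silently dropped.  An empty directory yields an empty list with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    neuron_dirs = sorted(d for d in path.iterdir() if d.is_dir() and (d / "meta.json").exists())
    if not neuron_dirs:
        warnings.warn(f"no neuron directories found under {path}", stacklevel=2)
        return []

    records = []
    for d in neuron_dirs:
        meta = json.loads((d / "meta.json").read_text())
        for f in _META_FIELDS:
            if f not in meta:
                raise SchemaError(f"{d / 'meta.json'}: missing field {f!r}")
        layout = _layout_from_meta(meta["layout"])

        spikes = pd.read_csv(d / "spikes.csv", float_precision="round_trip")
        for c in _SPIKE_COLUMNS:
            if c not in spikes.columns:
                raise SchemaError(f"{d / 'spikes.csv'}: missing column {c!r}")
        drum = pd.read_csv(d / "drum.csv", float_precision="round_trip")
        for c in _DRUM_COLUMNS:
            if c not in drum.columns:
                raise SchemaError(f"{d / 'drum.csv'}: missing column {c!r}")

        traces = {}
        for v, g in drum.groupby("speed_mm_s"):
            traces[float(v)] = DrumTrace(
                time_s=g["time_s"].to_numpy(),
                position_um=g["position_um"].to_numpy(),
                speed_mm_s=float(v),
            )
        trains = []
        keys = ["speed_mm_s", "rotation", "presentation", "orientation_deg"]
        for (v, rot, pres, theta), g in spikes.groupby(keys, sort=True):
            times = g["spike_time_s"].dropna().to_numpy()
            trains.append(
                SpikeTrain(
                    times_s=times,
                    neuron_id=str(meta["neuron_id"]),
                    orientation_deg=float(theta),
                    speed_mm_s=float(v),
                    rotation=int(rot),
                    presentation=int(pres),
                )
            )
        rec = NeuronRecord(
            neuron_id=str(meta["neuron_id"]),
            neuron_type=str(meta["neuron_type"]),
            spike_trains=trains,
            drum_traces=traces,
            layout=layout,
        )
        rec.validate()
        records.append(rec)
    return records
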