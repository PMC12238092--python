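"""Reading, writing and normalizing marker-trajectory recordings.

A trial is one recording of a grasp-and-place movement: an array of 3D
marker positions at a fixed sampling rate plus the trial's experimental
metadata (which object, how the object and the target plate were rotated).
Everything downstream works on the canonical :class:`TrialRecording`:
positions in centimetres, z-up, frames 0-based, NaN marking occluded
samples.

Two on-disk formats are supported: C3D (the motion-capture interchange
standard) and a long-form CSV dialect (``frame,marker,x,y,z`` plus a
``key=value`` metadata sidecar), which is convenient for version control
and synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import c3dio

__all__ = [
    "ROLES",
    "VALID_ANGLES",
    "TrackerLayout",
    "TrialMeta",
    "TrialRecording",
    "Dataset",
    "read_c3d",
    "write_c3d",
    "read_csv",
    "write_csv",
    "fill_gaps",
    "MissingLabelError",
    "UnitsMissingError",
    "MalformedFileError",
]

#: The seven marker roles every analysis needs. The four object-mounted
#: trackers of the rig collapse to the single role ``object`` because only
#: one object is present per trial.
ROLES = (
    "thumb",
    "index",
    "wrist_radial",
    "wrist_ulnar",
    "object",
    "glasses_frame",
    "glasses_lens",
)

#: The four rotation angles used for both the object and the target plate.
VALID_ANGLES = (0, 90, 180, 270)


class MissingLabelError(KeyError):
    """A layout role has no matching marker label in the file."""


class UnitsMissingError(ValueError):
    """The file does not declare its length units; refusing to guess."""


class MalformedFileError(ValueError):
    """The file violates the documented dialect."""


@dataclass(frozen=True)
class TrackerLayout:
    """Map from marker roles to the labels used in a given file.

    All seven roles must be mapped and the labels must be distinct; extra
    unmapped markers in a file are permitted and ignored.
    """

    roles: dict[str, str]

    def __post_init__(self) -> None:
        missing = [r for r in ROLES if r not in self.roles]
        if missing:
            raise ValueError(f"layout is missing roles: {missing}")
        labels = list(self.roles.values())
        if len(set(labels)) != len(labels):
            raise ValueError("marker labels in a layout must be unique")

    @classmethod
    def default(cls) -> "TrackerLayout":
        """Identity layout: each role is its own label."""
        return cls({r: r for r in ROLES})

    def label(self, role: str) -> str:
        try:
            return self.roles[role]
        except KeyError:
            raise MissingLabelError(role) from None


@dataclass(frozen=True)
class TrialMeta:
    """Per-trial experimental metadata."""

    participant_id: str
    trial_index: int
    object_id: int
    object_angle: int
    plate_angle: int

    def __post_init__(self) -> None:
        if self.trial_index < 1:
            raise ValueError("trial_index is 1-based")
        if self.object_id not in (1, 2, 3, 4):
            raise ValueError(f"object_id must be 1..4, got {self.object_id}")
        for name in ("object_angle", "plate_angle"):
            if getattr(self, name) not in VALID_ANGLES:
                raise ValueError(f"{name} must be one of {VALID_ANGLES}")


@dataclass
class TrialRecording:
    """One trial's marker positions (frames x markers x 3, cm) + metadata.

    ``gap_flag`` is set by :func:`fill_gaps` when an occlusion run was too
    long to interpolate and NaN remains in the data.
    """

    positions: np.ndarray
    sampling_rate: float
    marker_labels: list[str]
    layout: TrackerLayout
    meta: TrialMeta
    gap_flag: bool = False

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=float)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError("positions must be (frames, markers, 3)")
        if p.shape[0] < 2:
            raise ValueError("a recording needs at least 2 frames")
        if p.shape[1] != len(self.marker_labels):
            raise ValueError("one label per marker column required")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if np.isinf(p).any():
            raise ValueError("positions must be finite or NaN")
        self.positions = p

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.sampling_rate

    def marker_index(self, label: str) -> int:
        try:
            return self.marker_labels.index(label)
        except ValueError:
            raise MissingLabelError(label) from None

    def positions_for(self, role: str) -> np.ndarray:
        """(frames, 3) positions of the marker mapped to ``role``."""
        return self.positions[:, self.marker_index(self.layout.label(role)), :]


@dataclass
class Dataset:
    """An ordered collection of trials at a uniform sampling rate."""

    trials: list[TrialRecording] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(t.meta.participant_id, t.meta.trial_index) for t in self.trials]
        if len(set(keys)) != len(keys):
            raise ValueError("(participant_id, trial_index) pairs must be unique")
        rates = {t.sampling_rate for t in self.trials}
        if len(rates) > 1:
            raise ValueError(f"mixed sampling rates in dataset: {sorted(rates)}")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def participants(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trials:
            seen.setdefault(t.meta.participant_id, None)
        return list(seen)


# --------------------------------------------------------------------------
# C3D

_UNIT_TO_CM = {"mm": 0.1, "m": 100.0, "cm": 1.0}


def read_c3d(path, layout: TrackerLayout, meta: TrialMeta) -> TrialRecording:
    """Read a C3D file into the canonical recording.

    Positions are converted to centimetres according to POINT:UNITS; a file
    that does not declare units is rejected rather than guessed at.
    Invalid/occluded C3D samples come back as NaN.
    """
    try:
        pts = c3dio.read_c3d_points(path)
    except c3dio.C3DError as exc:
        raise MalformedFileError(f"{path}: {exc}") from exc
    if pts.units is None:
        raise UnitsMissingError(f"{path}: POINT:UNITS absent; refusing to guess")
    unit = pts.units.strip().lower()
    if unit not in _UNIT_TO_CM:
        raise UnitsMissingError(f"{path}: unsupported POINT:UNITS {pts.units!r}")
    missing = [r for r in ROLES if layout.label(r) not in pts.labels]
    if missing:
        raise MissingLabelError(
            f"{path}: labels absent for roles {missing} "
            f"(file has {pts.labels})"
        )
    return TrialRecording(
        positions=pts.positions * _UNIT_TO_CM[unit],
        sampling_rate=pts.rate,
        marker_labels=pts.labels,
        layout=layout,
        meta=meta,
    )


def write_c3d(recording: TrialRecording, path, units: str = "mm") -> None:
    """Write a recording as a floating-point C3D file (default units mm)."""
    factor = 1.0 / _UNIT_TO_CM[units]
    c3dio.write_c3d_points(
        path,
        recording.positions * factor,
        recording.marker_labels,
        recording.sampling_rate,
        units=units,
    )


# --------------------------------------------------------------------------
# CSV dialect

_META_KEYS = ("participant_id", "trial_index", "object_id", "object_angle",
              "plate_angle", "sampling_rate")


def _sidecar_path(path) -> Path:
    return Path(path).with_suffix(".meta")


def write_csv(recording: TrialRecording, path) -> None:
    """Write the long-form CSV (``frame,marker,x,y,z``) plus the
    ``key=value`` metadata sidecar next to it."""
    path = Path(path)
    n, m, _ = recording.positions.shape
    frames = np.repeat(np.arange(n), m)
    markers = np.tile(np.asarray(recording.marker_labels, dtype=object), n)
    flat = recording.positions.reshape(n * m, 3)
    df = pd.DataFrame(
        {"frame": frames, "marker": markers,
         "x": flat[:, 0], "y": flat[:, 1], "z": flat[:, 2]}
    )
    # occluded samples are written as literal "nan" — an *empty* coordinate
    # cell is reserved for flagging truncated/corrupt rows on read
    df.to_csv(path, index=False, float_format="%.12g", na_rep="nan")
    meta = recording.meta
    lines = [
        f"participant_id={meta.participant_id}",
        f"trial_index={meta.trial_index}",
        f"object_id={meta.object_id}",
        f"object_angle={meta.object_angle}",
        f"plate_angle={meta.plate_angle}",
        f"sampling_rate={recording.sampling_rate:.12g}",
    ]
    _sidecar_path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_sidecar(path) -> dict[str, str]:
    sp = _sidecar_path(path)
    if not sp.exists():
        raise MalformedFileError(f"metadata sidecar not found: {sp}")
    out: dict[str, str] = {}
    for i, line in enumerate(sp.read_text(encoding="utf-8").splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise MalformedFileError(f"{sp}:{i}: expected key=value, got {line!r}")
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    missing = [k for k in _META_KEYS if k not in out]
    if missing:
        raise MalformedFileError(f"{sp}: missing metadata keys {missing}")
    return out


def read_csv(path, layout: TrackerLayout) -> TrialRecording:
    """Read the long-form CSV dialect back into a recording.

    The marker/frame ordering in the file is irrelevant; rows are pivoted
    into the canonical frames x markers x 3 array. Missing coordinate cells
    and duplicated (frame, marker) rows are rejected with the offending
    location named.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise MalformedFileError(f"{path}: {exc}") from exc
    expected = ["frame", "marker", "x", "y", "z"]
    if list(raw.columns) != expected:
        raise MalformedFileError(f"{path}: header must be {','.join(expected)}")
    for col in ("frame", "x", "y", "z"):
        empty = raw[col].str.strip() == ""
        if empty.any():
            row = int(raw.index[empty][0]) + 2  # +1 header, +1 one-based
            raise MalformedFileError(f"{path}: line {row}: missing {col} cell")
    df = raw.copy()
    try:
        df["frame"] = raw["frame"].astype(int)
        for col in ("x", "y", "z"):
            df[col] = raw[col].astype(float)  # literal "nan" -> occlusion
    except (ValueError, TypeError) as exc:
        raise MalformedFileError(f"{path}: non-numeric cell ({exc})") from exc
    dup = df.duplicated(subset=["frame", "marker"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise MalformedFileError(f"{path}: line {row}: duplicate (frame, marker)")

    meta_raw = _read_sidecar(path)
    meta = TrialMeta(
        participant_id=meta_raw["participant_id"],
        trial_index=int(meta_raw["trial_index"]),
        object_id=int(meta_raw["object_id"]),
        object_angle=int(meta_raw["object_angle"]),
        plate_angle=int(meta_raw["plate_angle"]),
    )
    rate = float(meta_raw["sampling_rate"])

    markers = list(dict.fromkeys(df["marker"]))  # first-appearance order
    frames = np.sort(df["frame"].unique().astype(int))
    n = frames.max() + 1
    if not np.array_equal(frames, np.arange(n)):
        raise MalformedFileError(f"{path}: frame indices must cover 0..{n - 1}")
    counts = df.groupby("marker", sort=False).size()
    if (counts != n).any():
        bad_marker = counts.index[counts != n][0]
        raise MalformedFileError(
            f"{path}: marker {bad_marker!r} has {counts[bad_marker]} rows, expected {n}"
        )
    midx = {mk: j for j, mk in enumerate(markers)}
    pos = np.full((n, len(markers), 3), np.nan)
    pos[df["frame"].to_numpy(int), df["marker"].map(midx).to_numpy(int), :] = (
        df[["x", "y", "z"]].to_numpy(float)
    )
    return TrialRecording(pos, rate, markers, layout, meta)


# --------------------------------------------------------------------------
# occlusion handling


def fill_gaps(recording: TrialRecording, max_gap_frames: int) -> TrialRecording:
    """Linearly interpolate short occlusion gaps.

    NaN runs of length <= ``max_gap_frames`` that are bracketed by valid
    samples are filled per coordinate; longer (or edge-touching) runs are
    left as NaN and the recording's ``gap_flag`` is set. No valid sample is
    altered, which also makes the operation idempotent.
    """
    if max_gap_frames < 0:
        raise ValueError("max_gap_frames must be >= 0")
    pos = recording.positions.copy()
    n, m, _ = pos.shape
    flag = False
    for j in range(m):
        for c in range(3):
            col = pos[:, j, c]
            isnan = np.isnan(col)
            if not isnan.any():
                continue
            i = 0
            while i < n:
                if not isnan[i]:
                    i += 1
                    continue
                start = i
                while i < n and isnan[i]:
                    i += 1
                end = i  # NaN run is [start, end)
                run = end - start
                interior = start > 0 and end < n
                if interior and run <= max_gap_frames:
                    x0, x1 = col[start - 1], col[end]
                    t = np.arange(1, run + 1) / (run + 1)
                    col[start:end] = x0 + t * (x1 - x0)
                else:
                    flag = True
    return replace(recording, positions=pos, gap_flag=recording.gap_flag or flag)
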