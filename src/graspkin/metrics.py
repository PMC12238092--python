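"""Per-trial movement parameters and rotation-condition grouping.

Six parameters summarize each trial:

========================  ==============================================
initiation_time (T2-T1)   latency from visual access to first wrist lift
time_to_max_aperture      T3-T2, grasp-preparation duration
reaching_time (T4-T2)     transport phase, wrist lift to object lift
placement_time (T5-T4)    object transport and placement
total_time (T5-T1)        whole movement
wrist_path_cm (T2..T4)    3D arc length of the hand point while reaching
========================  ==============================================

Trials are grouped by the *relative* rotation between object and target
plate: N1 = 0 deg (congruent, no rotation needed), N2 = 90, N3 = 180,
N4 = 270.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import DetectionConfig, EventTimes
from .kinematics import midpoint_trajectory, path_length, smooth_gaussian
from .trial_io import VALID_ANGLES

__all__ = [
    "CONDITIONS",
    "PARAMETERS",
    "TrialMetrics",
    "ConditionTable",
    "assign_condition",
    "compute_metrics",
    "metrics_frame",
    "build_condition_table",
]

CONDITIONS = ("N1", "N2", "N3", "N4")

PARAMETERS = (
    "initiation_time",
    "time_to_max_aperture",
    "reaching_time",
    "placement_time",
    "total_time",
    "wrist_path_cm",
)

_ANGLE_TO_CONDITION = {0: "N1", 90: "N2", 180: "N3", 270: "N4"}


def assign_condition(object_angle: int, plate_angle: int) -> str:
    """Condition label from the relative rotation (plate - object) mod 360.

    Both angles must be one of 0/90/180/270 (adding whole turns is
    allowed and ignored).
    """
    for name, ang in (("object_angle", object_angle), ("plate_angle", plate_angle)):
        if ang % 360 not in VALID_ANGLES:
            raise ValueError(f"{name} must be a multiple-of-90 angle, got {ang}")
    rel = (plate_angle - object_angle) % 360
    return _ANGLE_TO_CONDITION[rel]


@dataclass
class TrialMetrics:
    """The six movement parameters of one trial (None where the required
    events were not detected; ``valid`` is True only when all six are
    present)."""

    participant_id: str
    trial_index: int
    condition: str
    initiation_time: float | None
    time_to_max_aperture: float | None
    reaching_time: float | None
    placement_time: float | None
    total_time: float | None
    wrist_path_cm: float | None

    @property
    def valid(self) -> bool:
        return all(
            getattr(self, p) is not None for p in PARAMETERS
        )

    def as_row(self) -> dict:
        row = {
            "participant_id": self.participant_id,
            "trial_index": self.trial_index,
            "condition": self.condition,
        }
        for p in PARAMETERS:
            row[p] = getattr(self, p)
        row["valid"] = self.valid
        return row


def _diff(events: EventTimes, later: str, earlier: str) -> float | None:
    a, b = events.seconds(later), events.seconds(earlier)
    if a is None or b is None:
        return None
    return a - b


def compute_metrics(recording, events: EventTimes,
                    cfg: DetectionConfig | None = None) -> TrialMetrics:
    """Durations from the event frames plus the wrist path length.

    Durations are simple frame differences over the sampling rate, so the
    additivity (T2-T1) + (T4-T2) + (T5-T4) = (T5-T1) is exact whenever all
    events are present. The path is measured on the smoothed virtual hand
    point — by default the thumb-index midpoint; ``cfg.wrist_path_markers
    = "wrist"`` selects the radial-ulnar midpoint instead.
    """
    cfg = cfg or DetectionConfig()
    meta = recording.meta
    condition = assign_condition(meta.object_angle, meta.plate_angle)

    wrist_path = None
    t2, t4 = events.frame("t2"), events.frame("t4")
    if t2 is not None and t4 is not None and t4 > t2:
        pair = ("thumb", "index") if cfg.wrist_path_markers == "thumb_index" else (
            "wrist_radial", "wrist_ulnar")
        traj = smooth_gaussian(midpoint_trajectory(recording, *pair), cfg.smooth_window)
        try:
            wrist_path = path_length(traj, t2, t4)
        except ValueError:
            wrist_path = None  # NaN in range: leave null, validity flag covers it

    return TrialMetrics(
        participant_id=meta.participant_id,
        trial_index=meta.trial_index,
        condition=condition,
        initiation_time=_diff(events, "t2", "t1"),
        time_to_max_aperture=_diff(events, "t3", "t2"),
        reaching_time=_diff(events, "t4", "t2"),
        placement_time=_diff(events, "t5", "t4"),
        total_time=_diff(events, "t5", "t1"),
        wrist_path_cm=wrist_path,
    )


def metrics_frame(rows) -> pd.DataFrame:
    """Stack TrialMetrics (or ready-made row dicts) into a tidy DataFrame,
    one row per trial."""
    records = [r.as_row() if isinstance(r, TrialMetrics) else dict(r) for r in rows]
    return pd.DataFrame.from_records(records)


@dataclass
class ConditionTable:
    """Participant x condition cell means, one wide table per parameter.

    ``cells[param]`` is a DataFrame indexed by participant with columns
    N1..N4; ``counts`` holds the number of valid trials behind each cell;
    ``incomplete`` lists participants with at least one empty cell (they
    are excluded listwise by the repeated-measures ANOVA).
    """

    cells: dict
    counts: pd.DataFrame
    incomplete: list

    def complete(self, parameter: str) -> pd.DataFrame:
        """The parameter's table restricted to complete participants."""
        t = self.cells[parameter]
        return t.dropna(axis=0, how="any")


def build_condition_table(metrics: pd.DataFrame | list) -> ConditionTable:
    """Average each parameter over valid trials per participant x condition."""
    df = metrics if isinstance(metrics, pd.DataFrame) else metrics_frame(metrics)
    if df.empty:
        raise ValueError("no metrics rows")
    cells: dict = {}
    for p in PARAMETERS:
        sub = df[df[p].notna()]
        wide = (
            sub.pivot_table(index="participant_id", columns="condition",
                            values=p, aggfunc="mean")
            .reindex(columns=list(CONDITIONS))
        )
        cells[p] = wide
    counts = (
        df.pivot_table(index="participant_id", columns="condition",
                       values="trial_index", aggfunc="count")
        .reindex(columns=list(CONDITIONS))
        .fillna(0)
        .astype(int)
    )
    incomplete = sorted(
        {
            str(pid)
            for p in PARAMETERS
            for pid in cells[p].index[cells[p].isna().any(axis=1)]
        }
    )
    return ConditionTable(cells=cells, counts=counts, incomplete=incomplete)
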