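"""Synthetic grasp-and-place trials with planted ground truth.

The generator reproduces the experiment's structure so the whole pipeline
(segmentation -> metrics -> statistics) is testable without any recorded
data:

* the factorial design — 4 objects x 4 object angles x 4 plate angles =
  64 trials per participant, shuffled by the sort-by-uniform-key scheme
  the protocol used;
* the object geometry — five 1 cm^3 cubes in a plane, plus a tracker cube
  centrally on top;
* one seven-marker recording per trial whose signals carry the morphology
  of a real trial: occlusion glasses opening from the closed distance D1
  to the open distance D2 at T1; a resting wrist that starts a
  minimum-jerk reach whose vertical-velocity threshold crossing lands at
  T2; a thumb-index aperture with two bumps (release of the start
  cylinder, then grasp preshaping peaking at T3); an object that rests,
  lifts at T4 and settles stably at T5; and white Gaussian sensor noise on
  every coordinate.

Planted event frames are calibrated against the noiseless smooth-then-
detect pipeline, so at zero noise every detector fires exactly on the
planted frame and any error measured at nonzero noise is attributable to
noise alone.

The default sensor noise is sigma = 0.001 cm (10 um) per coordinate per
frame. This is deliberate: after Gaussian smoothing (window 30) the
central-difference velocity noise floor is about 4.7 x sigma in cm/s, and
the protocol's object-channel rule (0.01 cm/s sustained for 20 frames) is
only meaningful while that floor stays comfortably below the threshold —
see docs/methods.md for the full budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import events as ev
from .events import DetectionConfig
from .kinematics import Signal1D, smooth_gaussian, velocity
from .metrics import CONDITIONS, assign_condition
from .trial_io import ROLES, Dataset, TrackerLayout, TrialMeta, TrialRecording

__all__ = [
    "DesignTrial",
    "ObjectShape",
    "TrialScenario",
    "EffectSpec",
    "ParamEffect",
    "enumerate_design",
    "randomize_sequence",
    "make_object_shape",
    "simulate_trial",
    "simulate_dataset",
    "iter_trials",
]

_ANGLES = (0, 90, 180, 270)


# --------------------------------------------------------------------------
# experimental design


@dataclass(frozen=True)
class DesignTrial:
    trial_index: int
    object_id: int
    object_angle: int
    plate_angle: int
    condition: str


def enumerate_design(n_objects: int = 4, n_object_angles: int = 4,
                     n_plate_angles: int = 4) -> list[DesignTrial]:
    """Full factorial over objects and the two rotation factors.

    At the defaults this is the 4 x 4 x 4 = 64-trial session of the
    protocol; each relative-rotation condition appears 16 times.
    """
    if n_objects < 1 or n_object_angles < 1 or n_plate_angles < 1:
        raise ValueError("all factor counts must be >= 1")
    if n_object_angles > 4 or n_plate_angles > 4:
        raise ValueError("at most 4 rotation angles exist")
    trials = []
    idx = 1
    for obj in range(1, n_objects + 1):
        for oa in _ANGLES[:n_object_angles]:
            for pa in _ANGLES[:n_plate_angles]:
                trials.append(DesignTrial(
                    trial_index=idx, object_id=obj,
                    object_angle=oa, plate_angle=pa,
                    condition=assign_condition(oa, pa),
                ))
                idx += 1
    return trials


def randomize_sequence(design: list[DesignTrial], seed) -> list[DesignTrial]:
    """Shuffle by assigning each trial an independent uniform(0,1) key and
    sorting — the spreadsheet randomization scheme. ``seed`` may be an int
    or a numpy Generator. Trial indices are reassigned 1..n in the new
    order."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keys = rng.random(len(design))
    order = np.argsort(keys, kind="stable")
    return [replace(design[i], trial_index=rank + 1)
            for rank, i in enumerate(order)]


# --------------------------------------------------------------------------
# object geometry

# Four planar pentomino arrangements, pairwise non-congruent under 90-degree
# rotations; coordinates are unit-cube centres on the table plane.
_SHAPES = {
    1: [(0, 0), (1, 0), (0, 1), (1, 1), (0, 2)],          # P
    2: [(0, 0), (1, 0), (2, 0), (1, 1), (1, 2)],          # T
    3: [(0, 0), (2, 0), (0, 1), (1, 1), (2, 1)],          # U
    4: [(0, 0), (0, 1), (0, 2), (0, 3), (1, 0)],          # L
}


@dataclass(frozen=True)
class ObjectShape:
    """One graspable object: five coplanar unit cubes plus the tracker cube."""

    object_id: int
    cells: np.ndarray        # (5, 3) cube centres, cm; z = 0.5 (on the table)
    tracker_cell: np.ndarray  # (3,) centre of the marker cube on top

    @property
    def volume_cm3(self) -> float:
        """Graspable volume: number of 1 cm^3 cubes (tracker cube excluded)."""
        return float(len(self.cells))


def make_object_shape(object_id: int) -> ObjectShape:
    """Build one of the four object geometries.

    The tracker cube sits directly on top of the cube nearest the shape's
    centroid, leaving the graspable structure unchanged.
    """
    if object_id not in _SHAPES:
        raise ValueError(f"object_id must be 1..4, got {object_id}")
    xy = np.asarray(_SHAPES[object_id], float)
    cells = np.column_stack([xy, np.full(len(xy), 0.5)])
    centroid = cells[:, :2].mean(axis=0)
    host = cells[np.argmin(np.linalg.norm(cells[:, :2] - centroid, axis=1))]
    tracker = np.array([host[0], host[1], host[2] + 1.0])
    return ObjectShape(object_id=object_id, cells=cells, tracker_cell=tracker)


# --------------------------------------------------------------------------
# single-trial simulation


@dataclass(frozen=True)
class TrialScenario:
    """Planted event frames plus the geometry of one synthetic trial."""

    t1: int = 500
    t2: int = 700
    t3: int = 900
    t4: int = 1200
    t5: int = 2100
    sampling_rate: float = 250.0
    noise_sigma_cm: float = 0.001
    seed: int = 0
    duration_frames: int | None = None   # default: t5 + 400
    # hand/reach geometry
    start_pos: tuple = (0.0, 0.0, 2.0)   # wrist point on the start cylinder
    transport_length: float = 28.0       # cm, straight-line reach
    transport_rise: float = 4.0          # vertical component of the reach
    reach_duration_s: float | None = None  # default: (t4 - t2)/fs - 0.1
    hand_above_object: float = 2.0
    # object transport
    lift_height: float = 2.0
    plate_offset: tuple = (-5.0, 25.0, 0.0)
    # occlusion glasses
    glasses_closed: float = 2.0          # D1, cm
    glasses_open: float = 10.0           # D2, cm
    glasses_ramp_frames: int = 60
    # grasp aperture
    aperture_baseline: float = 2.0
    release_peak: float = 6.0            # cm, first (release) bump apex
    grasp_peak: float = 8.0              # cm, second (grasp) bump apex = MGA
    aperture_sigma_frames: float = 25.0
    release_offset_frames: int = 80      # release apex at t2 + offset

    def __post_init__(self) -> None:
        frames = (self.t1, self.t2, self.t3, self.t4, self.t5)
        if any(f <= 0 for f in frames) or any(
                b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError(f"planted frames must be strictly increasing: {frames}")
        if self.n_frames <= self.t5 + 100:
            raise ValueError("trial too short after the placement event")
        geom = (self.transport_length, self.lift_height, self.glasses_closed,
                self.glasses_open, self.grasp_peak)
        if not all(np.isfinite(geom)):
            raise ValueError("geometry must be finite")
        if self.glasses_open <= self.glasses_closed:
            raise ValueError("open glasses distance must exceed closed distance")
        if self.transport_rise >= self.transport_length:
            raise ValueError("vertical rise cannot exceed transport length")

    @property
    def n_frames(self) -> int:
        return self.duration_frames if self.duration_frames is not None else self.t5 + 400

    @property
    def reach_frames(self) -> int:
        if self.reach_duration_s is not None:
            return int(round(self.reach_duration_s * self.sampling_rate))
        return max(100, (self.t4 - self.t2) - int(0.1 * self.sampling_rate))


def _minjerk(n_steps: int) -> np.ndarray:
    """Minimum-jerk position profile s(tau), 0 -> 1 over n_steps+1 samples."""
    tau = np.linspace(0.0, 1.0, n_steps + 1)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _ramp_cos(n_steps: int) -> np.ndarray:
    tau = np.linspace(0.0, 1.0, n_steps + 1)
    return 0.5 * (1 - np.cos(np.pi * tau))


def _segment_profile(n: int, start: int, n_steps: int, profile) -> np.ndarray:
    """0 before `start`, the profile over [start, start+n_steps], 1 after."""
    out = np.zeros(n)
    a = max(0, start)
    b = min(n - 1, start + n_steps)
    if b <= a:
        out[a:] = 1.0
        return out
    prof = profile(n_steps)
    out[a : b + 1] = prof[a - start : b - start + 1]
    out[b + 1 :] = 1.0
    return out


class _ChannelBuilder:
    """Noiseless channel construction with per-channel frame shifts.

    The shifts are what calibration adjusts so that each detector fires at
    the planted frame on the noiseless pipeline.
    """

    def __init__(self, scn: TrialScenario):
        self.scn = scn
        n = scn.n_frames
        self.n = n
        # geometry endpoints
        rise = scn.transport_rise
        horiz = np.sqrt(scn.transport_length**2 - rise**2)
        self.start = np.asarray(scn.start_pos, float)
        self.obj_rest = self.start + np.array([horiz / np.sqrt(2), horiz / np.sqrt(2), rise - scn.hand_above_object])
        self.hand_at_obj = self.obj_rest + np.array([0.0, 0.0, scn.hand_above_object])
        self.plate = self.obj_rest + np.asarray(scn.plate_offset, float)

    # ---- glasses
    def glasses_distance(self, shift: int) -> np.ndarray:
        scn = self.scn
        R = scn.glasses_ramp_frames
        # initial guess puts the near-complete part of the ramp at t1;
        # calibration then moves it by `shift`
        u99 = np.arccos(1 - 2 * 0.99) / np.pi
        start = int(round(scn.t1 - u99 * R)) + shift
        prof = _segment_profile(self.n, start, R, _ramp_cos)
        return scn.glasses_closed + (scn.glasses_open - scn.glasses_closed) * prof

    # ---- hand point (wrist virtual point and thumb-index midpoint follow it)
    def hand(self, reach_shift: int, obj_shifts: tuple) -> np.ndarray:
        scn = self.scn
        nreach = scn.reach_frames
        m0 = scn.t2 - int(round(0.03 * nreach)) + reach_shift
        prof = _segment_profile(self.n, m0, nreach, _minjerk)
        H = self.start[None, :] + prof[:, None] * (self.hand_at_obj - self.start)[None, :]
        # after the grasp the hand rides with the object
        O = self.object_pos(obj_shifts)
        carried = O + np.array([0.0, 0.0, scn.hand_above_object])
        o0 = self._o0(obj_shifts)
        H[o0:] = carried[o0:]
        return H

    # ---- object
    def _o0(self, obj_shifts: tuple) -> int:
        start_shift, _ = obj_shifts
        return self.scn.t4 - 8 + start_shift

    def _o1(self, obj_shifts: tuple) -> int:
        _, end_shift = obj_shifts
        return self.scn.t5 + 8 + end_shift

    def object_pos(self, obj_shifts: tuple) -> np.ndarray:
        """Rest, lift, carry, place. The vertical profile is a brisk
        minimum-jerk lift followed by a steady linear descent ending in an
        abrupt contact stop — the sharp velocity transitions at lift-off
        and touchdown are what make the 0.01 cm/s crossings well defined
        against sensor noise, and no stretch of the transport is
        stationary long enough to fake the 75-frame placement test."""
        scn = self.scn
        o0, o1 = self._o0(obj_shifts), self._o1(obj_shifts)
        up = min(150, max(20, (o1 - o0) // 3))
        horiz_prof = _segment_profile(self.n, o0, o1 - o0, _minjerk)
        O = self.obj_rest[None, :] + horiz_prof[:, None] * (self.plate - self.obj_rest)[None, :]
        O[:, 2] = self.obj_rest[2]
        rise = scn.lift_height * _segment_profile(self.n, o0, up, _minjerk)
        fall = scn.lift_height * _segment_profile(self.n, o0 + up, o1 - o0 - up,
                                                  lambda k: np.linspace(0.0, 1.0, k + 1))
        O[:, 2] += rise - fall
        return O

    # ---- aperture
    def aperture(self, grasp_shift: int) -> np.ndarray:
        scn = self.scn
        t = np.arange(self.n, dtype=float)
        s = scn.aperture_sigma_frames
        c1 = scn.t2 + scn.release_offset_frames
        c2 = scn.t3 + grasp_shift
        base = scn.aperture_baseline
        a = base
        a = a + (scn.release_peak - base) * np.exp(-0.5 * ((t - c1) / s) ** 2)
        a = a + (scn.grasp_peak - base) * np.exp(-0.5 * ((t - c2) / s) ** 2)
        return a


def _calibrate(builder: _ChannelBuilder, cfg: DetectionConfig) -> dict:
    """Align every noiseless channel so the detectors fire on the planted
    frames. Two fixed-point iterations suffice because each shift is a pure
    time translation of its channel."""
    scn = builder.scn
    fs = scn.sampling_rate
    shifts = {"glasses": 0, "reach": 0, "grasp": 0, "obj": (0, 0)}
    w = cfg.smooth_window

    def _sig(x):
        return smooth_gaussian(Signal1D(x, fs, unit="cm"), w)

    for _ in range(3):
        d = _sig(builder.glasses_distance(shifts["glasses"]))
        f1 = ev.detect_t1(d, cfg)
        shifts["glasses"] += scn.t1 - f1

        H = builder.hand(shifts["reach"], shifts["obj"])
        vz = velocity(_sig(H[:, 2]))
        f2, flag = ev.detect_t2(vz, scn.t1, cfg)
        if f2 is None:
            raise ValueError(f"infeasible scenario: wrist onset undetectable ({flag})")
        shifts["reach"] += scn.t2 - f2

        ap = _sig(builder.aperture(shifts["grasp"]))
        f3, flag = ev.detect_t3(ap, scn.t1, cfg)
        if f3 is None:
            raise ValueError(f"infeasible scenario: aperture peaks undetectable ({flag})")
        shifts["grasp"] += scn.t3 - f3

        vo = velocity(_sig(builder.object_pos(shifts["obj"])[:, 2]))
        f4, flag = ev.detect_t4(vo, scn.t3, cfg)
        if f4 is None:
            raise ValueError(f"infeasible scenario: object lift undetectable ({flag})")
        s0, s1 = shifts["obj"]
        s0 += scn.t4 - f4
        vo = velocity(_sig(builder.object_pos((s0, s1))[:, 2]))
        f5, flag = ev.detect_t5(vo, scn.t4, cfg)
        if f5 is None:
            raise ValueError(f"infeasible scenario: placement undetectable ({flag})")
        s1 += scn.t5 - f5
        shifts["obj"] = (s0, s1)
    return shifts


def simulate_trial(scenario: TrialScenario, meta: TrialMeta | None = None,
                   cfg: DetectionConfig | None = None) -> TrialRecording:
    """Generate one seven-marker recording for a scenario.

    Deterministic in (scenario, scenario.seed). The returned recording uses
    the identity layout (roles as labels). ``meta`` defaults to a
    placeholder single trial.
    """
    cfg = cfg or DetectionConfig()
    b = _ChannelBuilder(scenario)
    shifts = _calibrate(b, cfg)
    n = b.n

    d = b.glasses_distance(shifts["glasses"])
    H = b.hand(shifts["reach"], shifts["obj"])
    O = b.object_pos(shifts["obj"])
    ap = b.aperture(shifts["grasp"])

    markers = np.empty((n, 7, 3))
    e_ap = np.array([1.0, -1.0, 0.0]) / np.sqrt(2)  # aperture axis
    hand_off = np.array([0.0, 3.0, -1.5])           # fingers relative to wrist
    A = H + hand_off
    markers[:, 0] = A + 0.5 * ap[:, None] * e_ap            # thumb
    markers[:, 1] = A - 0.5 * ap[:, None] * e_ap            # index
    markers[:, 2] = H + np.array([1.5, 0.0, -1.0])          # wrist_radial
    markers[:, 3] = H + np.array([-1.5, 0.0, -1.0])         # wrist_ulnar
    markers[:, 4] = O + np.array([0.0, 0.0, 1.5])           # object tracker cube
    frame_pos = np.array([-15.0, -25.0, 35.0])
    markers[:, 5] = frame_pos                                # glasses_frame
    markers[:, 6] = frame_pos + np.array([0.0, 0.0, 0.0])
    markers[:, 6, 0] += d                                    # glasses_lens

    rng = np.random.default_rng(scenario.seed)
    if scenario.noise_sigma_cm > 0:
        markers = markers + rng.normal(0.0, scenario.noise_sigma_cm, markers.shape)

    meta = meta or TrialMeta("sim", 1, 1, 0, 0)
    return TrialRecording(
        positions=markers,
        sampling_rate=scenario.sampling_rate,
        marker_labels=list(ROLES),
        layout=TrackerLayout.default(),
        meta=meta,
    )


# --------------------------------------------------------------------------
# dataset simulation with planted condition effects


@dataclass(frozen=True)
class ParamEffect:
    """Normal model for one planted gap: per-condition mean = base +
    shift[condition] + participant offset (between_sd) + trial noise
    (within_sd)."""

    base: float
    shifts: tuple = (0.0, 0.0, 0.0, 0.0)
    within_sd: float = 0.0
    between_sd: float = 0.0

    def draw(self, cond: str, subj_offset: float, rng) -> float:
        i = CONDITIONS.index(cond)
        return self.base + self.shifts[i] + subj_offset + rng.normal(0.0, self.within_sd)


@dataclass(frozen=True)
class EffectSpec:
    """Planted condition effects, mirroring the study's qualitative result:
    rotated conditions (N2-N4) are slower and travel farther than the
    congruent condition N1."""

    initiation: ParamEffect = ParamEffect(0.8, (0.0, 0.15, 0.15, 0.15), 0.10, 0.05)
    aperture_gap: ParamEffect = ParamEffect(0.8, (0.0, 0.10, 0.05, 0.10), 0.08, 0.04)
    reaching: ParamEffect = ParamEffect(2.0, (0.0, 0.20, 0.10, 0.20), 0.15, 0.08)
    placement: ParamEffect = ParamEffect(1.5, (0.0, 0.20, 0.20, 0.30), 0.15, 0.08)
    transport_length: ParamEffect = ParamEffect(28.0, (0.0, 2.0, 1.0, 2.0), 1.0, 0.5)
    noise_sigma_cm: float = 0.001
    drift_per_trial_s: float = 0.0  # linear total-time learning drift, s/trial

    @classmethod
    def null(cls) -> "EffectSpec":
        """No condition effect anywhere (for type-I calibration)."""
        z = (0.0, 0.0, 0.0, 0.0)
        return cls(
            initiation=ParamEffect(0.8, z, 0.10, 0.05),
            aperture_gap=ParamEffect(0.8, z, 0.08, 0.04),
            reaching=ParamEffect(2.0, z, 0.15, 0.08),
            placement=ParamEffect(1.5, z, 0.15, 0.08),
            transport_length=ParamEffect(28.0, z, 1.0, 0.5),
        )


_GAPS = ("initiation", "aperture_gap", "reaching", "placement", "transport_length")


def _scenario_for(design: DesignTrial, effect: EffectSpec, offsets: dict,
                  rng, seed: int, fs: float = 250.0) -> tuple[TrialScenario, dict]:
    g_init = max(0.3, effect.initiation.draw(design.condition, offsets["initiation"], rng))
    g_reach = max(1.0, effect.reaching.draw(design.condition, offsets["reaching"], rng))
    g_ap = effect.aperture_gap.draw(design.condition, offsets["aperture_gap"], rng)
    g_ap = min(max(0.6, g_ap), g_reach - 0.3)
    g_place = max(1.2, effect.placement.draw(design.condition, offsets["placement"], rng))
    g_place += effect.drift_per_trial_s * (design.trial_index - 1)
    length = max(15.0, effect.transport_length.draw(
        design.condition, offsets["transport_length"], rng))

    t1 = 500
    t2 = t1 + int(round(g_init * fs))
    t3 = t2 + int(round(g_ap * fs))
    t4 = t2 + int(round(g_reach * fs))
    t5 = t4 + int(round(g_place * fs))
    scn = TrialScenario(
        t1=t1, t2=t2, t3=t3, t4=t4, t5=t5, sampling_rate=fs,
        noise_sigma_cm=effect.noise_sigma_cm, seed=seed,
        transport_length=length,
    )
    truth = {
        "initiation_time": (t2 - t1) / fs,
        "time_to_max_aperture": (t3 - t2) / fs,
        "reaching_time": (t4 - t2) / fs,
        "placement_time": (t5 - t4) / fs,
        "total_time": (t5 - t1) / fs,
        "wrist_path_cm": length,
        "t1_frame": t1, "t2_frame": t2, "t3_frame": t3,
        "t4_frame": t4, "t5_frame": t5,
    }
    return scn, truth


def iter_trials(n_participants: int = 21, effect: EffectSpec | None = None,
                seed: int = 0, cfg: DetectionConfig | None = None):
    """Stream (recording, ground-truth row) pairs for a whole experiment.

    Memory-friendly alternative to :func:`simulate_dataset`: recordings are
    produced one at a time (a full 21-participant session is ~0.7 GB if
    materialized at once).
    """
    effect = effect or EffectSpec()
    cfg = cfg or DetectionConfig()
    root = np.random.SeedSequence(seed)
    part_seqs = root.spawn(n_participants)
    for p, pseq in enumerate(part_seqs, start=1):
        pid = f"P{p:02d}"
        rng = np.random.default_rng(pseq)
        design = randomize_sequence(enumerate_design(), rng)
        offsets = {g: rng.normal(0.0, getattr(effect, g).between_sd) for g in _GAPS}
        for trial in design:
            trial_seed = int(rng.integers(0, 2**31 - 1))
            scn, truth = _scenario_for(trial, effect, offsets, rng, trial_seed)
            meta = TrialMeta(pid, trial.trial_index, trial.object_id,
                             trial.object_angle, trial.plate_angle)
            rec = simulate_trial(scn, meta=meta, cfg=cfg)
            row = {
                "participant_id": pid, "trial_index": trial.trial_index,
                "object_id": trial.object_id,
                "object_angle": trial.object_angle,
                "plate_angle": trial.plate_angle,
                "condition": trial.condition, **truth,
            }
            yield rec, row


def simulate_dataset(n_participants: int = 21, effect: EffectSpec | None = None,
                     seed: int = 0, cfg: DetectionConfig | None = None):
    """Materialize a whole synthetic experiment.

    Returns (Dataset, ground-truth DataFrame) with one row per trial
    (n_participants x 64 rows). For large experiments prefer
    :func:`iter_trials`.
    """
    import pandas as pd

    recs, rows = [], []
    for rec, row in iter_trials(n_participants, effect, seed, cfg):
        recs.append(rec)
        rows.append(row)
    return Dataset(recs), pd.DataFrame(rows)
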