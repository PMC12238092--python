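"""Detection of the five kinematic reference points of a grasp-and-place trial.

Each trial is delimited by five events:

* **T1** — occlusion-glasses opening: attainment of the maximal distance
  between the glasses-frame and lens-cover markers (the opened state),
  which timestamps the participant's first visual access to the scene.
* **T2** — wrist lift: the first time after T1 that the wrist vertical
  velocity exceeds 0.05 cm/s and stays above it for 20 consecutive frames.
  The wrist is the virtual midpoint of the radial/ulnar styloid markers.
* **T3** — maximum grasp aperture: the *second* significant peak of the
  thumb-index distance after T1. Two aperture cycles occur per trial —
  release of the start cylinder, then preshaping for the object grasp —
  so the grasp-relevant maximum is the second peak.
* **T4** — object lift: first time after T3 that the object's vertical
  velocity exceeds 0.01 cm/s for 20 consecutive frames.
* **T5** — object placement: first time after T4 that the object's
  vertical speed drops below 0.01 cm/s and averages under 0.05 cm/s over
  the following 75 frames (stable placement).

All detectors run on Gaussian-smoothed signals (smooth-then-detect) and use
strict > / < comparisons. Detection failure is reported through per-event
quality flags, never exceptions, and a failed event marks every downstream
event as not-found.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .kinematics import Signal1D, midpoint_trajectory, pair_distance, smooth_gaussian, velocity

__all__ = [
    "DetectionConfig",
    "EventTimes",
    "EVENT_NAMES",
    "NoOpeningError",
    "detect_t1",
    "detect_t2",
    "detect_t3",
    "detect_t4",
    "detect_t5",
    "segment_trial",
]

EVENT_NAMES = ("t1", "t2", "t3", "t4", "t5")

FOUND = "found"
NOT_FOUND = "not-found"
NAN_WINDOW = "nan-window"
DEGRADED = "degraded"  # event usable but from a fallback rule
ORDER_VIOLATION = "order-violation"


class NoOpeningError(ValueError):
    """The glasses-distance signal shows no opening excursion."""


@dataclass(frozen=True)
class DetectionConfig:
    """Every threshold and window the detectors use.

    The velocity thresholds, sustain counts and the placement window carry
    the published values of the protocol; the peak-prominence fraction, the
    T1 plateau fraction and the minimum opening excursion parameterize
    rules the protocol leaves qualitative ("significant peak", "maximum
    distance").
    """

    wrist_v_thresh: float = 0.05        # cm/s, wrist lift onset
    wrist_sustain: int = 20             # frames the wrist rule must hold
    object_lift_v_thresh: float = 0.01  # cm/s, object lift onset
    object_sustain: int = 20            # frames the object rule must hold
    place_v_thresh: float = 0.01        # cm/s, instantaneous placement test
    place_mean_thresh: float = 0.05     # cm/s, mean-speed placement test
    place_window: int = 75              # frames of the placement mean
    aperture_peak_prominence_frac: float = 0.10  # of post-T1 aperture range
    t1_plateau_frac: float = 0.99       # fraction of max glasses distance
    t1_min_excursion: float = 0.5       # cm, below which "no opening"
    smooth_window: int = 30             # samples, Gaussian moving average
    t1_mode: str = "plateau"            # "plateau" | "velocity"
    wrist_path_markers: str = "thumb_index"  # "thumb_index" | "wrist"

    def __post_init__(self) -> None:
        positive = (
            "wrist_v_thresh", "object_lift_v_thresh", "place_v_thresh",
            "place_mean_thresh", "t1_min_excursion",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("wrist_sustain", "object_sustain", "place_window", "smooth_window"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("aperture_peak_prominence_frac", "t1_plateau_frac"):
            if not (0 < getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.t1_mode not in ("plateau", "velocity"):
            raise ValueError("t1_mode must be 'plateau' or 'velocity'")
        if self.wrist_path_markers not in ("thumb_index", "wrist"):
            raise ValueError("wrist_path_markers must be 'thumb_index' or 'wrist'")


@dataclass
class EventTimes:
    """The five reference points of one trial.

    Frames are indices into the recording; seconds are frame / rate. A
    missing event has frame ``None`` and a flag explaining why.
    """

    frames: dict = field(default_factory=dict)   # event -> int | None
    flags: dict = field(default_factory=dict)    # event -> status string
    sampling_rate: float = 250.0
    d_open_max: float | None = None              # cm, maximal glasses distance

    def frame(self, event: str):
        return self.frames.get(event)

    def seconds(self, event: str):
        f = self.frames.get(event)
        return None if f is None else f / self.sampling_rate

    def found(self, event: str) -> bool:
        return self.frames.get(event) is not None

    @property
    def all_found(self) -> bool:
        return all(self.found(e) for e in EVENT_NAMES)

    def as_row(self) -> dict:
        row: dict = {}
        for e in EVENT_NAMES:
            row[f"{e}_s"] = self.seconds(e)
            row[f"{e}_flag"] = self.flags.get(e, NOT_FOUND)
        row["d_open_max_cm"] = self.d_open_max
        return row


# --------------------------------------------------------------------------
# primitive run/threshold searches


def _first_sustained_run(values: np.ndarray, thresh: float, sustain: int,
                         after_frame: int):
    """First frame f > after_frame with values[f : f+sustain] all > thresh.

    Returns (frame, flag). NaN anywhere in the searched span aborts with a
    nan-window flag rather than detecting across occlusion.
    """
    start = after_frame + 1
    if start < 0 or start >= values.size:
        return None, NOT_FOUND
    seg = values[start:]
    above = seg > thresh
    runs = np.convolve(above.astype(int), np.ones(sustain, dtype=int), mode="valid")
    hits = np.flatnonzero(runs == sustain)
    if hits.size == 0:
        if np.isnan(seg).any():
            return None, NAN_WINDOW
        return None, NOT_FOUND
    f = start + int(hits[0])
    if np.isnan(values[start : f + sustain]).any():
        return None, NAN_WINDOW
    return f, FOUND


def detect_t1(glasses_distance: Signal1D, cfg: DetectionConfig) -> int:
    """Glasses-opening frame from the (smoothed) frame-lens distance.

    Default rule: first frame at which the distance attains
    ``t1_plateau_frac`` of its trial maximum, i.e. the attainment of the
    fully-open distance. The alternative ``velocity`` rule takes the first
    sustained positive-velocity frame of the opening instead.

    Raises :class:`NoOpeningError` when the signal's excursion is below
    ``t1_min_excursion`` (glasses never opened).
    """
    d = glasses_distance.values
    if np.isnan(d).all():
        raise NoOpeningError("glasses signal is entirely NaN")
    rng = np.nanmax(d) - np.nanmin(d)
    if rng < cfg.t1_min_excursion:
        raise NoOpeningError(
            f"glasses distance excursion {rng:.3g} cm < {cfg.t1_min_excursion} cm"
        )
    if cfg.t1_mode == "velocity":
        v = np.gradient(d) * glasses_distance.sampling_rate
        # require the distance to have left the closed plateau
        open_enough = d > np.nanmin(d) + 0.1 * rng
        cand = (v > 0) & open_enough
        runs = np.convolve(cand.astype(int), np.ones(5, dtype=int), "valid")
        hits = np.flatnonzero(runs == 5)
        if hits.size == 0:
            raise NoOpeningError("no sustained positive opening velocity")
        return int(hits[0])
    thresh = cfg.t1_plateau_frac * np.nanmax(d)
    hits = np.flatnonzero(d >= thresh)
    return int(hits[0])


def detect_t2(wrist_vertical_velocity: Signal1D, after_frame: int,
              cfg: DetectionConfig):
    """Wrist-lift frame: sustained-run rule on the signed vertical velocity
    (positive up). Returns (frame | None, flag)."""
    return _first_sustained_run(
        wrist_vertical_velocity.values, cfg.wrist_v_thresh, cfg.wrist_sustain,
        after_frame,
    )


def detect_t3(aperture: Signal1D, after_frame: int, cfg: DetectionConfig):
    """Maximum-grasp-aperture frame: second significant peak after T1.

    Significance = topographic prominence of at least
    ``aperture_peak_prominence_frac`` x (range of the post-T1 aperture).
    A single significant peak is returned with a degraded flag; zero peaks
    give a no-peak result.
    """
    start = after_frame + 1
    a = aperture.values[start:]
    if a.size < 3:
        return None, NOT_FOUND
    if np.isnan(a).any():
        return None, NAN_WINDOW
    rng = float(a.max() - a.min())
    if rng <= 0:
        return None, NOT_FOUND
    peaks, _ = find_peaks(a, prominence=cfg.aperture_peak_prominence_frac * rng)
    if peaks.size == 0:
        return None, NOT_FOUND
    if peaks.size == 1:
        return start + int(peaks[0]), DEGRADED
    return start + int(peaks[1]), FOUND


def detect_t4(object_vertical_velocity: Signal1D, after_frame: int,
              cfg: DetectionConfig):
    """Object-lift frame: sustained-run rule on the object's signed
    vertical velocity with the object thresholds."""
    return _first_sustained_run(
        object_vertical_velocity.values, cfg.object_lift_v_thresh,
        cfg.object_sustain, after_frame,
    )


def detect_t5(object_vertical_velocity: Signal1D, after_frame: int,
              cfg: DetectionConfig):
    """Stable-placement frame.

    First frame f > after_frame with |v[f]| below the instantaneous
    threshold AND mean |v| over the next ``place_window`` frames below the
    mean threshold. The absolute value penalizes residual motion in either
    vertical direction.
    """
    v = np.abs(object_vertical_velocity.values)
    start = after_frame + 1
    w = cfg.place_window
    if start < 0 or start + w > v.size:
        return None, NOT_FOUND
    means = np.convolve(v, np.ones(w) / w, mode="valid")  # means[f] over [f, f+w)
    n_valid = means.size
    cand = (
        (v[:n_valid] < cfg.place_v_thresh)
        & (means < cfg.place_mean_thresh)
    )
    cand[: start] = False
    hits = np.flatnonzero(cand)
    if hits.size == 0:
        if np.isnan(v[start:]).any():
            return None, NAN_WINDOW
        return None, NOT_FOUND
    f = int(hits[0])
    if np.isnan(v[f : f + w]).any():
        return None, NAN_WINDOW
    return f, FOUND


# --------------------------------------------------------------------------
# whole-trial segmentation


def build_signals(recording, cfg: DetectionConfig) -> dict:
    """Construct the four smoothed analysis signals of a trial."""
    w = cfg.smooth_window
    glasses = smooth_gaussian(pair_distance(recording, "glasses_frame", "glasses_lens"), w)
    wrist = smooth_gaussian(midpoint_trajectory(recording, "wrist_radial", "wrist_ulnar"), w)
    wrist_z = Signal1D(wrist.positions[:, 2], recording.sampling_rate, unit="cm")
    aperture = smooth_gaussian(pair_distance(recording, "thumb", "index"), w)
    obj_z = smooth_gaussian(
        Signal1D(recording.positions_for("object")[:, 2], recording.sampling_rate, unit="cm"),
        w,
    )
    return {
        "glasses": glasses,
        "wrist_v": velocity(wrist_z),
        "aperture": aperture,
        "object_v": velocity(obj_z),
    }


def segment_trial(recording, cfg: DetectionConfig | None = None) -> EventTimes:
    """Detect T1..T5 on one recording.

    The detectors are chained (each searches after the previous event) and
    strict ordering is enforced; any failure marks the event and everything
    downstream as not-found. Never raises on detection failure.
    """
    cfg = cfg or DetectionConfig()
    sig = build_signals(recording, cfg)
    ev = EventTimes(sampling_rate=recording.sampling_rate)

    def _fail_from(event: str, flag: str) -> EventTimes:
        ev.frames[event] = None
        ev.flags[event] = flag
        idx = EVENT_NAMES.index(event)
        for later in EVENT_NAMES[idx + 1 :]:
            ev.frames[later] = None
            ev.flags[later] = NOT_FOUND
        return ev

    try:
        t1 = detect_t1(sig["glasses"], cfg)
    except NoOpeningError:
        return _fail_from("t1", NOT_FOUND)
    ev.frames["t1"] = t1
    ev.flags["t1"] = FOUND
    ev.d_open_max = float(np.nanmax(sig["glasses"].values))

    t2, flag = detect_t2(sig["wrist_v"], t1, cfg)
    if t2 is None:
        return _fail_from("t2", flag)
    ev.frames["t2"], ev.flags["t2"] = t2, flag

    t3, flag = detect_t3(sig["aperture"], t1, cfg)
    if t3 is None:
        return _fail_from("t3", flag)
    if t3 <= t2:
        return _fail_from("t3", ORDER_VIOLATION)
    ev.frames["t3"], ev.flags["t3"] = t3, flag

    t4, flag = detect_t4(sig["object_v"], t3, cfg)
    if t4 is None:
        return _fail_from("t4", flag)
    ev.frames["t4"], ev.flags["t4"] = t4, flag

    t5, flag = detect_t5(sig["object_v"], t4, cfg)
    if t5 is None:
        return _fail_from("t5", flag)
    ev.frames["t5"], ev.flags["t5"] = t5, flag
    return ev
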