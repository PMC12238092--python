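"""Signal construction for grasp-and-place trials.

Everything downstream of raw marker positions is built here: Gaussian
smoothing, numerical differentiation, virtual markers (midpoints and
inter-marker distances) and path length. All positions are in centimetres,
all rates in Hz, so velocities come out in cm/s — the unit the detection
thresholds are expressed in.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Signal1D",
    "Trajectory3D",
    "smooth_gaussian",
    "velocity",
    "pair_distance",
    "midpoint_trajectory",
    "path_length",
]


@dataclass(frozen=True)
class Signal1D:
    """A per-frame scalar signal with an explicit unit tag.

    Parameters
    ----------
    values : ndarray, shape (n,)
        One sample per frame. NaN marks occluded/invalid samples.
    sampling_rate : float
        Frames per second, > 0.
    unit : str
        ``"cm"`` for positional signals, ``"cm/s"`` for velocities.
    origin : int
        Frame index of ``values[0]`` in the parent recording.
    """

    values: np.ndarray
    sampling_rate: float
    unit: str
    origin: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("Signal1D needs a 1-D array of length >= 2")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if not self.unit:
            raise ValueError("unit tag is required")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class Trajectory3D:
    """A per-frame 3D position trace in centimetres."""

    positions: np.ndarray  # (n, 3)
    sampling_rate: float
    origin: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 2:
            raise ValueError("Trajectory3D needs an (n, 3) array with n >= 2")
        object.__setattr__(self, "positions", p)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")

    def __len__(self) -> int:
        return self.positions.shape[0]


def gaussian_kernel(window_frames: int, sigma: float | None = None) -> np.ndarray:
    """Normalized Gaussian weights over a centred window.

    ``sigma`` defaults to ``window_frames / 5`` so that the window spans
    +-2.5 standard deviations, the usual convention for window-length
    parameterized Gaussian moving averages.
    """
    if window_frames < 1:
        raise ValueError("window_frames must be >= 1")
    if sigma is None:
        sigma = window_frames / 5.0
    offsets = np.arange(window_frames, dtype=float) - (window_frames - 1) / 2.0
    k = np.exp(-0.5 * (offsets / sigma) ** 2)
    return k / k.sum()


def _smooth_values(x: np.ndarray, window_frames: int, sigma: float | None) -> np.ndarray:
    k = gaussian_kernel(window_frames, sigma)
    num = np.convolve(x, k, mode="same")
    # Dividing by the convolved window mass renormalizes the shrunken edge
    # windows, so constants are preserved exactly everywhere.
    den = np.convolve(np.ones_like(x), k, mode="same")
    return num / den


def smooth_gaussian(signal, window_frames: int = 30, sigma: float | None = None):
    """Gaussian-weighted moving average (window given in samples).

    Mirrors a window-length-30 Gaussian moving-average filter applied to the
    raw marker data before any event detection. At the edges the window
    shrinks and the remaining weights are renormalized; NaN samples
    propagate to every output sample whose window touches them, so occluded
    stretches stay visibly occluded instead of being silently inpainted.
    """
    if isinstance(signal, Signal1D):
        if window_frames > len(signal):
            raise ValueError("smoothing window longer than signal")
        return replace(signal, values=_smooth_values(signal.values, window_frames, sigma))
    if isinstance(signal, Trajectory3D):
        if window_frames > len(signal):
            raise ValueError("smoothing window longer than trajectory")
        cols = [_smooth_values(signal.positions[:, j], window_frames, sigma) for j in range(3)]
        return replace(signal, positions=np.column_stack(cols))
    raise TypeError(f"cannot smooth object of type {type(signal).__name__}")


def velocity(signal: Signal1D) -> Signal1D:
    """Differentiate a positional signal: central differences in the
    interior, one-sided differences at the two ends (cm -> cm/s)."""
    if signal.unit != "cm":
        raise ValueError(f"velocity expects a positional signal in cm, got {signal.unit!r}")
    v = np.gradient(signal.values) * signal.sampling_rate
    return replace(signal, values=v, unit="cm/s")


def pair_distance(recording, role_a: str, role_b: str) -> Signal1D:
    """Per-frame Euclidean 3D distance between two marker roles (cm).

    Used for the grasp aperture (thumb-index) and the occlusion-glasses
    opening distance (frame-lens). NaN in either marker propagates.
    """
    pa = recording.positions_for(role_a)
    pb = recording.positions_for(role_b)
    d = np.linalg.norm(pa - pb, axis=1)
    return Signal1D(d, recording.sampling_rate, unit="cm")


def midpoint_trajectory(recording, role_a: str, role_b: str) -> Trajectory3D:
    """Virtual marker halfway between two roles (e.g. the wrist point
    between the radial and ulnar styloid markers)."""
    pa = recording.positions_for(role_a)
    pb = recording.positions_for(role_b)
    return Trajectory3D(0.5 * (pa + pb), recording.sampling_rate)


def path_length(trajectory: Trajectory3D, frame_start: int, frame_end: int) -> float:
    """Cumulative 3D arc length of a trajectory over [frame_start, frame_end].

    Raises
    ------
    ValueError
        If the frame range is invalid or contains NaN (occlusion must be
        filled or the trial flagged before a path length is meaningful).
    """
    n = len(trajectory)
    if not (0 <= frame_start < frame_end < n):
        raise ValueError(f"invalid frame range [{frame_start}, {frame_end}] for n={n}")
    seg = trajectory.positions[frame_start : frame_end + 1]
    if np.isnan(seg).any():
        raise ValueError("NaN inside path-length range; fill gaps first")
    steps = np.diff(seg, axis=0)
    return float(np.linalg.norm(steps, axis=1).sum())
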