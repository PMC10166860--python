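"""Shared containers and circular-statistics helpers.

Conventions used throughout the package (all angles in radians, times in
seconds):

* Anatomical frame: ``x_lr`` is the left-right axis with **left positive**,
  ``y_rc`` the rostro-caudal axis with **rostral positive**, ``z`` dorsal.
* Ring angle ``alpha``: caudal ROIs sit at 0, left at +pi/2, right at -pi/2,
  increasing clockwise when the horizontal plane is viewed from above.
* Behavioral sign: tail laterality > 0 means a rightward swim; integrated
  heading therefore grows with right turns while the network phase, which
  rotates clockwise for left swims, moves the opposite way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_angle(theta):
    """Wrap angle(s) to the interval (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    wrapped = np.pi - np.mod(np.pi - theta, TWO_PI)
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


def circular_distance(a, b):
    """Smallest signed angular difference a - b, in (-pi, pi]."""
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def circular_rmse(a, b):
    """Root-mean-square circular distance between two angle series."""
    d = np.atleast_1d(circular_distance(a, b))
    return float(np.sqrt(np.mean(d**2)))


def anatomical_angle(x_lr, y_rc):
    """Angle of an anatomical position under the caudal-zero convention.

    Caudal (negative ``y_rc``) maps to 0, left (positive ``x_lr``) to +pi/2,
    right to -pi/2 and rostral to pi.
    """
    return np.arctan2(np.asarray(x_lr, float), -np.asarray(y_rc, float))


@dataclass
class RawFluorescence:
    """Raw ROI fluorescence (ROIs x frames), as extracted upstream."""

    values: np.ndarray
    rate: float
    roi_ids: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.roi_ids = np.asarray(self.roi_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (ROIs x frames) array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fluorescence values must be finite")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate


@dataclass
class TraceMatrix:
    """Preprocessed (smoothed, z-scored dF/F) activity, ROIs x frames."""

    values: np.ndarray
    rate: float
    roi_ids: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.roi_ids = np.asarray(self.roi_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (ROIs x frames) array")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    def subset(self, roi_ids) -> "TraceMatrix":
        """Return a new matrix restricted to ``roi_ids`` (order preserved)."""
        index = {rid: k for k, rid in enumerate(self.roi_ids)}
        rows = [index[rid] for rid in roi_ids]
        return TraceMatrix(self.values[rows], self.rate, np.asarray(roi_ids))


@dataclass
class TailTrace:
    """Tail angle per frame (difference of mean first-two and last-two
    tail-segment angles, computed upstream)."""

    angle: np.ndarray
    rate: float = 400.0

    def __post_init__(self):
        self.angle = np.asarray(self.angle, dtype=float)
        if not np.all(np.isfinite(self.angle)):
            raise ValueError("tail angles must be finite")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.angle.size) / self.rate


@dataclass
class GazeTrace:
    """Gaze direction (mean of both eye angles) with detected saccade times."""

    angle: np.ndarray
    rate: float
    saccade_times: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        self.angle = np.asarray(self.angle, dtype=float)
        self.saccade_times = np.asarray(self.saccade_times, dtype=float)
        if not np.all(np.isfinite(self.angle)):
            raise ValueError("gaze angles must be finite")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.angle.size) / self.rate


@dataclass
class SwimEvent:
    """One swim bout: onset/offset, laterality index, and class.

    ``laterality`` is the mean tail angle over the first 70 ms of the bout
    (positive = rightward).  ``swim_class`` is one of ``left``, ``right``,
    ``forward`` or None before classification.
    """

    onset_s: float
    offset_s: float
    laterality: float = np.nan
    swim_class: str | None = None

    def __post_init__(self):
        if self.offset_s <= self.onset_s:
            raise ValueError("offset must follow onset")


@dataclass
class PhaseTrace:
    """Decoded network phase: wrapped to (-pi, pi], unwrapped, and the norm
    of the population vector (decoding confidence)."""

    wrapped: np.ndarray
    unwrapped: np.ndarray
    vector_norm: np.ndarray
    rate: float

    def __post_init__(self):
        self.wrapped = np.asarray(self.wrapped, dtype=float)
        self.unwrapped = np.asarray(self.unwrapped, dtype=float)
        self.vector_norm = np.asarray(self.vector_norm, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.wrapped.size) / self.rate


@dataclass
class HeadingTrace:
    """Integrated heading estimate: piecewise constant, one step per swim."""

    heading: np.ndarray
    rate: float

    def __post_init__(self):
        self.heading = np.asarray(self.heading, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.heading.size) / self.rate
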