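"""From raw inertial sensor traces to per-stride vertical-displacement features.

The processing chain mirrors standard practice for body-mounted inertial
sensors on trotting horses: tri-axial acceleration is rotated into a
gravity-aligned, horse-based frame, double-integrated to vertical
displacement with high-pass drift suppression, segmented into strides, and
reduced to the per-step extrema (minima, maxima, upward amplitudes) that the
movement-asymmetry indices are built from.

Conventions
-----------
* Horse frame: right-handed, x positive forward, z positive up (aligned with
  gravity), y positive to the left of the horse.
* Orientation channels are Euler angles in degrees, ordered (roll, pitch,
  yaw), applied yaw-pitch-roll with pitch positive nose-up; a sensor at zero
  angles has its axes aligned with the horse frame.
* Displacement is expressed in millimetres throughout; acceleration in m/s².
* A stride at trot contains two vertical oscillations of the midline
  landmarks (one per diagonal step) and one dominant oscillation of each
  tuber coxae.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

GRAVITY = 9.81  # m/s^2

MIDLINE_LANDMARKS = ("poll", "withers", "sacrum")
TUBER_COXAE_LANDMARKS = ("left_tuber_coxae", "right_tuber_coxae")
LANDMARKS = MIDLINE_LANDMARKS + TUBER_COXAE_LANDMARKS

#: default hard floor of retained strides per assessment condition; data
#: collection aims at 25-30 steady-state strides, medians remain stable
#: down to roughly half of that.
DEFAULT_MIN_STRIDES = 15

#: strides whose duration deviates from the running median by more than
#: this fraction are treated as non-steady-state and discarded.
DEFAULT_STRIDE_TIME_OUTLIER_FRAC = 0.25


@dataclass
class SensorTrace:
    """One landmark's synchronized time series from a body-mounted IMU.

    Parameters
    ----------
    landmark
        One of :data:`LANDMARKS`.
    time
        Sample times in seconds, uniformly spaced.
    acceleration
        ``(n, 3)`` sensor-frame acceleration in m/s² (specific force: a
        resting, level sensor reads ``(0, 0, +9.81)``).
    orientation
        ``(n, 3)`` Euler angles in degrees, ``(roll, pitch, yaw)``.
    sample_rate
        Sampling rate in Hz (nominally 100).
    truth
        Optional ground-truth side-car attached by the synthetic generator.
    meta
        Free-form provenance (generator parameters, seed, ...).
    """

    landmark: str
    time: np.ndarray
    acceleration: np.ndarray
    orientation: np.ndarray | None
    sample_rate: float
    truth: object | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.landmark not in LANDMARKS:
            raise ValueError(
                f"unknown landmark {self.landmark!r}; valid landmarks: "
                f"{', '.join(LANDMARKS)}"
            )
        self.time = np.asarray(self.time, dtype=float)
        self.acceleration = np.asarray(self.acceleration, dtype=float)
        if self.acceleration.ndim != 2 or self.acceleration.shape[1] != 3:
            raise ValueError("acceleration must have shape (n, 3)")
        if self.orientation is not None:
            self.orientation = np.asarray(self.orientation, dtype=float)
            if self.orientation.shape != self.acceleration.shape:
                raise ValueError("orientation must have the same shape as acceleration")
        n = len(self.time)
        if n != len(self.acceleration):
            raise ValueError("time and acceleration lengths differ")
        if n >= 3:
            dt = np.diff(self.time)
            if np.any(np.abs(dt - 1.0 / self.sample_rate) > 0.01 / self.sample_rate):
                raise ValueError(
                    "time channel is not uniformly sampled at the stated rate "
                    f"({self.sample_rate} Hz, tolerance 1%)"
                )

    @property
    def n_samples(self) -> int:
        return len(self.time)


@dataclass
class StrideSet:
    """Stride boundaries and timing from segmentation.

    ``boundaries`` holds half-open ``[start, end)`` sample-index pairs of the
    retained (steady-state) strides; ``stride_times`` their durations in ms.
    """

    boundaries: np.ndarray  # (k, 2) int
    stride_times: np.ndarray  # (k,) ms
    n_discarded: int
    period_s: float  # estimated stride period

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=int)
        if b.ndim != 2 or b.shape[1] != 2:
            raise ValueError("boundaries must have shape (k, 2)")
        if np.any(b[:, 1] <= b[:, 0]):
            raise ValueError("stride boundaries must satisfy start < end")
        if len(b) > 1 and np.any(b[1:, 0] < b[:-1, 1]):
            raise ValueError("stride boundaries must be non-overlapping and increasing")
        self.boundaries = b
        self.stride_times = np.asarray(self.stride_times, dtype=float)

    @property
    def n_strides(self) -> int:
        return len(self.boundaries)


def rotation_from_euler(orientation_deg: np.ndarray) -> Rotation:
    """Rotation mapping sensor-frame vectors into the horse frame.

    Euler angles are ``(roll, pitch, yaw)`` in degrees, composed
    yaw-pitch-roll, with pitch positive nose-up in the z-up horse frame (so a
    +90° pitch maps the sensor x axis onto world +z).
    """
    o = np.atleast_2d(np.asarray(orientation_deg, dtype=float))
    angles = np.column_stack([o[:, 2], -o[:, 1], o[:, 0]])
    return Rotation.from_euler("ZYX", angles, degrees=True)


def rotate_to_horse_frame(trace: SensorTrace) -> np.ndarray:
    """Gravity-aligned vertical acceleration with gravity removed, in m/s².

    Applies the per-sample rotation encoded by the orientation channel and
    returns the horse-frame z component minus g.  A trace without orientation
    cannot be rotated: supply orientation angles or assert that the data are
    already gravity-aligned by constructing the trace with zero angles.
    """
    if trace.orientation is None or not np.all(np.isfinite(trace.orientation)):
        raise ValueError(
            "orientation channel missing or non-finite: supply Euler angles, "
            "or pass zero angles to assert pre-aligned data"
        )
    rot = rotation_from_euler(trace.orientation)
    world = rot.apply(trace.acceleration)
    return world[:, 2] - GRAVITY


def _highpass(x: np.ndarray, cutoff_hz: float, fs: float) -> np.ndarray:
    sos = sps.butter(4, cutoff_hz, btype="highpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def integrate_to_displacement(
    acc_z: np.ndarray,
    sample_rate: float,
    stride_freq_hint: float,
) -> np.ndarray:
    """Double-integrate vertical acceleration to vertical displacement (mm).

    Drift is suppressed with a fourth-order zero-phase Butterworth high-pass
    (cutoff ``0.5 * stride_freq_hint``) applied to the acceleration and again
    to the velocity; the result is zero-mean over the record.  The cutoff
    sits half an octave below the stride frequency, well clear of the
    two-per-stride oscillation that carries the asymmetry information.

    Parameters
    ----------
    acc_z
        Gravity-free vertical acceleration, m/s².
    sample_rate
        Hz.
    stride_freq_hint
        Approximate stride frequency in Hz (strides per second); at trot
        typically 1.2-1.5.
    """
    acc_z = np.asarray(acc_z, dtype=float)
    bad = ~np.isfinite(acc_z)
    if bad.any():
        raise ValueError(f"non-finite acceleration sample at index {int(np.argmax(bad))}")
    if stride_freq_hint <= 0:
        raise ValueError("stride_freq_hint must be positive")
    if np.allclose(acc_z, acc_z[0] if len(acc_z) else 0.0):
        # constant acceleration carries no cyclic motion; integrates to zero
        # displacement after drift suppression
        return np.zeros_like(acc_z)
    dt = 1.0 / sample_rate
    cutoff = 0.5 * stride_freq_hint
    a = _highpass(acc_z, cutoff, sample_rate)
    v = cumulative_trapezoid(a, dx=dt, initial=0.0)
    v = _highpass(v, cutoff, sample_rate)
    d = cumulative_trapezoid(v, dx=dt, initial=0.0)
    # the second integration re-accumulates the sub-cutoff remnants of the
    # filtered velocity into a slow wander, so the displacement is
    # high-passed once more
    d = _highpass(d, cutoff, sample_rate)
    d = d - d.mean()
    return d * 1000.0


def estimate_step_period(x: np.ndarray, sample_rate: float,
                         min_period_s: float = 0.15,
                         max_period_s: float = 1.0) -> float:
    """Dominant cycle period of a periodic series via autocorrelation, in s.

    For midline displacement at trot this is the *step* period (half a
    stride).  Raises if no periodic structure is found.
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    if len(x) < 4 or np.std(x) < 1e-12:
        raise ValueError("no cyclic structure found (constant or empty signal)")
    ac = np.correlate(x, x, mode="full")[len(x) - 1:]
    ac = ac / ac[0]
    lo = max(2, int(min_period_s * sample_rate))
    hi = min(len(ac) - 1, int(max_period_s * sample_rate))
    if hi <= lo:
        raise ValueError("record too short to estimate a cycle period")
    peaks, props = sps.find_peaks(ac[lo:hi], height=0.25)
    if len(peaks) == 0:
        raise ValueError("no cyclic structure found (no autocorrelation peak)")
    return float((peaks[0] + lo) / sample_rate)


def segment_strides(
    displacement: np.ndarray,
    sample_rate: float,
    min_strides: int = DEFAULT_MIN_STRIDES,
    outlier_frac: float = DEFAULT_STRIDE_TIME_OUTLIER_FRAC,
) -> StrideSet:
    """Segment midline vertical displacement into strides.

    The stride period is estimated as twice the autocorrelation step period
    (midline landmarks oscillate twice per stride), boundaries are placed on
    every other displacement minimum — phase-locked to the deepest minimum so
    the within-cycle landmark is consistent — and strides whose duration
    deviates more than ``outlier_frac`` from the running median are discarded
    as non-steady-state.

    Intended for a midline landmark; the sacrum signal is the usual choice.
    """
    z = np.asarray(displacement, dtype=float)
    step_period = estimate_step_period(z, sample_rate)
    stride_period = 2.0 * step_period

    minima, _ = sps.find_peaks(-z, distance=max(1, int(0.35 * stride_period * sample_rate)))
    if len(minima) < 3:
        raise ValueError("fewer than three displacement minima: cannot segment strides")
    deepest = int(np.argmin(z[minima]))
    bounds = minima[deepest % 2 :: 2]
    if len(bounds) < 2:
        raise ValueError("fewer than two stride boundaries found")

    stride_times = np.diff(bounds) / sample_rate * 1000.0  # ms
    running_med = (
        pd.Series(stride_times).rolling(7, center=True, min_periods=1).median().to_numpy()
    )
    keep = np.abs(stride_times - running_med) <= outlier_frac * running_med
    boundaries = np.column_stack([bounds[:-1], bounds[1:]])[keep]
    retained_times = stride_times[keep]
    n_discarded = int((~keep).sum())
    if len(boundaries) < min_strides:
        raise ValueError(
            f"only {len(boundaries)} steady-state strides retained "
            f"(minimum {min_strides}); {n_discarded} discarded"
        )
    if n_discarded:
        logger.info("segment_strides: discarded %d non-steady-state strides", n_discarded)
    return StrideSet(
        boundaries=boundaries,
        stride_times=retained_times,
        n_discarded=n_discarded,
        period_s=float(np.median(retained_times) / 1000.0),
    )


def trim_strides(strides: StrideSet, n: int = 1) -> StrideSet:
    """Drop the first and last ``n`` strides (integration transient guard).

    Double integration with zero-phase filtering leaves its largest residual
    wander at the record edges, so the pipeline discards the outermost
    strides before feature extraction.
    """
    if n <= 0 or strides.n_strides <= 2 * n:
        return strides
    return StrideSet(
        boundaries=strides.boundaries[n:-n],
        stride_times=strides.stride_times[n:-n],
        n_discarded=strides.n_discarded,  # outlier-rule count, not edge trims
        period_s=strides.period_s,
    )


def attribute_steps(
    ltc_displacement: np.ndarray,
    rtc_displacement: np.ndarray,
    strides: StrideSet,
) -> np.ndarray:
    """Label every sample with the hind limb in stance ('left'/'right').

    Each tuber coxae rises ("hikes") during the stance of the contralateral
    hind limb, so within each half-stride the side whose tuber coxae rises
    more identifies the stance limb of the opposite side.  Samples outside
    retained strides are labelled '' and ignored downstream.
    """
    n = len(ltc_displacement)
    labels = np.full(n, "", dtype=object)
    for start, end in strides.boundaries:
        mid = (start + end) // 2
        for a, b in ((start, mid), (mid, end)):
            lw = ltc_displacement[a:b]
            rw = rtc_displacement[a:b]
            if len(lw) == 0:
                continue
            rise_l = float(np.max(lw) - lw[0])
            rise_r = float(np.max(rw) - rw[0])
            labels[a:b] = "right" if rise_l > rise_r else "left"
    return labels


def _window_upward_amplitude(w: np.ndarray) -> float:
    """Maximum of the window minus the minimum preceding that maximum."""
    i = int(np.argmax(w))
    return float(w[i] - np.min(w[: i + 1]))


def extract_stride_features(
    displacements: Mapping[str, np.ndarray],
    strides: StrideSet,
    attribution: np.ndarray,
    sample_rate: float,
) -> tuple[pd.DataFrame, int]:
    """Per-stride displacement features for all supplied landmarks.

    For midline landmarks each retained stride must contain exactly two local
    minima, two local maxima and the two upward amplitudes (maximum minus the
    immediately preceding minimum), each attributed to the left or right step
    via the stance ``attribution`` labels.  For each tuber coxae the upward
    amplitude during the contralateral hind stance ("hike") and the total
    range of motion over the stride are extracted.  Strides lacking a clean
    extrema pattern are dropped; the count of dropped strides is returned.

    Returns
    -------
    (features, n_dropped)
        ``features`` is tidy: columns ``stride``, ``landmark``, ``feature``
        (min/max/up/hike/rom), ``side``, ``value_mm``.
    """
    step_samples = strides.period_s / 2.0 * sample_rate
    rows: list[tuple] = []
    dropped: set[int] = set()

    for lm in displacements:
        if lm not in LANDMARKS:
            raise ValueError(
                f"unknown landmark {lm!r}; valid landmarks: {', '.join(LANDMARKS)}"
            )

    for lm in MIDLINE_LANDMARKS:
        if lm not in displacements:
            continue
        z = np.asarray(displacements[lm], dtype=float)
        dist = max(1, int(0.6 * step_samples))
        all_min, _ = sps.find_peaks(-z, distance=dist)
        all_max, _ = sps.find_peaks(z, distance=dist)
        for k, (start, end) in enumerate(strides.boundaries):
            q = int(0.25 * step_samples)
            mins = all_min[(all_min >= start - q) & (all_min < end - q)]
            maxs = all_max[(all_max >= start) & (all_max < end)]
            if len(mins) != 2 or len(maxs) != 2:
                dropped.add(k)
                continue
            half = (end - start) / 2.0
            sides = (
                str(attribution[int(start + half / 2)]),
                str(attribution[int(start + 3 * half / 2)]),
            )
            if "" in sides or sides[0] == sides[1]:
                dropped.add(k)
                continue
            for i in (0, 1):
                prev_min = all_min[all_min < maxs[i]]
                if len(prev_min) == 0:
                    dropped.add(k)
                    break
                up = float(z[maxs[i]] - z[prev_min[-1]])
                rows.append((k, lm, "min", sides[i], float(z[mins[i]])))
                rows.append((k, lm, "max", sides[i], float(z[maxs[i]])))
                rows.append((k, lm, "up", sides[i], up))

    for lm, own_side in (("left_tuber_coxae", "left"), ("right_tuber_coxae", "right")):
        if lm not in displacements:
            continue
        z = np.asarray(displacements[lm], dtype=float)
        contra = "right" if own_side == "left" else "left"
        for k, (start, end) in enumerate(strides.boundaries):
            in_stride = np.arange(start, end)
            stance_mask = np.asarray(
                [attribution[i] == contra for i in in_stride], dtype=bool
            )
            if not stance_mask.any():
                dropped.add(k)
                continue
            w = z[in_stride[stance_mask]]
            rows.append((k, lm, "hike", own_side, _window_upward_amplitude(w)))
            rows.append((k, lm, "rom", own_side, float(z[start:end].max() - z[start:end].min())))

    features = pd.DataFrame(rows, columns=["stride", "landmark", "feature", "side", "value_mm"])
    if dropped:
        features = features[~features["stride"].isin(dropped)].reset_index(drop=True)
        logger.info("extract_stride_features: dropped %d strides without clean extrema", len(dropped))
    return features, len(dropped)
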