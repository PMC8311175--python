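"""Synthetic trot signals and study-level datasets with known ground truth.

Two levels of generation are provided:

* **Signal level** — :func:`simulate_landmark_signal` builds vertical
  displacement waveforms for the five body landmarks (poll, withers, sacrum,
  left/right tuber coxae) with analytically controlled per-step extrema, and
  emits the sensor-frame acceleration (the analytic second derivative, seen
  through a known fixed rotation, plus white noise) that the kinematics
  pipeline consumes.  Injected left/right differences in minima, maxima and
  upward amplitudes are met *exactly* before noise, so the whole processing
  chain can be validated by parameter recovery.

* **Study level** — :func:`simulate_study` draws condition tables
  (horse x surface x speed x direction) directly from the additive
  random-intercept model that the statistics layer assumes, including a
  circle term that injects body-lean-driven asymmetry of opposite sign on
  the two reins.

The waveform is a chain of quintic smoothstep arcs between prescribed
extrema (one arc per quarter/half cycle, i.e. step-scaled oscillations at
stride and twice-stride frequency), chosen because it is analytically
invertible: the second derivative exists in closed form, is continuous, and
the extrema are the prescribed values exactly.  Note a
structural consequence: with upward amplitude defined as maximum minus the
immediately preceding minimum, the upward-amplitude asymmetry of a midline
landmark is identically ``asym_max - asym_min`` and cannot be injected
independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kinematics import (
    GRAVITY,
    LANDMARKS,
    MIDLINE_LANDMARKS,
    SensorTrace,
    rotation_from_euler,
)

PARAMETERS = (
    "HDmin", "HDmax", "HDup",
    "WDmin", "WDmax", "WDup",
    "PDmin", "PDmax", "PDup",
    "HHD", "RD",
)

#: midline landmark carrying each index family
INDEX_LANDMARK = {"HD": "poll", "WD": "withers", "PD": "sacrum"}

SURFACES = ("hard", "soft")
SPEEDS = ("slow", "fast")
DIRECTIONS = ("straight", "left", "right")

_DEFAULT_AMPLITUDE = {
    # vertical oscillation half-amplitudes, mm (typical trot magnitudes)
    "poll": 45.0,
    "withers": 25.0,
    "sacrum": 40.0,
    "tuber_coxae": 30.0,
}


def body_lean_angle(speed: float, radius: float) -> float:
    """Body lean angle (degrees) of a horse trotting on a circle.

    Balancing the centripetal force F = m v^2 / r against gravity under the
    assumption that the horse minimises extrasagittal joint torques gives a
    trunk lean of ``arctan(v^2 / (g r))`` toward the circle centre.

    Strictly increasing in speed, strictly decreasing in radius.
    """
    if radius <= 0:
        raise ValueError("circle radius must be positive")
    if speed < 0:
        raise ValueError("speed must be non-negative")
    return math.degrees(math.atan(speed * speed / (GRAVITY * radius)))


@dataclass(frozen=True)
class CircleParams:
    """Lunging-circle geometry and the lean-to-asymmetry mapping.

    ``lean_gain`` converts body lean (degrees) into millimetres of induced
    movement asymmetry directed toward the inside of the circle; the mapping
    is linear, with the gain a free parameter of the generator.  The default
    radius corresponds to a 15 m lunging circle.
    """

    speed: float  # m/s
    radius: float = 7.5  # m
    mass: float = 500.0  # kg, used only for centripetal-force reporting
    lean_gain: float = 0.8  # mm per degree of body lean
    direction: str = "left"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("circle radius must be positive")
        if self.speed < 0:
            raise ValueError("speed must be non-negative")
        if self.direction not in ("left", "right"):
            raise ValueError("direction must be 'left' or 'right'")

    @property
    def lean_deg(self) -> float:
        return body_lean_angle(self.speed, self.radius)

    @property
    def centripetal_force(self) -> float:
        """F = m v^2 / r, in newtons."""
        return self.mass * self.speed**2 / self.radius


def circle_asymmetry_offset(circle: CircleParams) -> float:
    """Signed induced asymmetry (mm), positive toward the horse's left.

    Under the left-minus-right sign convention an inward-directed asymmetry
    is positive on the left rein and negative on the right rein; left- and
    right-rein offsets at equal speed are exact mirror images.
    """
    sign = 1.0 if circle.direction == "left" else -1.0
    return sign * circle.lean_gain * circle.lean_deg


@dataclass(frozen=True)
class TrotParams:
    """Ground-truth parameters of one synthetic trotting condition.

    All displacement quantities are in mm.  ``asym_min``/``asym_max`` hold
    the injected left-minus-right differences of the per-step displacement
    minima/maxima per midline landmark; ``asym_up`` may be given for
    documentation but must equal ``asym_max - asym_min`` (a consequence of
    pairing each maximum with its immediately preceding minimum).
    ``hike_diff`` and ``rom_diff`` inject the tuber-coxae hike and
    range-of-motion differences (left minus right).
    """

    stride_time: float = 0.75  # s
    amplitude: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_AMPLITUDE))
    asym_min: Mapping[str, float] = field(default_factory=dict)
    asym_max: Mapping[str, float] = field(default_factory=dict)
    asym_up: Mapping[str, float] | None = None
    hike_diff: float = 0.0
    rom_diff: float = 0.0
    noise_sd: float = 0.0  # mm, displacement-equivalent at step frequency
    sample_rate: float = 100.0  # Hz
    duration: float = 24.0  # s
    stride_time_jitter: float = 0.0  # fractional, uniform
    orientation_deg: tuple[float, float, float] = (4.0, -3.0, 25.0)  # roll, pitch, yaw

    def __post_init__(self) -> None:
        if self.stride_time <= 0:
            raise ValueError("stride_time must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if any(a < 0 for a in self.amplitude.values()):
            raise ValueError("amplitudes must be non-negative")
        if self.duration < 2 * self.stride_time:
            raise ValueError("duration must cover at least two strides")
        if not 0 <= self.stride_time_jitter < 0.25:
            raise ValueError("stride_time_jitter must be a small fraction in [0, 0.25)")
        if self.asym_up is not None:
            for lm, up in self.asym_up.items():
                implied = self.asym_max.get(lm, 0.0) - self.asym_min.get(lm, 0.0)
                if abs(up - implied) > 1e-9:
                    raise ValueError(
                        f"asym_up[{lm!r}]={up} inconsistent with asym_max-asym_min"
                        f"={implied}; upward amplitude pairs each maximum with the"
                        " immediately preceding minimum"
                    )

    @property
    def n_strides(self) -> int:
        return int(round(self.duration / self.stride_time))


@dataclass
class GroundTruth:
    """Side-car of a simulated trace: the answers the pipeline should find."""

    stride_starts_s: np.ndarray
    stride_durations_s: np.ndarray
    boundary_samples: np.ndarray
    stance_labels: np.ndarray  # per sample, 'left'/'right' hind stance
    displacement_mm: np.ndarray  # noise-free vertical displacement
    injected: dict[str, float]  # expected values of the 11 indices
    params: TrotParams
    circle: CircleParams | None


def expected_indices(params: TrotParams, circle: CircleParams | None = None) -> dict[str, float]:
    """The 11 asymmetry-index values implied by the injected parameters."""
    p = _modulated_params(params, circle) if circle is not None else params
    out: dict[str, float] = {}
    for fam, lm in INDEX_LANDMARK.items():
        dmin = p.asym_min.get(lm, 0.0)
        dmax = p.asym_max.get(lm, 0.0)
        out[f"{fam}min"] = dmin
        out[f"{fam}max"] = dmax
        out[f"{fam}up"] = dmax - dmin
    out["HHD"] = p.hike_diff
    out["RD"] = p.rom_diff
    return out


def _modulated_params(params: TrotParams, circle: CircleParams) -> TrotParams:
    """Shift the injected asymmetries by the circle-induced lean offset.

    The lean offset is added in full to the extrema differences that express
    weight-bearing asymmetry (minima, hike, range of motion) and at half
    magnitude to the maxima differences, a fixed allocation that touches all
    eleven indices while keeping every induced component linear in the lean
    angle (so opposite reins mirror exactly).
    """
    delta = circle_asymmetry_offset(circle)
    if delta == 0.0:
        return params
    asym_min = {lm: params.asym_min.get(lm, 0.0) + delta for lm in MIDLINE_LANDMARKS}
    asym_max = {lm: params.asym_max.get(lm, 0.0) + delta / 2.0 for lm in MIDLINE_LANDMARKS}
    return replace(
        params,
        asym_min=asym_min,
        asym_max=asym_max,
        asym_up=None,
        hike_diff=params.hike_diff + delta,
        rom_diff=params.rom_diff + delta,
    )


def _stride_schedule(params: TrotParams, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-stride start times and durations, shared across landmarks.

    The timing stream is derived from the seed alone (not the landmark) so
    that all five traces of one condition share identical stride boundaries.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    n = params.n_strides
    jitter = rng.uniform(-params.stride_time_jitter, params.stride_time_jitter, size=n)
    durations = params.stride_time * (1.0 + jitter)
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return starts, durations


def _extrema_phases_values(params: TrotParams, landmark: str) -> tuple[np.ndarray, np.ndarray]:
    """Within-stride phases and values (mm) of the landmark's extrema.

    Midline landmarks: minima at phases 0 and 0.5 (left/right step), maxima
    at 0.25 and 0.75.  Tuber coxae: one dominant oscillation per stride with
    the hike (rise during the contralateral hind stance) and a smaller
    secondary oscillation, arranged so hike amplitude and range of motion
    are independently controllable.
    """
    if landmark in MIDLINE_LANDMARKS:
        A = params.amplitude.get(landmark, 0.0)
        dmin = params.asym_min.get(landmark, 0.0)
        dmax = params.asym_max.get(landmark, 0.0)
        phases = np.array([0.0, 0.25, 0.5, 0.75])
        values = np.array([
            -A + dmin / 2.0,  # left-step minimum
            A + dmax / 2.0,   # left-step maximum
            -A - dmin / 2.0,  # right-step minimum
            A - dmax / 2.0,   # right-step maximum
        ])
        return phases, values

    A = params.amplitude.get("tuber_coxae", 30.0)
    if A <= 0:
        raise ValueError("tuber_coxae amplitude must be positive")
    side = 1.0 if landmark == "left_tuber_coxae" else -1.0
    up = 1.5 * A + side * params.hike_diff / 2.0
    rom = 2.0 * A + side * params.rom_diff / 2.0
    if rom <= up + 0.05 * A or up <= 0:
        raise ValueError(
            "incompatible tuber-coxae geometry: need range of motion to exceed "
            f"hike amplitude (up={up:.2f}, rom={rom:.2f} mm)"
        )
    m_h = -A                 # minimum preceding the hike
    M = -A + up              # hike maximum
    m_b = M - rom            # base (global) minimum
    s = m_h + 0.25 * up      # secondary maximum
    if landmark == "left_tuber_coxae":
        # hike during right-hind stance (second half of the stride)
        phases = np.array([0.05, 0.30, 0.55, 0.80])
        values = np.array([m_b, s, m_h, M])
    else:
        # mirrored: hike during left-hind stance (first half)
        phases = np.array([0.05, 0.30, 0.55, 0.80])
        values = np.array([m_h, M, m_b, s])
    return phases, values


def _smoothstep_track(
    t: np.ndarray,
    ext_t: np.ndarray,
    ext_v: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the extrema chain and its second derivative at times ``t``.

    Between consecutive extrema ``(t0,v0) -> (t1,v1)`` the track follows the
    quintic smoothstep ``v0 + (v1-v0) (6 tau^5 - 15 tau^4 + 10 tau^3)``:
    monotone, with zero velocity *and* zero acceleration at both ends, so
    the prescribed extrema are exact and the analytic acceleration is
    continuous everywhere.  (C² continuity matters: a chain with
    acceleration jumps has a slowly decaying acceleration spectrum whose
    sampled aliases fold onto the stride harmonics and corrupt the
    double-integrated displacement.)
    """
    i = np.clip(np.searchsorted(ext_t, t, side="right") - 1, 0, len(ext_t) - 2)
    t0, t1 = ext_t[i], ext_t[i + 1]
    v0, v1 = ext_v[i], ext_v[i + 1]
    dv = v1 - v0
    dt = t1 - t0
    tau = (t - t0) / dt
    z = v0 + dv * tau**3 * (10.0 + tau * (-15.0 + 6.0 * tau))
    acc = dv * 60.0 * tau * (1.0 + tau * (-3.0 + 2.0 * tau)) / dt**2
    return z, acc


def simulate_landmark_signal(
    params: TrotParams,
    landmark: str,
    seed: int,
    circle: CircleParams | None = None,
) -> SensorTrace:
    """Simulate one landmark's IMU trace with ground truth attached.

    The vertical displacement is the smoothstep extrema chain described in
    the module docstring; the acceleration channel is its analytic second
    derivative (plus gravity), expressed in the sensor frame through the
    fixed rotation encoded by ``params.orientation_deg``, with optional white
    noise.  ``noise_sd`` is specified as displacement-equivalent mm at the
    step frequency and converted to acceleration units via ``(2 pi f_step)^2``.

    Deterministic for a fixed seed; traces of different landmarks generated
    with the same seed share identical stride timing.
    """
    if landmark not in LANDMARKS:
        raise ValueError(
            f"unknown landmark {landmark!r}; valid landmarks: {', '.join(LANDMARKS)}"
        )
    eff = _modulated_params(params, circle) if circle is not None else params

    starts, durations = _stride_schedule(eff, seed)
    total = float(starts[-1] + durations[-1])
    fs = eff.sample_rate
    n_samples = int(np.floor(total * fs))
    t = np.arange(n_samples) / fs

    phases, values = _extrema_phases_values(eff, landmark)
    ext_t = (starts[:, None] + phases[None, :] * durations[:, None]).ravel()
    ext_v = np.tile(values, len(starts))
    # pad one stride on each side so every sample lies between two extrema
    ext_t = np.concatenate([ext_t[:4] - durations[0], ext_t, ext_t[-4:] + durations[-1]])
    ext_v = np.concatenate([ext_v[:4], ext_v, ext_v[-4:]])
    if np.any(np.diff(ext_t) <= 0):
        raise ValueError(
            "stride_time too short for the sample rate: extrema collide"
        )

    # displacement is effectively band-limited at 100 Hz and is sampled
    # directly; the acceleration is not (its spectrum decays only ~1/f^2),
    # so it is sampled the way a real IMU front end does: evaluated
    # oversampled, anti-alias filtered, then decimated to the sample rate
    z_mm, _ = _smoothstep_track(t, ext_t, ext_v)
    q = 8
    t_fine = np.arange(n_samples * q) / (fs * q)
    _, acc_fine = _smoothstep_track(t_fine, ext_t, ext_v)
    from scipy.signal import decimate

    acc_mm = decimate(acc_fine, q, ftype="fir", zero_phase=True)
    acc_world = np.zeros((n_samples, 3))
    acc_world[:, 2] = acc_mm * 1e-3 + GRAVITY

    rot = rotation_from_euler(np.asarray(eff.orientation_deg))
    acc_sensor = rot.inv().apply(acc_world)

    if eff.noise_sd > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), 13, LANDMARKS.index(landmark)])
        )
        # white accelerometer noise, scaled so that noise_sd is the
        # displacement-equivalent amplitude at the stride frequency — the
        # band that carries the left/right asymmetry information
        f_stride = 1.0 / eff.stride_time
        sd_acc = eff.noise_sd * 1e-3 * (2.0 * np.pi * f_stride) ** 2
        acc_sensor = acc_sensor + rng.normal(0.0, sd_acc, size=acc_sensor.shape)

    orientation = np.tile(np.asarray(eff.orientation_deg, dtype=float), (n_samples, 1))

    stride_idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(starts) - 1)
    phase = (t - starts[stride_idx]) / durations[stride_idx]
    stance = np.where(phase < 0.5, "left", "right").astype(object)

    truth = GroundTruth(
        stride_starts_s=starts,
        stride_durations_s=durations,
        boundary_samples=np.round(starts * fs).astype(int),
        stance_labels=stance,
        displacement_mm=z_mm,
        injected=expected_indices(params, circle),
        params=params,
        circle=circle,
    )
    return SensorTrace(
        landmark=landmark,
        time=t,
        acceleration=acc_sensor,
        orientation=orientation,
        sample_rate=fs,
        truth=truth,
        meta={"params": params, "seed": int(seed), "circle": circle},
    )


def apply_circle_modulation(trace: SensorTrace, circle: CircleParams) -> SensorTrace:
    """Re-simulate a synthetic trace with circle-induced lean asymmetry.

    Adds ``lean_gain * body_lean_angle(speed, radius)`` mm of asymmetry
    directed toward the inside of the circle; at zero speed the trace is
    unchanged, and left/right-rein modulations at equal speed are mirror
    images.  Only traces produced by :func:`simulate_landmark_signal` carry
    the generation metadata this needs.
    """
    if "params" not in trace.meta:
        raise ValueError("trace was not produced by the synthetic generator")
    return simulate_landmark_signal(
        trace.meta["params"], trace.landmark, trace.meta["seed"], circle=circle
    )


def simulate_condition(
    params: TrotParams,
    seed: int,
    circle: CircleParams | None = None,
) -> dict[str, SensorTrace]:
    """All five landmark traces of one assessment condition (shared timing)."""
    return {lm: simulate_landmark_signal(params, lm, seed, circle=circle) for lm in LANDMARKS}


@dataclass(frozen=True)
class StudyEffects:
    """Generative model of a full lunging study at the condition level.

    Each of the 11 asymmetry parameters is generated, in the frame of the
    horse's own ("preexisting") asymmetry direction, as

    ``baseline + horse intercept + surface_effect*1[hard] +
    speed_effect*1[fast] + circle term + residual``,

    and then flipped to the raw left/right frame by a per-horse,
    per-parameter side sign (left- or right-sided preexisting asymmetry).
    The circle term is ``lean_gain * lean(speed)`` toward the inside of the
    circle, mirrored between reins, which is the mechanism by which
    average-rein values cancel circle-induced asymmetry.  Stride time is
    generated from its own additive model (grand mean, speed/surface shifts,
    direction offsets, horse intercept, residual).

    Defaults emulate the magnitudes of the emulated study design: 27 horses,
    12 conditions (2 surfaces x 2 speeds x 3 directions), baselines of a few
    to ~18 mm per parameter, between-horse SD 3 mm, residual SD 2 mm, slow
    and fast trot at 3 and 4 m/s on a 7.5 m circle.
    """

    horse_sd: float = 3.0
    surface_effect: float = 2.0  # hard minus soft, mm
    speed_effect: float = 0.0  # fast minus slow, mm (speed acts via the circle term)
    residual_sd: float = 2.0
    baseline: Mapping[str, float] = field(
        default_factory=lambda: {
            "HDmin": 11.2, "HDmax": 9.9, "HDup": 18.4,
            "WDmin": 5.5, "WDmax": 4.9, "WDup": 10.0,
            "PDmin": 4.9, "PDmax": 6.4, "PDup": 7.8,
            "HHD": 8.5, "RD": 7.8,
        }
    )
    n_horses: int = 27
    conditions: Sequence[tuple[str, str, str]] = field(
        default_factory=lambda: tuple(
            (surface, speed, direction)
            for surface in SURFACES
            for speed in SPEEDS
            for direction in DIRECTIONS
        )
    )
    # circle geometry and speed categories
    radius: float = 7.5
    lean_gain: float = 0.8
    slow_speed: float = 3.0  # m/s
    fast_speed: float = 4.0  # m/s
    side_prob: float = 0.5  # P(left-sided preexisting asymmetry)
    n_strides: int = 30
    # stride-time model, ms
    st_grand: float = 772.0
    st_speed: float = -38.0  # fast minus slow
    st_surface: float = -14.0  # hard minus soft
    # straight-line trot is faster (shorter strides) than lunging; the two
    # reins share one offset — equal rein speeds are the study's premise
    st_direction: Mapping[str, float] = field(
        default_factory=lambda: {"straight": -25.0, "left": 12.5, "right": 12.5}
    )
    st_horse_sd: float = 20.0
    st_residual_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.horse_sd < 0 or self.residual_sd < 0 or self.st_horse_sd < 0 or self.st_residual_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_horses < 2:
            raise ValueError("need at least two horses")
        if not self.conditions:
            raise ValueError("conditions must be non-empty")
        for cond in self.conditions:
            surface, speed, direction = cond
            if surface not in SURFACES or speed not in SPEEDS or direction not in DIRECTIONS:
                raise ValueError(f"invalid condition {cond!r}")
        if not 0 <= self.side_prob <= 1:
            raise ValueError("side_prob must be a probability")

    def condition_speed(self, speed: str) -> float:
        return self.fast_speed if speed == "fast" else self.slow_speed


def simulate_study(effects: StudyEffects, seed: int) -> pd.DataFrame:
    """Draw one full study: a condition-level asymmetry table.

    Returns a tidy wide table with one row per horse x surface x speed x
    direction, the 11 asymmetry parameters (mm, raw left-minus-right frame),
    stride time (ms) and stride count.  Deterministic per seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 42]))
    params = list(effects.baseline.keys())
    rows = []
    for h in range(effects.n_horses):
        horse = f"H{h + 1:02d}"
        intercepts = {p: rng.normal(0.0, effects.horse_sd) for p in params}
        sides = {
            p: 1.0 if rng.random() < effects.side_prob else -1.0 for p in params
        }
        st_intercept = rng.normal(0.0, effects.st_horse_sd)
        for surface, speed, direction in effects.conditions:
            row: dict[str, object] = {
                "horse": horse, "surface": surface, "speed": speed, "direction": direction,
            }
            if direction == "straight":
                circle_raw = 0.0
            else:
                circle = CircleParams(
                    speed=effects.condition_speed(speed),
                    radius=effects.radius,
                    lean_gain=effects.lean_gain,
                    direction=direction,
                )
                circle_raw = circle_asymmetry_offset(circle)
            for p in params:
                core = (
                    effects.baseline[p]
                    + intercepts[p]
                    + (effects.surface_effect if surface == "hard" else 0.0)
                    + (effects.speed_effect if speed == "fast" else 0.0)
                    + rng.normal(0.0, effects.residual_sd)
                )
                row[p] = sides[p] * core + circle_raw
            row["stride_time"] = (
                effects.st_grand
                + (effects.st_speed / 2.0 if speed == "fast" else -effects.st_speed / 2.0)
                + (effects.st_surface / 2.0 if surface == "hard" else -effects.st_surface / 2.0)
                + effects.st_direction.get(direction, 0.0)
                + st_intercept
                + rng.normal(0.0, effects.st_residual_sd)
            )
            row["n_strides"] = effects.n_strides
            rows.append(row)
    return pd.DataFrame(rows)
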