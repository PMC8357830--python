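"""Synthetic gaze sessions: scripts, forward maps and feature generation.

The generator produces ground-truth sessions at the *feature* level: a
session script lists the screen targets the (simulated) subject fixates, a
head-pose schedule, and fixational-noise parameters; a forward map converts
(true gaze, head pose) into the noise-free 4D eye features ``(x, y, m, n)``
each eye camera would measure.  Tremor, microsaccades, blinks and corner
measurement noise are then added, and fixation medians are assembled —
exactly the data the regression, interaction and evaluation stages consume.

The default forward map is deliberately *outside* every candidate
polynomial family: the pupil displacement grows with the tangent of gaze
eccentricity and its gain is modulated by head pose.  A map inside the
fitted family would make all candidate models equivalent and hide the
overfitting behaviour that motivates model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from gazekit.geometry import DisplayGeometry
from gazekit.session import SessionRecord

__all__ = [
    "NoiseParams",
    "TargetEvent",
    "SessionScript",
    "TangentForwardMap",
    "LinearForwardMap",
    "generate_gaze_session",
    "nine_point_targets",
    "grid_targets",
    "accuracy_grid_targets",
    "make_model_selection_script",
    "make_accuracy_script",
    "make_provocation_script",
    "DEFAULT_POSE_OFFSETS",
]


@dataclass(frozen=True)
class NoiseParams:
    """Fixational and measurement noise of the simulated subject/camera.

    tremor_sd : white Gaussian jitter of the pupil position, px.
    drift_sd : slow ocular drift, px per sqrt-second; modelled as a
        mean-reverting (Ornstein-Uhlenbeck) walk with time constant
        ``drift_tau`` so fixation medians carry realistic px-scale noise
        that frame averaging cannot remove.
    microsaccade_rate : Poisson rate of small involuntary jumps, 1/s.
    microsaccade_amp : amplitude range of those jumps, px.
    microsaccade_tau : exponential decay time back to fixation, s.
    blink_rate : Poisson rate of blinks, 1/s (blinked frames are invalid).
    blink_duration : s.
    corner_sd : corner-tracker measurement jitter on (m, n), px.
    """

    tremor_sd: float = 0.3
    drift_sd: float = 0.15
    drift_tau: float = 2.0
    microsaccade_rate: float = 1.5
    microsaccade_amp: tuple[float, float] = (1.0, 3.0)
    microsaccade_tau: float = 0.025
    blink_rate: float = 0.08
    blink_duration: float = 0.25
    corner_sd: float = 0.2


@dataclass(frozen=True)
class TargetEvent:
    """One scripted fixation: where, when and for how long."""

    gx: float
    gy: float
    onset: float
    duration: float
    target_id: int = 0

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class SessionScript:
    """Reproducible description of a session.

    ``pose_steps`` is a piecewise-constant head-pose schedule: a list of
    ``(time, dm, dn)`` entries (camera pixels) applied from that time on.
    ``pose_drift_sd`` adds a slow smooth random-walk drift on top (px per
    sqrt-second; realization drawn from ``seed``).  Identical script and
    seed produce a bit-identical session.
    """

    targets: tuple[TargetEvent, ...]
    pose_steps: tuple[tuple[float, float, float], ...] = ((0.0, 0.0, 0.0),)
    pose_drift_sd: float = 0.0
    noise: NoiseParams = field(default_factory=NoiseParams)
    fps: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("script has no targets")
        if any(tg.duration <= 0 for tg in self.targets):
            raise ValueError("target durations must be positive")
        ordered = sorted(self.targets, key=lambda tg: tg.onset)
        for a, b in zip(ordered[:-1], ordered[1:]):
            if b.onset < a.offset - 1e-9:
                raise ValueError(
                    f"overlapping target intervals: {a} and {b}"
                )

    @property
    def duration(self) -> float:
        return max(tg.offset for tg in self.targets)

    def with_seed(self, seed: int) -> "SessionScript":
        return replace(self, seed=seed)


# ---------------------------------------------------------------- forward maps
@dataclass(frozen=True)
class TangentForwardMap:
    """Pupil response growing with the tangent of gaze eccentricity.

    For centered screen coordinates ``u = gx - 0.5``, ``v = gy - aspect/2``
    the noise-free response of one eye is::

        r(u) = tan(curvature * u) / curvature + asymmetry * u**2
        x = x_rest + gain_factor * gain_x * r(u) + pose_coupling * dm
        y = y_rest + gain_factor * gain_y * r(v) + pose_coupling * dn
        m = m0 + dm,   n = n0 + dn

    with ``gain_factor = 1 + gain_modulation * dn``.  A head-pose change
    both translates the eye-corner anchor and slightly re-scales the pupil
    response, emulating the pattern changes a real pose change produces;
    the even ``u**2`` term models the perspective compression of an
    obliquely mounted eye camera and the mild tangent curvature the growth
    of pupil displacement with gaze eccentricity.  No polynomial of fixed
    degree inverts this map exactly.
    """

    gain_x: float = 120.0
    gain_y: float = 110.0
    curvature: float = 0.9
    asymmetry: float = 0.45
    pose_coupling: float = 5.5
    gain_modulation: float = 0.004
    x_rest: float = -110.0
    y_rest: float = -55.0
    corner_left: tuple[float, float] = (420.0, 260.0)
    corner_right: tuple[float, float] = (220.0, 262.0)
    right_gain_scale: float = 0.94
    aspect: float = 9.0 / 16.0

    def features(self, g, pose, eye: str) -> np.ndarray:
        g = np.atleast_2d(np.asarray(g, dtype=float))
        pose = np.atleast_2d(np.asarray(pose, dtype=float))
        dm, dn = pose[:, 0], pose[:, 1]
        u = g[:, 0] - 0.5
        v = g[:, 1] - self.aspect / 2.0
        scale = 1.0 if eye == "left" else self.right_gain_scale
        m0, n0 = self.corner_left if eye == "left" else self.corner_right
        gain_factor = 1.0 + self.gain_modulation * dn

        def response(w):
            return np.tan(self.curvature * w) / self.curvature + self.asymmetry * w**2

        x = (
            self.x_rest
            + scale * gain_factor * self.gain_x * response(u)
            + self.pose_coupling * dm
        )
        y = (
            self.y_rest
            + scale * gain_factor * self.gain_y * response(v)
            + self.pose_coupling * dn
        )
        return np.column_stack([x, y, m0 + dm, n0 + dn])


@dataclass(frozen=True)
class LinearForwardMap:
    """Affine map from gaze to pupil features; head pose is pure translation.

    Lies inside every candidate model family (the inverse is affine in
    ``(x, y)``), so any model fit on noise-free data from this map predicts
    exactly — used as the exact-recovery control condition.
    """

    gain_x: float = 120.0
    gain_y: float = 110.0
    x_rest: float = -110.0
    y_rest: float = -55.0
    corner_left: tuple[float, float] = (420.0, 260.0)
    corner_right: tuple[float, float] = (220.0, 262.0)
    aspect: float = 9.0 / 16.0

    def features(self, g, pose, eye: str) -> np.ndarray:
        g = np.atleast_2d(np.asarray(g, dtype=float))
        pose = np.atleast_2d(np.asarray(pose, dtype=float))
        m0, n0 = self.corner_left if eye == "left" else self.corner_right
        x = self.x_rest + self.gain_x * (g[:, 0] - 0.5)
        y = self.y_rest + self.gain_y * (g[:, 1] - self.aspect / 2.0)
        return np.column_stack(
            [x, y, m0 + pose[:, 0], n0 + pose[:, 1]]
        )


# ---------------------------------------------------------------- target layouts
def grid_targets(rows: int, cols: int, display: DisplayGeometry | None = None,
                 margin: float = 0.12) -> list[tuple[float, float]]:
    """Row-major grid of equally spaced screen positions inside the display."""
    display = display or DisplayGeometry()
    xs = np.linspace(margin, 1.0 - margin, cols)
    ys = np.linspace(margin * display.aspect, (1.0 - margin) * display.aspect, rows)
    return [(float(x), float(y)) for y in ys for x in xs]


def nine_point_targets(display: DisplayGeometry | None = None) -> list[tuple[float, float]]:
    """The standard 9-point (3 x 3) initial calibration pattern."""
    return grid_targets(3, 3, display)


def accuracy_grid_targets(display: DisplayGeometry | None = None,
                          rows: int = 10, cols: int = 18) -> list[tuple[float, float]]:
    """Centers of rows 2-11 x columns 2-19 of a 12 x 20 display partition.

    The full layout has 10 x 18 = 180 targets; smaller ``rows``/``cols``
    subsample the same region evenly for reduced-scale runs.
    """
    display = display or DisplayGeometry()
    row_idx = np.linspace(1, 10, rows)
    col_idx = np.linspace(1, 18, cols)
    return [
        (float((c + 0.5) / 20.0), float(display.aspect * (r + 0.5) / 12.0))
        for r in row_idx
        for c in col_idx
    ]


#: Head-pose offsets (dm, dn) in camera px for the 8-round model-selection
#: protocol; round 1 (the calibration round) is at the reference pose.
DEFAULT_POSE_OFFSETS: tuple[tuple[float, float], ...] = (
    (0.0, 0.0),
    (8.0, -5.0),
    (-6.0, 7.0),
    (12.0, 4.0),
    (-11.0, -8.0),
    (5.0, 12.0),
    (-14.0, 3.0),
    (9.0, -12.0),
)


def _sequence_script(positions, duration, ids=None, start=0.0) -> list[TargetEvent]:
    ids = ids if ids is not None else range(len(positions))
    return [
        TargetEvent(gx, gy, start + i * duration, duration, target_id=tid)
        for i, ((gx, gy), tid) in enumerate(zip(positions, ids))
    ]


def make_model_selection_script(
    n_rounds: int = 8,
    fixation_duration: float = 3.0,
    pose_offsets=DEFAULT_POSE_OFFSETS,
    pose_scale: float = 1.0,
    noise: NoiseParams | None = None,
    seed: int = 0,
    display: DisplayGeometry | None = None,
) -> SessionScript:
    """Model-selection protocol: 3 x 5 target grid repeated over poses.

    Fifteen targets in three rows of five equally spaced locations are
    fixated in sequence; after each round the head pose steps to the next
    offset.  Calibration uses the first round, the remaining rounds test
    how each candidate model generalizes to unseen poses.
    """
    grid = grid_targets(3, 5, display)
    targets: list[TargetEvent] = []
    steps: list[tuple[float, float, float]] = []
    round_duration = len(grid) * fixation_duration
    for r in range(n_rounds):
        start = r * round_duration
        dm, dn = pose_offsets[r % len(pose_offsets)]
        steps.append((start, pose_scale * dm, pose_scale * dn))
        targets.extend(
            _sequence_script(grid, fixation_duration,
                             ids=range(len(grid)), start=start)
        )
    return SessionScript(
        targets=tuple(targets),
        pose_steps=tuple(steps),
        noise=noise or NoiseParams(),
        seed=seed,
    )


def make_accuracy_script(
    n_targets: int = 60,
    target_duration: float = 1.0,
    calibration_duration: float = 3.0,
    pose_drift_sd: float = 2.0,
    noise: NoiseParams | None = None,
    seed: int = 0,
    display: DisplayGeometry | None = None,
) -> SessionScript:
    """Group accuracy protocol: 9-point calibration then a target grid.

    Nine calibration points are shown for ``calibration_duration`` seconds
    each, followed by ``n_targets`` test targets sampled evenly from the
    rows 2-11 x columns 2-19 layout at ``target_duration`` intervals.  The
    head pose drifts smoothly (``pose_drift_sd`` px per sqrt-second), the
    condition that separates progressive from fixed calibration.
    """
    display = display or DisplayGeometry()
    calib = nine_point_targets(display)
    rows = max(2, int(round(np.sqrt(n_targets / 1.8))))
    cols = max(2, int(np.ceil(n_targets / rows)))
    test = accuracy_grid_targets(display, rows, cols)[:n_targets]
    targets = _sequence_script(calib, calibration_duration, ids=range(9))
    t0 = 9 * calibration_duration
    targets += _sequence_script(test, target_duration,
                                ids=range(9, 9 + len(test)), start=t0)
    return SessionScript(
        targets=tuple(targets),
        pose_drift_sd=pose_drift_sd,
        noise=noise or NoiseParams(),
        seed=seed,
    )


def make_provocation_script(
    n_targets: int = 40,
    spike_event: int = 20,
    spike_offset: tuple[float, float] = (22.0, -16.0),
    target_duration: float = 1.5,
    calibration_duration: float = 3.0,
    pose_drift_sd: float = 2.0,
    noise: NoiseParams | None = None,
    seed: int = 0,
    display: DisplayGeometry | None = None,
) -> SessionScript:
    """Provocation protocol: a large sudden head movement mid-session.

    After 9-point calibration and ``spike_event`` test fixations, the
    head jumps by ``spike_offset`` (camera px) and stays there; the
    following events measure how quickly progressive calibration
    recovers.  The subject also keeps drifting slowly throughout
    (``pose_drift_sd``), as a deliberately restless subject would.
    """
    display = display or DisplayGeometry()
    calib = nine_point_targets(display)
    rng = np.random.default_rng(12345)  # layout is part of the script, fixed
    test = [
        (float(rng.uniform(0.1, 0.9)),
         float(rng.uniform(0.1 * display.aspect, 0.9 * display.aspect)))
        for _ in range(n_targets)
    ]
    targets = _sequence_script(calib, calibration_duration, ids=range(9))
    t0 = 9 * calibration_duration
    targets += _sequence_script(test, target_duration,
                                ids=range(9, 9 + n_targets), start=t0)
    spike_time = t0 + spike_event * target_duration
    steps = ((0.0, 0.0, 0.0), (spike_time, *spike_offset))
    return SessionScript(
        targets=tuple(targets),
        pose_steps=steps,
        pose_drift_sd=pose_drift_sd,
        noise=noise or NoiseParams(),
        seed=seed,
    )


# ---------------------------------------------------------------- generation
def _pose_at(script: SessionScript, t: np.ndarray, rng: np.random.Generator):
    steps = sorted(script.pose_steps)
    times = np.array([s[0] for s in steps])
    dm = np.array([s[1] for s in steps])
    dn = np.array([s[2] for s in steps])
    idx = np.clip(np.searchsorted(times, t, side="right") - 1, 0, len(steps) - 1)
    pose = np.column_stack([dm[idx], dn[idx]])
    if script.pose_drift_sd > 0:
        dt = 1.0 / script.fps
        walk = rng.normal(0.0, script.pose_drift_sd * np.sqrt(dt), size=(len(t), 2))
        drift = np.cumsum(walk, axis=0)
        # low-pass so the drift is smooth at the frame scale
        drift = gaussian_filter1d(drift, sigma=script.fps * 0.5, axis=0)
        pose = pose + drift
    return pose


def _microsaccade_signal(t: np.ndarray, noise: NoiseParams,
                         rng: np.random.Generator) -> np.ndarray:
    """Sum of Poisson-timed jump-and-decay transients, shared by both eyes."""
    signal = np.zeros((len(t), 2))
    duration = t[-1] - t[0] if len(t) > 1 else 0.0
    n_events = rng.poisson(noise.microsaccade_rate * max(duration, 0.0))
    onsets = rng.uniform(t[0], t[-1], size=n_events) if n_events else []
    for onset in np.sort(onsets):
        amp = rng.uniform(*noise.microsaccade_amp)
        angle = rng.uniform(0.0, 2 * np.pi)
        vec = amp * np.array([np.cos(angle), np.sin(angle)])
        after = t >= onset
        decay = np.exp(-(t[after] - onset) / noise.microsaccade_tau)
        signal[after] += vec * decay[:, None]
    return signal


def _drift_signal(t: np.ndarray, noise: NoiseParams,
                  rng: np.random.Generator) -> np.ndarray:
    """Mean-reverting slow drift of the line of gaze, shared by both eyes."""
    if noise.drift_sd <= 0:
        return np.zeros((len(t), 2))
    signal = np.zeros((len(t), 2))
    for i in range(1, len(t)):
        dt = max(t[i] - t[i - 1], 0.0)
        decay = np.exp(-dt / noise.drift_tau)
        signal[i] = signal[i - 1] * decay + rng.normal(
            0.0, noise.drift_sd * np.sqrt(dt), size=2
        )
    return signal


def _blink_mask(t: np.ndarray, noise: NoiseParams,
                rng: np.random.Generator) -> np.ndarray:
    mask = np.zeros(len(t), dtype=bool)
    duration = t[-1] - t[0] if len(t) > 1 else 0.0
    n_blinks = rng.poisson(noise.blink_rate * max(duration, 0.0))
    for onset in rng.uniform(t[0], t[-1], size=n_blinks):
        mask |= (t >= onset) & (t < onset + noise.blink_duration)
    return mask


def generate_gaze_session(
    script: SessionScript,
    forward_map=None,
    display: DisplayGeometry | None = None,
) -> SessionRecord:
    """Generate a feature-level session from a script and forward map.

    Frames are produced at ``script.fps`` for the duration of every target
    fixation (gaze is assumed to land on the target instantaneously).  The
    per-frame features are the forward map's noise-free output plus tremor,
    microsaccades and corner measurement noise; blinked frames have NaN
    features.  The fixation table holds component-wise medians over the
    valid frames of each fixation and a validity flag requiring >= 50%
    valid frames.  Deterministic given (script, seed).
    """
    forward_map = forward_map or TangentForwardMap()
    display = display or DisplayGeometry()
    for tg in script.targets:
        if not display.contains([(tg.gx, tg.gy)])[0]:
            raise ValueError(f"target {tg} outside display region")

    ss = np.random.SeedSequence(script.seed)
    rng_pose, rng_blink, rng_ms, rng_tremor, rng_corner, rng_drift = (
        np.random.default_rng(child) for child in ss.spawn(6)
    )

    ordered = sorted(script.targets, key=lambda tg: tg.onset)
    dt = 1.0 / script.fps
    frame_t, frame_target, frame_g, fixation_slices = [], [], [], []
    for tg in ordered:
        n = max(1, int(round(tg.duration * script.fps)))
        start = len(frame_t)
        ts = tg.onset + dt * np.arange(n)
        frame_t.extend(ts)
        frame_target.extend([tg.target_id] * n)
        frame_g.extend([(tg.gx, tg.gy)] * n)
        fixation_slices.append((tg, slice(start, start + n)))
    t = np.asarray(frame_t)
    g_true = np.asarray(frame_g)

    pose = _pose_at(script, t, rng_pose)
    blink = _blink_mask(t, script.noise, rng_blink)
    ms = _microsaccade_signal(t, script.noise, rng_ms)
    drift = _drift_signal(t, script.noise, rng_drift)

    features = {}
    for eye, tag in (("left", "L"), ("right", "R")):
        e = forward_map.features(g_true, pose, eye)
        e[:, 0:2] += ms + drift
        e[:, 0:2] += rng_tremor.normal(0.0, script.noise.tremor_sd, size=(len(t), 2))
        e[:, 2:4] += rng_corner.normal(0.0, script.noise.corner_sd, size=(len(t), 2))
        e[blink] = np.nan
        features[tag] = e

    frames = pd.DataFrame(
        {
            "t": t,
            "target_id": frame_target,
            "gx": g_true[:, 0],
            "gy": g_true[:, 1],
            "dm": pose[:, 0],
            "dn": pose[:, 1],
            "blink": blink,
            **{
                f"{c}{tag}": features[tag][:, i]
                for tag in ("L", "R")
                for i, c in enumerate(("x", "y", "m", "n"))
            },
        }
    )

    fix_rows = []
    for fid, (tg, sl) in enumerate(fixation_slices):
        chunk = frames.iloc[sl]
        valid_mask = ~chunk["blink"].to_numpy()
        n_frames, n_valid = len(chunk), int(valid_mask.sum())
        row = {
            "fixation_id": fid,
            "target_id": tg.target_id,
            "t_on": tg.onset,
            "t_off": tg.offset,
            "gx": tg.gx,
            "gy": tg.gy,
            "dm": float(np.median(chunk["dm"])),
            "dn": float(np.median(chunk["dn"])),
            "n_frames": n_frames,
            "n_valid": n_valid,
            "valid": n_valid >= 0.5 * n_frames and n_valid >= 1,
        }
        for col in ("xL", "yL", "mL", "nL", "xR", "yR", "mR", "nR"):
            vals = chunk[col].to_numpy()[valid_mask]
            row[col] = float(np.median(vals)) if len(vals) else np.nan
        fix_rows.append(row)

    meta = {
        "seed": script.seed,
        "fps": script.fps,
        "n_targets": len(script.targets),
        "forward_map": type(forward_map).__name__,
        "pose_steps": list(script.pose_steps),
        "pose_drift_sd": script.pose_drift_sd,
        "noise": vars(script.noise).copy() if hasattr(script.noise, "__dict__")
        else {f: getattr(script.noise, f) for f in script.noise.__dataclass_fields__},
        "aspect": display.aspect,
    }
    return SessionRecord(frames=frames, fixations=pd.DataFrame(fix_rows), meta=meta)
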