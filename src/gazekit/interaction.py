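"""Dwell-based gaze interaction: targets, landing zones and triggers.

Interactive targets capture the gaze inside a *landing zone* larger than
their visual shape (ambient fixation); holding the gaze there accumulates
dwell time, the target visually shrinks in proportion, and when the dwell
exceeds the target's threshold its linked event fires — once per dwell
episode.  Requiring a dwell (plus the visual feedback) is what prevents
the Midas-touch problem of gaze interfaces: merely glancing at or sweeping
across a target never activates it.

Every completed selection is also a calibration opportunity: the gaze was,
by construction, on a target with a known center, so the median of the
buffered eye features paired with that center is emitted as a
:class:`~gazekit.model.CalibrationSample` for progressive model refinement.
Landing zones start large (a coarse model must still be usable) and shrink
as calibration samples accumulate; a spike in recent prediction error
temporarily re-expands them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from gazekit.model import CalibrationSample, median_fixation_features

__all__ = [
    "InteractiveTarget",
    "ZoneSchedule",
    "Event",
    "GazeInteractionMachine",
    "load_scene",
]


@dataclass
class InteractiveTarget:
    """A gaze-selectable object on screen (normalized screen units).

    The landing radius must be at least the visual radius; a dwell
    threshold of 0 makes the target an immediate interaction (fires on the
    first in-zone sample).
    """

    id: str
    center: tuple[float, float]
    visual_radius: float = 0.04
    landing_radius: float | None = None
    dwell_threshold: float = 1.5
    linked_event: str = ""
    state: str = "idle"  # idle | hovered | triggered

    def __post_init__(self):
        if self.landing_radius is None:
            self.landing_radius = self.visual_radius
        if self.landing_radius < self.visual_radius:
            raise ValueError("landing radius must be >= visual radius")
        if self.dwell_threshold < 0:
            raise ValueError("dwell threshold must be >= 0")


@dataclass(frozen=True)
class ZoneSchedule:
    """Landing-zone radius as a function of calibration progress.

    The radius shrinks linearly from ``initial_radius`` by
    ``shrink_per_sample`` for each accumulated calibration sample, floored
    at ``min_radius``; while the recent prediction error exceeds
    ``error_trigger`` (percent screen width) the zone re-expands by
    ``expand_factor`` (capped at the initial radius).  Defaults are
    engineering choices read from an external parameter file in a deployed
    system.
    """

    initial_radius: float = 0.12
    min_radius: float = 0.062
    shrink_per_sample: float = 0.004
    error_trigger: float = 8.0
    expand_factor: float = 1.6

    def __post_init__(self):
        if not 0 < self.min_radius <= self.initial_radius:
            raise ValueError("need 0 < min_radius <= initial_radius")

    def landing_radius(self, n_samples: int, recent_error: float | None = None
                       ) -> float:
        if n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        base = max(self.min_radius,
                   self.initial_radius - self.shrink_per_sample * n_samples)
        if recent_error is not None and recent_error > self.error_trigger:
            return min(self.initial_radius, base * self.expand_factor)
        return base


@dataclass(frozen=True)
class Event:
    """UI event emitted by the state machine."""

    kind: str  # hover-enter | dwell-progress | trigger | hover-exit
    target_id: str
    t: float
    shrink_fraction: float = 0.0
    linked_event: str = ""
    sample: CalibrationSample | None = None
    cue: bool = False  # highlight/sound prompt flag on hover-enter


@dataclass
class _DwellState:
    target_id: str
    elapsed: float = 0.0
    missing: float = 0.0
    triggered: bool = False
    buffer_left: list = field(default_factory=list)
    buffer_right: list = field(default_factory=list)
    buffer_valid: list = field(default_factory=list)


class GazeInteractionMachine:
    """Per-frame dwell state machine over a scene of interactive targets.

    ``step`` consumes the current combined gaze point (or None while gaze
    is missing), optional per-eye feature vectors for the calibration
    buffer, and the frame interval ``dt``; it returns the list of events
    fired this frame.  Policies:

    * hover tie-break: when the gaze lies in several landing zones the
      nearest target center wins;
    * dwell reset: leaving the landing zone, or more than
      ``missing_gaze_tolerance`` seconds of missing gaze, resets the dwell
      counter to zero;
    * one trigger per dwell episode; re-arming requires a hover-exit;
    * a trigger emits a calibration sample only when at least half of the
      buffered dwell frames had valid features.
    """

    def __init__(self, targets, schedule: ZoneSchedule | None = None,
                 missing_gaze_tolerance: float = 0.2,
                 min_valid_fraction: float = 0.5):
        self.targets = {tg.id: tg for tg in targets}
        if len(self.targets) != len(list(targets)):
            raise ValueError("duplicate target ids")
        self.schedule = schedule
        self.missing_gaze_tolerance = missing_gaze_tolerance
        self.min_valid_fraction = min_valid_fraction
        self.n_samples = 0
        self.recent_error: float | None = None
        self.t = 0.0
        self._dwell: _DwellState | None = None

    # -------------------------------------------------------------- zones
    def landing_radius(self, target: InteractiveTarget) -> float:
        if self.schedule is None:
            return target.landing_radius
        return max(
            target.visual_radius,
            self.schedule.landing_radius(self.n_samples, self.recent_error),
        )

    def _hit(self, gaze) -> InteractiveTarget | None:
        hits = []
        for tg in self.targets.values():
            d = float(np.hypot(gaze[0] - tg.center[0], gaze[1] - tg.center[1]))
            if d <= self.landing_radius(tg):
                hits.append((d, tg.id))
        if not hits:
            return None
        return self.targets[min(hits)[1]]

    # -------------------------------------------------------------- step
    def step(self, gaze, dt: float, e_left=None, e_right=None,
             valid: bool = True) -> list[Event]:
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.t += dt
        events: list[Event] = []

        if gaze is None or np.any(np.isnan(np.asarray(gaze, dtype=float))):
            if self._dwell is not None:
                self._dwell.missing += dt
                if self._dwell.missing > self.missing_gaze_tolerance:
                    events.append(self._exit_event())
            return events

        hit = self._hit(gaze)
        if self._dwell is not None and (
            hit is None or hit.id != self._dwell.target_id
        ):
            events.append(self._exit_event())
        if hit is None:
            return events

        if self._dwell is None:
            self._dwell = _DwellState(target_id=hit.id)
            hit.state = "hovered"
            events.append(Event("hover-enter", hit.id, self.t, cue=True))

        dw = self._dwell
        dw.missing = 0.0
        if e_left is not None:
            dw.buffer_left.append(np.asarray(e_left, dtype=float))
        if e_right is not None:
            dw.buffer_right.append(np.asarray(e_right, dtype=float))
        dw.buffer_valid.append(bool(valid))

        if dw.triggered:
            return events

        dw.elapsed += dt
        threshold = hit.dwell_threshold
        if threshold > 0:
            frac = min(1.0, dw.elapsed / threshold)
            events.append(Event("dwell-progress", hit.id, self.t,
                                shrink_fraction=frac))
        if dw.elapsed >= threshold:
            events.append(self._trigger(hit))
        return events

    def _exit_event(self) -> Event:
        dw = self._dwell
        tg = self.targets[dw.target_id]
        tg.state = "idle"
        self._dwell = None
        return Event("hover-exit", tg.id, self.t)

    def _trigger(self, target: InteractiveTarget) -> Event:
        dw = self._dwell
        dw.triggered = True
        target.state = "triggered"
        sample = self.on_trigger(target, dw)
        if sample is not None:
            self.n_samples += 1
        return Event("trigger", target.id, self.t, shrink_fraction=1.0,
                     linked_event=target.linked_event, sample=sample)

    def on_trigger(self, target: InteractiveTarget,
                   dwell: _DwellState) -> CalibrationSample | None:
        """Build the calibration sample for a completed selection.

        The gaze target center is taken as ground truth and paired with
        the median of the buffered per-eye features; returns None (event
        still fires) when the buffer misses the validity quota.
        """
        n = len(dwell.buffer_valid)
        if n == 0 or sum(dwell.buffer_valid) < self.min_valid_fraction * n:
            return None
        valid = np.asarray(dwell.buffer_valid, dtype=bool)

        def _median(buf):
            if len(buf) != n:
                return None
            med = median_fixation_features(
                np.asarray(buf), valid, self.min_valid_fraction
            )
            return None if med is None else tuple(med)

        e_left = _median(dwell.buffer_left)
        e_right = _median(dwell.buffer_right)
        if e_left is None and e_right is None:
            return None
        return CalibrationSample(t=self.t, g=tuple(target.center),
                                 e_left=e_left, e_right=e_right)


def load_scene(path) -> list[InteractiveTarget]:
    """Read a scene description (YAML/JSON list of targets)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    targets = []
    for item in data:
        item = dict(item)
        item["center"] = tuple(item["center"])
        targets.append(InteractiveTarget(**item))
    return targets
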