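"""Dwell interaction: triggering, Midas-touch protection, landing zones."""

import numpy as np
import pytest

from gazekit.interaction import (
    Event,
    GazeInteractionMachine,
    InteractiveTarget,
    ZoneSchedule,
    load_scene,
)

DT = 1.0 / 30.0


def make_scene():
    return [
        InteractiveTarget(id="a", center=(0.25, 0.25), visual_radius=0.03,
                          landing_radius=0.08, dwell_threshold=1.0,
                          linked_event="open-menu"),
        InteractiveTarget(id="b", center=(0.75, 0.25), visual_radius=0.03,
                          landing_radius=0.08, dwell_threshold=1.0,
                          linked_event="play"),
    ]


def run_trace(machine, trace, dt=DT, features=None):
    events = []
    for i, gaze in enumerate(trace):
        e = (features[i] if features else (None, None))
        events.extend(machine.step(gaze, dt, e_left=e[0], e_right=e[1]))
    return events


class TestDwellTrigger:
    def test_holding_gaze_for_threshold_triggers_exactly_once(self):
        machine = GazeInteractionMachine(make_scene())
        n = int(2.0 / DT)  # hold well past the 1 s threshold
        events = run_trace(machine, [(0.25, 0.25)] * n)
        kinds = [e.kind for e in events]
        assert kinds.count("trigger") == 1
        assert kinds[0] == "hover-enter"
        trig = next(e for e in events if e.kind == "trigger")
        assert trig.linked_event == "open-menu"

    def test_retrigger_requires_hover_exit(self):
        machine = GazeInteractionMachine(make_scene())
        n = int(2.0 / DT)
        trace = [(0.25, 0.25)] * n + [(0.5, 0.4)] * 10 + [(0.25, 0.25)] * n
        events = run_trace(machine, trace)
        assert [e.kind for e in events].count("trigger") == 2
        assert [e.kind for e in events].count("hover-exit") >= 1

    def test_landing_zone_captures_gaze_outside_visual_radius(self):
        machine = GazeInteractionMachine(make_scene())
        # 0.06 from center: outside visual (0.03), inside landing (0.08)
        events = run_trace(machine, [(0.31, 0.25)] * 3)
        assert events[0].kind == "hover-enter" and events[0].cue

    def test_zero_dwell_threshold_triggers_immediately(self):
        target = InteractiveTarget(id="now", center=(0.5, 0.3),
                                   visual_radius=0.05, dwell_threshold=0.0)
        machine = GazeInteractionMachine([target])
        events = machine.step((0.5, 0.3), DT)
        assert any(e.kind == "trigger" for e in events)

    def test_dwell_progress_reports_shrink_fraction(self):
        machine = GazeInteractionMachine(make_scene())
        events = run_trace(machine, [(0.25, 0.25)] * 15)
        progress = [e.shrink_fraction for e in events
                    if e.kind == "dwell-progress"]
        assert progress == sorted(progress)
        assert 0 < progress[0] < progress[-1] <= 0.5

    def test_missing_gaze_beyond_tolerance_resets_dwell(self):
        machine = GazeInteractionMachine(make_scene())
        half = int(0.5 / DT)
        trace = ([(0.25, 0.25)] * half + [None] * 10  # 333 ms gap
                 + [(0.25, 0.25)] * half)
        events = run_trace(machine, trace)
        # dwell restarted after the gap: total in-zone time per episode < 1 s
        assert not any(e.kind == "trigger" for e in events)

    def test_brief_missing_gaze_is_tolerated(self):
        machine = GazeInteractionMachine(make_scene())
        half = int(0.6 / DT)
        trace = ([(0.25, 0.25)] * half + [None] * 4  # 133 ms < tolerance
                 + [(0.25, 0.25)] * half)
        events = run_trace(machine, trace)
        assert any(e.kind == "trigger" for e in events)

    def test_tie_break_prefers_nearest_center(self):
        scene = [
            InteractiveTarget(id="near", center=(0.50, 0.30),
                              landing_radius=0.2, visual_radius=0.02),
            InteractiveTarget(id="far", center=(0.60, 0.30),
                              landing_radius=0.2, visual_radius=0.02),
        ]
        machine = GazeInteractionMachine(scene)
        events = machine.step((0.52, 0.30), DT)
        assert events[0].target_id == "near"


class TestMidasTouch:
    def test_fast_sweep_across_all_targets_triggers_nothing(self):
        machine = GazeInteractionMachine(make_scene())
        sweep = [(x, 0.25) for x in np.linspace(0.0, 1.0, 20)]  # 0.67 s sweep
        events = run_trace(machine, sweep)
        assert not any(e.kind == "trigger" for e in events)
        assert any(e.kind == "hover-enter" for e in events)

    def test_false_trigger_rate_drops_as_landing_zones_shrink(self):
        # identical random-walk gaze traces against wide vs narrow zones
        rng = np.random.default_rng(11)
        steps = rng.normal(0.0, 0.02, size=(800, 2))
        trace = 0.5 + np.cumsum(steps, axis=0) % 0.4 - 0.2
        trace[:, 1] = np.abs(trace[:, 1]) * 0.5 + 0.05

        def count_triggers(radius):
            scene = [
                InteractiveTarget(id=f"t{i}", center=c, visual_radius=0.02,
                                  landing_radius=radius, dwell_threshold=0.3)
                for i, c in enumerate([(0.4, 0.2), (0.6, 0.2), (0.5, 0.35)])
            ]
            machine = GazeInteractionMachine(scene)
            ev = run_trace(machine, [tuple(g) for g in trace])
            return sum(e.kind == "trigger" for e in ev)

        assert count_triggers(0.062) <= count_triggers(0.12)


class TestZoneSchedule:
    def test_radius_shrinks_with_samples_to_floor(self):
        sched = ZoneSchedule()
        assert sched.landing_radius(0) == sched.initial_radius
        assert sched.landing_radius(1000) == sched.min_radius
        radii = [sched.landing_radius(n) for n in range(0, 40, 5)]
        assert radii == sorted(radii, reverse=True)

    def test_error_spike_reexpands_then_reshrinks(self):
        sched = ZoneSchedule()
        shrunk = sched.landing_radius(10, recent_error=2.0)
        spiked = sched.landing_radius(10, recent_error=20.0)
        assert spiked > shrunk
        assert spiked <= sched.initial_radius
        # accumulating more samples shrinks the zone again
        assert sched.landing_radius(30, recent_error=2.0) < spiked

    def test_radius_always_within_bounds(self):
        sched = ZoneSchedule()
        for n in range(0, 200, 7):
            for err in (None, 0.0, 50.0):
                r = sched.landing_radius(n, err)
                assert sched.min_radius <= r <= sched.initial_radius

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            ZoneSchedule(initial_radius=0.05, min_radius=0.08)


class TestCalibrationEmission:
    def feature_trace(self, n, valid_from=0):
        feats = []
        for i in range(n):
            e = np.array([10.0, -5.0, 400.0, 300.0])
            feats.append((e, e + [0.5, 0, -180, 2]))
        return feats

    def test_trigger_emits_sample_at_target_center(self):
        target = InteractiveTarget(id="c", center=(0.25, 0.4),
                                   visual_radius=0.05, dwell_threshold=0.3)
        machine = GazeInteractionMachine([target])
        feats = self.feature_trace(15)
        events = run_trace(machine, [(0.25, 0.4)] * 15, features=feats)
        trig = next(e for e in events if e.kind == "trigger")
        assert trig.sample is not None
        assert trig.sample.g == (0.25, 0.4)
        assert trig.sample.e_left == pytest.approx((10.0, -5.0, 400.0, 300.0))
        assert machine.n_samples == 1

    def test_mostly_blinked_dwell_fires_event_without_sample(self):
        target = InteractiveTarget(id="c", center=(0.25, 0.4),
                                   visual_radius=0.05, dwell_threshold=0.3)
        machine = GazeInteractionMachine([target])
        events = []
        for i in range(15):
            # 60% of frames invalid
            events.extend(machine.step((0.25, 0.4), DT,
                                       e_left=[10, -5, 400, 300],
                                       valid=(i % 5 >= 3)))
        trig = next(e for e in events if e.kind == "trigger")
        assert trig.sample is None
        assert machine.n_samples == 0

    def test_scripted_session_grows_model_by_at_most_one_per_trigger(self):
        target = InteractiveTarget(id="c", center=(0.5, 0.3),
                                   visual_radius=0.05, dwell_threshold=0.2)
        machine = GazeInteractionMachine([target])
        triggers = samples = 0
        for episode in range(20):
            for _ in range(10):
                for e in machine.step((0.5, 0.3), DT,
                                      e_left=[1, 2, 400, 300]):
                    if e.kind == "trigger":
                        triggers += 1
                        samples += e.sample is not None
            machine.step((0.9, 0.5), DT)  # hover exit between episodes
        assert triggers == 20
        assert samples <= 20
        assert machine.n_samples == samples


def test_scene_roundtrip_from_yaml(tmp_path):
    path = tmp_path / "scene.yaml"
    path.write_text(
        "- id: play\n  center: [0.7, 0.3]\n  visual_radius: 0.04\n"
        "  landing_radius: 0.1\n  dwell_threshold: 1.5\n"
        "  linked_event: start-game\n"
    )
    scene = load_scene(path)
    assert scene[0].id == "play"
    assert scene[0].center == (0.7, 0.3)
    assert scene[0].landing_radius == 0.1
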