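"""Stepwise evaluation protocols: regression, prediction and fixed errors.

The data of a session is processed stepwise.  The first ``n_initial``
fixation events form the initial calibration; then, at each subsequent
event ``t``:

* the *regression* estimate uses a model fit on all events up to and
  including ``t`` (in-sample),
* the *prediction* estimate uses the model fit on events up to ``t - 1``
  only (out-of-sample, the quantity the user actually experiences),
* the *fixed* estimate uses the initial calibration set alone, never
  updated.

Each estimate is compared with the true target location and expressed as a
percentage of the screen width.  Head displacement between consecutive
fixation events is tracked from the eye-corner medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gazekit.geometry import DisplayGeometry, error_percent_width
from gazekit.model import BinocularGazeEstimator, get_spec
from gazekit.session import SessionRecord

__all__ = [
    "stepwise_errors",
    "percentile_error",
    "compare_models",
    "head_displacement",
    "StepwiseResult",
    "group_accuracy_experiment",
    "provocation_experiment",
]


@dataclass
class StepwiseResult:
    """Per-event stepwise errors for one session and one model spec."""

    events: pd.DataFrame
    spec_name: str
    n_initial: int

    @property
    def mean_regression_error(self) -> float:
        return float(np.nanmean(self.events["regression_error"]))

    @property
    def mean_prediction_error(self) -> float:
        return float(np.nanmean(self.events["prediction_error"]))

    @property
    def mean_fixed_error(self) -> float:
        return float(np.nanmean(self.events["fixed_error"]))


def _binocular_fit(spec, XL, XR, G, rows) -> BinocularGazeEstimator:
    est = BinocularGazeEstimator(spec=spec)
    est.fit(XL[rows], XR[rows], G[rows])
    return est


def stepwise_errors(
    session: SessionRecord,
    spec="quadratic_pupil_linear_corner",
    n_initial: int = 9,
    display: DisplayGeometry | None = None,
) -> StepwiseResult:
    """Stepwise regression / prediction / fixed-model errors for a session.

    Only fixations meeting the validity quota participate.  Events where
    the prediction model is not yet determined (fewer prior rows than
    coefficients) have NaN prediction error and are flagged; likewise the
    regression and fixed estimates are NaN until enough rows exist (the
    fixed model needs ``n_initial >= n_terms``).  Errors are percentages
    of the screen width; ``head_displacement`` is the corner movement (px)
    since the previous event, averaged over the two eyes.
    """
    spec = get_spec(spec)
    XL, XR = session.features("left"), session.features("right")
    G = session.targets()
    K = len(G)
    if K < n_initial + 1:
        raise ValueError(
            f"session has {K} valid fixation events; "
            f"need at least n_initial + 1 = {n_initial + 1}"
        )

    import warnings as _warnings

    with _warnings.catch_warnings():
        # constant head pose during calibration makes corner columns
        # collinear with the constant term; minimum-norm fit is intended
        _warnings.simplefilter("ignore", RuntimeWarning)
        fixed = (
            _binocular_fit(spec, XL, XR, G, slice(0, n_initial))
            if n_initial >= spec.n_terms
            else None
        )

        corners = 0.5 * (
            session.valid_fixations()[["mL", "nL"]].to_numpy()
            + session.valid_fixations()[["mR", "nR"]].to_numpy()
        )
        rows = []
        for t_idx in range(n_initial, K):
            if t_idx + 1 >= spec.n_terms:
                reg_est = _binocular_fit(spec, XL, XR, G, slice(0, t_idx + 1))
                g_reg = reg_est.predict(XL[[t_idx]], XR[[t_idx]])[0]
                reg_err = float(error_percent_width(g_reg, G[t_idx])[0])
            else:
                reg_err = np.nan
            if t_idx >= spec.n_terms:
                pred_est = _binocular_fit(spec, XL, XR, G, slice(0, t_idx))
                g_pred = pred_est.predict(XL[[t_idx]], XR[[t_idx]])[0]
                pred_err = float(error_percent_width(g_pred, G[t_idx])[0])
                pred_defined = True
            else:
                pred_err, pred_defined = np.nan, False
            if fixed is not None:
                g_fix = fixed.predict(XL[[t_idx]], XR[[t_idx]])[0]
                fix_err = float(error_percent_width(g_fix, G[t_idx])[0])
            else:
                fix_err = np.nan
            rows.append(
                {
                    "event": t_idx,
                    "t": float(session.valid_fixations()["t_on"].iloc[t_idx]),
                    "target_id": int(
                        session.valid_fixations()["target_id"].iloc[t_idx]
                    ),
                    "regression_error": reg_err,
                    "prediction_error": pred_err,
                    "prediction_defined": pred_defined,
                    "fixed_error": fix_err,
                    "head_displacement": float(
                        np.linalg.norm(corners[t_idx] - corners[t_idx - 1])
                    ),
                    "head_displacement_abs": float(
                        np.linalg.norm(corners[t_idx] - corners[0])
                    ),
                }
            )
    return StepwiseResult(
        events=pd.DataFrame(rows), spec_name=spec.name, n_initial=n_initial
    )


def percentile_error(errors, q: float) -> float:
    """Empirical q-th percentile (linear interpolation between order stats)."""
    errors = np.asarray(errors, dtype=float)
    errors = errors[~np.isnan(errors)]
    if errors.size == 0:
        raise ValueError("empty error list")
    if not 0.0 < q < 100.0:
        raise ValueError("q must be in (0, 100)")
    return float(np.percentile(errors, q, method="linear"))


def compare_models(
    session: SessionRecord,
    specs=("quadratic_pupil", "quadratic_pupil_linear_corner",
           "cubic_pupil_linear_corner", "full_quadratic"),
    n_initial: int = 15,
    display: DisplayGeometry | None = None,
) -> pd.DataFrame:
    """Mean regression and prediction error per candidate model spec.

    Runs the stepwise protocol for each spec on the same session and
    tabulates the trial means.  Specs whose coefficient count exceeds the
    available events are flagged and excluded from the argmin columns.
    The returned frame carries ``best_regression`` / ``best_prediction``
    attrs naming the winning spec of each column.
    """
    n_events = len(session.targets())
    rows = []
    for spec in specs:
        spec = get_spec(spec)
        if n_events < max(spec.n_terms, n_initial) + 1:
            rows.append(
                {
                    "spec": spec.name,
                    "n_terms": spec.n_terms,
                    "mean_regression_error": np.nan,
                    "mean_prediction_error": np.nan,
                    "included": False,
                }
            )
            continue
        res = stepwise_errors(session, spec, n_initial=n_initial, display=display)
        rows.append(
            {
                "spec": spec.name,
                "n_terms": spec.n_terms,
                "mean_regression_error": res.mean_regression_error,
                "mean_prediction_error": res.mean_prediction_error,
                "included": True,
            }
        )
    table = pd.DataFrame(rows)
    ok = table[table["included"]]
    if len(ok):
        table.attrs["best_regression"] = ok.loc[
            ok["mean_regression_error"].idxmin(), "spec"
        ]
        table.attrs["best_prediction"] = ok.loc[
            ok["mean_prediction_error"].idxmin(), "spec"
        ]
    return table


def head_displacement(session: SessionRecord, mode: str = "relative") -> np.ndarray:
    """Head displacement per fixation event from the corner medians (px).

    ``relative``: Euclidean distance between consecutive fixation-median
    corner positions. ``absolute``: distance from the pose at the first
    fixation event (the provocation-analysis variant).
    """
    fx = session.valid_fixations()
    corners = 0.5 * (
        fx[["mL", "nL"]].to_numpy(dtype=float)
        + fx[["mR", "nR"]].to_numpy(dtype=float)
    )
    if len(corners) < 2:
        raise ValueError("need at least 2 fixation events")
    if mode == "relative":
        return np.linalg.norm(np.diff(corners, axis=0), axis=1)
    if mode == "absolute":
        return np.linalg.norm(corners - corners[0], axis=1)
    raise ValueError("mode must be 'relative' or 'absolute'")


# ------------------------------------------------------------------ harnesses
def group_accuracy_experiment(
    n_subjects: int = 5,
    n_targets: int = 60,
    seed: int = 0,
    spec="quadratic_pupil_linear_corner",
    pose_drift_sd: float = 2.0,
    full_scale: bool = False,
) -> dict:
    """Group accuracy protocol over several synthetic subjects.

    Each subject completes a 9-point, 3 s calibration followed by
    ``n_targets`` sequential test targets (``full_scale=True`` restores
    the 13-subject x 180-target layout) while the head pose drifts.  The
    stepwise protocol pools per-event prediction and fixed-model errors
    across subjects; the headline statistics are the pooled 95th
    percentiles of both and the relative head displacement distribution.
    """
    from gazekit.synth import generate_gaze_session, make_accuracy_script

    if full_scale:
        n_subjects, n_targets = 13, 180
    ss = np.random.SeedSequence(seed)
    subject_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_subjects)]

    per_subject = []
    pred_all, fixed_all, disp_all = [], [], []
    for sid, sseed in enumerate(subject_seeds):
        script = make_accuracy_script(n_targets=n_targets,
                                      pose_drift_sd=pose_drift_sd, seed=sseed)
        session = generate_gaze_session(script)
        res = stepwise_errors(session, spec, n_initial=9)
        ev = res.events
        pred_all.append(ev["prediction_error"].to_numpy())
        fixed_all.append(ev["fixed_error"].to_numpy())
        disp_all.append(ev["head_displacement"].to_numpy())
        per_subject.append(
            {
                "subject": sid,
                "seed": sseed,
                "mae_prediction": float(np.nanmean(ev["prediction_error"])),
                "mae_regression": float(ev["regression_error"].mean()),
                "mae_fixed": float(ev["fixed_error"].mean()),
                "p95_prediction": percentile_error(ev["prediction_error"], 95),
                "p95_fixed": percentile_error(ev["fixed_error"], 95),
            }
        )
    pred = np.concatenate(pred_all)
    fixed = np.concatenate(fixed_all)
    disp = np.concatenate(disp_all)
    return {
        "per_subject": pd.DataFrame(per_subject),
        "prediction_errors": pred,
        "fixed_errors": fixed,
        "head_displacements": disp,
        "p95_prediction": percentile_error(pred, 95),
        "p95_fixed": percentile_error(fixed, 95),
        "p95_head_displacement_px": percentile_error(disp, 95),
    }


def provocation_experiment(
    seed: int = 0,
    n_targets: int = 40,
    spike_event: int = 20,
    spike_offset: tuple[float, float] = (22.0, -16.0),
    spec="quadratic_pupil_linear_corner",
    recovery_window: int = 10,
) -> dict:
    """Provocation protocol: a deliberate large head movement mid-session.

    Measures the per-event prediction error before the scripted pose
    spike (baseline), at the spike, and the number of events until the
    error returns under twice the baseline — quantifying how quickly
    progressive calibration recovers from sudden extreme motion.
    """
    from gazekit.synth import generate_gaze_session, make_provocation_script

    script = make_provocation_script(n_targets=n_targets,
                                     spike_event=spike_event,
                                     spike_offset=spike_offset, seed=seed)
    session = generate_gaze_session(script)
    res = stepwise_errors(session, spec, n_initial=9)
    ev = res.events.reset_index(drop=True)

    pred = ev["prediction_error"].to_numpy()
    spike_idx = spike_event
    baseline = float(np.nanmedian(pred[:spike_idx]))
    spike_error = float(pred[spike_idx])
    recovered_after = None
    for k in range(spike_idx + 1, min(spike_idx + 1 + recovery_window, len(pred))):
        if pred[k] <= 2.0 * baseline:
            recovered_after = k - spike_idx
            break
    return {
        "events": ev,
        "baseline_error": baseline,
        "spike_error": spike_error,
        "recovered_after_events": recovered_after,
        "abs_head_displacement": head_displacement(session, mode="absolute"),
        "p95_prediction": percentile_error(pred, 95),
    }
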