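"""Session records: time-stamped logs of truth, features and fixations.

A :class:`SessionRecord` is the common currency between the synthetic-data
generator, the vision front end and the evaluation protocols.  It holds a
per-frame table (ground-truth gaze, head pose, blink state and per-eye
features) and a per-fixation table (median features per target fixation),
and round-trips to plain-text files: JSON-lines for frames, CSV for
fixations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FRAME_COLUMNS = [
    "t",
    "target_id",
    "gx",
    "gy",
    "dm",
    "dn",
    "blink",
    "xL",
    "yL",
    "mL",
    "nL",
    "xR",
    "yR",
    "mR",
    "nR",
]

FIXATION_COLUMNS = [
    "fixation_id",
    "target_id",
    "t_on",
    "t_off",
    "gx",
    "gy",
    "dm",
    "dn",
    "n_frames",
    "n_valid",
    "valid",
    "xL",
    "yL",
    "mL",
    "nL",
    "xR",
    "yR",
    "mR",
    "nR",
]


@dataclass
class SessionRecord:
    """Frame-level and fixation-level log of one gaze session.

    Attributes
    ----------
    frames : pandas.DataFrame
        One row per video frame with ground truth (``gx, gy`` normalized
        screen units; ``dm, dn`` head-pose offset in camera pixels; blink
        flag) and the measured per-eye features ``(x, y, m, n)``.
    fixations : pandas.DataFrame
        One row per fixation event: its target, onset/offset, the median
        per-eye features over valid frames, and whether the fixation met
        the >= 50% valid-frame quota required to emit a calibration sample.
    meta : dict
        Script parameters, seed and generator configuration.
    """

    frames: pd.DataFrame
    fixations: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def n_fixations(self) -> int:
        return len(self.fixations)

    def valid_fixations(self) -> pd.DataFrame:
        return self.fixations[self.fixations["valid"]].reset_index(drop=True)

    def features(self, eye: str) -> np.ndarray:
        """Fixation-median feature matrix (K, 4) for 'left' or 'right'."""
        cols = {"left": ["xL", "yL", "mL", "nL"], "right": ["xR", "yR", "mR", "nR"]}[eye]
        return self.valid_fixations()[cols].to_numpy(dtype=float)

    def targets(self) -> np.ndarray:
        """Fixation target centers (K, 2) in normalized screen units."""
        return self.valid_fixations()[["gx", "gy"]].to_numpy(dtype=float)

    # -------------------------------------------------- serialization
    def save(self, directory) -> None:
        """Write frames as JSON-lines, fixations as CSV, meta as JSON."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "frames.jsonl", "w") as fh:
            for rec in self.frames.to_dict(orient="records"):
                fh.write(json.dumps(rec) + "\n")
        self.fixations.to_csv(directory / "fixations.csv", index=False)
        with open(directory / "meta.json", "w") as fh:
            json.dump(self.meta, fh, indent=2, default=str)

    @classmethod
    def load(cls, directory) -> "SessionRecord":
        directory = Path(directory)
        with open(directory / "frames.jsonl") as fh:
            frames = pd.DataFrame([json.loads(line) for line in fh if line.strip()])
        fixations = pd.read_csv(directory / "fixations.csv")
        meta_path = directory / "meta.json"
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(frames=frames, fixations=fixations, meta=meta)
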