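"""Display geometry: normalized screen coordinates and the error metric.

Screen coordinates are normalized so the display width is exactly 1 with the
origin at the top-left corner; the vertical extent is ``aspect`` (height /
width).  All gaze errors are Euclidean distances in this system, reported as
percentages of the screen width — a dimensionless accuracy measure that does
not depend on projector resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml


@dataclass(frozen=True)
class DisplayGeometry:
    """Normalized display region ``[0, 1] x [0, aspect]``.

    Parameters
    ----------
    aspect : float
        Height of the display divided by its width. Default 9/16.
    width_px : int, optional
        Physical horizontal resolution; only used when converting
        normalized errors to pixels for reporting.
    """

    aspect: float = 9.0 / 16.0
    width_px: int | None = None

    def __post_init__(self) -> None:
        if self.aspect <= 0:
            raise ValueError("aspect must be positive")

    def contains(self, g) -> np.ndarray:
        g = np.atleast_2d(np.asarray(g, dtype=float))
        return (
            (g[:, 0] >= 0.0)
            & (g[:, 0] <= 1.0)
            & (g[:, 1] >= 0.0)
            & (g[:, 1] <= self.aspect)
        )

    @property
    def center(self) -> tuple[float, float]:
        return (0.5, self.aspect / 2.0)

    @classmethod
    def from_yaml(cls, path) -> "DisplayGeometry":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(**cfg)


def error_percent_width(g_est, g_true) -> np.ndarray:
    """Euclidean gaze error as a percentage of the screen width.

    Both arguments are in normalized screen units (width = 1), so the
    distance itself is a screen-width fraction; the result is that fraction
    times 100.  Invariant under any joint rescaling of both coordinates.
    """
    g_est = np.asarray(g_est, dtype=float)
    g_true = np.asarray(g_true, dtype=float)
    return 100.0 * np.linalg.norm(np.atleast_2d(g_est - g_true), axis=-1)
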