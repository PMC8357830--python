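"""Eye-video front end: pupil segmentation and eye-corner tracking.

Per frame, two quantities are extracted from each eye camera: the pupil
center ``(px, py)`` — adaptive intensity thresholding, morphology, contour
extraction and ellipse fitting inside the eye-region box — and the inner
eye-corner position ``(m, n)`` tracked with a correlation tracker.  The
relative pupil coordinates are ``x = px - m`` and ``y = py - n`` exactly,
yielding the 4D feature vector ``e = (x, y, m, n)`` consumed by the gaze
model.  Pixel coordinates: origin top-left, x rightward, y downward; all
boxes are half-open integer rectangles.

The corner tracker backend is pluggable; the baseline is normalized
cross-correlation template matching with sub-pixel peak interpolation —
a member of the correlation-filter family whose contract (track a
translating landmark within 2 px) is what the system needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import binary_closing, binary_opening
from skimage.feature import match_template
from skimage.measure import EllipseModel, find_contours, label, regionprops

__all__ = [
    "Rect",
    "PupilDetection",
    "PupilConfig",
    "segment_pupil",
    "CornerTrack",
    "NCCTracker",
    "init_corner_tracker",
    "update_corner_tracker",
    "EyeFeatures",
    "extract_features",
    "track_video",
]


@dataclass(frozen=True)
class Rect:
    """Half-open integer rectangle [x0, x1) x [y0, y1)."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self):
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError("empty rectangle")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)

    def contains_point(self, p) -> bool:
        return self.x0 <= p[0] < self.x1 and self.y0 <= p[1] < self.y1

    def inside(self, shape) -> bool:
        h, w = shape[:2]
        return 0 <= self.x0 and 0 <= self.y0 and self.x1 <= w and self.y1 <= h

    def crop(self, img: np.ndarray) -> np.ndarray:
        return img[self.y0 : self.y1, self.x0 : self.x1]

    def translated(self, dx: int, dy: int) -> "Rect":
        return Rect(self.x0 + dx, self.y0 + dy, self.x1 + dx, self.y1 + dy)

    @classmethod
    def centered(cls, center, width, height) -> "Rect":
        x0 = int(round(center[0] - width / 2.0))
        y0 = int(round(center[1] - height / 2.0))
        return cls(x0, y0, x0 + int(width), y0 + int(height))


# ------------------------------------------------------------------ pupil
@dataclass(frozen=True)
class PupilConfig:
    """Acceptance bounds that reject non-pupil dark blobs and highlights."""

    quantile_fallback: float = 0.05
    min_area: float = 150.0
    max_area: float = 30000.0
    max_axis_ratio: float = 3.0
    max_fit_residual: float = 2.0  # px, mean distance of edge to ellipse
    morphology_size: int = 2


@dataclass(frozen=True)
class PupilDetection:
    """Fitted pupil ellipse; ``valid`` is False on blink/occlusion."""

    center: tuple[float, float] | None
    axes: tuple[float, float] | None
    angle: float | None
    valid: bool
    residual: float | None = None


_INVALID = PupilDetection(None, None, None, False)


def _adaptive_threshold(pixels: np.ndarray, quantile: float) -> float:
    """Histogram valley below the darkest mode; quantile fallback.

    The pupil is the darkest structure in the eye region, so the gray-level
    histogram has a distinct dark mode.  The threshold is placed at the
    first valley after that mode; when no clear valley exists the given
    low quantile of the intensity distribution is used instead.
    """
    hist, edges = np.histogram(pixels, bins=64, range=(0, 255))
    smooth = np.convolve(hist, np.ones(5) / 5.0, mode="same")
    peaks = [
        i
        for i in range(1, 63)
        if smooth[i] >= smooth[i - 1] and smooth[i] >= smooth[i + 1]
        and smooth[i] > 0
    ]
    if peaks:
        dark_mode = peaks[0]
        for i in range(dark_mode + 1, 63):
            if smooth[i] <= smooth[i - 1] and smooth[i] <= smooth[i + 1]:
                valley = edges[i + 1]
                # valley must separate the dark mode from brighter content
                if np.any(pixels > valley):
                    return float(valley)
                break
    return float(np.quantile(pixels, quantile))


def segment_pupil(frame: np.ndarray, region: Rect,
                  config: PupilConfig | None = None) -> PupilDetection:
    """Detect the pupil ellipse inside the eye-region box.

    Thresholding, morphological opening/closing, contour extraction and
    least-squares ellipse fitting.  Returns ``valid=False`` (never raises)
    when no acceptable dark elliptical blob exists — the blink case.

    Raises ``ValueError`` only for a region that lies outside the frame.
    """
    cfg = config or PupilConfig()
    if not region.inside(frame.shape):
        raise ValueError("eye region lies outside the frame")
    crop = region.crop(np.asarray(frame, dtype=float))

    thr = _adaptive_threshold(crop.ravel(), cfg.quantile_fallback)
    mask = crop < thr
    k = np.ones((cfg.morphology_size * 2 + 1,) * 2, dtype=bool)
    mask = binary_closing(binary_opening(mask, k), k)
    if not mask.any():
        return _INVALID

    labels = label(mask)
    best = None
    for prop in regionprops(labels):
        if not cfg.min_area <= prop.area <= cfg.max_area:
            continue
        if prop.axis_minor_length < 1e-6:
            continue
        if prop.axis_major_length / prop.axis_minor_length > cfg.max_axis_ratio:
            continue
        if best is None or prop.area > best.area:
            best = prop
    if best is None:
        return _INVALID

    blob = labels == best.label
    contours = find_contours(blob.astype(float), 0.5)
    if not contours:
        return _INVALID
    contour = max(contours, key=len)  # (row, col) sub-pixel points
    pts = np.column_stack([contour[:, 1], contour[:, 0]])  # -> (x, y)

    model = EllipseModel.from_estimate(pts)
    if not model:
        return _INVALID
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not np.all(np.isfinite([xc, yc, a, b, theta])) or a <= 0 or b <= 0:
        return _INVALID
    axes = (max(a, b), min(a, b))
    if axes[0] / axes[1] > cfg.max_axis_ratio:
        return _INVALID
    residual = float(np.sqrt(np.mean(model.residuals(pts) ** 2)))
    if residual > cfg.max_fit_residual:
        return _INVALID
    center = (float(xc + region.x0), float(yc + region.y0))
    if not region.contains_point(center):
        return _INVALID
    return PupilDetection(center=center, axes=(float(axes[0]), float(axes[1])),
                          angle=float(theta), valid=True, residual=residual)


# ------------------------------------------------------------------ corner
class NCCTracker:
    """Normalized cross-correlation template tracker with sub-pixel peak.

    A fixed-size template around the landmark is matched within a search
    window each frame; the correlation peak is refined by quadratic
    interpolation.  The template is updated by a slow exponential moving
    average, but only on confident matches, so brief occlusions do not
    corrupt it.  Confidence below ``min_confidence`` flags the target lost
    and the last position is held.
    """

    def __init__(self, template_size: int = 32, search_radius: int = 20,
                 min_confidence: float = 0.5, template_alpha: float = 0.02):
        self.template_size = template_size
        self.search_radius = search_radius
        self.min_confidence = min_confidence
        self.template_alpha = template_alpha

    def start(self, frame: np.ndarray, point) -> None:
        self.point = (float(point[0]), float(point[1]))
        self.template = self._patch(frame, self.point).astype(float)
        self.confidence = 1.0
        self.lost = False

    def _patch(self, frame, center):
        box = Rect.centered(center, self.template_size, self.template_size)
        if not box.inside(frame.shape):
            raise ValueError("template box outside frame")
        return box.crop(np.asarray(frame, dtype=float))

    def update(self, frame: np.ndarray) -> tuple[tuple[float, float], float]:
        frame = np.asarray(frame, dtype=float)
        half = self.template_size // 2
        r = self.search_radius
        cx, cy = self.point
        h, w = frame.shape
        x0 = int(np.clip(round(cx) - half - r, 0, w - self.template_size))
        y0 = int(np.clip(round(cy) - half - r, 0, h - self.template_size))
        x1 = int(np.clip(round(cx) + half + r, self.template_size, w))
        y1 = int(np.clip(round(cy) + half + r, self.template_size, h))
        window = frame[y0:y1, x0:x1]
        ncc = match_template(window, self.template)
        iy, ix = np.unravel_index(np.argmax(ncc), ncc.shape)
        peak = float(ncc[iy, ix])
        dx = _subpixel_offset(ncc, iy, ix, axis=1)
        dy = _subpixel_offset(ncc, iy, ix, axis=0)
        new_point = (x0 + ix + dx + half, y0 + iy + dy + half)

        self.confidence = peak
        if peak < self.min_confidence:
            self.lost = True  # hold last position
            return self.point, peak
        self.lost = False
        self.point = (float(new_point[0]), float(new_point[1]))
        if self.template_alpha > 0 and peak > 0.9:
            try:
                current = self._patch(frame, self.point)
                a = self.template_alpha
                self.template = (1 - a) * self.template + a * current
            except ValueError:
                pass
        return self.point, peak


def _subpixel_offset(ncc, iy, ix, axis):
    idx = [iy, ix]
    if not 0 < idx[axis] < ncc.shape[axis] - 1:
        return 0.0
    lo, hi = list(idx), list(idx)
    lo[axis] -= 1
    hi[axis] += 1
    y0, y1, y2 = ncc[tuple(lo)], ncc[iy, ix], ncc[tuple(hi)]
    denom = y0 - 2 * y1 + y2
    if abs(denom) < 1e-12:
        return 0.0
    return float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))


@dataclass
class CornerTrack:
    """Tracked inner eye corner plus the derived bounding boxes.

    ``corner_box`` is centered on the current corner estimate ``(m, n)``;
    ``eye_region`` spans inner to outer corner with a fixed aspect ratio
    and translates rigidly with the corner.
    """

    point: tuple[float, float]
    corner_box: Rect
    eye_region: Rect
    backend: object
    lost: bool = False
    confidence: float = 1.0

    @property
    def m(self) -> float:
        return self.point[0]

    @property
    def n(self) -> float:
        return self.point[1]


def init_corner_tracker(
    frame: np.ndarray,
    inner_corner,
    outer_corner,
    corner_box_size: int = 32,
    aspect: float = 4.0 / 3.0,
    margin: float = 0.3,
    inner_side: str = "right",
    order: str = "auto",
    backend=None,
) -> CornerTrack:
    """Initialize corner tracking from two operator-supplied marks.

    The eye-region box spans the horizontal extent between the marks,
    inflated by ``margin`` and given a fixed width:height ``aspect``; the
    marking need not be pixel-accurate because the corner landmark is a
    textured region rather than a point feature.  ``inner_side`` states on
    which side of the outer corner the inner mark lies ("right" for a
    left-eye camera); with ``order="auto"`` swapped marks are corrected,
    with ``order="strict"`` they raise.
    """
    inner = (float(inner_corner[0]), float(inner_corner[1]))
    outer = (float(outer_corner[0]), float(outer_corner[1]))
    if np.hypot(inner[0] - outer[0], inner[1] - outer[1]) < 1e-9:
        raise ValueError("inner and outer corner marks coincide")
    wrong_order = (inner[0] < outer[0]) if inner_side == "right" else (
        inner[0] > outer[0]
    )
    if wrong_order:
        if order == "strict":
            raise ValueError("inner/outer corner marks appear swapped")
        inner, outer = outer, inner

    h, w = np.asarray(frame).shape[:2]
    if not (0 <= inner[0] < w and 0 <= inner[1] < h
            and 0 <= outer[0] < w and 0 <= outer[1] < h):
        raise ValueError("corner marks must lie inside the frame")

    span = abs(inner[0] - outer[0])
    region_w = span * (1.0 + margin)
    region_h = region_w / aspect
    mid = ((inner[0] + outer[0]) / 2.0, (inner[1] + outer[1]) / 2.0)
    eye_region = Rect.centered(mid, region_w, region_h)

    backend = backend or NCCTracker()
    backend.start(frame, inner)
    corner_box = Rect.centered(inner, corner_box_size, corner_box_size)
    return CornerTrack(point=inner, corner_box=corner_box,
                       eye_region=eye_region, backend=backend)


def update_corner_tracker(track: CornerTrack, frame: np.ndarray) -> CornerTrack:
    """Advance the corner track by one frame (returns the same object).

    On low-confidence matches (occlusion) the position is held and
    ``lost`` is set; boxes translate with the integer part of the motion.
    """
    old = track.point
    point, conf = track.backend.update(frame)
    track.confidence = conf
    track.lost = getattr(track.backend, "lost", False)
    if not track.lost:
        dx = int(round(point[0] - old[0]))
        dy = int(round(point[1] - old[1]))
        track.point = point
        track.corner_box = Rect.centered(point, track.corner_box.width,
                                         track.corner_box.height)
        if dx or dy:
            track.eye_region = track.eye_region.translated(dx, dy)
    return track


# ------------------------------------------------------------------ features
@dataclass(frozen=True)
class EyeFeatures:
    """Per-frame 4D feature vector ``e = (x, y, m, n)``.

    ``x = px - m`` and ``y = py - n`` hold exactly; an invalid pupil
    propagates as ``valid=False`` with NaN pupil-dependent entries.
    """

    t: float
    x: float
    y: float
    m: float
    n: float
    valid: bool = True

    @property
    def e(self) -> np.ndarray:
        return np.array([self.x, self.y, self.m, self.n])


def extract_features(pupil: PupilDetection, track: CornerTrack,
                     t: float) -> EyeFeatures:
    """Assemble the feature vector from a pupil detection and corner track."""
    if not pupil.valid:
        return EyeFeatures(t=t, x=np.nan, y=np.nan,
                           m=track.m, n=track.n, valid=False)
    px, py = pupil.center
    return EyeFeatures(t=t, x=px - track.m, y=py - track.n,
                       m=track.m, n=track.n, valid=True)


def track_video(frames, inner_corner, outer_corner, fps: float = 30.0,
                pupil_config: PupilConfig | None = None,
                **init_kwargs) -> pd.DataFrame:
    """Run the full front end over a frame sequence.

    Returns a per-frame log with columns t, px, py, m, n, x, y, valid —
    the CSV layout written per eye.
    """
    rows = []
    track = None
    for i, frame in enumerate(frames):
        frame = np.asarray(frame)
        if track is None:
            track = init_corner_tracker(frame, inner_corner, outer_corner,
                                        **init_kwargs)
        else:
            update_corner_tracker(track, frame)
        pupil = segment_pupil(frame, track.eye_region, pupil_config)
        feats = extract_features(pupil, track, t=i / fps)
        px, py = pupil.center if pupil.valid else (np.nan, np.nan)
        rows.append(
            {
                "t": feats.t,
                "px": px,
                "py": py,
                "m": feats.m,
                "n": feats.n,
                "x": feats.x,
                "y": feats.y,
                "valid": feats.valid,
                "tracker_lost": track.lost,
            }
        )
    return pd.DataFrame(rows)
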