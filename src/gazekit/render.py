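"""Rendering of synthetic eye-camera frames and table-camera videos.

Grayscale only, and deliberately simple: a dark elliptical pupil inside a
darker iris disc on a light sclera, ripple-textured landmarks at the inner
and outer eye corners, an eyelid fill for blinks, and optional bright-disc
specular distractors.  All structures are evaluated analytically on the
pixel grid, so sub-pixel positions are rendered faithfully and the reported
ground truth always equals the parameters used to draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

__all__ = [
    "EyeRenderConfig",
    "render_eye_frame",
    "render_session_frames",
    "generate_table_video",
    "make_table_mask",
]


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


@dataclass(frozen=True)
class EyeRenderConfig:
    """Appearance parameters of the rendered eye image (grayscale 0-255)."""

    shape: tuple[int, int] = (480, 640)  # rows, cols
    sclera_value: float = 200.0
    iris_value: float = 115.0
    pupil_value: float = 28.0
    lid_value: float = 175.0
    iris_radius: float = 60.0
    pupil_axes: tuple[float, float] = (40.0, 30.0)
    pupil_angle: float = 0.0
    edge_softness: float = 1.5
    corner_texture_amp: float = 55.0
    corner_texture_sigma: float = 7.0
    corner_texture_period: float = 6.5
    outer_corner_offset: tuple[float, float] = (-240.0, -5.0)
    noise_sd: float = 2.0


def _ellipse_alpha(X, Y, center, axes, angle, softness):
    a, b = axes
    ca, sa = np.cos(angle), np.sin(angle)
    dx, dy = X - center[0], Y - center[1]
    xr = dx * ca + dy * sa
    yr = -dx * sa + dy * ca
    # approximate signed distance to the ellipse boundary in px
    r = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)
    dist = (r - 1.0) * min(a, b)
    return _smoothstep(0.5 - dist / max(softness, 1e-6))


def _corner_pattern(X, Y, center, cfg: EyeRenderConfig):
    """Concentric-ripple landmark centered (sub-pixel) on ``center``."""
    r = np.hypot(X - center[0], Y - center[1])
    envelope = np.exp(-(r**2) / (2.0 * cfg.corner_texture_sigma**2))
    return cfg.corner_texture_amp * envelope * np.cos(
        2.0 * np.pi * r / cfg.corner_texture_period
    )


def render_eye_frame(
    pupil_center,
    inner_corner,
    outer_corner=None,
    blink: bool = False,
    highlights=(),
    config: EyeRenderConfig | None = None,
    rng: np.random.Generator | None = None,
):
    """Render one grayscale eye frame.

    Parameters
    ----------
    pupil_center : (px, py) in image coordinates (x right, y down).
    inner_corner, outer_corner : landmark centers; the outer corner
        defaults to ``inner_corner + config.outer_corner_offset``.
    blink : draw an eyelid occluding the pupil; the returned ground truth
        flags the pupil as absent.
    highlights : iterable of (x, y, radius) bright specular distractors.
    rng : source for the additive Gaussian noise (no noise when None and
        ``config.noise_sd`` > 0 requires an rng, so pass one for noisy
        frames; noise is skipped when rng is None).

    Returns
    -------
    image : uint8 array of ``config.shape``.
    truth : dict with the drawn pupil center/axes, corner positions and
        ``pupil_visible``.
    """
    cfg = config or EyeRenderConfig()
    h, w = cfg.shape
    px, py = float(pupil_center[0]), float(pupil_center[1])
    a, b = cfg.pupil_axes
    if a <= 0 or b <= 0:
        raise ValueError("pupil ellipse axes must be positive")
    if not blink and not (a <= px <= w - a and b <= py <= h - b):
        raise ValueError("pupil ellipse must lie fully inside the frame")
    inner = (float(inner_corner[0]), float(inner_corner[1]))
    if outer_corner is None:
        outer = (inner[0] + cfg.outer_corner_offset[0],
                 inner[1] + cfg.outer_corner_offset[1])
    else:
        outer = (float(outer_corner[0]), float(outer_corner[1]))

    Y, X = np.mgrid[0:h, 0:w].astype(float)
    img = np.full((h, w), cfg.sclera_value)
    # slight vertical shading so the background is not perfectly flat
    img -= 10.0 * (Y / h - 0.5)

    iris = _ellipse_alpha(X, Y, (px, py), (cfg.iris_radius, cfg.iris_radius),
                          0.0, cfg.edge_softness)
    img = img * (1 - iris) + cfg.iris_value * iris
    pupil = _ellipse_alpha(X, Y, (px, py), (a, b), cfg.pupil_angle,
                           cfg.edge_softness)
    img = img * (1 - pupil) + cfg.pupil_value * pupil

    img += _corner_pattern(X, Y, inner, cfg)
    img += _corner_pattern(X, Y, outer, cfg)

    for hx, hy, hr in highlights:
        spot = _ellipse_alpha(X, Y, (hx, hy), (hr, hr), 0.0, 1.0)
        img = img * (1 - spot) + 250.0 * spot

    if blink:
        # eyelid: gently curved lower edge covering the pupil region
        lid_edge = py + b + 8.0 - 2e-4 * (X - px) ** 2
        lid = _smoothstep((lid_edge - Y) / 3.0 + 0.5)
        img = img * (1 - lid) + cfg.lid_value * lid

    if rng is not None and cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)

    truth = {
        "pupil_center": (px, py),
        "pupil_axes": (a, b),
        "pupil_angle": cfg.pupil_angle,
        "pupil_visible": not blink,
        "inner_corner": inner,
        "outer_corner": outer,
    }
    return np.clip(img, 0, 255).astype(np.uint8), truth


def render_session_frames(record, eye: str = "left",
                          config: EyeRenderConfig | None = None,
                          rng: np.random.Generator | None = None):
    """Yield (image, truth) per frame of a feature-level session record.

    The pupil is drawn at the absolute position ``(m + x, n + y)`` implied
    by that frame's features — the identity the tracking front end must
    reproduce — and the corner landmark at ``(m, n)``.  Blink frames carry
    NaN features, so the last valid geometry is reused under the eyelid.
    """
    cfg = config or EyeRenderConfig()
    tag = {"left": "L", "right": "R"}[eye]
    cols = [f"{c}{tag}" for c in ("x", "y", "m", "n")]
    last = None
    for _, row in record.frames.iterrows():
        x, y, m, n = (float(row[c]) for c in cols)
        blink = bool(row["blink"])
        if np.isnan(x):
            if last is None:
                continue
            (px, py), (m, n) = last
        else:
            px, py = m + x, n + y
            last = ((px, py), (m, n))
        yield render_eye_frame((px, py), (m, n), blink=blink,
                               config=cfg, rng=rng)


# ------------------------------------------------------------------ table video
def make_table_mask(shape=(240, 320), kind: str = "band") -> np.ndarray:
    """Binary mask of the patient-bed region: a horizontal band or a box."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    if kind == "band":
        mask[h // 3 : 2 * h // 3, :] = True
    elif kind == "box":
        mask[h // 4 : 3 * h // 4, w // 4 : 3 * w // 4] = True
    else:
        raise ValueError("kind must be 'band' or 'box'")
    return mask


@dataclass(frozen=True)
class _Texture:
    field: np.ndarray
    pad: int

    def sample(self, shape, offset):
        h, w = shape
        rows, cols = np.mgrid[0:h, 0:w].astype(float)
        return map_coordinates(
            self.field,
            [rows + self.pad + offset[1], cols + self.pad + offset[0]],
            order=3,
            mode="reflect",
        )


def _make_texture(shape, pad, rng, smooth=2.0, contrast=60.0, base=120.0):
    h, w = shape
    noise = rng.normal(size=(h + 2 * pad, w + 2 * pad))
    tex = gaussian_filter(noise, smooth)
    tex = base + contrast * tex / max(tex.std(), 1e-9)
    return _Texture(field=tex, pad=pad)


def generate_table_video(
    shift_per_frame,
    n_frames: int,
    shape=(240, 320),
    mask: np.ndarray | None = None,
    moving_region: str = "full",
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Textured frames translating by a constant (possibly sub-pixel) shift.

    ``shift_per_frame`` is an (sx, sy) vector in px/frame (x right, y
    down), magnitude < 10.  Frame ``k`` samples the same smooth random
    texture at coordinates displaced by ``k * shift``, so the motion is
    exact by construction, including sub-pixel shifts.  ``moving_region``
    selects which pixels move: ``"full"`` (everything), ``"mask"`` (bed
    region only, static surround) or ``"outside"`` (static bed, moving
    surround — the mask-contract control case).

    Returns ``(frames, mask, truth)`` where frames is a (n, h, w) uint8
    array and truth records the applied per-frame shift.
    """
    shift = np.asarray(shift_per_frame, dtype=float)
    if np.hypot(*shift) >= 10.0:
        raise ValueError("per-frame shift magnitude must be < 10 px")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if mask is None:
        mask = make_table_mask(shape)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tuple(shape):
        raise ValueError("mask shape must match frame shape")
    if not mask.any():
        raise ValueError("mask is empty")

    rng = np.random.default_rng(seed)
    pad = int(np.ceil(np.abs(shift).max() * n_frames)) + 8
    moving = _make_texture(shape, pad, rng)
    static = _make_texture(shape, pad, rng)

    if moving_region == "full":
        region = np.ones(shape, dtype=bool)
    elif moving_region == "mask":
        region = mask
    elif moving_region == "outside":
        region = ~mask
    else:
        raise ValueError("moving_region must be 'full', 'mask' or 'outside'")

    static_frame = static.sample(shape, (0.0, 0.0))
    frames = np.empty((n_frames, *shape), dtype=np.uint8)
    for k in range(n_frames):
        # sampling at +offset moves the pattern by -offset; negate so the
        # visible texture translates by +shift each frame
        frame = moving.sample(shape, (-k * shift[0], -k * shift[1]))
        frame = np.where(region, frame, static_frame)
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=shape)
        frames[k] = np.clip(frame, 0, 255).astype(np.uint8)

    truth = {"shift_per_frame": tuple(shift), "moving_region": moving_region}
    return frames, mask, truth
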