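"""Image pre-processing chain for cyclic immunofluorescence runs.

Stage order (fixed): register each cycle to the run reference by normalized
cross-correlation -> subtract the previous bleach (or secondary-only, or the
run blank) stack -> divide by the illumination field estimated from the same
cycle's bleach image -> project the z-stack to one all-in-focus plane
(extended depth of field) -> rolling-ball background removal, edge crop and
16-bit intensity stretch.

Subtraction happens between like-registered, like-illuminated images, and
illumination is removed before focus projection so that plane selection is
driven by sharpness, not by the shading field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, ndimage
from skimage.feature import match_template
from skimage.restoration import rolling_ball
from skimage.transform import resize

from .io import ConfigError, MelcRun, U16_MAX, ValidationError
from .synthetic import translate


class DegenerateCorrelationError(ValueError):
    """Cross-correlation is undefined for a constant image."""


@dataclass
class PreprocessParams:
    max_shift_px: int = 50
    spline_grid: int = 16
    illumination_floor: float = 0.05
    edf_window_px: int = 9
    rolling_ball_radius_px: int = 50
    stretch_percentiles: tuple[float, float] = (0.0, 100.0)
    crop_margin_px: int | None = None  # None: max observed |shift|

    def __post_init__(self) -> None:
        low, high = self.stretch_percentiles
        if not (0 <= low < high <= 100):
            raise ConfigError("stretch_percentiles must satisfy 0 <= low < high <= 100")
        if self.max_shift_px <= 0 or self.spline_grid <= 0 or self.edf_window_px <= 0:
            raise ConfigError("preprocessing parameters must be positive")


# ---------------------------------------------------------------------------
# registration

def register_cycle(
    moving: np.ndarray, reference: np.ndarray, max_shift_px: int
) -> tuple[tuple[int, int], np.ndarray]:
    """Integer-pixel registration of ``moving`` onto ``reference``.

    The returned ``shift`` (dr, dc) maximizes the normalized cross-correlation
    over all |dr|, |dc| <= max_shift_px, with ties broken by smallest
    |dr| + |dc| and then lexicographically.  ``registered`` is ``moving``
    translated by -shift with zero fill, i.e. aligned to the reference frame.
    """
    moving = np.asarray(moving, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if moving.shape != reference.shape:
        raise ValidationError("moving and reference must share shape")
    if max_shift_px >= min(moving.shape) // 4:
        raise ConfigError("max_shift_px must be < min(shape)/4")
    if moving.std() == 0 or reference.std() == 0:
        raise DegenerateCorrelationError("constant image: correlation peak undefined")
    m = max_shift_px
    padded = np.pad(reference, m, mode="edge")
    ncc = match_template(padded, moving, pad_input=False)
    peak = ncc.max()
    cand = np.argwhere(ncc >= peak - 1e-9)
    shifts = [(m - int(i), m - int(j)) for i, j in cand]
    dr, dc = min(shifts, key=lambda s: (abs(s[0]) + abs(s[1]), s[0], s[1]))
    return (dr, dc), translate(moving, -dr, -dc)


# ---------------------------------------------------------------------------
# background and illumination

def subtract_background(fluo: np.ndarray, bleach_prev: np.ndarray) -> np.ndarray:
    """Bleach-image background subtraction, clamped at zero."""
    fluo = np.asarray(fluo, dtype=np.float64)
    bleach_prev = np.asarray(bleach_prev, dtype=np.float64)
    if fluo.shape != bleach_prev.shape:
        raise ValidationError(
            f"shape mismatch: fluorescence {fluo.shape} vs bleach {bleach_prev.shape}"
        )
    return np.maximum(fluo - bleach_prev, 0.0)


def subtract_secondary(fluo_primary: np.ndarray, fluo_secondary_only: np.ndarray) -> np.ndarray:
    """Secondary-antibody background subtraction (uncoupled antibodies)."""
    return subtract_background(fluo_primary, fluo_secondary_only)


def estimate_illumination(
    bleach: np.ndarray,
    spline_grid: int = 16,
    floor: float = 0.05,
    ignore_margin_px: int = 0,
) -> np.ndarray:
    """Smooth multiplicative illumination field from a bleach image.

    The image is lightly denoised, tiled into ``spline_grid`` x
    ``spline_grid`` blocks, and the per-block minimum intensities (the
    stain-free background, which carries the shading field) are median
    filtered to reject blocks fully covered by signal.  A smoothing cubic
    spline surface through the block-center/minimum pairs is evaluated at
    every pixel (edge pixels beyond the outermost block centers take the
    boundary value), normalized to unit spatial mean, and clipped below at
    ``floor``.

    ``ignore_margin_px`` excludes an edge band from the block grid (the
    zero-filled frame left behind by registration would otherwise pull the
    surface to zero at the borders).  A bleach image with (near-)zero mean
    carries no illumination information and yields the flat field 1.
    """
    if spline_grid < 4:
        raise ConfigError("spline_grid must be >= 4")
    bleach = np.asarray(bleach, dtype=np.float64)
    if bleach.min() < -1e-9:
        raise ValidationError("bleach image must be nonnegative")
    h, w = bleach.shape
    if bleach.mean() <= 1e-9:
        return np.ones_like(bleach)
    # light denoising only: the minimum of an un-smoothed noisy block sits
    # several noise SDs below the background, but that bias is uniform and
    # cancels in the mean normalization as long as smoothing stays small
    smoothed = ndimage.gaussian_filter(bleach, sigma=1.5)
    m0 = int(ignore_margin_px + 3) if ignore_margin_px else 0
    if min(h, w) - 2 * m0 < 2 * spline_grid:
        m0 = 0
    rows = np.linspace(m0, h - m0, spline_grid + 1).astype(int)
    cols = np.linspace(m0, w - m0, spline_grid + 1).astype(int)
    centers_r = (rows[:-1] + rows[1:]) / 2.0
    centers_c = (cols[:-1] + cols[1:]) / 2.0
    mins = np.array([
        [smoothed[rows[i]:rows[i + 1], cols[j]:cols[j + 1]].min()
         for j in range(spline_grid)]
        for i in range(spline_grid)
    ])
    mins = ndimage.median_filter(mins, size=3, mode="nearest")
    scale = np.median(mins)
    if scale <= 1e-9:
        return np.ones_like(bleach)
    mins = mins / scale
    field = None
    n = spline_grid * spline_grid
    # escalate the smoothing factor until fitpack converges
    for s in (n * 2e-3, n * 2e-2, n * 2e-1, None):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                spline = interpolate.RectBivariateSpline(
                    centers_r, centers_c, mins, kx=3, ky=3, s=s
                )
            except ValueError:
                continue
        rr = np.clip(np.arange(h, dtype=float), centers_r[0], centers_r[-1])
        cc = np.clip(np.arange(w, dtype=float), centers_c[0], centers_c[-1])
        cand = np.asarray(spline(rr, cc))
        if np.all(np.isfinite(cand)) and cand.mean() > 1e-9:
            field = cand
            break
    if field is None:
        return np.ones_like(bleach)
    field = field / field.mean()
    field = np.clip(field, floor, None)
    # a fit that needed heavy floor-clipping carries no usable shading
    # information (shading fields vary by tens of percent, not folds)
    if field.mean() > 1.2:
        return np.ones_like(bleach)
    return field


def correct_illumination(img: np.ndarray, field: np.ndarray, floor: float = 0.05) -> np.ndarray:
    """Pixelwise division by a mean-one illumination field.

    Floor-clipping in :func:`estimate_illumination` can push the spatial mean
    slightly above one; anything further from one is a contract violation.
    """
    field = np.asarray(field, dtype=np.float64)
    if not (1.0 - 1e-6 <= field.mean() <= 1.25):
        raise ValidationError("illumination field must have spatial mean ~1")
    if field.min() < floor - 1e-9:
        raise ValidationError(f"illumination field below floor {floor}")
    return np.asarray(img, dtype=np.float64) / field


# ---------------------------------------------------------------------------
# focus projection and normalization

def extended_depth_of_field(zstack: np.ndarray, window_px: int = 9) -> np.ndarray:
    """All-in-focus projection: per pixel, keep the plane with the highest
    local intensity variance; the plane-selection map is median filtered to
    suppress isolated selections.  Ties resolve to the lowest z index.
    """
    zstack = np.asarray(zstack, dtype=np.float64)
    if zstack.ndim != 3 or zstack.shape[0] < 1:
        raise ValidationError("zstack must be 3D with >= 1 plane")
    if window_px % 2 == 0:
        raise ConfigError("edf window must be odd")
    if zstack.shape[0] == 1:
        return zstack[0].copy()
    local_var = np.empty_like(zstack)
    for z in range(zstack.shape[0]):
        mu = ndimage.uniform_filter(zstack[z], window_px)
        mu2 = ndimage.uniform_filter(zstack[z] ** 2, window_px)
        local_var[z] = mu2 - mu**2
    sel = np.argmax(local_var, axis=0)  # first max -> lowest z on ties
    sel = ndimage.median_filter(sel, size=window_px)
    return np.take_along_axis(zstack, sel[None], axis=0)[0]


def _rolling_ball_background(img: np.ndarray, radius: int) -> np.ndarray:
    """ImageJ-style background: shrink for large radii, roll, expand.

    The ball lives in (x, y, intensity) space with one radius for all axes,
    so intensities are first rescaled to 8-bit-like counts (the ImageJ
    convention); otherwise the ball would sink into structures on [0, 1]
    float images.
    """
    ptp = float(img.max() - img.min())
    if ptp == 0.0:
        return img.copy()
    scale = 255.0 / ptp
    return _rolling_ball_raw(img * scale, radius) / scale


def _rolling_ball_raw(img: np.ndarray, radius: int) -> np.ndarray:
    if radius >= 16:
        factor = 2
        small = resize(img, (max(img.shape[0] // factor, 8), max(img.shape[1] // factor, 8)),
                       order=1, anti_aliasing=True, preserve_range=True)
        bg_small = rolling_ball(small, radius=max(radius // factor, 1))
        bg = resize(bg_small, img.shape, order=1, preserve_range=True)
    else:
        bg = rolling_ball(img, radius=radius)
    return np.minimum(bg, img)


def normalize_image(img: np.ndarray, params: PreprocessParams,
                    crop_margin_px: int | None = None) -> np.ndarray:
    """Rolling-ball background removal, edge crop, 16-bit intensity stretch.

    The crop margin accounts for the maximum stage shift (zero-filled frame
    edges after registration carry no signal).  The [p_low, p_high]
    percentile range of the cropped image is mapped linearly onto
    [0, 65535]; output is float in 16-bit range.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.min() < -1e-9:
        raise ValidationError("image must be nonnegative")
    margin = params.crop_margin_px if crop_margin_px is None else crop_margin_px
    margin = int(margin or 0)
    img = img - _rolling_ball_background(img, params.rolling_ball_radius_px)
    img = np.maximum(img, 0.0)
    if margin > 0:
        if min(img.shape) - 2 * margin < 64:
            raise ValidationError(f"crop margin {margin} leaves < 64 px per side")
        img = img[margin:-margin, margin:-margin]
    low, high = params.stretch_percentiles
    p_lo, p_hi = np.percentile(img, [low, high])
    if p_hi - p_lo < 1e-12:
        return np.zeros_like(img)
    out = (img - p_lo) / (p_hi - p_lo) * U16_MAX
    return np.clip(out, 0.0, U16_MAX)


# ---------------------------------------------------------------------------
# whole-run driver

def preprocess_run(
    run: MelcRun, params: PreprocessParams | None = None
) -> tuple[dict[str, np.ndarray], dict[int, tuple[int, int]]]:
    """Full pre-processing of a run: one corrected, cropped, 16-bit-stretched
    2D image per marker, plus the per-cycle shift log.
    """
    params = params or PreprocessParams()
    reference = run.reference_phase_contrast
    z_mid = run.geometry.z_steps
    max_shift = min(
        params.max_shift_px,
        run.geometry.max_autofocus_shift_px,
        min(run.geometry.image_shape) // 4 - 1,
    )

    # one shift per cycle, measured on the summed central planes of all the
    # cycle's acquisitions (all channels of a cycle share the stage position)
    shifts: dict[int, tuple[int, int]] = {}
    for cyc in run.cycle_indices:
        moving = np.sum([
            rec.fluorescence_zstack[z_mid] for rec in run.cycles
            if rec.cycle_index == cyc
        ], axis=0)
        (dr, dc), _ = register_cycle(moving, reference, max_shift)
        shifts[cyc] = (dr, dc)

    def register_stack(stack: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
        dr, dc = shift
        return translate(stack, -dr, -dc)

    if params.crop_margin_px is not None:
        margin = params.crop_margin_px
    else:
        margin = max((max(abs(dr), abs(dc)) for dr, dc in shifts.values()), default=0)

    # previous registered bleach stack per channel; run blank for the first
    prev_bleach: dict[str, np.ndarray] = {}
    corrected: dict[str, np.ndarray] = {}
    for rec in run.cycles:
        shift = shifts[rec.cycle_index]
        fluo = register_stack(rec.fluorescence_zstack, shift)
        bleach = register_stack(rec.bleach_zstack, shift)
        if rec.marker.uses_secondary_antibody and rec.secondary_only_zstack is not None:
            subtrahend = register_stack(rec.secondary_only_zstack, shift)
        else:
            subtrahend = prev_bleach.get(rec.channel)
            if subtrahend is None:
                if run.blank_bleach_zstack is None:
                    raise ValidationError(
                        f"cycle {rec.cycle_index} ({rec.marker.name}): no earlier "
                        "bleach stack in this channel and no run blank"
                    )
                subtrahend = run.blank_bleach_zstack  # acquired pre-run, unshifted
        sub = subtract_background(fluo, subtrahend)
        # z-mean of the bleach stack: same illumination, sqrt(n) less noise
        field = estimate_illumination(
            bleach.mean(axis=0), params.spline_grid, params.illumination_floor,
            ignore_margin_px=max(abs(shift[0]), abs(shift[1])),
        )
        corr = np.stack([
            correct_illumination(p, field, params.illumination_floor) for p in sub
        ])
        edf = extended_depth_of_field(corr, params.edf_window_px)
        corrected[rec.marker.name] = normalize_image(edf, params, crop_margin_px=margin)
        prev_bleach[rec.channel] = bleach
    return corrected, shifts
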