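"""Piecewise-rigid motion correction and axial (z) motion estimation.

The in-plane correction follows the standard patchwise approach: the
frame is divided into overlapping patches, a rigid translation per patch
is estimated against a template by FFT cross-correlation with
matrix-multiply DFT subpixel upsampling, the patch shifts are
interpolated to a dense motion field, and the field is applied by
inverse bilinear warping.  The per-frame displacement reported for the
x/y axes is the maximum-magnitude shift over patches.

Axial motion is estimated by correlating motion-corrected patches
against the same patches in a reference z-stack (1 um plane spacing)
and averaging the per-patch peak plane, refined by parabolic
interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from skimage.registration import phase_cross_correlation

from .synth import ZStack

__all__ = [
    "PatchGrid",
    "MotionField",
    "DisplacementSummary",
    "estimate_template",
    "estimate_patch_shifts",
    "interpolate_motion_field",
    "apply_motion_field",
    "correct_movie",
    "frame_displacement",
    "rms_displacement",
    "between_trial_offsets",
    "estimate_z",
]


@dataclass(frozen=True)
class PatchGrid:
    """Overlapping-patch layout for estimation and application."""

    patch_size_px: tuple[int, int] = (128, 128)
    stride_px: tuple[int, int] = (64, 64)
    apply_patch_size_px: tuple[int, int] = (32, 32)

    def __post_init__(self) -> None:
        if any(s > p for s, p in zip(self.stride_px, self.patch_size_px)):
            raise ValueError("stride must not exceed patch size (patches must overlap)")
        if any(a > p for a, p in zip(self.apply_patch_size_px, self.patch_size_px)):
            raise ValueError("apply patch size must not exceed estimation patch size")

    def patch_slices(self, shape: tuple[int, int]):
        """Top-left anchored overlapping patches covering ``shape``.

        The last patch along each axis is shifted inward so the frame is
        fully covered without going out of bounds.
        """
        out = []
        for dim, (size, stride) in enumerate(zip(self.patch_size_px, self.stride_px)):
            n = shape[dim]
            size = min(size, n)
            starts = list(range(0, max(n - size, 0) + 1, stride))
            if starts[-1] != n - size:
                starts.append(n - size)
            out.append([(s, s + size) for s in starts])
        return [
            (slice(y0, y1), slice(x0, x1))
            for (y0, y1) in out[0]
            for (x0, x1) in out[1]
        ]

    def patch_centers(self, shape: tuple[int, int]) -> np.ndarray:
        return np.array(
            [
                ((sy.start + sy.stop - 1) / 2.0, (sx.start + sx.stop - 1) / 2.0)
                for sy, sx in self.patch_slices(shape)
            ]
        )


@dataclass
class MotionField:
    """Estimated motion for a movie: per-patch shifts plus the dense field."""

    patch_shifts: np.ndarray            # (T, n_patches, 2) px, (dy, dx)
    patch_centers: np.ndarray           # (n_patches, 2)
    frame_shape: tuple[int, int]
    max_shift_px: float = 10.0
    upsample_factor: int = 10
    confidence: np.ndarray | None = None  # (T, n_patches) peak / second-peak

    def dense_field(self, t: int) -> np.ndarray:
        return interpolate_motion_field(
            self.patch_shifts[t], self.patch_centers, self.frame_shape
        )


@dataclass
class DisplacementSummary:
    per_frame: np.ndarray               # (T, 2), (dy, dx)
    rms_per_axis: dict = field(default_factory=dict)   # {"x": ..., "y": ...} um


def _register_translation(reference, moving, upsample_factor=10):
    """Shift of ``moving``'s content relative to ``reference`` (dy, dx).

    If moving(y, x) = reference(y - dy, x - dx), returns (dy, dx).
    """
    shift, _, _ = phase_cross_correlation(
        reference, moving, upsample_factor=upsample_factor, normalization=None
    )
    return -shift


def estimate_template(
    movie: np.ndarray, n_frames: int = 100, n_iter: int = 3, upsample_factor: int = 10
) -> np.ndarray:
    """Iterative mean-of-registered-frames template.

    ``n_iter=0`` falls back to the plain mean of the first ``n_frames``.
    """
    if movie.shape[0] == 0:
        raise ValueError("empty movie")
    frames = np.asarray(movie[: min(n_frames, movie.shape[0])], dtype=float)
    template = frames.mean(axis=0)
    for _ in range(n_iter):
        registered = []
        for f in frames:
            d = _register_translation(template, f, upsample_factor)
            registered.append(_shift_frame(f, -d))
        template = np.mean(registered, axis=0)
    return template


def _shift_frame(frame, displacement):
    """Shift content by (dy, dx) with bilinear sampling, edges clamped."""
    return ndimage.shift(
        np.asarray(frame, dtype=float), displacement, order=1, mode="nearest"
    )


def _int_xcorr_peak(a, b, max_shift):
    """Integer-shift correlation surface of mean-subtracted patches.

    Returns (best_shift, confidence) where confidence is the ratio of the
    global peak to the largest local maximum outside the peak's 3x3
    neighbourhood.  Ties break toward the smallest shift magnitude.
    """
    a = a - a.mean()
    b = b - b.mean()
    fa = np.fft.fft2(a)
    fb = np.fft.fft2(b)
    cc = np.real(np.fft.ifft2(fa * np.conj(fb)))
    cc = np.fft.fftshift(cc)
    cy, cx = a.shape[0] // 2, a.shape[1] // 2
    ms = int(max_shift)
    win = cc[
        max(cy - ms, 0) : cy + ms + 1, max(cx - ms, 0) : cx + ms + 1
    ]
    peak = win.max()
    ys, xs = np.where(win == peak)
    oy = max(cy - ms, 0)
    ox = max(cx - ms, 0)
    shifts = np.column_stack([ys + oy - cy, xs + ox - cx])
    best = shifts[np.argmin((shifts**2).sum(axis=1))]
    # second peak for the confidence ratio
    py, px = ys[0], xs[0]
    masked = win.copy()
    masked[max(py - 1, 0) : py + 2, max(px - 1, 0) : px + 2] = -np.inf
    second = masked.max()
    conf = np.inf if second <= 0 else peak / second
    # lag l maximises sum a[x+l] b[x]: a's content sits at +l relative to b
    return best.astype(float), float(conf)


def estimate_patch_shifts(
    frame: np.ndarray,
    template: np.ndarray,
    grid: PatchGrid,
    max_shift_px: float = 10.0,
    upsample_factor: int = 10,
    min_confidence: float = 1.1,
    window: bool = True,
):
    """Per-patch rigid translation of ``frame`` relative to ``template``.

    Returns ``(shifts, confidence)``: (n_patches, 2) subpixel shifts in
    (dy, dx), clipped to +-max_shift_px, and the peak/second-peak
    confidence ratio per patch.  Flat (zero-variance) patches get shift
    (0, 0) with confidence 0; patches below ``min_confidence`` inherit
    the median shift of confident patches.

    ``window`` tapers each mean-subtracted patch with a raised-cosine
    (Hann) window before correlation; cropping a patch out of the frame
    cuts structures at its border, and with sparse scenes the resulting
    edge terms bias the correlation peak by up to ~0.5 px unless tapered.
    """
    if max_shift_px < 1:
        raise ValueError("max_shift_px must be >= 1")
    frame = np.asarray(frame, dtype=float)
    template = np.asarray(template, dtype=float)
    h, w = frame.shape
    slices = grid.patch_slices(template.shape)
    shifts = np.zeros((len(slices), 2))
    conf = np.zeros(len(slices))
    win_cache: dict[tuple[int, int], np.ndarray] = {}
    for i, (sy, sx) in enumerate(slices):
        tp = template[sy, sx]
        fp = frame[sy, sx]
        if tp.std() == 0 or fp.std() == 0:
            shifts[i] = 0.0
            conf[i] = 0.0
            continue
        if window:
            if tp.shape not in win_cache:
                win_cache[tp.shape] = (
                    np.hanning(tp.shape[0])[:, None] * np.hanning(tp.shape[1])[None, :]
                )
            w2 = win_cache[tp.shape]
            tpw = (tp - tp.mean()) * w2
            fpw = (fp - fp.mean()) * w2
        else:
            tpw, fpw = tp, fp
        # stage 1: integer shift and confidence from the (windowed)
        # correlation surface
        d_int, c = _int_xcorr_peak(fpw, tpw, max_shift_px)
        # stage 2: re-crop the frame patch at the integer offset (pulling
        # real data from the full frame, clamped at its border) and
        # refine the sub-pixel residual, where taper bias is negligible
        dy, dx = int(d_int[0]), int(d_int[1])
        ys = np.clip(np.arange(sy.start, sy.stop) + dy, 0, h - 1)
        xs = np.clip(np.arange(sx.start, sx.stop) + dx, 0, w - 1)
        fp2 = frame[np.ix_(ys, xs)]
        if window:
            fp2 = (fp2 - fp2.mean()) * win_cache[tp.shape]
        else:
            fp2 = fp2
        resid = _register_translation(tpw, fp2, upsample_factor)
        resid = np.clip(resid, -1.0, 1.0)
        shifts[i] = np.clip(d_int + resid, -max_shift_px, max_shift_px)
        conf[i] = c
    good = conf >= min_confidence
    if good.any() and not good.all():
        fallback = np.median(shifts[good], axis=0)
        shifts[~good] = fallback
    return shifts, conf


def interpolate_motion_field(
    patch_shifts: np.ndarray,
    patch_centers: np.ndarray,
    frame_shape: tuple[int, int],
) -> np.ndarray:
    """Bilinear interpolation of patch shifts to a dense (H, W, 2) field.

    Patch centers must lie on a regular grid (as produced by PatchGrid);
    outside the patch-center hull the field is extrapolated as constant.
    The field evaluated at a patch center equals that patch's shift.
    """
    patch_shifts = np.asarray(patch_shifts, dtype=float)
    if patch_shifts.size == 0:
        raise ValueError("need at least one patch")
    if not np.isfinite(patch_shifts).all():
        raise ValueError("non-finite patch shifts")
    h, w = frame_shape
    cy = np.unique(patch_centers[:, 0])
    cx = np.unique(patch_centers[:, 1])
    if len(cy) * len(cx) != len(patch_centers):
        raise ValueError("patch centers do not form a regular grid")
    grid_shifts = patch_shifts.reshape(len(cy), len(cx), 2)
    if len(cy) == 1 and len(cx) == 1:
        return np.broadcast_to(grid_shifts[0, 0], (h, w, 2)).copy()
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    # clamp query points to the center hull => constant extrapolation
    yq = np.clip(yy, cy[0], cy[-1])
    xq = np.clip(xx, cx[0], cx[-1])
    out = np.empty((h, w, 2))
    for k in range(2):
        if len(cy) == 1:
            interp = np.interp(xq.ravel(), cx, grid_shifts[0, :, k])
        elif len(cx) == 1:
            interp = np.interp(yq.ravel(), cy, grid_shifts[:, 0, k])
        else:
            rgi = RegularGridInterpolator((cy, cx), grid_shifts[..., k], method="linear")
            interp = rgi(np.column_stack([yq.ravel(), xq.ravel()]))
        out[..., k] = interp.reshape(h, w)
    return out


def apply_motion_field(
    frame: np.ndarray, dense_field: np.ndarray, grid: PatchGrid | None = None
) -> np.ndarray:
    """Undo the motion described by ``dense_field`` (the displacement of
    the frame's content relative to the template).

    Inverse bilinear warp: corrected(y, x) = frame(y + dy, x + dx), with
    edge clamping; the pixelwise warp is the limit of warping small
    overlapping patches with feathered blending.  A zero field returns
    the frame unchanged (bit-identical).
    """
    frame = np.asarray(frame)
    h, w = frame.shape
    dense_field = np.asarray(dense_field, dtype=float)
    if not np.isfinite(dense_field).all():
        raise ValueError("non-finite motion field")
    if np.abs(dense_field).max() > max(h, w):
        raise ValueError("motion field magnitude exceeds frame size")
    if np.all(dense_field == 0):
        return frame.copy()
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    coords = np.stack([yy + dense_field[..., 0], xx + dense_field[..., 1]])
    out = ndimage.map_coordinates(
        np.asarray(frame, dtype=float), coords, order=1, mode="nearest"
    )
    return np.clip(out, 0, None)


def correct_movie(
    movie: np.ndarray,
    template: np.ndarray | None = None,
    grid: PatchGrid | None = None,
    max_shift_px: float = 10.0,
    upsample_factor: int = 10,
    template_frames: int = 100,
) -> tuple[np.ndarray, MotionField]:
    """Full piecewise-rigid correction of a movie; returns the corrected
    movie and the estimated MotionField."""
    grid = grid or PatchGrid()
    if template is None:
        template = estimate_template(movie, n_frames=template_frames)
    centers = grid.patch_centers(template.shape)
    n_patches = len(centers)
    T = movie.shape[0]
    shifts = np.zeros((T, n_patches, 2))
    conf = np.zeros((T, n_patches))
    corrected = np.empty_like(np.asarray(movie, dtype=np.float32))
    for t in range(T):
        s, c = estimate_patch_shifts(
            movie[t], template, grid, max_shift_px, upsample_factor
        )
        shifts[t] = s
        conf[t] = c
        dense = interpolate_motion_field(s, centers, template.shape)
        corrected[t] = apply_motion_field(movie[t], dense, grid)
    mf = MotionField(
        patch_shifts=shifts,
        patch_centers=centers,
        frame_shape=template.shape,
        max_shift_px=max_shift_px,
        upsample_factor=upsample_factor,
        confidence=conf,
    )
    return corrected, mf


def frame_displacement(patch_shifts: np.ndarray) -> np.ndarray:
    """Per-axis signed shift of maximum magnitude over patches.

    Input (n_patches, 2) or (T, n_patches, 2); output (2,) or (T, 2) in
    (dy, dx) order.
    """
    s = np.asarray(patch_shifts, dtype=float)
    single = s.ndim == 2
    if single:
        s = s[None]
    idx = np.abs(s).argmax(axis=1)                      # (T, 2)
    out = np.take_along_axis(s, idx[:, None, :], axis=1)[:, 0, :]
    return out[0] if single else out


def rms_displacement(per_frame: np.ndarray, um_per_px: float = 1.0) -> dict:
    """Root-mean-square displacement per axis, converted to um.

    Axis naming follows the imaging convention: x = columns
    (medio-lateral), y = rows (anterior-posterior); input is (T, 2) in
    (dy, dx).
    """
    d = np.atleast_2d(np.asarray(per_frame, dtype=float))
    rms = np.sqrt(np.mean(d**2, axis=0)) * um_per_px
    return {"y": float(rms[0]), "x": float(rms[1])}


def between_trial_offsets(
    trial_templates: np.ndarray, reference: np.ndarray, upsample_factor: int = 10
) -> np.ndarray:
    """Single rigid subpixel offset of each trial template vs the session
    reference, (n_trials, 2) in (dy, dx)."""
    trial_templates = np.asarray(trial_templates, dtype=float)
    if trial_templates.ndim == 2:
        trial_templates = trial_templates[None]
    if np.asarray(reference).std() == 0:
        raise ValueError("flat reference template")
    out = np.zeros((trial_templates.shape[0], 2))
    for i, t in enumerate(trial_templates):
        if t.std() == 0:
            raise ValueError(f"flat trial template {i}")
        out[i] = _register_translation(reference, t, upsample_factor)
    return out


def _parabolic_peak(y: np.ndarray, k: int) -> float:
    """Refine an argmax index by fitting a parabola through its neighbours."""
    if k == 0 or k == len(y) - 1:
        return float(k)
    denom = y[k - 1] - 2 * y[k] + y[k + 1]
    if denom == 0:
        return float(k)
    return k + 0.5 * (y[k - 1] - y[k + 1]) / denom


def estimate_z(
    frames: np.ndarray,
    zstack: ZStack,
    grid: PatchGrid | None = None,
) -> np.ndarray:
    """Axial position of each (motion-corrected) frame in um.

    Each patch of the frame is correlated (Pearson) against the same
    patch in every plane of the reference stack; the per-patch peak
    plane is refined by parabolic interpolation and the frame z is the
    mean over valid patches.  Patches with zero variance in the frame or
    in all planes are excluded; a frame with no valid patch yields NaN
    with a warning.
    """
    if zstack.planes.shape[0] < 3:
        raise ValueError("z-stack needs at least 3 planes")
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    grid = grid or PatchGrid()
    slices = grid.patch_slices(frames.shape[1:])
    z_axis = zstack.z_um
    # pre-normalise stack patches
    stack_patches = []
    for sy, sx in slices:
        p = zstack.planes[:, sy, sx].reshape(zstack.planes.shape[0], -1).astype(float)
        p = p - p.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(p, axis=1)
        stack_patches.append((p, norm))
    out = np.full(frames.shape[0], np.nan)
    for t, frame in enumerate(frames):
        zs = []
        for (sy, sx), (p, pnorm) in zip(slices, stack_patches):
            f = frame[sy, sx].ravel().astype(float)
            f = f - f.mean()
            fn = np.linalg.norm(f)
            if fn == 0 or np.all(pnorm == 0):
                continue
            valid = pnorm > 0
            corr = np.full(p.shape[0], -np.inf)
            corr[valid] = (p[valid] @ f) / (pnorm[valid] * fn)
            k = int(np.argmax(corr))
            if corr[k] >= 1.0 - 1e-12:
                # perfect match with one plane: no refinement needed
                kf = float(k)
            else:
                kf = _parabolic_peak(np.where(np.isfinite(corr), corr, corr[k] - 1.0), k)
            zs.append(np.interp(kf, np.arange(len(z_axis)), z_axis))
        if zs:
            out[t] = float(np.mean(zs))
        else:
            warnings.warn(f"frame {t}: no patch with usable correlation; z is NaN")
    return out
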