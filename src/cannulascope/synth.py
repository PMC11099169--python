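"""Synthetic two-photon imaging data with known ground truth.

Emulates sparse GCaMP6f-labelled CA1 somata imaged at 30 Hz over a
~600 x 600 um field of view: transient calcium dynamics, photon/read
noise, smooth in-plane motion of a few um, axial drift on the scale of
the 9.1 um axial PSF, multi-session fields of view sharing a cell
constellation under translation and zoom change, odor-tuned trial
responses, and repeated-insertion bead images.

Every generator is a pure function of its arguments including the seed,
and every stochastic choice is recorded so that downstream recovery
tests never need to re-simulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "SessionRecord",
    "ZStack",
    "make_cells",
    "simulate_transients",
    "transient_kernel",
    "render_movie",
    "make_zstack",
    "make_sessions",
    "make_odor_trials",
    "make_insertion_series",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SceneSpec:
    """Imaging-scene parameters.

    Defaults reproduce the described rig: ~600 um field of view at
    512 px (1.17 um/px), 30 Hz frame rate, lateral/axial PSF FWHM of
    1.2/9.1 um.
    """

    fov_px: tuple[int, int] = (256, 256)
    um_per_px: float = 600.0 / 512.0
    frame_rate_hz: float = 30.0
    n_cells: int = 30
    soma_radius_um: float = 8.0
    axial_fwhm_um: float = 9.1
    lateral_fwhm_um: float = 1.2
    photon_noise: bool = False
    read_noise_sd: float = 0.0
    intensity_scale: float = 100.0
    background: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.fov_px) <= 0:
            raise ValueError("fov_px must be positive")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.axial_fwhm_um <= 0:
            raise ValueError("axial_fwhm_um must be positive")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")

    @property
    def soma_sigma_px(self) -> float:
        # soma footprint is a 2D Gaussian truncated at 2 sigma, so the
        # nominal soma radius corresponds to 2 sigma
        return self.soma_radius_um / 2.0 / self.um_per_px


@dataclass
class GroundTruth:
    """Everything the generators decided, for parameter-recovery tests."""

    masks: np.ndarray | None = None          # (n_cells, H, W) weights
    centers: np.ndarray | None = None        # (n_cells, 2) (y, x) px
    true_traces: np.ndarray | None = None    # (n_cells, T)
    motion_true: np.ndarray | None = None    # (T, 2) or (T, H, W, 2) px (dy, dx)
    z_true: np.ndarray | None = None         # (T,) um
    session_offsets: list | None = None      # per-session ((dy, dx), zoom)
    cell_identity_map: dict | None = None    # (sess_a, sess_b) -> [(ia, ib)]
    odor_labels: np.ndarray | None = None    # per trial
    extras: dict = field(default_factory=dict)


@dataclass
class SessionRecord:
    """One imaging session: the unit of longitudinal comparison."""

    fov_image: np.ndarray
    um_per_px: float
    masks: np.ndarray
    traces: np.ndarray | None = None
    trial_table: pd.DataFrame | None = None
    session_date: str | None = None
    session_id: int | None = None


@dataclass
class ZStack:
    """Reference axial stack, one averaged image per plane."""

    planes: np.ndarray       # (Z, H, W)
    spacing_um: float
    z0_um: float             # axial position of planes[0]

    @property
    def z_um(self) -> np.ndarray:
        return self.z0_um + self.spacing_um * np.arange(self.planes.shape[0])


def _axial_gain(z_um, axial_fwhm_um: float):
    """Gaussian axial sensitivity; unity at focus, 1/2 at half-FWHM offset."""
    return 2.0 ** (-((2.0 * np.asarray(z_um, dtype=float) / axial_fwhm_um) ** 2))


def gaussian_soma_mask(center_yx, sigma_px: float, shape) -> np.ndarray:
    """2D Gaussian soma footprint truncated at 2 sigma (weights in [0, 1])."""
    h, w = shape
    cy, cx = center_yx
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    m = np.exp(-0.5 * r2 / sigma_px**2)
    m[r2 > (2.0 * sigma_px) ** 2] = 0.0
    return m.astype(np.float32)


def make_cells(
    spec: SceneSpec,
    min_separation_px: float | None = None,
    max_attempts: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Place ``spec.n_cells`` Gaussian somata in the field of view.

    Returns ``(masks, centers)``: masks is (n_cells, H, W) float32 and
    centers is (n_cells, 2) in (y, x) pixel coordinates.  Somata are kept
    a soma-radius away from the frame edge; an optional minimum centre
    separation is enforced by rejection sampling.
    """
    h, w = spec.fov_px
    sigma = spec.soma_sigma_px
    margin = 2.0 * sigma + 1.0
    if 2 * margin >= min(h, w):
        raise ValueError("somata do not fit within fov_px")
    rng = np.random.default_rng(spec.seed)
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < spec.n_cells:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {spec.n_cells} cells with separation "
                f"{min_separation_px} px after {max_attempts} attempts"
            )
        attempts += 1
        c = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
        if min_separation_px is not None and centers:
            d2 = [(c[0] - a) ** 2 + (c[1] - b) ** 2 for a, b in centers]
            if min(d2) < min_separation_px**2:
                continue
        centers.append(c)
    centers_arr = np.asarray(centers, dtype=float).reshape(len(centers), 2)
    masks = np.stack(
        [gaussian_soma_mask(c, sigma, (h, w)) for c in centers]
    ) if centers else np.zeros((0, h, w), dtype=np.float32)
    return masks, centers_arr


def transient_kernel(
    tau_rise_s: float, tau_decay_s: float, frame_rate_hz: float, n_taus: float = 8.0
) -> np.ndarray:
    """Difference-of-exponentials calcium-transient kernel sampled at the frame rate."""
    if tau_rise_s <= 0 or tau_decay_s <= 0:
        raise ValueError("time constants must be positive")
    t = np.arange(0.0, n_taus * tau_decay_s, 1.0 / frame_rate_hz)
    return np.exp(-t / tau_decay_s) - np.exp(-t / tau_rise_s)


def simulate_transients(
    n_cells: int,
    duration_s: float,
    frame_rate_hz: float = 30.0,
    event_rate_hz: float = 0.1,
    amplitude: float = 1.0,
    tau_rise_s: float = 0.05,
    tau_decay_s: float = 0.4,
    seed: int = 0,
    baseline: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson event trains convolved with a GCaMP6f-like kernel.

    Returns ``(traces, events)`` with traces (n_cells, T) on a unit
    baseline and the integer event-count array used to build them.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n_frames = int(round(duration_s * frame_rate_hz))
    rng = np.random.default_rng(seed)
    events = rng.poisson(event_rate_hz / frame_rate_hz, size=(n_cells, n_frames))
    kernel = transient_kernel(tau_rise_s, tau_decay_s, frame_rate_hz)
    traces = np.empty((n_cells, n_frames))
    for i in range(n_cells):
        traces[i] = np.convolve(events[i] * amplitude, kernel)[:n_frames]
    return traces + baseline, events


def _warp_frame(frame: np.ndarray, displacement) -> np.ndarray:
    """Shift frame content by ``displacement`` (uniform (dy, dx) or dense (H, W, 2)).

    Uses inverse bilinear sampling with edge clamping, so that
    ``warped(y, x) = frame(y - dy, x - dx)`` -- content moves by +d.
    """
    h, w = frame.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    d = np.asarray(displacement, dtype=float)
    if d.shape == (2,):
        if np.all(d == 0):
            return frame.copy()
        coords = np.stack([yy - d[0], xx - d[1]])
    elif d.shape == (h, w, 2):
        coords = np.stack([yy - d[..., 0], xx - d[..., 1]])
    else:
        raise ValueError(f"displacement shape {d.shape} not understood")
    return ndimage.map_coordinates(frame, coords, order=1, mode="nearest")


def cell_axial_offsets(spec: SceneSpec, n_cells: int, spread_um: float = 5.0) -> np.ndarray:
    """Per-cell axial offsets drawn uniformly in +-spread_um (seeded).

    Somata in the pyramidal layer are staggered over several um in depth;
    without this stagger every z-stack plane is a scaled copy of the same
    scene and axial position cannot be resolved by correlation.
    """
    rng = np.random.default_rng(spec.seed + 3)
    return rng.uniform(-spread_um, spread_um, n_cells)


def render_movie(
    masks: np.ndarray,
    true_traces: np.ndarray,
    motion_true: np.ndarray | None,
    z_true: np.ndarray | None,
    spec: SceneSpec,
    cell_z_um: np.ndarray | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a movie: per-frame scene = sum of masks x trace x axial gain,
    warped by the motion field, plus photon and read noise.

    ``cell_z_um`` gives each soma its own axial position (default: all at
    the focal plane); the axial gain of cell i at frame t is then
    g(z_true[t] - cell_z_um[i])."""
    n_cells = masks.shape[0]
    n_frames = true_traces.shape[1]
    if true_traces.shape[0] != n_cells:
        raise ValueError("masks and true_traces disagree on n_cells")
    if motion_true is None:
        motion_true = np.zeros((n_frames, 2))
    motion_true = np.asarray(motion_true, dtype=float)
    if z_true is None:
        z_true = np.zeros(n_frames)
    z_true = np.asarray(z_true, dtype=float)
    if motion_true.shape[0] != n_frames or z_true.shape[0] != n_frames:
        raise ValueError("motion_true / z_true length must equal frame count")

    h, w = masks.shape[1:]
    flat_masks = masks.reshape(n_cells, -1)
    if cell_z_um is None:
        cell_z_um = np.zeros(n_cells)
    cell_z_um = np.asarray(cell_z_um, dtype=float)
    # (T, n_cells) axial gain per cell per frame
    gains = _axial_gain(z_true[:, None] - cell_z_um[None, :], spec.axial_fwhm_um)
    rng = np.random.default_rng(spec.seed + 1)
    movie = np.empty((n_frames, h, w), dtype=np.float32)
    for t in range(n_frames):
        scene = (true_traces[:, t] * gains[t]) @ flat_masks
        scene = scene.reshape(h, w) + spec.background
        frame = _warp_frame(scene, motion_true[t])
        frame *= spec.intensity_scale
        if spec.photon_noise:
            frame = rng.poisson(np.clip(frame, 0, None)).astype(np.float32)
        if spec.read_noise_sd > 0:
            frame = frame + rng.normal(0.0, spec.read_noise_sd, size=frame.shape)
        movie[t] = np.clip(frame, 0, None)
    gt = GroundTruth(
        masks=masks, true_traces=true_traces, motion_true=motion_true, z_true=z_true,
        extras={"cell_z_um": cell_z_um},
    )
    return movie, gt


def make_zstack(
    masks: np.ndarray,
    spec: SceneSpec,
    z_range_um: tuple[float, float] = (-10.0, 10.0),
    spacing_um: float = 1.0,
    n_average: int = 100,
    cell_z_um: np.ndarray | None = None,
) -> ZStack:
    """Reference z-stack: one image per 1 um plane, noise-averaged as if
    each plane were the mean of ``n_average`` frames.

    ``cell_z_um`` must match the offsets used to render the movie the
    stack is compared against."""
    if spacing_um <= 0:
        raise ValueError("spacing_um must be positive")
    z0, z1 = z_range_um
    z_planes = np.arange(z0, z1 + 0.5 * spacing_um, spacing_um)
    if z_planes.size == 0:
        raise ValueError("empty z range")
    n_cells = masks.shape[0]
    if cell_z_um is None:
        cell_z_um = np.zeros(n_cells)
    cell_z_um = np.asarray(cell_z_um, dtype=float)
    h, w = masks.shape[1:]
    flat_masks = masks.reshape(n_cells, -1)
    rng = np.random.default_rng(spec.seed + 2)
    planes = np.empty((z_planes.size, h, w), dtype=np.float32)
    for k, z in enumerate(z_planes):
        gains = _axial_gain(z - cell_z_um, spec.axial_fwhm_um)
        img = (gains @ flat_masks).reshape(h, w) + spec.background
        img = img * spec.intensity_scale
        if spec.photon_noise:
            # averaging n Poisson frames: mean lam, sd sqrt(lam/n)
            img = img + rng.normal(0.0, np.sqrt(np.clip(img, 0, None) / n_average))
        if spec.read_noise_sd > 0:
            img = img + rng.normal(
                0.0, spec.read_noise_sd / np.sqrt(n_average), size=img.shape
            )
        planes[k] = np.clip(img, 0, None)
    return ZStack(planes=planes, spacing_um=float(spacing_um), z0_um=float(z0))


def _render_session_masks(
    centers: np.ndarray,
    keep: np.ndarray,
    spec: SceneSpec,
    offset_px: tuple[float, float],
    zoom: float,
) -> np.ndarray:
    """Re-render kept somata under a session's translation and zoom.

    Zoom scales distances about the field centre (zoom 2 doubles soma
    diameters in px, i.e. halves um/px); the offset is applied in the
    session's pixel coordinates.
    """
    h, w = spec.fov_px
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    sigma = spec.soma_sigma_px * zoom
    out = []
    for c in centers[keep]:
        ny = cy + (c[0] - cy) * zoom + offset_px[0]
        nx = cx + (c[1] - cx) * zoom + offset_px[1]
        out.append(gaussian_soma_mask((ny, nx), sigma, (h, w)))
    return np.stack(out) if out else np.zeros((0, h, w), dtype=np.float32)


def make_sessions(
    base_masks: np.ndarray,
    base_centers: np.ndarray,
    spec: SceneSpec,
    n_sessions: int = 2,
    retention_frac: float = 1.0,
    offsets_px: list[tuple[float, float]] | None = None,
    zooms: list[float] | None = None,
    seed: int = 0,
) -> tuple[list[SessionRecord], GroundTruth]:
    """Multi-session fields of view sharing a cell constellation.

    Each session keeps a random ``round(retention_frac * n)`` subset of
    the base cells, shifted by its offset and rescaled by its zoom; the
    true cross-session pairings are recorded in the ground truth.

    A cell whose footprint falls more than half outside the session's
    field of view is not detectable in that session and is dropped from
    its mask set (and hence from the true pairings).
    """
    if not (0 < retention_frac <= 1):
        raise ValueError("retention_frac must be in (0, 1]")
    n = base_masks.shape[0]
    offsets_px = offsets_px or [(0.0, 0.0)] * n_sessions
    zooms = zooms or [1.0] * n_sessions
    rng = np.random.default_rng(seed)
    n_keep = int(round(retention_frac * n))
    h, w = spec.fov_px
    sessions: list[SessionRecord] = []
    kept_base: list[np.ndarray] = []
    for s in range(n_sessions):
        keep = np.sort(rng.choice(n, size=n_keep, replace=False))
        masks = _render_session_masks(base_centers, keep, spec, offsets_px[s], zooms[s])
        # full (unclipped) footprint integral at this session's zoom
        probe = gaussian_soma_mask(
            ((h - 1) / 2.0, (w - 1) / 2.0), spec.soma_sigma_px * zooms[s], (h, w)
        ).sum()
        visible = masks.reshape(len(keep), -1).sum(axis=1) / probe
        in_frame = visible >= 0.5
        if len(keep) and not in_frame.any():
            raise ValueError(f"session {s}: offset {offsets_px[s]} pushes all cells out of frame")
        keep = keep[in_frame]
        masks = masks[in_frame]
        fov = masks.sum(axis=0) * spec.intensity_scale + spec.background
        if spec.read_noise_sd > 0:
            fov = np.clip(fov + rng.normal(0.0, spec.read_noise_sd, size=fov.shape), 0, None)
        sessions.append(
            SessionRecord(
                fov_image=fov.astype(np.float32),
                um_per_px=spec.um_per_px / zooms[s],
                masks=masks,
                session_id=s,
            )
        )
        kept_base.append(keep)
    identity: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for a in range(n_sessions):
        for b in range(a + 1, n_sessions):
            common = np.intersect1d(kept_base[a], kept_base[b])
            la = {cell: i for i, cell in enumerate(kept_base[a])}
            lb = {cell: i for i, cell in enumerate(kept_base[b])}
            identity[(a, b)] = [(la[c], lb[c]) for c in common]
    gt = GroundTruth(
        masks=base_masks,
        centers=base_centers,
        session_offsets=[(tuple(o), z) for o, z in zip(offsets_px, zooms)],
        cell_identity_map=identity,
        extras={"kept_base_indices": kept_base},
    )
    return sessions, gt


def make_odor_trials(
    n_trials: int,
    n_odors: int,
    tuned_cells: dict[int, int],
    effect_size: float,
    spec: SceneSpec,
    seed: int = 0,
    trial_len_s: float = 3.0,
    base_amplitude: float = 0.2,
    noise_sd: float = 0.02,
    balanced: bool = True,
) -> tuple[np.ndarray, pd.DataFrame, GroundTruth]:
    """Odor-trial session: per trial 0.5 s blank air then 1 s odorized air.

    Every cell responds to odor onset with a transient of amplitude
    ``base_amplitude``; a tuned cell's amplitude is multiplied by
    ``(1 + effect_size)`` on trials of its preferred odor.  Returns the
    fractional-fluorescence traces (n_cells x T), a trial table with
    columns (trial_id, t_start_s, t_odor_on_s, odor_label), and ground
    truth recording labels and injected amplitudes.
    """
    if n_odors < 2:
        raise ValueError("need at least 2 odors")
    if trial_len_s < 1.5:
        raise ValueError("trial window must be at least 1.5 s (0.5 s blank + 1 s odor)")
    if balanced and n_trials % n_odors != 0:
        raise ValueError("n_trials must be divisible by n_odors for balanced labels")
    rng = np.random.default_rng(seed)
    labels = rng.permutation(np.repeat(np.arange(n_odors), n_trials // n_odors)) \
        if balanced else rng.integers(0, n_odors, size=n_trials)
    fs = spec.frame_rate_hz
    frames_per_trial = int(round(trial_len_s * fs))
    n_frames = frames_per_trial * n_trials
    n_cells = spec.n_cells
    kernel = transient_kernel(0.05, 0.4, fs)
    traces = np.zeros((n_cells, n_frames))
    amplitudes = np.zeros((n_trials, n_cells))
    odor_on_frame = int(round(0.5 * fs))
    for t in range(n_trials):
        start = t * frames_per_trial
        for c in range(n_cells):
            a = base_amplitude
            if tuned_cells.get(c) == labels[t]:
                a *= 1.0 + effect_size
            amplitudes[t, c] = a
            onset = start + odor_on_frame
            seg = min(len(kernel), n_frames - onset)
            traces[c, onset : onset + seg] += a * kernel[:seg]
    if noise_sd > 0:
        traces = traces + rng.normal(0.0, noise_sd, size=traces.shape)
    table = pd.DataFrame(
        {
            "trial_id": np.arange(n_trials),
            "t_start_s": np.arange(n_trials) * trial_len_s,
            "t_odor_on_s": np.arange(n_trials) * trial_len_s + 0.5,
            "odor_label": labels,
        }
    )
    gt = GroundTruth(
        odor_labels=labels,
        extras={"amplitudes": amplitudes, "tuned_cells": dict(tuned_cells),
                "base_amplitude": base_amplitude, "effect_size": effect_size},
    )
    return traces, table, gt


def make_insertion_series(
    n_insertions: int,
    displacement_sd_um: float,
    spec: SceneSpec,
    seed: int = 0,
    n_beads: int = 50,
    bead_sigma_um: float = 0.6,
) -> tuple[np.ndarray, np.ndarray]:
    """Repeated-insertion images of a fixed fluorescent-bead constellation.

    Each insertion shifts the whole constellation by an independent
    Gaussian (dy, dx) displacement with the given per-axis sd; beads are
    rendered analytically at subpixel positions so the recorded truth is
    exact.  Returns ``(images, true_displacements_px)``.
    """
    if n_insertions < 1:
        raise ValueError("n_insertions must be >= 1")
    h, w = spec.fov_px
    rng = np.random.default_rng(seed)
    margin = 6.0
    bead_yx = np.column_stack(
        [rng.uniform(margin, h - margin, n_beads), rng.uniform(margin, w - margin, n_beads)]
    )
    sd_px = displacement_sd_um / spec.um_per_px
    disp = rng.normal(0.0, sd_px, size=(n_insertions, 2)) if sd_px > 0 else np.zeros((n_insertions, 2))
    sigma_px = bead_sigma_um / spec.um_per_px
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    images = np.empty((n_insertions, h, w), dtype=np.float32)
    for i in range(n_insertions):
        img = np.zeros((h, w))
        for cy, cx in bead_yx + disp[i]:
            r2 = (yy - cy) ** 2 + (xx - cx) ** 2
            img += np.exp(-0.5 * r2 / sigma_px**2)
        img *= spec.intensity_scale
        if spec.read_noise_sd > 0:
            img = img + rng.normal(0.0, spec.read_noise_sd, size=img.shape)
        images[i] = np.clip(img, 0, None)
    return images, disp
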