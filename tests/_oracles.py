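"""Independent oracles used by the test suite.

Each function recomputes a quantity by a route independent of the
implementation it checks: dense brute-force searches, closed forms, or
fine numerical quadrature.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import fourier_shift

from cannulascope.optics import CannulaGeometry, CollectionModel, no_cannula


def dense_shift_search(reference, moving, dy_range, dx_range, step=0.05):
    """Brute-force subpixel registration: try every shift on a dense grid,
    score by correlation of the Fourier-shifted moving image."""
    ref = reference - reference.mean()
    best = None
    best_score = -np.inf
    F = np.fft.fft2(moving)
    for dy in np.arange(*dy_range, step):
        for dx in np.arange(*dx_range, step):
            shifted = np.real(np.fft.ifft2(fourier_shift(F, (-dy, -dx))))
            shifted -= shifted.mean()
            score = float((ref * shifted).sum())
            if score > best_score:
                best_score = score
                best = (dy, dx)
    return np.array(best)


def integer_offset_search(img_a, img_b, max_offset):
    """Exhaustive integer-offset normalised correlation on overlapping
    regions; returns the offset of b's content relative to a."""
    h, w = img_a.shape
    best = None
    best_score = -np.inf
    for dy in range(-max_offset, max_offset + 1):
        for dx in range(-max_offset, max_offset + 1):
            # offset (dy, dx) means b's content sits at +d relative to a:
            # compare a with b translated back by -d
            a = img_a[max(-dy, 0) : h + min(-dy, 0), max(-dx, 0) : w + min(-dx, 0)]
            b = img_b[max(dy, 0) : h + min(dy, 0), max(dx, 0) : w + min(dx, 0)]
            if a.size < 64:
                continue
            av = a - a.mean()
            bv = b - b.mean()
            den = np.sqrt((av**2).sum() * (bv**2).sum())
            if den == 0:
                continue
            score = float((av * bv).sum() / den)
            if score > best_score:
                best_score = score
                best = (dy, dx)
    return np.array(best)


def windowed_mode(trace, frame_rate_hz, window_minutes=3.0):
    """Direct per-window histogram mode at window centres (no interpolation)."""
    win = int(round(window_minutes * 60 * frame_rate_hz))
    hop = max(win // 2, 1)
    n = len(trace)
    centers, modes = [], []
    for s in range(0, n - win + 1, hop):
        seg = np.asarray(trace[s : s + win], dtype=float)
        counts, edges = np.histogram(seg, bins="fd")
        k = int(np.argmax(counts))
        centers.append(s + (win - 1) / 2.0)
        modes.append(0.5 * (edges[k] + edges[k + 1]))
    return np.array(centers), np.array(modes)


def quadrature_no_cannula_efficiency(
    depth_um: float,
    model: CollectionModel | None = None,
    geometry: CannulaGeometry | None = None,
    n: int = 400_001,
) -> float:
    """Collection efficiency for a bare coverslip by deterministic angular
    quadrature over the upward emission hemisphere (azimuthal symmetry):
    each polar angle is refracted water -> glass -> air analytically and
    passed through the two paraxial stops."""
    model = model or CollectionModel()
    g = geometry or no_cannula()
    d = depth_um / 1000.0
    tg = g.glass_thickness_mm
    th = (np.arange(n) + 0.5) * (np.pi / 2) / n
    sw = np.sin(th)
    s_glass = g.n_water * sw / g.n_glass
    escapes = (g.n_water * sw) < g.n_air           # no TIR at glass-air
    s_air = np.clip(g.n_water * sw / g.n_air, 0.0, 1.0 - 1e-12)
    tan_glass = s_glass / np.sqrt(1.0 - s_glass**2)
    tan_air = s_air / np.sqrt(1.0 - s_air**2)
    rho = d * np.tan(th) + tg * tan_glass          # exit radius at the glass top
    ok = escapes
    ok &= np.abs(rho + model.lens_focal_mm * tan_air) <= model.objective_aperture_diameter_mm / 2
    ok &= rho <= model.image_stop_half_diameter_mm
    return float(0.5 * np.trapezoid(ok.astype(float) * np.sin(th), th))


def cone_clip_fraction(source_r_mm, geometry, excitation_na=0.6, n_theta=400, n_phi=720):
    """Dense angular sampling of the excitation cone: fraction of solid
    angle whose straight air path clears the cannula wall and rim."""
    g = geometry
    theta_max = np.arcsin(excitation_na / g.n_water)
    th = (np.arange(n_theta) + 0.5) * theta_max / n_theta
    ph = (np.arange(n_phi) + 0.5) * 2 * np.pi / n_phi
    TH, PH = np.meshgrid(th, ph, indexing="ij")
    w = np.sin(TH)
    # refract at glass analytically (flat plates preserve transverse direction)
    s_air = g.n_water * np.sin(TH)
    s_glass = g.n_water * np.sin(TH) / g.n_glass
    tan_a = s_air / np.sqrt(1 - np.clip(s_air, 0, 1 - 1e-12) ** 2)
    tan_g = s_glass / np.sqrt(1 - s_glass**2)
    depth = 0.15
    rho0 = depth * np.tan(TH) + g.glass_thickness_mm * tan_g
    x0 = source_r_mm + rho0 * np.cos(PH)
    y0 = rho0 * np.sin(PH)
    clear = s_air < 1.0
    # walk the air path and require radius(z) inside the wall
    for frac in np.linspace(0.0, 1.0, 101):
        z = frac * g.height_mm
        x = x0 + tan_a * np.cos(PH) * z
        y = y0 + tan_a * np.sin(PH) * z
        clear &= np.hypot(x, y) <= g.radius_at(z)
    return float((w * clear).sum() / w.sum())


def rayleigh_cross_section_um2(diameter_um, wavelength_nm, n_particle, n_medium):
    """Rayleigh-limit scattering cross-section (x << 1) in um^2."""
    lam_medium = wavelength_nm / 1000.0 / n_medium
    x = np.pi * diameter_um / lam_medium
    m2 = (n_particle / n_medium) ** 2
    r = diameter_um / 2.0
    return (8.0 / 3.0) * np.pi * r**2 * x**4 * ((m2 - 1) / (m2 + 2)) ** 2
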