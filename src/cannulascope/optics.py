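"""Monte Carlo ray tracing of fluorescence collection through an imaging cannula.

The physical setup: a point fluorescent source sits in water ~150 um
below a #1 coverslip glued to the bottom of a steel cannula (conical,
5.2 mm top / 3.6 mm bottom inner diameter, or cylindrical, 5.1 mm bore;
height 2.6 mm).  Emitted light refracts water -> glass -> air; rays that
undergo total internal reflection at the glass-air interface are lost.
Inside the cannula, rays hitting the wall are reflected specularly with
reflectivity R (polished steel) or terminated (matte paint).  Above the
cannula, the objective and downstream collection optics are modelled
paraxially as a 4f pair of ideal lenses (f = 13 mm, 1x magnification)
with a 20 mm aperture stop at the first lens and a 1.5 mm half-diameter
stop at the image plane encoding the measured spatio-angular acceptance.

The measurement this reproduces scans the *cannula* relative to the
microscope, so the source always lies on the optical axis while the
cannula is displaced; tracing is done in cannula-centred coordinates
with the source at transverse position (r, 0) and the paraxial
acceptance referenced to the axis through the source.

The module also computes the Mie scattering length of the polystyrene
bead tissue phantom and analytic numerical-aperture utilities.

All lengths are mm internally; depths and scattering lengths are um at
the user interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "CannulaGeometry",
    "CollectionModel",
    "SourceSpec",
    "EfficiencyProfile",
    "MiePhantomSpec",
    "RayTraceResult",
    "conical_cannula",
    "cylindrical_cannula",
    "no_cannula",
    "half_angular_aperture",
    "sample_emission",
    "refract",
    "fresnel_transmittance",
    "trace_through_cannula",
    "acceptance_test",
    "collection_efficiency",
    "gain_profile",
    "excitation_transmission",
    "mie_scattering_length",
    "mie_efficiencies",
]

# ray status codes
ALIVE = 0
COLLECTED = 1
LOST = 2        # left the system without reaching the detector
TIR = 3         # trapped by total internal reflection at glass-air
ABSORBED = 4    # terminated at a matte wall / weight exhausted


@dataclass(frozen=True)
class CannulaGeometry:
    """Frustum (or cylinder) cannula with a glass floor.

    ``shape`` is "conical", "cylindrical" or "none" (cannula removed,
    bare coverslip).  Dimensions follow the machined parts: conical
    5.2 mm top / 3.6 mm bottom inner diameter; cylindrical 5.1 mm bore;
    height 2.6 mm; #1 coverslip (0.15 mm).
    """

    shape: str = "conical"
    top_inner_diameter_mm: float = 5.2
    bottom_inner_diameter_mm: float = 3.6
    height_mm: float = 2.6
    wall: str = "reflective"            # "reflective" | "matte"
    reflectivity: float = 0.6
    glass_thickness_mm: float = 0.15
    n_water: float = 1.33
    n_glass: float = 1.515
    n_air: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in ("conical", "cylindrical", "none"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.shape != "none":
            if self.height_mm <= 0:
                raise ValueError("degenerate geometry: height must be positive")
            if self.bottom_inner_diameter_mm > self.top_inner_diameter_mm:
                raise ValueError("bottom diameter must not exceed top diameter")
        if not (0.0 <= self.reflectivity <= 1.0):
            raise ValueError("reflectivity must be in [0, 1]")

    @property
    def r_bottom(self) -> float:
        return self.bottom_inner_diameter_mm / 2.0

    @property
    def r_top(self) -> float:
        return self.top_inner_diameter_mm / 2.0

    @property
    def wall_slope(self) -> float:
        """d(radius)/dz of the inner wall."""
        return (self.r_top - self.r_bottom) / self.height_mm

    def radius_at(self, z: float) -> float:
        return self.r_bottom + self.wall_slope * z


def conical_cannula(**kw) -> CannulaGeometry:
    return CannulaGeometry(shape="conical", **kw)


def cylindrical_cannula(wall: str = "matte", **kw) -> CannulaGeometry:
    """The conventional cylindrical cannula (non-reflective by default)."""
    kw.setdefault("top_inner_diameter_mm", 5.1)
    kw.setdefault("bottom_inner_diameter_mm", 5.1)
    return CannulaGeometry(shape="cylindrical", wall=wall, **kw)


def no_cannula(**kw) -> CannulaGeometry:
    """Bare coverslip reference (cannula removed)."""
    return CannulaGeometry(shape="none", **kw)


@dataclass(frozen=True)
class CollectionModel:
    """Paraxial 4f acceptance model of the objective + collection optics."""

    lens_focal_mm: float = 13.0
    objective_aperture_diameter_mm: float = 20.0
    image_stop_half_diameter_mm: float = 1.5
    magnification: float = 1.0

    def __post_init__(self) -> None:
        if min(self.lens_focal_mm, self.objective_aperture_diameter_mm,
               self.image_stop_half_diameter_mm) <= 0:
            raise ValueError("model dimensions must be positive")


@dataclass(frozen=True)
class SourceSpec:
    """Isotropic point emitter at radial offset r, depth d below the glass."""

    r_mm: float = 0.0
    depth_um: float = 150.0
    n_rays: int = 100_000
    seed: int = 0


@dataclass
class EfficiencyProfile:
    radii_mm: np.ndarray
    raw_efficiency: np.ndarray
    mc_error: np.ndarray
    normalized: np.ndarray | None = None
    normalization: str = "no-cannula reference, scaled to cylindrical center"
    valid: np.ndarray | None = None


@dataclass
class RayTraceResult:
    """Batched ray-trace outcome with conserved weight accounting."""

    position: np.ndarray       # (N, 3) mm; exit position for surviving rays
    direction: np.ndarray      # (N, 3)
    weight: np.ndarray         # (N,)
    status: np.ndarray         # (N,) int codes
    absorbed_weight: float = 0.0   # weight deposited in walls (1 - R per bounce)

    def weight_totals(self) -> dict:
        out = {}
        for name, code in (("alive", ALIVE), ("collected", COLLECTED),
                           ("lost", LOST), ("tir", TIR), ("absorbed", ABSORBED)):
            out[name] = float(self.weight[self.status == code].sum())
        out["wall_absorbed"] = self.absorbed_weight
        return out


def half_angular_aperture(na: float, n_medium: float) -> float:
    """Half angular aperture in degrees: arcsin(NA / n)."""
    if not 0 <= na < n_medium:
        raise ValueError("NA must satisfy 0 <= NA < n_medium")
    return float(np.degrees(np.arcsin(na / n_medium)))


def sample_emission(source: SourceSpec, geometry: CannulaGeometry | None = None):
    """Isotropic unit directions over the full sphere, origins at the source.

    Returns ``(positions, directions, weights)``; the source sits at
    (r, 0, -(glass + depth)) in cannula-centred coordinates with z = 0 at
    the top (inner) surface of the glass.
    """
    if source.n_rays < 1:
        raise ValueError("n_rays must be >= 1")
    g = geometry or CannulaGeometry()
    rng = np.random.default_rng(source.seed)
    n = source.n_rays
    u = rng.uniform(-1.0, 1.0, n)            # cos(theta)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(1.0 - u**2)
    directions = np.column_stack([s * np.cos(phi), s * np.sin(phi), u])
    z0 = -(g.glass_thickness_mm + source.depth_um / 1000.0)
    positions = np.tile([source.r_mm, 0.0, z0], (n, 1)).astype(float)
    return positions, directions, np.ones(n)


def refract(direction, normal, n1: float, n2: float):
    """Vector Snell refraction; supports batched (N, 3) inputs.

    Returns ``(refracted, tir)``: unit refracted directions (rows are
    unchanged where TIR occurs) and a boolean TIR flag.  ``normal``
    should oppose the incoming direction (d . n < 0).
    """
    d = np.atleast_2d(np.asarray(direction, dtype=float))
    nrm = np.atleast_2d(np.asarray(normal, dtype=float))
    if nrm.shape[0] == 1:
        nrm = np.broadcast_to(nrm, d.shape)
    eta = n1 / n2
    cos_i = -np.sum(d * nrm, axis=1)
    sin2_t = eta**2 * (1.0 - cos_i**2)
    tir = sin2_t > 1.0
    cos_t = np.sqrt(np.clip(1.0 - sin2_t, 0.0, None))
    out = eta * d + (eta * cos_i - cos_t)[:, None] * nrm
    out[tir] = d[tir]
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    out = out / np.where(norms > 0, norms, 1.0)
    if np.asarray(direction).ndim == 1:
        return out[0], bool(tir[0])
    return out, tir


def fresnel_transmittance(cos_i, cos_t, n1: float, n2: float):
    """Unpolarized Fresnel power transmittance (average of s and p)."""
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 1.0 - 0.5 * (rs**2 + rp**2)


def _refract_plane_z(pos, d, w, status, z_plane, n1, n2, fresnel=False):
    """Propagate alive upward rays to a horizontal plane and refract."""
    alive = status == ALIVE
    t = np.where(d[:, 2] > 0, (z_plane - pos[:, 2]) / np.where(d[:, 2] != 0, d[:, 2], 1.0), np.inf)
    pos[alive] += d[alive] * t[alive, None]
    eta = n1 / n2
    cos_i = d[alive, 2]
    sin2_t = eta**2 * (1.0 - cos_i**2)
    tir = sin2_t > 1.0
    cos_t = np.sqrt(np.clip(1.0 - sin2_t, 0.0, None))
    new_d = d[alive].copy()
    new_d[:, 0] *= eta
    new_d[:, 1] *= eta
    new_d[:, 2] = cos_t
    new_d[tir] = d[alive][tir]
    if fresnel:
        w_alive = w[alive]
        w_alive[~tir] *= fresnel_transmittance(cos_i[~tir], cos_t[~tir], n1, n2)
        w[alive] = w_alive
    d[alive] = new_d
    idx = np.where(alive)[0]
    status[idx[tir]] = TIR
    return pos, d, w, status


def trace_through_cannula(
    positions: np.ndarray,
    directions: np.ndarray,
    weights: np.ndarray,
    geometry: CannulaGeometry,
    max_bounces: int = 10,
    fresnel: bool = False,
    from_water: bool = True,
) -> RayTraceResult:
    """Trace rays from the water, through the glass floor and the cannula
    interior, to the plane of the cannula's top rim.

    ``from_water=False`` starts rays directly in the air inside the
    cannula (skipping emission/refraction bookkeeping), which is useful
    for probing wall interactions in isolation.

    Surviving rays end with status ALIVE at z = height (or at the glass
    top for ``shape='none'``, where they are simply extended); rays are
    terminated by downward emission, TIR at the glass-air interface,
    striking the metal floor outside the bore, or matte-wall absorption.
    Specular wall hits multiply the weight by the reflectivity and
    deposit the remainder as absorbed; bounces are capped at
    ``max_bounces``.
    """
    g = geometry
    pos = np.array(positions, dtype=float)
    d = np.array(directions, dtype=float)
    w = np.array(weights, dtype=float)
    status = np.full(len(w), ALIVE, dtype=int)
    absorbed = 0.0

    if from_water:
        # downward emission is lost (no backscatter)
        status[d[:, 2] <= 0] = LOST

        zg = -g.glass_thickness_mm
        pos, d, w, status = _refract_plane_z(pos, d, w, status, zg, g.n_water, g.n_glass, fresnel)
        pos, d, w, status = _refract_plane_z(pos, d, w, status, 0.0, g.n_glass, g.n_air, fresnel)

        if g.shape == "none":
            return RayTraceResult(pos, d, w, status, absorbed)

        # rays emerging outside the bore strike the cannula's metal floor
        alive = status == ALIVE
        r2 = pos[:, 0] ** 2 + pos[:, 1] ** 2
        outside = alive & (r2 > g.r_bottom**2)
        status[outside] = LOST
    elif g.shape == "none":
        return RayTraceResult(pos, d, w, status, absorbed)

    k = g.wall_slope
    r0 = g.r_bottom
    h = g.height_mm
    R = g.reflectivity if g.wall == "reflective" else 0.0

    for _ in range(max_bounces + 1):
        alive = np.where(status == ALIVE)[0]
        inside = alive[pos[alive, 2] < h - 1e-12]
        if inside.size == 0:
            break
        p = pos[inside]
        v = d[inside]
        # candidate 1: top plane z = h
        with np.errstate(divide="ignore", invalid="ignore"):
            t_top = np.where(v[:, 2] > 0, (h - p[:, 2]) / v[:, 2], np.inf)
            t_floor = np.where(v[:, 2] < 0, (0.0 - p[:, 2]) / v[:, 2], np.inf)
        # candidate 2: frustum wall x^2 + y^2 = (r0 + k z)^2
        A = v[:, 0] ** 2 + v[:, 1] ** 2 - (k * v[:, 2]) ** 2
        rz = r0 + k * p[:, 2]
        B = 2.0 * (p[:, 0] * v[:, 0] + p[:, 1] * v[:, 1] - k * rz * v[:, 2])
        C = p[:, 0] ** 2 + p[:, 1] ** 2 - rz**2
        t_wall = np.full(len(inside), np.inf)
        eps = 1e-9
        lin = np.abs(A) < 1e-14
        with np.errstate(divide="ignore", invalid="ignore"):
            t_lin = -C / np.where(lin, B, 1.0)
        t_wall[lin & (t_lin > eps)] = t_lin[lin & (t_lin > eps)]
        disc = B**2 - 4 * A * C
        quad = (~lin) & (disc >= 0)
        sq = np.sqrt(np.clip(disc, 0, None))
        for sign in (-1.0, 1.0):
            t_c = (-B + sign * sq) / (2 * A)
            take = quad & (t_c > eps) & (t_c < t_wall)
            t_wall[take] = t_c[take]
        t_hit = np.minimum(np.minimum(t_top, t_floor), t_wall)
        newp = p + v * t_hit[:, None]
        pos[inside] = newp

        hit_top = t_top <= np.minimum(t_floor, t_wall)
        hit_floor = (~hit_top) & (t_floor <= t_wall)
        hit_wall = ~(hit_top | hit_floor)

        status[inside[hit_floor]] = LOST  # back onto the glass floor: discarded
        # top-exiting rays stay ALIVE and are done (z == h)

        wi = inside[hit_wall]
        if wi.size:
            if R == 0.0:
                absorbed += float(w[wi].sum())
                w[wi] = 0.0
                status[wi] = ABSORBED
            else:
                x, y, z = pos[wi, 0], pos[wi, 1], pos[wi, 2]
                rr = np.sqrt(x**2 + y**2)
                rr = np.where(rr > 0, rr, 1.0)
                # inward surface normal of the frustum
                nvec = np.column_stack([-x / rr, -y / rr, np.full(len(wi), k)])
                nvec /= np.linalg.norm(nvec, axis=1, keepdims=True)
                vv = d[wi]
                d[wi] = vv - 2.0 * np.sum(vv * nvec, axis=1, keepdims=True) * nvec
                absorbed += float((w[wi] * (1.0 - R)).sum())
                w[wi] *= R
    # bounce cap: anything still below the rim is dropped as absorbed
    alive = np.where(status == ALIVE)[0]
    stuck = alive[pos[alive, 2] < h - 1e-12]
    if stuck.size:
        absorbed += float(w[stuck].sum())
        w[stuck] = 0.0
        status[stuck] = ABSORBED
    return RayTraceResult(pos, d, w, status, absorbed)


def acceptance_test(
    positions: np.ndarray,
    directions: np.ndarray,
    model: CollectionModel,
    axis_xy: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Paraxial spatio-angular acceptance of exit rays (boolean mask).

    Each ray is extrapolated back to the nominal focal plane z = 0 to
    obtain its apparent transverse position p (relative to the optics
    axis ``axis_xy``) and slope u.  Stop 1 (objective front aperture):
    |p + f u| <= aperture/2 at the first lens.  Stop 2 (image stop, 4f
    with -1x image): |p| <= image stop half-diameter.  Collected iff
    both pass.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    up = d[:, 2] > 0
    u = np.zeros((len(d), 2))
    u[up] = d[up, :2] / d[up, 2][:, None]
    p = pos[:, :2] - u * pos[:, 2][:, None]
    p = p - np.asarray(axis_xy, dtype=float)
    at_lens = p + model.lens_focal_mm * u
    ok1 = np.linalg.norm(at_lens, axis=1) <= model.objective_aperture_diameter_mm / 2.0
    ok2 = np.linalg.norm(p, axis=1) <= model.image_stop_half_diameter_mm
    out = up & ok1 & ok2
    return out if np.asarray(positions).ndim == 2 else out[0]


def collection_efficiency(
    source: SourceSpec,
    geometry: CannulaGeometry,
    model: CollectionModel | None = None,
    max_bounces: int = 10,
    fresnel: bool = False,
) -> tuple[float, float]:
    """Fraction of emitted light reaching the detector, with MC error.

    Efficiency = sum of collected ray weights / n_rays; the error is the
    standard error of the per-ray collected weight.
    """
    model = model or CollectionModel()
    if source.n_rays < 1:
        raise ValueError("n_rays must be >= 1")
    pos, d, w = sample_emission(source, geometry)
    res = trace_through_cannula(pos, d, w, geometry, max_bounces, fresnel)
    alive = res.status == ALIVE
    collected_w = np.zeros(source.n_rays)
    if alive.any():
        acc = acceptance_test(
            res.position[alive], res.direction[alive], model, axis_xy=(source.r_mm, 0.0)
        )
        collected_w[np.where(alive)[0][acc]] = res.weight[alive][acc]
        idx = np.where(alive)[0]
        res.status[idx[acc]] = COLLECTED
        res.status[idx[~acc]] = LOST
    eff = float(collected_w.mean())
    se = float(collected_w.std(ddof=1) / np.sqrt(source.n_rays)) if source.n_rays > 1 else np.nan
    return eff, se


def gain_profile(
    radii_mm: np.ndarray,
    depth_um: float = 150.0,
    conical: CannulaGeometry | None = None,
    cylindrical: CannulaGeometry | None = None,
    model: CollectionModel | None = None,
    n_rays: int = 100_000,
    seed: int = 0,
) -> tuple[EfficiencyProfile, EfficiencyProfile, np.ndarray]:
    """Normalized collection profiles for both cannulas and their gain ratio.

    Each profile is divided by the no-cannula (bare coverslip) reference
    efficiency and scaled so the cylindrical profile equals 1 at the
    cannula centre, mirroring the fluorescein-well measurement protocol.
    Radii beyond the conical cannula's bottom radius are flagged invalid
    (the hatched region of the measurement); radii beyond the
    cylindrical bore raise.
    """
    conical = conical or conical_cannula()
    cylindrical = cylindrical or cylindrical_cannula()
    model = model or CollectionModel()
    radii = np.asarray(radii_mm, dtype=float)
    if np.any(radii > cylindrical.r_bottom):
        raise ValueError("radius beyond the cylindrical bore")
    valid = radii <= conical.r_bottom

    ref_eff, _ = collection_efficiency(
        SourceSpec(0.0, depth_um, n_rays, seed), no_cannula(), model
    )
    prof = {}
    for name, geom in (("conical", conical), ("cylindrical", cylindrical)):
        eff = np.empty_like(radii)
        err = np.empty_like(radii)
        for i, r in enumerate(radii):
            eff[i], err[i] = collection_efficiency(
                SourceSpec(float(r), depth_um, n_rays, seed + 7 * i + 1), geom, model
            )
        prof[name] = EfficiencyProfile(radii, eff, err, valid=valid)
    scale = prof["cylindrical"].raw_efficiency[np.argmin(np.abs(radii))] / ref_eff
    for p in prof.values():
        p.normalized = (p.raw_efficiency / ref_eff) / scale
    gains = np.where(
        valid, prof["conical"].raw_efficiency / prof["cylindrical"].raw_efficiency, np.nan
    )
    return prof["conical"], prof["cylindrical"], gains


def excitation_transmission(
    source_r_mm: float,
    geometry: CannulaGeometry,
    excitation_na: float = 0.6,
    n_theta: int = 120,
    n_phi: int = 240,
) -> tuple[float, float]:
    """Unclipped fraction f of the focused excitation cone, and f^2.

    The excitation converges through the cannula onto the source; by
    reversibility, the clear fraction is the solid-angle-weighted share
    of rays from the source (within the water-side cone of the given
    air-side NA) whose straight air path from the glass top to the top
    rim stays inside the wall.  f^2 is the two-photon signal factor.
    """
    if not 0 <= excitation_na < 1:
        raise ValueError("NA must be in [0, 1)")
    g = geometry
    if g.shape == "none":
        return 1.0, 1.0
    theta_w_max = np.arcsin(excitation_na / g.n_water)
    th = (np.arange(n_theta) + 0.5) * theta_w_max / n_theta
    ph = (np.arange(n_phi) + 0.5) * 2 * np.pi / n_phi
    TH, PH = np.meshgrid(th, ph, indexing="ij")
    wgt = np.sin(TH)
    d = np.stack(
        [np.sin(TH) * np.cos(PH), np.sin(TH) * np.sin(PH), np.cos(TH)], axis=-1
    ).reshape(-1, 3)
    depth = 0.15  # source depth is immaterial to the clipping above the glass
    pos = np.tile([source_r_mm, 0.0, -(g.glass_thickness_mm + depth)], (len(d), 1))
    res = trace_through_cannula(pos, d, np.ones(len(d)), g, max_bounces=0)
    # a clipped ray either died (floor/wall/TIR) or bounced (weight < 1)
    clear = (res.status == ALIVE) & (res.weight >= 1.0 - 1e-12) & (
        res.position[:, 2] >= g.height_mm - 1e-9
    )
    f = float((wgt.ravel() * clear).sum() / wgt.sum())
    return f, f * f


# ----------------------------------------------------------------------
# Mie scattering


@dataclass(frozen=True)
class MiePhantomSpec:
    """Polystyrene-bead tissue phantom (scattering mimic of brain tissue)."""

    bead_diameter_um: float = 0.974
    density_per_ml: float = 5.4e9
    wavelength_nm: float = 520.0
    n_particle: float = 1.598
    n_medium: float = 1.336

    def __post_init__(self) -> None:
        if min(self.bead_diameter_um, self.wavelength_nm, self.n_medium) <= 0:
            raise ValueError("phantom parameters must be positive")
        if self.n_particle <= self.n_medium:
            raise ValueError("n_particle must exceed n_medium")


def mie_efficiencies(x: float, m: complex) -> tuple[float, float]:
    """Mie extinction and scattering efficiencies (Q_ext, Q_sca) for a
    homogeneous sphere of size parameter x and relative index m.

    Standard Lorenz–Mie series with the logarithmic-derivative downward
    recurrence for the internal field and upward recurrence of the
    Riccati–Bessel functions for the external field.
    """
    if x <= 0:
        raise ValueError("size parameter must be positive")
    m = complex(m)
    nmax = int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))
    mx = m * x
    # logarithmic derivative D_n(mx), downward recurrence
    nmx = int(np.ceil(max(nmax, abs(mx)) + 16))
    D = np.zeros(nmx + 1, dtype=complex)
    for n in range(nmx, 0, -1):
        D[n - 1] = n / mx - 1.0 / (D[n] + n / mx)
    n = np.arange(1, nmax + 1)
    # Riccati-Bessel psi_n(x) = x j_n(x), chi_n(x) = -x y_n(x)
    psi = x * special.spherical_jn(n, x)
    chi = -x * special.spherical_yn(n, x)
    psi0 = np.sin(x)
    chi0 = np.cos(x)
    psi_prev = np.concatenate([[psi0], psi[:-1]])
    chi_prev = np.concatenate([[chi0], chi[:-1]])
    xi = psi - 1j * chi
    xi_prev = psi_prev - 1j * chi_prev
    Dn = D[1 : nmax + 1]
    fa = Dn / m + n / x
    fb = Dn * m + n / x
    a = (fa * psi - psi_prev) / (fa * xi - xi_prev)
    b = (fb * psi - psi_prev) / (fb * xi - xi_prev)
    coeff = 2.0 * n + 1.0
    qext = (2.0 / x**2) * float(np.sum(coeff * (a + b).real))
    qsca = (2.0 / x**2) * float(np.sum(coeff * (np.abs(a) ** 2 + np.abs(b) ** 2)))
    return qext, qsca


def mie_scattering_cross_section(phantom: MiePhantomSpec) -> float:
    """Scattering cross-section of one bead, in um^2."""
    lam_um = phantom.wavelength_nm / 1000.0
    x = np.pi * phantom.bead_diameter_um * phantom.n_medium / lam_um
    m = phantom.n_particle / phantom.n_medium
    _, qsca = mie_efficiencies(x, m)
    radius = phantom.bead_diameter_um / 2.0
    return qsca * np.pi * radius**2


def mie_scattering_length(phantom: MiePhantomSpec) -> float:
    """Scattering mean free path of the phantom in um: 1 / (density sigma_s).

    Zero density returns inf (nothing to scatter off).
    """
    if phantom.density_per_ml == 0:
        return float("inf")
    sigma_um2 = mie_scattering_cross_section(phantom)
    density_per_um3 = phantom.density_per_ml / 1e12  # 1 mL = 1e12 um^3
    return float(1.0 / (density_per_um3 * sigma_um2))
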