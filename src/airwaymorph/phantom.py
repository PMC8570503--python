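"""Synthetic paired CT airway phantoms with analytically known truth.

A phantom is a tubular air-filled lumen (elliptical cross-section of
prescribed area and axis-ratio profiles) embedded in a soft-tissue block,
optionally decorated with anterior dead-space pockets (mouth, vallecula)
and disconnected air blobs (islands). The analytic geometry makes every
reported airway parameter computable by quadrature, independent of any
voxelization, so the voxel pipeline can be validated against closed truth.

The paired-scan perturbation model multiplies the area profile by a smooth
random field, jitters the soft-tissue landmark fractions, and optionally
bends the tube axis — emulating posture/breathing variation between two
acquisitions. The bony PNS landmark is never perturbed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy import ndimage, optimize

from .core import AirwayParameters, LandmarkSet, VolumeImage
from .errors import ValidationError

__all__ = [
    "PhantomSpec", "PhantomTruth", "Pocket", "Island", "Perturbation",
    "make_phantom", "perturb_phantom", "analytic_truth",
    "default_spec", "constant_tube_spec", "ball_spec", "random_subject_spec",
]

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(10)


@dataclass(frozen=True)
class Pocket:
    """Anterior dead-space lobe attached to the lumen from above."""
    center: tuple[float, float, float]   # mm
    radius: float                        # mm
    attachment: str = "mouth"            # {"mouth", "vallecular"}


@dataclass(frozen=True)
class Island:
    """Disconnected air blob, strictly outside lumen and pockets."""
    center: tuple[float, float, float]   # mm
    radius: float                        # mm


@dataclass
class PhantomSpec:
    """Analytic description of one phantom scan.

    The superior (PNS) boundary plane is at ``z = axis_length`` and the
    inferior (BEP) plane at ``z = 0``; the lumen tube extends a little
    beyond both planes so that boundary cropping is exercised.
    """

    axis_length: float = 60.0
    area_profile: Callable[[np.ndarray], np.ndarray] = None       # z (mm) -> mm^2
    ellipse_ratio_profile: Callable[[np.ndarray], np.ndarray] = None  # z -> LAT/AP ratio
    center_profile: Callable[[np.ndarray], np.ndarray] | None = None  # z -> (cx, cy) mm
    landmark_fracs: dict[str, float] = field(
        default_factory=lambda: {"TUV": 0.45, "TEP": 0.75, "BEP": 1.0})
    pockets: tuple[Pocket, ...] = ()
    islands: tuple[Island, ...] = ()
    hu_air: float = -1000.0
    hu_tissue: float = 40.0
    noise_sd: float = 10.0
    voxel_spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    pns_margin: float = 5.0      # anterior clearance of PNS beyond the lumen wall
    pns_y: float | None = None   # frozen anterior-cut height; resolved if None
    z_pad: float = 3.0           # tube overhang beyond each boundary plane
    xy_margin: float = 2.0       # tissue margin around all air features

    def __post_init__(self) -> None:
        if self.area_profile is None:
            self.area_profile = lambda z: np.full_like(np.asarray(z, float), 200.0)
        if self.ellipse_ratio_profile is None:
            self.ellipse_ratio_profile = lambda z: np.ones_like(np.asarray(z, float))
        self.pockets = tuple(self.pockets)
        self.islands = tuple(self.islands)


@dataclass
class PhantomTruth:
    """Per-region ground-truth parameters computed from the analytic geometry."""

    per_region: dict[str, AirwayParameters]
    landmark_heights: dict[str, float]

    def __getitem__(self, region: str) -> AirwayParameters:
        return self.per_region[region]


@dataclass(frozen=True)
class Perturbation:
    """Paired-scan variation model amplitudes (all >= 0)."""
    area_scale_amp: float = 0.0      # fractional, smooth field in [1-amp, 1+amp]
    landmark_jitter_sd: float = 0.0  # mm, applied to soft-tissue landmark heights
    axis_bend_amp: float = 0.0       # mm, lateral bowing of the tube axis


# ---------------------------------------------------------------------------
# validation and resolved geometry
# ---------------------------------------------------------------------------

def validate_spec(spec: PhantomSpec) -> None:
    z = np.linspace(0.0, spec.axis_length, 2001)
    if spec.axis_length <= 0:
        raise ValidationError("axis_length must be positive")
    areas = np.asarray(spec.area_profile(z), float)
    # zero area is tolerated at the exact endpoints so that a closed tube may
    # degenerate to a ball (the sphericity-of-one extreme)
    if not (np.all(areas >= 0) and np.all(areas[1:-1] > 0)):
        raise ValidationError(
            "invariant violated: area_profile(z) > 0 for all z in (0, axis_length)")
    fr = spec.landmark_fracs
    for name in ("TUV", "TEP", "BEP"):
        if name not in fr:
            raise ValidationError(f"landmark_fracs missing {name!r}")
    if not (0.0 < fr["TUV"] < fr["TEP"] < fr["BEP"] <= 1.0):
        raise ValidationError(
            "invariant violated: landmark fractions must satisfy "
            "0 < frac(TUV) < frac(TEP) < frac(BEP) <= 1")
    for amp in (spec.noise_sd,):
        if amp < 0:
            raise ValidationError("noise_sd must be >= 0")


class _Geometry:
    """Resolved semi-axes and centre of the lumen as functions of height."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        self.L = spec.axis_length

    def clamped(self, z):
        return np.clip(np.asarray(z, float), 0.0, self.L)

    def ab(self, z):
        """Semi-axes (a lateral, b anteroposterior) at height z (clamped)."""
        zc = self.clamped(z)
        A = np.asarray(self.spec.area_profile(zc), float)
        r = np.asarray(self.spec.ellipse_ratio_profile(zc), float)
        b = np.sqrt(np.maximum(A, 0.0) / (np.pi * r))
        return r * b, b

    def center(self, z):
        zc = self.clamped(z)
        if self.spec.center_profile is None:
            zc = np.asarray(zc)
            zero = np.zeros(zc.shape)
            return zero, zero
        c = np.asarray(self.spec.center_profile(zc), float)
        return c[..., 0], c[..., 1]


def resolve_pns_y(spec: PhantomSpec) -> float:
    """Anterior-cut height: anterior-most lumen wall plus a fixed margin.

    Frozen into the spec by :func:`perturb_phantom` so that the bony PNS
    landmark is re-used between paired scans.
    """
    if spec.pns_y is not None:
        return float(spec.pns_y)
    geo = _Geometry(spec)
    z = np.linspace(0.0, spec.axis_length, 2001)
    _, b = geo.ab(z)
    _, cy = geo.center(z)
    return float(np.max(cy + b) + spec.pns_margin)


def landmark_heights(spec: PhantomSpec) -> dict[str, float]:
    L = spec.axis_length
    fr = spec.landmark_fracs
    z = {"PNS": L}
    for name in ("TUV", "TEP", "BEP"):
        z[name] = L * (1.0 - fr[name])
    z["MUE"] = 0.5 * (z["TUV"] + z["TEP"])
    return z


# ---------------------------------------------------------------------------
# analytic truth
# ---------------------------------------------------------------------------

def _panel_quad(f, z0: float, z1: float, panels: int) -> float:
    """Composite 10-point Gauss-Legendre quadrature of a vectorized f."""
    edges = np.linspace(z0, z1, panels + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    half = 0.5 * (edges[1:] - edges[:-1])
    zs = (mid[:, None] + half[:, None] * _GL_NODES[None, :]).ravel()
    w = (half[:, None] * _GL_WEIGHTS[None, :]).ravel()
    return float(np.dot(np.asarray(f(zs), float), w))


def _lateral_surface(geo: _Geometry, z0: float, z1: float,
                     n_theta: int = 256, panels: int = 120) -> float:
    """Lateral area of the generalized elliptic cylinder between two planes.

    Parametrize r(theta, z) = (cx + a cos t, cy + b sin t, z) and integrate
    |dr/dt x dr/dz|. The squared-semi-axis derivative form keeps the
    integrand finite even where the profile pinches to zero area (the
    degenerate-ball case).
    """
    spec = geo.spec
    eps = 1e-6 * geo.L
    theta = (np.arange(n_theta) + 0.5) * (2 * np.pi / n_theta)
    sin2, cos2 = np.sin(theta) ** 2, np.cos(theta) ** 2
    sin_t, cos_t = np.sin(theta), np.cos(theta)

    def integrand(z):
        z = np.asarray(z, float)
        A = np.asarray(spec.area_profile(np.clip(z, 0, geo.L)), float)
        r = np.asarray(spec.ellipse_ratio_profile(np.clip(z, 0, geo.L)), float)
        g = A * r / np.pi            # a^2
        h = A / (np.pi * r)          # b^2
        a = np.sqrt(np.maximum(g, 0.0))
        b = np.sqrt(np.maximum(h, 0.0))

        def gh(zz):
            zz = np.asarray(zz, float)
            AA = np.asarray(spec.area_profile(zz), float)
            rr = np.asarray(spec.ellipse_ratio_profile(zz), float)
            return AA * rr / np.pi, AA / (np.pi * rr)

        gp, hp = gh(z + eps)
        gm, hm = gh(z - eps)
        dg = (gp - gm) / (2 * eps)   # d(a^2)/dz = 2 a a'
        dh = (hp - hm) / (2 * eps)   # d(b^2)/dz = 2 b b'
        # a*b' = (a/b)*(b b') = r * dh/2 ; a'*b = (b/a)*(a a') = dg/(2 r)
        ab_p = r * dh / 2.0
        ap_b = dg / (2.0 * r)
        cxp, cyp = geo.center(z + eps)
        cxm, cym = geo.center(z - eps)
        dcx = (np.asarray(cxp) - np.asarray(cxm)) / (2 * eps)
        dcy = (np.asarray(cyp) - np.asarray(cym)) / (2 * eps)

        # broadcast (z, theta)
        zcomp = (a[:, None] * dcy[:, None] * sin_t[None, :]
                 + ab_p[:, None] * sin2[None, :]
                 + b[:, None] * dcx[:, None] * cos_t[None, :]
                 + ap_b[:, None] * cos2[None, :])
        mag2 = (np.maximum(h, 0)[:, None] * cos2[None, :]
                + np.maximum(g, 0)[:, None] * sin2[None, :]
                + zcomp ** 2)
        return np.sqrt(mag2).mean(axis=1) * (2 * np.pi)

    return _panel_quad(integrand, z0, z1, panels)


def _region_bounds(spec: PhantomSpec) -> dict[str, tuple[float, float]]:
    z = landmark_heights(spec)
    return {
        "velopharynx": (z["TUV"], z["PNS"]),
        "oropharynx": (z["MUE"], z["TUV"]),
        "tongue_base": (z["TEP"], z["MUE"]),
        "epiglottis": (z["BEP"], z["TEP"]),
    }


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def analytic_truth(spec: PhantomSpec, *, surface: bool = True) -> PhantomTruth:
    """Ground-truth airway parameters from the analytic geometry.

    Quadrature-based and independent of any voxelization; with
    ``surface=False`` the (relatively costly) lateral-surface integral,
    and hence SA/SA'/sphericity, are skipped (NaN).
    """
    validate_spec(spec)
    geo = _Geometry(spec)
    bounds = _region_bounds(spec)
    per_region: dict[str, AirwayParameters] = {}

    def area(z):
        return np.asarray(spec.area_profile(np.asarray(z, float)), float)

    for name, (z0, z1) in bounds.items():
        V = _panel_quad(area, z0, z1, panels=200)
        L = z1 - z0
        # minimum cross-sectional area: dense scan + bounded refinement
        zs = np.linspace(z0, z1, 4001)
        az = area(zs)
        k = int(np.argmin(az))
        lo, hi = zs[max(k - 1, 0)], zs[min(k + 1, len(zs) - 1)]
        res = optimize.minimize_scalar(lambda z: float(area(z)),
                                       bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-10})
        if res.fun < az[k]:
            mca, mca_z = float(res.fun), float(res.x)
        else:
            mca, mca_z = float(az[k]), float(zs[k])
        a, b = geo.ab(mca_z)
        LAT, AP = 2.0 * float(a), 2.0 * float(b)
        if surface:
            lat_sa = _lateral_surface(geo, z0, z1)
            SA_closed = lat_sa + float(area(z0)) + float(area(z1))
        else:
            lat_sa = SA_closed = float("nan")
        meanCSA = V / L
        per_region[name] = AirwayParameters(
            region_tag=name, V=V, L=L, SA=lat_sa, SA_closed=SA_closed,
            MCA=mca, MCA_z=mca_z, LAT=LAT, AP=AP, meanCSA=meanCSA,
            lat_ap_ratio=_safe_div(LAT, AP),
            uniformity=_safe_div(mca, meanCSA),
            sphericity=np.pi ** (1 / 3) * (6 * V) ** (2 / 3) / SA_closed,
        )

    # total assembled from the regions so additivity invariants hold exactly
    regs = [per_region[n] for n in bounds]
    V = sum(r.V for r in regs)
    L = sum(r.L for r in regs)
    kmin = int(np.argmin([r.MCA for r in regs]))
    mca, mca_z = regs[kmin].MCA, regs[kmin].MCA_z
    LAT, AP = regs[kmin].LAT, regs[kmin].AP
    if surface:
        lat_sa = sum(r.SA for r in regs)
        SA_closed = lat_sa + float(area(0.0)) + float(area(spec.axis_length))
    else:
        lat_sa = SA_closed = float("nan")
    meanCSA = V / L
    per_region["total"] = AirwayParameters(
        region_tag="total", V=V, L=L, SA=lat_sa, SA_closed=SA_closed,
        MCA=mca, MCA_z=mca_z, LAT=LAT, AP=AP, meanCSA=meanCSA,
        lat_ap_ratio=_safe_div(LAT, AP), uniformity=_safe_div(mca, meanCSA),
        sphericity=np.pi ** (1 / 3) * (6 * V) ** (2 / 3) / SA_closed,
    )
    return PhantomTruth(per_region=per_region, landmark_heights=landmark_heights(spec))


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _grid_coords(spec: PhantomSpec, geo: _Geometry):
    """Voxel-centre coordinate vectors covering lumen, pockets and islands."""
    z_dense = np.linspace(0.0, spec.axis_length, 501)
    a, b = geo.ab(z_dense)
    cx, cy = geo.center(z_dense)
    xs = [float(np.max(cx + a)), float(-np.min(cx - a))]
    ys = [float(np.max(cy + b)), float(-np.min(cy - b))]
    y_pns = resolve_pns_y(spec)
    ys[0] = max(ys[0], y_pns)
    for p in list(spec.pockets) + list(spec.islands):
        c, r = p.center, p.radius
        xs[0] = max(xs[0], c[0] + r)
        xs[1] = max(xs[1], -(c[0] - r))
        ys[0] = max(ys[0], c[1] + r)
        ys[1] = max(ys[1], -(c[1] - r))
    m = spec.xy_margin
    dx, dy, dz = spec.voxel_spacing
    x = np.arange(-(xs[1] + m), xs[0] + m + dx, dx)
    y = np.arange(-(ys[1] + m), ys[0] + m + dy, dy)
    z = np.arange(-spec.z_pad, spec.axis_length + spec.z_pad + dz, dz)
    return x, y, z, y_pns


def _rasterize_lumen(spec: PhantomSpec, geo: _Geometry, x, y, z) -> np.ndarray:
    a, b = geo.ab(z)
    cx, cy = geo.center(z)
    X = x[:, None, None]
    Y = y[None, :, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (X - cx[None, None, :]) / a[None, None, :]
        v = (Y - cy[None, None, :]) / b[None, None, :]
        inside = (u * u + v * v) <= 1.0
    return inside & np.isfinite(u).all(axis=(0, 1))[None, None, :]


def _rasterize_sphere(center, radius, x, y, z) -> np.ndarray:
    d2 = ((x[:, None, None] - center[0]) ** 2
          + (y[None, :, None] - center[1]) ** 2
          + (z[None, None, :] - center[2]) ** 2)
    return d2 <= radius ** 2


def _carve_bridge(lumen: np.ndarray, pocket: np.ndarray) -> np.ndarray:
    """Thin diagonal staircase connecting the pocket top to the lumen wall.

    Each step ascends one slice while moving one voxel posterior, so
    consecutive bridge voxels are 26-adjacent in 3D but never vertically
    aligned: the pocket becomes 3D-connected to the lumen (survives island
    removal) yet is excluded by seeded slice-descent (dead-space removal).
    """
    nz = lumen.shape[2]
    ii, jj, kk = np.nonzero(pocket)
    k_top = kk.max()
    at_top = kk == k_top
    i0 = int(np.round(ii[at_top].mean()))
    j0 = int(np.round(jj[at_top].mean()))
    bridge = np.zeros_like(lumen)
    i, j, k = i0, j0, k_top
    for _ in range(lumen.shape[1]):
        j -= 1
        k += 1
        if k >= nz or j < 0:
            raise ValidationError(
                "pocket cannot attach: bridge left the grid before reaching the lumen")
        bridge[i, j, k] = True
        sl = lumen[:, :, k]
        if sl[max(i - 1, 0):i + 2, max(j - 1, 0):j + 2].any():
            return bridge
    raise ValidationError("pocket cannot attach to the lumen")


def make_phantom(spec: PhantomSpec, seed: int) -> tuple[VolumeImage, LandmarkSet, PhantomTruth]:
    """Rasterize a phantom scan; deterministic given ``(spec, seed)``.

    The RNG seed drives named streams (geometry, noise) so that noise can be
    toggled without changing geometry.
    """
    validate_spec(spec)
    geo = _Geometry(spec)
    x, y, z, y_pns = _grid_coords(spec, geo)
    dx, dy, dz = spec.voxel_spacing

    lumen = _rasterize_lumen(spec, geo, x, y, z)
    air = lumen.copy()
    for pocket in spec.pockets:
        pk = _rasterize_sphere(pocket.center, pocket.radius, x, y, z)
        if (pk & lumen).any():
            raise ValidationError(
                f"pocket at {pocket.center} intersects the lumen")
        air |= pk
        air |= _carve_bridge(lumen, pk)
    non_island_air = air.copy()
    for island in spec.islands:
        blob = _rasterize_sphere(island.center, island.radius, x, y, z)
        grown = ndimage.binary_dilation(blob, structure=np.ones((3, 3, 3), bool))
        if (grown & air).any():
            raise ValidationError(
                "invariant violated: island centers must lie strictly outside "
                f"the lumen + pockets (island at {island.center} touches other air)")
        air |= blob

    _geom_ss, noise_ss = np.random.SeedSequence(seed).spawn(2)
    hu = np.where(air, spec.hu_air, spec.hu_tissue).astype(np.float32)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(noise_ss)
        hu = hu + rng.normal(0.0, spec.noise_sd, hu.shape).astype(np.float32)

    volume = VolumeImage(data=hu, spacing=(dx, dy, dz),
                         origin=(float(x[0]), float(y[0]), float(z[0])))
    zl = landmark_heights(spec)
    _, b_at = geo.ab(np.array([zl["TUV"], zl["TEP"], zl["BEP"]]))
    _, cy_at = geo.center(np.array([zl["TUV"], zl["TEP"], zl["BEP"]]))
    wall = np.asarray(cy_at) + np.asarray(b_at)
    points = {
        "PNS": [0.0, y_pns, zl["PNS"]],
        "TUV": [0.0, float(wall[0]), zl["TUV"]],
        "TEP": [0.0, float(wall[1]), zl["TEP"]],
        "BEP": [0.0, float(wall[2]), zl["BEP"]],
        # FH fiducials on a horizontal triangle above the PNS plane
        "PO_L": [25.0, -10.0, zl["PNS"] + 5.0],
        "PO_R": [-25.0, -10.0, zl["PNS"] + 5.0],
        "OR": [0.0, 20.0, zl["PNS"] + 5.0],
    }
    landmarks = LandmarkSet(points)
    truth = analytic_truth(spec)
    return volume, landmarks, truth


# ---------------------------------------------------------------------------
# paired-scan perturbation
# ---------------------------------------------------------------------------

def perturb_phantom(spec: PhantomSpec, perturbation: Perturbation | dict,
                    seed: int) -> PhantomSpec:
    """Derive the second-timepoint spec under the variation model.

    The area profile is multiplied by ``1 + amp*sin(2*pi*k*z/L + phi)`` with
    random integer wavenumber and phase (a smooth field in [1-amp, 1+amp]
    with unit mean over phases); soft-tissue landmark fractions are jittered;
    the axis may bow laterally. The anterior-cut height (PNS) is frozen to
    the unperturbed geometry. All-zero amplitudes return the spec unchanged.
    """
    if isinstance(perturbation, dict):
        perturbation = Perturbation(**perturbation)
    for fname in ("area_scale_amp", "landmark_jitter_sd", "axis_bend_amp"):
        if getattr(perturbation, fname) < 0:
            raise ValidationError(f"perturbation amplitude {fname} must be >= 0")
    validate_spec(spec)
    if (perturbation.area_scale_amp == 0 and perturbation.landmark_jitter_sd == 0
            and perturbation.axis_bend_amp == 0):
        return spec

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    L = spec.axis_length
    new = replace(spec)
    new.pns_y = resolve_pns_y(spec)   # PNS localized once, re-used at T1

    if perturbation.area_scale_amp > 0:
        amp = perturbation.area_scale_amp
        kwave = int(rng.integers(1, 4))
        phi = float(rng.uniform(0.0, 2 * np.pi))
        base_area = spec.area_profile

        def scaled_area(z, _base=base_area, _a=amp, _k=kwave, _p=phi, _L=L):
            z = np.asarray(z, float)
            return np.asarray(_base(z), float) * (
                1.0 + _a * np.sin(2 * np.pi * _k * z / _L + _p))

        new.area_profile = scaled_area

    if perturbation.landmark_jitter_sd > 0:
        sd_frac = perturbation.landmark_jitter_sd / L
        base = spec.landmark_fracs
        for _ in range(200):
            fr = {name: base[name] + float(rng.normal(0.0, sd_frac))
                  for name in ("TUV", "TEP", "BEP")}
            fr["BEP"] = min(fr["BEP"], 1.0)
            if 0.0 < fr["TUV"] < fr["TEP"] < fr["BEP"] <= 1.0:
                new.landmark_fracs = fr
                break
        else:
            raise ValidationError(
                "landmark jitter could not preserve landmark ordering")

    if perturbation.axis_bend_amp > 0:
        amp = perturbation.axis_bend_amp
        psi = float(rng.uniform(0.0, 2 * np.pi))
        base_center = spec.center_profile

        def bent_center(z, _base=base_center, _a=amp, _psi=psi, _L=L):
            z = np.asarray(z, float)
            bow = _a * np.sin(np.pi * np.clip(z, 0, _L) / _L)
            off = np.stack([bow * np.cos(_psi), bow * np.sin(_psi)], axis=-1)
            if _base is not None:
                off = off + np.asarray(_base(z), float)
            return off

        new.center_profile = bent_center

    return new


# ---------------------------------------------------------------------------
# ready-made specs
# ---------------------------------------------------------------------------

def constant_tube_spec(radius: float = 8.0, axis_length: float = 60.0, *,
                       noise_sd: float = 0.0,
                       voxel_spacing: tuple[float, float, float] = (0.5, 0.5, 0.5),
                       ) -> PhantomSpec:
    """Circular tube of constant radius — the closed-form reference case."""
    area = np.pi * radius ** 2
    return PhantomSpec(
        axis_length=axis_length,
        area_profile=lambda z: np.full_like(np.asarray(z, float), area),
        ellipse_ratio_profile=lambda z: np.ones_like(np.asarray(z, float)),
        noise_sd=noise_sd, voxel_spacing=voxel_spacing)


def ball_spec(radius: float = 8.0) -> PhantomSpec:
    """Closed tube degenerating to a ball: the sphericity-of-one extreme."""
    L = 2.0 * radius
    return PhantomSpec(
        axis_length=L,
        area_profile=lambda z: np.pi * np.maximum(
            radius ** 2 - (np.asarray(z, float) - radius) ** 2, 0.0),
        ellipse_ratio_profile=lambda z: np.ones_like(np.asarray(z, float)),
        noise_sd=0.0)


def default_spec(*, noise_sd: float = 10.0,
                 voxel_spacing: tuple[float, float, float] = (0.5, 0.5, 0.5),
                 with_pockets: bool = True,
                 with_islands: bool = True) -> PhantomSpec:
    """An airway-like phantom exercising every segmentation cleanup rule.

    Wide velopharynx, a Gaussian constriction (area ~80 mm^2) in the
    tongue-base region, an anterior "mouth" pocket, a vallecular pocket,
    and a posterior island blob.
    """
    def area(z):
        z = np.asarray(z, float)
        return 250.0 - 170.0 * np.exp(-((z - 20.0) ** 2) / (2 * 8.0 ** 2))

    def ratio(z):
        z = np.asarray(z, float)
        return 2.0 + 0.4 * np.cos(np.pi * z / 60.0)

    pockets = (Pocket(center=(0.0, 8.7, 32.0), radius=2.0, attachment="mouth"),
               Pocket(center=(0.0, 7.5, 15.0), radius=1.8, attachment="vallecular"),
               ) if with_pockets else ()
    islands = (Island(center=(0.0, -9.0, 20.0), radius=1.5),) if with_islands else ()
    return PhantomSpec(
        axis_length=60.0, area_profile=area, ellipse_ratio_profile=ratio,
        landmark_fracs={"TUV": 0.45, "TEP": 0.75, "BEP": 1.0},
        pockets=pockets, islands=islands,
        noise_sd=noise_sd, voxel_spacing=voxel_spacing)


def random_subject_spec(seed: int, **kwargs) -> PhantomSpec:
    """A subject-to-subject variant of :func:`default_spec`.

    Scales the overall calibre, constriction depth/position and landmark
    fractions so that a cohort has realistic between-subject variance.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    base = float(rng.uniform(200.0, 320.0))
    depth = float(rng.uniform(120.0, 200.0))
    zc = float(rng.uniform(14.0, 30.0))
    width = float(rng.uniform(6.0, 10.0))
    ratio0 = float(rng.uniform(1.6, 2.6))
    axis_length = float(rng.uniform(50.0, 70.0))

    def area(z, _b=base, _d=depth, _zc=zc, _w=width):
        z = np.asarray(z, float)
        return _b - _d * np.exp(-((z - _zc) ** 2) / (2 * _w ** 2))

    def ratio(z, _r=ratio0, _L=axis_length):
        z = np.asarray(z, float)
        return _r + 0.3 * np.cos(np.pi * z / _L)

    fr_tuv = float(rng.uniform(0.40, 0.50))
    fr_tep = float(rng.uniform(0.70, 0.80))
    spec = PhantomSpec(
        axis_length=axis_length, area_profile=area, ellipse_ratio_profile=ratio,
        landmark_fracs={"TUV": fr_tuv, "TEP": fr_tep, "BEP": 1.0}, **kwargs)
    return spec
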