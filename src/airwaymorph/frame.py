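"""Frankfort-Horizontal reference frame: plane construction, derived
landmarks, volume reorientation, and rigid superimposition of paired scans.

Registration between paired scans is landmark-based (orthogonal Procrustes /
Kabsch); an intensity-based hook can be plugged in by supplying a
:class:`RigidTransform` obtained elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import LandmarkSet, VolumeImage
from .errors import DegenerateGeometryError, ValidationError

__all__ = [
    "Plane", "RigidTransform", "construct_fh_plane", "compute_mue",
    "reorient", "superimpose", "apply_transform",
]


@dataclass
class Plane:
    """A plane given by a point on it and a unit normal."""

    point: np.ndarray
    unit_normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, float)
        self.unit_normal = np.asarray(self.unit_normal, float)
        n = np.linalg.norm(self.unit_normal)
        if abs(n - 1.0) > 1e-9:
            raise ValidationError("plane normal must be unit length")

    def signed_distance(self, xyz) -> float:
        return float(np.dot(np.asarray(xyz, float) - self.point, self.unit_normal))


@dataclass
class RigidTransform:
    """Proper rigid transform x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float)
        R = self.rotation
        if R.shape != (3, 3):
            raise ValidationError("rotation must be 3x3")
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-9:
            raise ValidationError("rotation must be orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValidationError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, xyz) -> np.ndarray:
        p = np.asarray(xyz, float)
        return p @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m) -> "RigidTransform":
        m = np.asarray(m, float)
        return cls(m[:3, :3], m[:3, 3])


def construct_fh_plane(fiducials: dict | LandmarkSet,
                       names: tuple[str, str, str] = ("PO_L", "PO_R", "OR")) -> Plane:
    """Fit the Frankfort Horizontal plane through three cephalometric fiducials.

    The standard triple is bilateral porion plus orbitale; fiducial names are
    configurable. The returned normal points superior (positive z of the
    input frame).
    """
    if isinstance(fiducials, LandmarkSet):
        pts = [fiducials[n] for n in names]
    else:
        try:
            pts = [np.asarray(fiducials[n], float) for n in names]
        except KeyError as e:
            raise ValidationError(f"missing fiducial {e.args[0]!r}") from None
    a, b, c = pts
    n = np.cross(b - a, c - a)
    area = 0.5 * np.linalg.norm(n)
    if area < 1e-6:
        raise DegenerateGeometryError(
            f"fiducials are (near-)collinear: triangle area {area:.3g} mm^2")
    n = n / np.linalg.norm(n)
    if n[2] < 0:
        n = -n
    return Plane(point=(a + b + c) / 3.0, unit_normal=n)


def compute_mue(tuv, tep) -> np.ndarray:
    """Midpoint between the uvula tip and the epiglottis tip."""
    tuv = np.asarray(tuv, float)
    tep = np.asarray(tep, float)
    if np.allclose(tuv, tep):
        raise DegenerateGeometryError("TUV and TEP coincide; midpoint undefined")
    return (tuv + tep) / 2.0


def _rotation_to_z(normal: np.ndarray) -> np.ndarray:
    """Smallest rotation taking ``normal`` to +z."""
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(n, z)
    s = np.linalg.norm(v)
    c = float(np.dot(n, z))
    if s < 1e-15:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def apply_transform(volume: VolumeImage, transform: RigidTransform, *,
                    is_mask: bool = False,
                    fill_value: float = 40.0) -> VolumeImage:
    """Resample ``volume`` under a world-space rigid transform.

    HU volumes are resampled with trilinear interpolation, masks with
    nearest-neighbour; out-of-field voxels are filled with ``fill_value``
    (soft tissue by default, so no phantom air is created at borders).
    The output grid equals the input grid.
    """
    S = np.diag(volume.spacing)
    Sinv = np.diag([1.0 / s for s in volume.spacing])
    Rinv = transform.rotation.T
    origin = np.asarray(volume.origin)
    # output index -> input index: i_in = Sinv (R^T (origin + S i_out - t) - origin)
    M = Sinv @ Rinv @ S
    off = Sinv @ (Rinv @ (origin - transform.translation) - origin)
    order = 0 if is_mask else 1
    data = ndimage.affine_transform(
        volume.data.astype(float), M, offset=off, order=order,
        mode="constant", cval=0.0 if is_mask else fill_value)
    if is_mask:
        data = data > 0.5
    return VolumeImage(data=data, spacing=volume.spacing, origin=volume.origin,
                       orientation=volume.orientation)


def reorient(volume: VolumeImage, landmarks: LandmarkSet, fh: Plane, *,
             is_mask: bool = False,
             fill_value: float = 40.0) -> tuple[VolumeImage, LandmarkSet]:
    """Rotate volume and landmarks so the FH plane becomes horizontal (+z up).

    The rotation pivots about the volume's geometric centre (keeping the
    anatomy in the field of view); landmarks are transformed consistently.
    """
    R = _rotation_to_z(fh.unit_normal)
    if np.abs(R - np.eye(3)).max() < 1e-12:
        return volume, landmarks.transformed(lambda p: p)
    c = (np.asarray(volume.origin)
         + (np.asarray(volume.shape) - 1) / 2.0 * np.asarray(volume.spacing))
    t = c - R @ c
    transform = RigidTransform(R, t)
    vol = apply_transform(volume, transform, is_mask=is_mask, fill_value=fill_value)
    lm = landmarks.transformed(transform.apply)
    return vol, lm


def superimpose(moving: dict | LandmarkSet, fixed: dict | LandmarkSet,
                names: tuple[str, ...] | None = None) -> RigidTransform:
    """Least-squares rigid (Kabsch) alignment of labelled point sets.

    Returns the proper rigid transform T minimising sum ||T(m_i) - f_i||^2.
    A reflection is never returned; for reflected inputs the best proper
    rotation is used (nonzero residual).
    """
    mov = moving.points if isinstance(moving, LandmarkSet) else {
        k: np.asarray(v, float) for k, v in moving.items()}
    fix = fixed.points if isinstance(fixed, LandmarkSet) else {
        k: np.asarray(v, float) for k, v in fixed.items()}
    if names is None:
        names = tuple(sorted(set(mov) & set(fix)))
    if len(names) < 3:
        raise DegenerateGeometryError(
            f"need >= 3 corresponding points, got {len(names)}")
    P = np.stack([mov[n] for n in names])   # moving
    Q = np.stack([fix[n] for n in names])   # fixed
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    # collinearity check: rank of the centred moving set
    if np.linalg.matrix_rank(P0, tol=1e-9 * max(1.0, np.abs(P0).max())) < 2:
        raise DegenerateGeometryError("point set is collinear")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    return RigidTransform(R, t)
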