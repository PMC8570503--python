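"""Core data containers shared across the pipeline.

Internal coordinate convention: right-handed, +x left, +y anterior,
+z superior; all world coordinates are in millimetres. Array axes are
ordered (x, y, z) and voxel indices are 0-based; a voxel (i, j, k) is the
cell centred at ``origin + (i + 0.5, j + 0.5, k + 0.5) * spacing`` minus
half a voxel -- i.e. ``origin`` is the centre of voxel (0, 0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, ValidationError

#: canonical landmark names
AIRWAY_LANDMARKS = ("PNS", "TUV", "TEP", "BEP")
FH_FIDUCIALS = ("PO_L", "PO_R", "OR")
REGIONS = ("velopharynx", "oropharynx", "tongue_base", "epiglottis")
ALL_REGIONS = ("total",) + REGIONS

#: the ten reported airway parameters, in report order
PARAMETERS = (
    "V", "L", "SA", "MCA", "LAT", "AP",
    "meanCSA", "LAT/AP", "uniformity", "sphericity",
)

PARAMETER_UNITS = {
    "V": "mm^3", "L": "mm", "SA": "mm^2", "SA_closed": "mm^2",
    "MCA": "mm^2", "LAT": "mm", "AP": "mm", "meanCSA": "mm^2",
    "LAT/AP": "", "uniformity": "", "sphericity": "",
}


@dataclass
class VolumeImage:
    """A 3D scalar grid of HU values with anisotropic voxel spacing."""

    data: np.ndarray                       # (nx, ny, nz) float array, HU
    spacing: tuple[float, float, float]    # mm per voxel along (x, y, z)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "LAS"               # +x left, +y anterior, +z superior

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError("VolumeImage.data must be 3-dimensional")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one axis."""
        n = self.data.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    def index_to_world(self, idx) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx, float) * np.asarray(self.spacing)

    def world_to_index(self, xyz) -> np.ndarray:
        return (np.asarray(xyz, float) - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass
class LandmarkSet:
    """Named 3D points in mm in the volume's frame."""

    points: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = {k: np.asarray(v, float) for k, v in self.points.items()}
        for name, p in self.points.items():
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise ValidationError(f"landmark {name!r} must be a finite 3-vector")

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise ValidationError(f"missing landmark {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.points]
        if missing:
            raise ValidationError(f"missing landmark(s): {', '.join(missing)}")

    def with_point(self, name: str, xyz) -> "LandmarkSet":
        pts = dict(self.points)
        pts[name] = np.asarray(xyz, float)
        return LandmarkSet(pts)

    def transformed(self, func) -> "LandmarkSet":
        """Apply ``func(point) -> point`` to every landmark."""
        return LandmarkSet({k: np.asarray(func(v), float) for k, v in self.points.items()})

    def to_dict(self) -> dict[str, list[float]]:
        return {k: [float(x) for x in v] for k, v in self.points.items()}


@dataclass
class AirwayMask:
    """Binary voxel mask of the airway lumen on its source volume's lattice.

    ``z_top``/``z_bottom`` are the superior/inferior boundary-plane heights
    in mm; no foreground voxel centre may lie outside ``[z_bottom, z_top]``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    z_top: float = np.inf
    z_bottom: float = -np.inf
    region_tag: str = "total"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, bool)
        if self.data.ndim != 3:
            raise ValidationError("AirwayMask.data must be 3-dimensional")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if not self.z_top >= self.z_bottom:
            raise ValidationError("z_top must not be below z_bottom")
        # equal heights are allowed (degenerate empty region slabs)
        if self.data.any():
            zc = self.z_coords()[self.data.any(axis=(0, 1))]
            eps = 1e-6 * self.spacing[2]
            if zc.max() > self.z_top + eps or zc.min() < self.z_bottom - eps:
                raise ValidationError(
                    "foreground voxels lie outside [z_bottom, z_top]")

    def z_coords(self) -> np.ndarray:
        return self.origin[2] + np.arange(self.data.shape[2]) * self.spacing[2]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def count(self) -> int:
        return int(self.data.sum())

    def replace_data(self, data: np.ndarray, **kw) -> "AirwayMask":
        fields = dict(data=np.asarray(data, bool), spacing=self.spacing,
                      origin=self.origin, z_top=self.z_top,
                      z_bottom=self.z_bottom, region_tag=self.region_tag)
        fields.update(kw)
        return AirwayMask(**fields)

    @classmethod
    def from_volume(cls, volume: VolumeImage, data: np.ndarray, **kw) -> "AirwayMask":
        return cls(data=data, spacing=volume.spacing, origin=volume.origin, **kw)


@dataclass
class RegionPartition:
    """The four sub-region masks sharing one lattice; exact voxel partition."""

    velopharynx: AirwayMask
    oropharynx: AirwayMask
    tongue_base: AirwayMask
    epiglottis: AirwayMask

    def __iter__(self):
        for name in REGIONS:
            yield name, getattr(self, name)

    def validate_against(self, total: AirwayMask) -> None:
        stack = np.stack([m.data for _, m in self], axis=0)
        if (stack.sum(axis=0) > 1).any():
            raise ValidationError("region masks overlap")
        if not np.array_equal(stack.any(axis=0), total.data):
            raise ValidationError("region union does not equal the total mask")


@dataclass
class AirwayParameters:
    """Per-region record of the ten reported airway parameters."""

    region_tag: str
    V: float            # mm^3
    L: float            # mm
    SA: float           # mm^2, open surface (no top/bottom caps)
    SA_closed: float    # mm^2, closed surface incl. caps (used for sphericity)
    MCA: float          # mm^2
    MCA_z: float        # mm, height of the MCA slice
    LAT: float          # mm
    AP: float           # mm
    meanCSA: float      # mm^2
    lat_ap_ratio: float
    uniformity: float
    sphericity: float

    def as_dict(self) -> dict[str, float]:
        return {
            "V": self.V, "L": self.L, "SA": self.SA, "SA_closed": self.SA_closed,
            "MCA": self.MCA, "MCA_z": self.MCA_z, "LAT": self.LAT, "AP": self.AP,
            "meanCSA": self.meanCSA, "LAT/AP": self.lat_ap_ratio,
            "uniformity": self.uniformity, "sphericity": self.sphericity,
        }


def check_finite_hu(volume: VolumeImage) -> None:
    if not np.all(np.isfinite(volume.data)):
        raise DataError("volume contains non-finite HU values")
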