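"""Airway lumen extraction, boundary cropping, cleanup, and partitioning.

Conventions (documented interpretations of the manual workflow):

* the air test is STRICT: a voxel is air iff HU < threshold (a voxel at
  exactly the threshold is tissue);
* "islands" are 3D 26-connected components that do not span from the
  superior to the inferior boundary slice; if no component spans, the
  largest one is kept and a warning is emitted;
* "dead space" removal is a seeded slice-descent: starting from the seed's
  2D component (8-connectivity) on the top slice, each lower slice keeps
  only 2D components that vertically overlap the kept set of the slice
  above — anterior pockets reachable only via a re-ascending path are
  thereby excluded;
* the anterior cut at PNS is the single plane y = y(PNS) applied to the
  whole cropped slab.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .core import AirwayMask, LandmarkSet, RegionPartition, VolumeImage, check_finite_hu
from .errors import (BoundaryError, EmptyInputError, OrderingError,
                     SeedPointError)
from .frame import compute_mue

__all__ = [
    "threshold_air", "crop_boundaries", "remove_islands",
    "remove_dead_space", "partition_regions", "extract_airway",
]

_STRUCT_26 = np.ones((3, 3, 3), bool)
_STRUCT_8 = np.ones((3, 3), bool)

#: default soft-tissue reconstruction level (HU)
DEFAULT_AIR_THRESHOLD = -400.0


def threshold_air(volume: VolumeImage,
                  air_threshold: float = DEFAULT_AIR_THRESHOLD) -> AirwayMask:
    """Binarize the HU volume: foreground = voxels strictly below threshold."""
    check_finite_hu(volume)
    data = volume.data < air_threshold
    return AirwayMask.from_volume(volume, data)


def _slice_eps(mask: AirwayMask) -> float:
    return 1e-6 * mask.spacing[2]


def crop_boundaries(mask: AirwayMask, pns, bep) -> AirwayMask:
    """Crop to the slab between the PNS and BEP planes, with the anterior cut.

    Removes voxels whose centre lies above z(PNS), below z(BEP), or anterior
    to y(PNS); records the two plane heights on the result.
    """
    pns = np.asarray(pns, float)
    bep = np.asarray(bep, float)
    z_top, z_bottom, y_cut = float(pns[2]), float(bep[2]), float(pns[1])
    if not z_top > z_bottom:
        raise BoundaryError(
            f"z(PNS)={z_top:.3f} must exceed z(BEP)={z_bottom:.3f}")
    zc = mask.z_coords()
    eps = _slice_eps(mask)
    if z_top < zc[0] - eps or z_bottom > zc[-1] + eps:
        raise BoundaryError("boundary planes lie outside the volume extent")
    keep_z = (zc >= z_bottom - eps) & (zc <= z_top + eps)
    yc = mask.origin[1] + np.arange(mask.data.shape[1]) * mask.spacing[1]
    keep_y = yc <= y_cut + 1e-6 * mask.spacing[1]
    data = mask.data & keep_z[None, None, :] & keep_y[None, :, None]
    return mask.replace_data(data, z_top=z_top, z_bottom=z_bottom)


def _boundary_slice_indices(mask: AirwayMask) -> tuple[int, int]:
    zc = mask.z_coords()
    eps = _slice_eps(mask)
    inside = np.nonzero((zc >= mask.z_bottom - eps) & (zc <= mask.z_top + eps))[0]
    if inside.size == 0:
        raise BoundaryError("no lattice slice lies between z_bottom and z_top")
    return int(inside[-1]), int(inside[0])   # (top, bottom)


def remove_islands(mask: AirwayMask) -> AirwayMask:
    """Drop 3D components that do not span the top and bottom boundary slices.

    Falls back to the largest component (with a warning) if none spans.
    """
    if not mask.data.any():
        raise EmptyInputError("cannot remove islands from an empty mask")
    labels, n = ndimage.label(mask.data, structure=_STRUCT_26)
    k_top, k_bot = _boundary_slice_indices(mask)
    top_labels = np.unique(labels[:, :, k_top])
    bot_labels = np.unique(labels[:, :, k_bot])
    spanning = (set(top_labels) & set(bot_labels)) - {0}
    if spanning:
        keep = np.isin(labels, sorted(spanning))
    else:
        warnings.warn("no air component spans the boundary planes; "
                      "keeping the largest component", stacklevel=2)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        keep = labels == int(np.argmax(counts))
    return mask.replace_data(mask.data & keep)


def _default_seed(mask: AirwayMask, k_top: int) -> tuple[int, int]:
    sl = mask.data[:, :, k_top]
    ii, jj = np.nonzero(sl)
    if ii.size == 0:
        raise SeedPointError("top boundary slice has no foreground")
    j_min = jj.min()                      # most posterior row (+y is anterior)
    cand = ii[jj == j_min]
    return int(cand[0]), int(j_min)


def remove_dead_space(mask: AirwayMask, seed_point=None) -> AirwayMask:
    """Seeded slice-descent retention (removes mouth/vallecular pockets).

    ``seed_point`` is a world-coordinate point on the top boundary slice;
    by default the most posterior foreground voxel there. If several 2D seed
    components tie, the one with the most posterior centroid wins.
    """
    if not mask.data.any():
        raise EmptyInputError("cannot remove dead space from an empty mask")
    k_top, k_bot = _boundary_slice_indices(mask)
    if seed_point is None:
        i0, j0 = _default_seed(mask, k_top)
    else:
        p = np.asarray(seed_point, float)
        idx = np.round((p - np.asarray(mask.origin)) / np.asarray(mask.spacing))
        i0, j0, k0 = (int(v) for v in idx)
        if k0 != k_top:
            k0 = k_top   # seed is defined on the top slice by contract
        if not (0 <= i0 < mask.data.shape[0] and 0 <= j0 < mask.data.shape[1]
                and mask.data[i0, j0, k_top]):
            raise SeedPointError(
                f"seed point {tuple(p)} is not foreground on the top slice")

    kept = np.zeros_like(mask.data)
    labels, _ = ndimage.label(mask.data[:, :, k_top], structure=_STRUCT_8)
    kept[:, :, k_top] = labels == labels[i0, j0]
    prev = kept[:, :, k_top]
    for k in range(k_top - 1, k_bot - 1, -1):
        sl = mask.data[:, :, k]
        if not sl.any():
            prev = np.zeros_like(prev)
            continue
        labels, n = ndimage.label(sl, structure=_STRUCT_8)
        overlapping = np.unique(labels[prev & sl])
        overlapping = overlapping[overlapping > 0]
        cur = np.isin(labels, overlapping)
        kept[:, :, k] = cur
        prev = cur
    return mask.replace_data(mask.data & kept)


def partition_regions(mask: AirwayMask, landmarks: LandmarkSet) -> RegionPartition:
    """Split the airway into the four FH-parallel sub-region slabs.

    Half-open height intervals (closed at each region's inferior plane) make
    the partition exact: every foreground voxel lands in exactly one region.
    """
    landmarks.require("TUV", "TEP")
    if "MUE" in landmarks:
        z_mue = float(landmarks["MUE"][2])
    else:
        z_mue = float(compute_mue(landmarks["TUV"], landmarks["TEP"])[2])
    z_tuv, z_tep = float(landmarks["TUV"][2]), float(landmarks["TEP"][2])
    order = [mask.z_top, z_tuv, z_mue, z_tep, mask.z_bottom]
    if not all(a >= b for a, b in zip(order[:-1], order[1:])):
        raise OrderingError(
            "landmark ordering violated: need z_top >= z(TUV) >= z(MUE) >= "
            f"z(TEP) >= z_bottom, got {order}")
    zc = mask.z_coords()[None, None, :]
    d = mask.data
    velo = d & (zc >= z_tuv)
    oro = d & (zc >= z_mue) & (zc < z_tuv)
    tongue = d & (zc >= z_tep) & (zc < z_mue)
    epi = d & (zc < z_tep)
    mk = mask.replace_data
    part = RegionPartition(
        velopharynx=mk(velo, z_bottom=z_tuv, region_tag="velopharynx"),
        oropharynx=mk(oro, z_top=z_tuv, z_bottom=z_mue, region_tag="oropharynx"),
        tongue_base=mk(tongue, z_top=z_mue, z_bottom=z_tep, region_tag="tongue_base"),
        epiglottis=mk(epi, z_top=z_tep, region_tag="epiglottis"),
    )
    part.validate_against(mask)
    return part


def extract_airway(volume: VolumeImage, landmarks: LandmarkSet, *,
                   air_threshold: float = DEFAULT_AIR_THRESHOLD,
                   log=None) -> tuple[AirwayMask, RegionPartition]:
    """Full segmentation chain: threshold, crop, islands, dead space, partition."""
    landmarks.require("PNS", "TUV", "TEP", "BEP")
    mask = threshold_air(volume, air_threshold)
    counts = [("threshold", mask.count())]
    mask = crop_boundaries(mask, landmarks["PNS"], landmarks["BEP"])
    counts.append(("crop", mask.count()))
    mask = remove_islands(mask)
    counts.append(("islands", mask.count()))
    mask = remove_dead_space(mask)
    counts.append(("dead_space", mask.count()))
    if log is not None:
        for stage, n in counts:
            log.info("segmentation stage %-10s: %d voxels", stage, n)
    partition = partition_regions(mask, landmarks)
    return mask, partition
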