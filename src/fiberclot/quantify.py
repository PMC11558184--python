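"""Micro-CT clot quantification: segmentation, masking, crops, profiles and maps.

The analysis chain mirrors how clot was extracted from reconstructed scans of
the flow chambers: threshold the grayscale volume into fluid vs material,
subtract a clean-chamber mask so only clot remains, crop the stated margins
to exclude wall and inlet edge effects, then summarise the clot as
longitudinal slice profiles (normalised by the void volume available for clot
to form), replicate-averaged voxel probability maps, 2D projections, and
1-mm slab volumes at matched surface-exposure depths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_multiotsu, threshold_otsu

from .geometry import ChamberSpec
from .volume import AXIS_FLOW, AXIS_HEIGHT, AXIS_WIDTH, ClotSegmentation, VoxelVolume

__all__ = [
    "SliceProfile",
    "ProbabilityMap",
    "segment_volume",
    "subtract_mask",
    "crop_volume",
    "slice_profile",
    "normalize_clot_volume",
    "probability_map",
    "project_axis",
    "clot_at_equivalent_distance",
    "dice_coefficient",
]

#: default crop margins, mm: top/bottom (y), each side (x), inlet (z); the
#: outlet edge is left untouched.
DEFAULT_CROP_TOP_BOTTOM = 0.4
DEFAULT_CROP_SIDES = 1.3
DEFAULT_CROP_INLET = 1.0

FIVE_SEGMENT_CENTERS = (0.05, 0.25, 0.50, 0.75, 0.95)


def segment_volume(gray: VoxelVolume, method: str = "otsu_two_stage", threshold: float = 0.4) -> VoxelVolume:
    """Threshold a grayscale volume into a material (solid-or-clot) mask.

    ``otsu_two_stage`` fits a three-class Otsu split (fluid / clot / solid)
    and cuts at the lower threshold, separating fluid from everything
    denser; ``fixed`` uses the given absolute threshold.  A flat (zero
    variance) image carries no segmentation information and is rejected.
    """
    img = np.asarray(gray.grid, dtype=float)
    if img.min() == img.max():
        raise ValueError("cannot segment a flat (zero-variance) image")
    if method == "fixed":
        thr = threshold
    elif method == "otsu_two_stage":
        try:
            thr = float(threshold_multiotsu(img.ravel(), classes=3)[0])
        except ValueError:
            # fewer than three distinct gray levels: plain Otsu suffices
            thr = float(threshold_otsu(img.ravel()))
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    return gray.with_grid(img > thr)


def subtract_mask(seg: VoxelVolume, clean: VoxelVolume) -> VoxelVolume:
    """Remove the clean-chamber solid from a segmented scan, leaving clot.

    clot = seg AND NOT clean; the result is disjoint from ``clean`` by
    construction.  Grids must share shape and physical geometry.
    """
    if not (seg.is_binary and clean.is_binary):
        raise TypeError("both volumes must be binary masks")
    if seg.grid.shape != clean.grid.shape:
        raise ValueError(f"grid shapes differ: {seg.grid.shape} vs {clean.grid.shape}")
    if not seg.same_geometry_as(clean):
        raise ValueError("volumes have mismatched voxel size or origin")
    return seg.with_grid(seg.grid & ~clean.grid)


def _margin_voxels(margin_mm: float, voxel_mm: float) -> int:
    """Snap a physical margin to whole voxels toward the interior (ceil)."""
    n = margin_mm / voxel_mm
    n_int = int(math.ceil(n - 1e-9))
    return max(n_int, 0)


def crop_volume(
    vol: VoxelVolume,
    top_bottom: float = DEFAULT_CROP_TOP_BOTTOM,
    sides: float = DEFAULT_CROP_SIDES,
    inlet: float = DEFAULT_CROP_INLET,
) -> VoxelVolume:
    """Crop wall and inlet edge effects: y margins top and bottom, x margins
    each side, a single z margin at the inlet; the outlet face is untouched.

    Margins are snapped to whole voxels toward the interior, and the origin
    is advanced so distances from the true inlet remain available downstream.
    """
    if min(top_bottom, sides, inlet) < 0:
        raise ValueError("margins must be non-negative")
    vs = vol.voxel_size_mm
    my = _margin_voxels(top_bottom, vs)
    mx = _margin_voxels(sides, vs)
    mz = _margin_voxels(inlet, vs)
    nx, ny, nz = vol.grid.shape
    if 2 * mx >= nx or 2 * my >= ny or mz >= nz:
        raise ValueError("crop margins meet or exceed the volume extents")
    grid = vol.grid[mx : nx - mx, my : ny - my, mz:]
    origin = (
        vol.origin[0] + mx * vs,
        vol.origin[1] + my * vs,
        vol.origin[2] + mz * vs,
    )
    return VoxelVolume(grid=grid.copy(), voxel_size=vol.voxel_size, origin=origin)


@dataclass
class SliceProfile:
    """Clot volume and normalised fraction per longitudinal segment.

    ``segment_centers`` are mm from the true inlet.  ``normalized_fraction``
    divides each segment's clot volume by the void volume available for clot
    in that segment (segment region volume x (1 - PD)).
    """

    segment_centers: np.ndarray  # mm from inlet
    segment_length: float  # mm
    clot_volume: np.ndarray  # mm^3 per segment
    normalized_fraction: np.ndarray
    mode: str

    def total_volume(self) -> float:
        return float(self.clot_volume.sum())


def slice_profile(
    clot: ClotSegmentation | VoxelVolume,
    spec: ChamberSpec | None = None,
    mode: str = "five_segments",
    segment_length: float = 2.0,
) -> SliceProfile:
    """Summarise clot along the flow axis in ``segment_length``-mm segments.

    ``five_segments`` places segments at the entrance, first quarter, middle,
    third quarter and downstream end of the (cropped) length — centers at
    5/25/50/75/95 % — clipped to the volume bounds.  ``tiling`` covers the
    length with contiguous segments so the volumes partition the total.
    """
    if isinstance(clot, ClotSegmentation):
        vol, spec = clot.clot, clot.spec
    else:
        vol = clot
        if spec is None:
            raise ValueError("spec is required when passing a bare VoxelVolume")
    if not vol.is_binary:
        raise TypeError("slice_profile expects a binary clot volume")
    vs = vol.voxel_size_mm
    nz = vol.grid.shape[AXIS_FLOW]
    length = nz * vs
    if segment_length > length + 1e-9:
        raise ValueError(f"segment length {segment_length} mm exceeds volume length {length:.3f} mm")
    seg_vox = max(1, int(round(segment_length / vs)))

    counts_per_slice = vol.grid.sum(axis=(AXIS_WIDTH, AXIS_HEIGHT))
    if mode == "tiling":
        starts = list(range(0, nz, seg_vox))
        bounds = [(s, min(s + seg_vox, nz)) for s in starts]
    elif mode == "five_segments":
        bounds = []
        for frac in FIVE_SEGMENT_CENTERS:
            lo = int(round(frac * nz - seg_vox / 2))
            lo = min(max(lo, 0), nz - seg_vox)
            bounds.append((lo, lo + seg_vox))
    else:
        raise ValueError(f"unknown slice-profile mode {mode!r}")

    voxvol = vol.voxel_volume_mm3
    nx, ny = vol.grid.shape[AXIS_WIDTH], vol.grid.shape[AXIS_HEIGHT]
    volumes, centers, fractions = [], [], []
    for lo, hi in bounds:
        v = float(counts_per_slice[lo:hi].sum()) * voxvol
        region = (hi - lo) * nx * ny * voxvol
        volumes.append(v)
        centers.append(vol.origin[AXIS_FLOW] + (lo + hi) / 2.0 * vs)
        # voxelization can leave a cropped segment's true void slightly above
        # the nominal (1 - PD), so the fraction is capped at full occupancy
        available = region * (1.0 - spec.packing_density)
        fractions.append(min(1.0, v / available))
    return SliceProfile(
        segment_centers=np.asarray(centers),
        segment_length=seg_vox * vs,
        clot_volume=np.asarray(volumes),
        normalized_fraction=np.asarray(fractions),
        mode=mode,
    )


def normalize_clot_volume(v_clot: float, spec: ChamberSpec, region_volume: float) -> float:
    """Clot volume as a fraction of the void volume available for clot.

    Returns ``v_clot / (region_volume * (1 - PD))``: the chamber region's
    volume times its void fraction is the space clot can actually occupy.
    """
    if region_volume <= 0:
        raise ValueError("region volume must be positive")
    if v_clot < 0:
        raise ValueError("clot volume must be non-negative")
    available = region_volume * (1.0 - spec.packing_density)
    if v_clot > available * (1.0 + 1e-9):
        raise ValueError(
            f"clot volume {v_clot} mm^3 exceeds the available void volume "
            f"{available:.4f} mm^3 — physically impossible"
        )
    return v_clot / available


@dataclass
class ProbabilityMap:
    """Voxelwise clot-occurrence probability across replicate runs."""

    probabilities: VoxelVolume
    n_replicates: int
    label: str | None = None


def probability_map(replicates: list[ClotSegmentation | VoxelVolume], label: str | None = None) -> ProbabilityMap:
    """Average replicate binary clot masks into a per-voxel probability map.

    All replicates must share grid shape and geometry.  The mean of the map
    over all voxels equals the mean clot fraction of the inputs (linearity).
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    vols = [r.clot if isinstance(r, ClotSegmentation) else r for r in replicates]
    first = vols[0]
    acc = np.zeros(first.grid.shape, dtype=np.float64)
    for v in vols:
        if not v.is_binary:
            raise TypeError("probability maps are built from binary masks")
        if not v.same_geometry_as(first):
            raise ValueError("replicate grids do not match")
        acc += v.grid
    acc /= len(vols)
    return ProbabilityMap(
        probabilities=VoxelVolume(grid=acc, voxel_size=first.voxel_size, origin=first.origin),
        n_replicates=len(vols),
        label=label,
    )


def project_axis(pmap: ProbabilityMap | VoxelVolume, axis: str = "rod_axis") -> np.ndarray:
    """Average a 3D map along one axis into a 2D image.

    ``rod_axis`` (default) averages along the chamber height, producing the
    inlet-to-outlet plan view used for clot-distribution figures;
    ``flow_axis`` averages along the flow, producing a cross-section view.
    """
    vol = pmap.probabilities if isinstance(pmap, ProbabilityMap) else pmap
    if axis == "rod_axis":
        return np.asarray(vol.grid, dtype=float).mean(axis=AXIS_HEIGHT)
    if axis == "flow_axis":
        return np.asarray(vol.grid, dtype=float).mean(axis=AXIS_FLOW)
    raise ValueError(f"unknown projection axis {axis!r}")


def clot_at_equivalent_distance(
    clot: ClotSegmentation | VoxelVolume,
    distance: float,
    slab: float = 1.0,
    path_length: float | None = None,
) -> float:
    """Clot volume (mm^3) in a slab [distance, distance + slab) from the inlet.

    Distances are measured from the *true* inlet (pre-crop); the volume's
    origin supplies the offset of cropped grids.  Voxels are attributed to
    the slab by their center coordinate.
    """
    if isinstance(clot, ClotSegmentation):
        vol = clot.clot
        if path_length is None:
            path_length = clot.spec.path_length
    else:
        vol = clot
    if not vol.is_binary:
        raise TypeError("expects a binary clot volume")
    if path_length is None:
        path_length = vol.origin[AXIS_FLOW] + vol.extent_mm[AXIS_FLOW]
    if distance < 0 or distance + slab > path_length + 1e-9:
        raise ValueError(
            f"slab [{distance}, {distance + slab}) mm outside the chamber length {path_length} mm"
        )
    zc = vol.flow_coordinates_mm()
    sel = (zc >= distance) & (zc < distance + slab)
    count = vol.grid[:, :, sel].sum()
    return float(count) * vol.voxel_volume_mm3


def dice_coefficient(a: np.ndarray | VoxelVolume, b: np.ndarray | VoxelVolume) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two binary masks."""
    ga = a.grid if isinstance(a, VoxelVolume) else np.asarray(a)
    gb = b.grid if isinstance(b, VoxelVolume) else np.asarray(b)
    if ga.shape != gb.shape:
        raise ValueError("mask shapes differ")
    inter = np.logical_and(ga, gb).sum()
    denom = ga.sum() + gb.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float(inter) / float(denom)
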