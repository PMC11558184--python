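"""Parametric rod-array flow chambers and the hemodynamic quantities derived from them.

A miniature flow chamber stands in for a small section of an artificial-lung
hollow-fiber bundle: vertical micro-rods (the fibers) arrayed evenly in a
rectangular duct, blood flowing perpendicular to the rod axis.  The chamber is
fully described by its width ``W``, height ``H``, path length ``L`` (inlet face
to outlet face along the flow), areal packing density ``PD`` (fraction of the
plan region covered by rod cross-sections) and fiber diameter ``d_f``.

Unit policy: all lengths are stored in millimetres, time in minutes, pressure
in mmHg.  Velocities are quoted in cm/min and flow rates in mL/min, matching
the conventions of the bench experiments the package emulates; conversions are
localised in the functions that need them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

__all__ = [
    "ChamberSpec",
    "FlowCondition",
    "RodArray",
    "PackingError",
    "SQUARE_PACKING_BOUND",
    "HEX_PACKING_BOUND",
    "build_rod_array",
    "flow_rate_for_velocity",
    "velocity_for_flow_rate",
    "interstitial_velocity",
    "hydraulic_diameter",
    "reynolds",
    "cumulative_surface_area",
    "equivalent_distance",
    "EQUIVALENT_DISTANCE_TABLE",
]

#: circle-packing bound for a square lattice: rods touch when spacing == d_f
SQUARE_PACKING_BOUND = math.pi / 4.0
#: circle-packing bound for a hexagonal lattice
HEX_PACKING_BOUND = math.pi / (2.0 * math.sqrt(3.0))


class PackingError(ValueError):
    """Requested packing density is infeasible for the chosen lattice."""


@dataclass(frozen=True)
class ChamberSpec:
    """Geometric definition of a rod-array flow chamber.

    Parameters
    ----------
    width, height, path_length
        Chamber dimensions in mm.  Flow travels along ``path_length``; the
        rods span the full ``height``.
    packing_density
        Areal fraction of the plan (width x path-length) region occupied by
        rod cross-sections, in (0, 1) and below the lattice packing bound.
    fiber_diameter
        Rod diameter in mm (380 um fibers -> 0.380).
    lattice
        ``"square"`` (default, flow-axis aligned) or ``"hexagonal"``.
    """

    width: float = 7.3
    height: float = 3.0
    path_length: float = 20.0
    packing_density: float = 0.50
    fiber_diameter: float = 0.380
    lattice: str = "square"

    def __post_init__(self) -> None:
        for name in ("width", "height", "path_length", "fiber_diameter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")
        if self.lattice not in ("square", "hexagonal"):
            raise ValueError(f"unknown lattice {self.lattice!r}")
        bound = SQUARE_PACKING_BOUND if self.lattice == "square" else HEX_PACKING_BOUND
        if not 0.0 < self.packing_density < 1.0:
            raise PackingError(
                f"packing density must lie in (0, 1), got {self.packing_density}"
            )
        if self.packing_density > bound:
            raise PackingError(
                f"packing density {self.packing_density} exceeds the "
                f"{self.lattice}-lattice circle-packing bound {bound:.4f}"
            )

    @property
    def frontal_area(self) -> float:
        """Frontal area W x H perpendicular to flow, mm^2."""
        return self.width * self.height

    @property
    def chamber_volume(self) -> float:
        """Total enclosed volume W x H x L, mm^3."""
        return self.width * self.height * self.path_length

    @property
    def rod_spacing(self) -> float:
        """Center-to-center rod spacing (lattice constant), mm."""
        pd, d = self.packing_density, self.fiber_diameter
        if self.lattice == "square":
            return d * math.sqrt(math.pi / (4.0 * pd))
        return d * math.sqrt(math.pi / (2.0 * math.sqrt(3.0) * pd))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ChamberSpec":
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ChamberSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class FlowCondition:
    """Operating point of a chamber: velocity, flow rate and fluid properties.

    ``superficial_velocity`` (cm/min) is the primary quantity; the matching
    flow rate follows from Q = u_s * A_f.  ``viscosity``/``density`` default
    to the 3.4 cP glycerol-water analogue used for clot-free baselines.
    """

    superficial_velocity: float  # cm/min
    flow_rate: float | None = None  # mL/min; derived from velocity if None
    viscosity: float = 3.4  # cP
    density: float = 1.09  # g/mL

    def __post_init__(self) -> None:
        if self.superficial_velocity < 0:
            raise ValueError("superficial velocity must be non-negative")
        if self.viscosity <= 0 or self.density <= 0:
            raise ValueError("viscosity and density must be positive")

    @classmethod
    def for_velocity(cls, u_s: float, spec: ChamberSpec, **kw) -> "FlowCondition":
        """Build a condition with the flow rate consistent with ``spec``."""
        return cls(
            superficial_velocity=u_s,
            flow_rate=flow_rate_for_velocity(u_s, spec),
            **kw,
        )

    def resolved_flow_rate(self, spec: ChamberSpec) -> float:
        """Flow rate in mL/min, derived from velocity when not set explicitly.

        If both are set they must agree within 0.5 % (relative).
        """
        q_from_u = flow_rate_for_velocity(self.superficial_velocity, spec)
        if self.flow_rate is None:
            return q_from_u
        if q_from_u > 0 and abs(self.flow_rate - q_from_u) / q_from_u > 0.005:
            raise ValueError(
                f"flow rate {self.flow_rate} mL/min inconsistent with "
                f"{self.superficial_velocity} cm/min through a "
                f"{spec.frontal_area} mm^2 frontal area (expected {q_from_u:.4f})"
            )
        return self.flow_rate


@dataclass
class RodArray:
    """Plan-view rod layout for a chamber: circle centers in the (x, z) plane.

    ``centers`` is an (n, 2) array of (x, z) coordinates in mm with x across
    the width and z along the flow.  Rods overlapping the chamber boundary are
    kept; the voxelizer clips them, mirroring how wall edge effects are later
    cropped out of the analysis.
    """

    centers: np.ndarray
    radius: float  # mm
    spacing: float  # mm
    spec: ChamberSpec
    realized_pd: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)

    def min_center_distance(self) -> float:
        from scipy.spatial import cKDTree

        if len(self.centers) < 2:
            return math.inf
        d, _ = cKDTree(self.centers).query(self.centers, k=2)
        return float(d[:, 1].min())


def build_rod_array(spec: ChamberSpec, measure_pd: bool = True) -> RodArray:
    """Lay out evenly spaced rods tiling the W x L plan region.

    Square lattices are aligned with the flow axis with spacing
    ``s = d_f * sqrt(pi / (4 PD))``; hexagonal lattices use the analogous
    row-staggered layout.  ``realized_pd`` is measured by fine-grid
    rasterization of an interior window snapped to whole lattice cells.
    """
    s = spec.rod_spacing
    r = spec.fiber_diameter / 2.0
    W, L = spec.width, spec.path_length

    if spec.lattice == "square":
        nx = int(math.ceil(W / s))
        nz = int(math.ceil(L / s))
        xs = (np.arange(nx) + 0.5) * s
        zs = (np.arange(nz) + 0.5) * s
        X, Z = np.meshgrid(xs, zs, indexing="ij")
        centers = np.column_stack([X.ravel(), Z.ravel()])
    else:
        row = s * math.sqrt(3.0) / 2.0
        nrow = int(math.ceil(L / row)) + 1
        nx = int(math.ceil(W / s)) + 1
        pts = []
        for j in range(nrow):
            z = (j + 0.5) * row
            off = 0.25 * s if j % 2 == 0 else 0.75 * s
            for i in range(nx):
                x = i * s + off
                if -r <= x <= W + r and -r <= z <= L + r:
                    pts.append((x, z))
        centers = np.asarray(pts)

    arr = RodArray(centers=centers, radius=r, spacing=s, spec=spec)
    if measure_pd:
        arr.realized_pd = _measure_realized_pd(arr)
    return arr


def _measure_realized_pd(arr: RodArray, pixel: float = 0.01) -> float:
    """Rasterize an interior, lattice-periodic window and return covered fraction."""
    spec = arr.spec
    s = arr.spacing
    period_z = s if spec.lattice == "square" else s * math.sqrt(3.0)
    # window snapped to whole lattice periods, at least one spacing from walls
    x0, x1 = _snap_window(spec.width, s)
    z0, z1 = _snap_window(spec.path_length, period_z)
    if x1 <= x0 or z1 <= z0:  # chamber too small for an interior window
        x0, x1, z0, z1 = 0.0, spec.width, 0.0, spec.path_length
    nx = max(1, int(round((x1 - x0) / pixel)))
    nz = max(1, int(round((z1 - z0) / pixel)))
    xc = x0 + (np.arange(nx) + 0.5) * (x1 - x0) / nx
    zc = z0 + (np.arange(nz) + 0.5) * (z1 - z0) / nz
    covered = rasterize_rods(arr, xc, zc)
    return float(covered.mean())


def _snap_window(extent: float, period: float) -> tuple[float, float]:
    n = int(math.floor(extent / period))
    if n < 3:
        return 0.0, extent
    n_inner = n - 2  # drop one period at each wall
    lo = (extent - n_inner * period) / 2.0
    return lo, lo + n_inner * period


def rasterize_rods(arr: RodArray, xc: np.ndarray, zc: np.ndarray) -> np.ndarray:
    """Boolean coverage of pixel centers ``(xc x zc)`` by the rod circles."""
    out = np.zeros((len(xc), len(zc)), dtype=bool)
    r2 = arr.radius**2
    dx = xc[1] - xc[0] if len(xc) > 1 else arr.radius
    dz = zc[1] - zc[0] if len(zc) > 1 else arr.radius
    for cx, cz in arr.centers:
        i0 = np.searchsorted(xc, cx - arr.radius - dx)
        i1 = np.searchsorted(xc, cx + arr.radius + dx)
        j0 = np.searchsorted(zc, cz - arr.radius - dz)
        j1 = np.searchsorted(zc, cz + arr.radius + dz)
        if i0 >= i1 or j0 >= j1:
            continue
        sub = (xc[i0:i1, None] - cx) ** 2 + (zc[None, j0:j1] - cz) ** 2 <= r2
        out[i0:i1, j0:j1] |= sub
    return out


# ---------------------------------------------------------------------------
# hemodynamic quantities
# ---------------------------------------------------------------------------


def flow_rate_for_velocity(u_s: float, spec: ChamberSpec) -> float:
    """Flow rate Q (mL/min) for a superficial velocity ``u_s`` (cm/min).

    Q = u_s * A_f with the frontal area in cm^2; e.g. 20 cm/min through a
    7.3 mm x 3 mm chamber gives 4.38 mL/min.
    """
    if u_s < 0:
        raise ValueError("superficial velocity must be non-negative")
    area_cm2 = (spec.width / 10.0) * (spec.height / 10.0)
    return u_s * area_cm2


def velocity_for_flow_rate(q: float, spec: ChamberSpec) -> float:
    """Superficial velocity (cm/min) for a flow rate ``q`` (mL/min)."""
    area_cm2 = (spec.width / 10.0) * (spec.height / 10.0)
    return q / area_cm2


def interstitial_velocity(u_s: float, packing_density: float) -> float:
    """Mean velocity in the void space: u_i = u_s / (1 - PD)."""
    if not 0.0 <= packing_density < 1.0:
        raise ValueError("packing density must lie in [0, 1)")
    return u_s / (1.0 - packing_density)


def hydraulic_diameter(spec: ChamberSpec) -> float:
    """Hydraulic diameter of an infinite rod bundle, mm.

    D_h = 4 x void volume / wetted rod surface = d_f (1 - PD) / PD; the
    chamber walls are excluded, consistent with cropping wall effects out of
    the analysis.
    """
    pd = spec.packing_density
    return spec.fiber_diameter * (1.0 - pd) / pd


def reynolds(density: float, velocity: float, d_h: float, viscosity: float) -> float:
    """Reynolds number rho * u * D_h / mu, evaluated in consistent SI units.

    Parameters are in the package's working units: density in g/mL, velocity
    in cm/min, hydraulic diameter in mm, dynamic viscosity in cP.  The SI
    conversion collapses to rho * u * D_h / (6 mu).
    """
    for name, v in (("density", density), ("d_h", d_h), ("viscosity", viscosity)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if velocity < 0:
        raise ValueError("velocity must be non-negative")
    # (rho*1000 kg/m^3) * (u/6000 m/s) * (D/1000 m) / (mu/1000 Pa.s)
    return density * velocity * d_h / (6.0 * viscosity)


def cumulative_surface_area(spec: ChamberSpec, z: float) -> float:
    """Rod lateral surface area (mm^2) from the inlet to depth ``z`` mm.

    S(z) = 4 PD W H z / d_f: each lattice cell of area s^2 holds one rod of
    lateral area pi d_f H, and PD = pi d_f^2 / (4 s^2).  Walls excluded.
    """
    if not 0.0 <= z <= spec.path_length:
        raise ValueError(f"z={z} outside [0, {spec.path_length}] mm")
    return 4.0 * spec.packing_density * spec.width * spec.height * z / spec.fiber_diameter


#: published 1-mm-slab comparison depths, keyed by (velocity cm/min, PD):
#: matched fiber-surface exposure across the velocity set and the packing set.
EQUIVALENT_DISTANCE_TABLE: dict[tuple[float, float], float] = {
    (16.0, 0.50): 6.8,
    (20.0, 0.50): 5.7,
    (25.0, 0.50): 4.5,
    (20.0, 0.40): 10.0,
    (20.0, 0.60): 3.2,
}

_EQ_REF = (20.0, 0.50, 5.7)  # reference condition and depth for the analytic rule


def equivalent_distance(
    velocity: float, packing_density: float, criterion: str = "published"
) -> float:
    """Depth from the inlet (mm) at which conditions have matched surface exposure.

    ``published`` returns the published depths for the five studied
    (velocity, PD) conditions verbatim.  ``equal_cumulative_surface`` solves
    S(d)/Q = S(d_ref)/Q_ref against the (20 cm/min, 50 %, 5.7 mm) reference,
    i.e. matches cumulative fiber surface per volumetric throughput, giving
    d = d_ref (PD_ref/PD)(u/u_ref).  The analytic rule is provided for
    exploration; it does not reproduce the published packing-density depths.
    """
    if criterion == "published":
        key = (round(float(velocity), 6), round(float(packing_density), 6))
        try:
            return EQUIVALENT_DISTANCE_TABLE[key]
        except KeyError:
            raise KeyError(
                f"no published equivalent distance for u={velocity} cm/min, "
                f"PD={packing_density}; use criterion='equal_cumulative_surface'"
            ) from None
    if criterion == "equal_cumulative_surface":
        u_ref, pd_ref, d_ref = _EQ_REF
        return d_ref * (pd_ref / packing_density) * (velocity / u_ref)
    raise ValueError(f"unknown criterion {criterion!r}")
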