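"""Flow resistance computation and trajectory analysis against clot-free baselines.

Resistance is the pressure drop per unit flow, R = dP/Q, in mmHg·min/mL.
Clot-free baselines for each chamber configuration were measured with a
3.4 cP glycerol-water analogue; resistances above baseline indicate clot.
Trajectories are analysed on the natural-log scale, matching how occlusion
dynamics are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ChamberSpec

__all__ = [
    "ResistanceSeries",
    "BASELINE_RESISTANCE",
    "baseline_r0",
    "resistance",
    "ln_resistance",
    "excess_over_baseline",
    "baseline_ratio",
]

#: Measured clot-free baseline resistances (mmHg·min/mL), keyed by
#: (packing density, path length mm).  These are bench-measured constants
#: shipped as a fixture, not quantities the package predicts.
BASELINE_RESISTANCE: dict[tuple[float, float], float] = {
    (0.40, 20.0): 0.333,
    (0.50, 20.0): 0.365,
    (0.60, 20.0): 0.379,
    (0.50, 40.0): 0.615,
}


def baseline_r0(spec: ChamberSpec, allow_scaling: bool = True) -> float:
    """Clot-free baseline resistance for ``spec``.

    Exact fixture lookup on (PD, L).  For chambers at a fixture PD but a
    different path length, the 2 cm value is scaled proportionally in L
    (Darcy flow: resistance of a homogeneous bundle grows linearly with its
    length) when ``allow_scaling`` — used for scaled-down study chambers.
    """
    key = (round(spec.packing_density, 6), round(spec.path_length, 6))
    if key in BASELINE_RESISTANCE:
        return BASELINE_RESISTANCE[key]
    ref = (round(spec.packing_density, 6), 20.0)
    if allow_scaling and ref in BASELINE_RESISTANCE:
        return BASELINE_RESISTANCE[ref] * spec.path_length / 20.0
    raise KeyError(f"no baseline resistance fixture for PD={spec.packing_density}, L={spec.path_length} mm")


def resistance(dp: float, q: float) -> float:
    """R = dP / Q (mmHg·min/mL).  ``q`` must be positive."""
    if q <= 0:
        raise ValueError("flow rate must be positive to define resistance")
    return dp / q


@dataclass
class ResistanceSeries:
    """Time-stamped pressure drop, flow and resistance for one run.

    ``times`` are minutes from the start of flow (0, 3, ..., 15 in the
    emulated protocol); ``dp`` is the pressure drop across the device in
    mmHg; ``q`` the flow rate in mL/min.  R = dP/Q holds at every point by
    construction.
    """

    times: np.ndarray
    dp: np.ndarray
    q: np.ndarray
    baseline_r0: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.dp = np.asarray(self.dp, dtype=float)
        self.q = np.broadcast_to(np.asarray(self.q, dtype=float), self.times.shape).copy()
        if not (self.times.shape == self.dp.shape == self.q.shape):
            raise ValueError("times, dp and q must have matching shapes")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.q <= 0):
            raise ValueError("flow rates must be positive")

    @classmethod
    def from_resistance(
        cls,
        times: np.ndarray,
        r: np.ndarray,
        q: float | np.ndarray,
        baseline_r0: float | None = None,
        label: str | None = None,
    ) -> "ResistanceSeries":
        times = np.asarray(times, dtype=float)
        r = np.asarray(r, dtype=float)
        q_arr = np.broadcast_to(np.asarray(q, dtype=float), times.shape)
        return cls(times=times, dp=r * q_arr, q=q_arr, baseline_r0=baseline_r0, label=label)

    @property
    def r(self) -> np.ndarray:
        """Resistance R(t) = dP(t)/Q(t), mmHg·min/mL."""
        return self.dp / self.q

    @property
    def ln_r(self) -> np.ndarray:
        return ln_resistance(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "dP_mmHg": self.dp,
                "Q_mL_min": self.q,
                "R": self.r,
                "lnR": self.ln_r,
            }
        )


def ln_resistance(series: ResistanceSeries | np.ndarray) -> np.ndarray:
    """Natural log of the resistance trajectory; requires R > 0 throughout."""
    r = series.r if isinstance(series, ResistanceSeries) else np.asarray(series, dtype=float)
    if np.any(r <= 0):
        raise ValueError("ln(resistance) undefined for non-positive resistance")
    return np.log(r)


def excess_over_baseline(series: ResistanceSeries, r0: float | None = None) -> np.ndarray:
    """Boolean per time point: R(t) strictly above the clot-free baseline.

    The baseline itself is clot-free, so equality does not flag clot.
    """
    if r0 is None:
        r0 = series.baseline_r0
    if r0 is None or r0 <= 0:
        raise ValueError("a positive baseline resistance is required")
    return series.r > r0


def baseline_ratio(r_a: float, r_b: float) -> float:
    """Ratio of two baseline resistances, r_a / r_b."""
    if r_b <= 0:
        raise ValueError("denominator resistance must be positive")
    return r_a / r_b
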