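"""Post-hoc glenohumeral stability analysis.

Given a solved motion, the reaction-force direction at the glenoid is
summarized as the angle theta between the force and the glenoid axis, the
occupancy histogram of theta over the movement, and a violation report
against the stability cone half-angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .multibody import GlenoidGeometry

__all__ = ["AngleHistogram", "jrf_angle", "angle_histogram", "violation_report"]

ZERO_FORCE_NORM = 1e-6  # N


@dataclass(frozen=True)
class AngleHistogram:
    """Occupancy (%) of JRF angles in half-open bins [lo, hi) of equal width."""

    bin_edges_deg: np.ndarray
    occupancy_percent: np.ndarray
    n_frames: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo_deg": self.bin_edges_deg[:-1],
                "bin_hi_deg": self.bin_edges_deg[1:],
                "occupancy_percent": self.occupancy_percent,
            }
        )


def jrf_angle(F: np.ndarray, glenoid: GlenoidGeometry) -> float:
    """Angle (deg) between a reaction force and the glenoid axis.

    Zero force is defined stable and reports 0 deg.
    """
    F = np.asarray(F, float)
    norm = np.linalg.norm(F)
    if norm < ZERO_FORCE_NORM:
        return 0.0
    cosang = float(np.clip(F @ np.asarray(glenoid.direction) / norm, -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def angle_histogram(theta_series_deg: np.ndarray, bin_width_deg: float = 2.0) -> AngleHistogram:
    """Occupancy histogram (percent of frames per angle bin)."""
    theta = np.asarray(theta_series_deg, float)
    if theta.size == 0:
        raise ValueError("empty angle series")
    # top edge strictly above the max so every bin is effectively [lo, hi)
    hi = max(bin_width_deg, bin_width_deg * math.ceil((theta.max() + 1e-12) / bin_width_deg))
    edges = np.arange(0.0, hi + bin_width_deg * 0.5, bin_width_deg)
    counts, edges = np.histogram(theta, bins=edges)
    return AngleHistogram(
        bin_edges_deg=edges,
        occupancy_percent=100.0 * counts / theta.size,
        n_frames=int(theta.size),
    )


def violation_report(theta_series_deg: np.ndarray, theta_max_deg: float) -> tuple[float, float]:
    """(fraction of frames above theta_max, max exceedance in deg)."""
    theta = np.asarray(theta_series_deg, float)
    if theta.size == 0:
        raise ValueError("empty angle series")
    over = theta > theta_max_deg
    frac = float(np.count_nonzero(over)) / theta.size
    excess = float(np.max(theta - theta_max_deg)) if np.any(over) else 0.0
    return frac, max(excess, 0.0)
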