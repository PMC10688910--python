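"""Trajectory I/O and conditioning.

Coordinate trajectories live in a TrajectoryTable (time + one column per
coordinate) and on disk in the OpenSim STO/MOT storage dialect: a small
key=value header terminated by ``endheader``, then a whitespace-delimited
numeric block whose first column is time.  Angles are radians in memory; a
header flag ``inDegrees=yes`` converts on read/write.

Conditioning mirrors the usual inverse-kinematics post-processing chain:
zero-phase 4th-order Butterworth low-pass at 3 Hz, then cubic-spline
differentiation to coordinate speeds and accelerations.  Robustness
ensembles perturb the angle trajectories directly with band-limited
Gaussian jitter (a stand-in for marker-placement uncertainty propagated
through inverse kinematics, which needs marker data this package does not
consume).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import CubicSpline

__all__ = [
    "TrajectoryTable",
    "StorageParseError",
    "read_storage",
    "write_storage",
    "lowpass_filter",
    "differentiate",
    "resample",
    "perturb_trajectory",
]

UNIFORM_TOL = 1e-9  # s, max deviation from uniform sampling tolerated by filters


class StorageParseError(ValueError):
    """Malformed storage file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


@dataclass
class TrajectoryTable:
    """Time-indexed coordinate series (rad, rad/s or rad/s² by `kind`)."""

    time: np.ndarray
    columns: dict[str, np.ndarray]
    kind: str = "angles"  # angles | speeds | accelerations
    name: str = "trajectory"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or self.time.size == 0:
            raise ValueError("time must be a non-empty 1-D array")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        self.columns = {k: np.asarray(v, dtype=float) for k, v in self.columns.items()}
        for k, v in self.columns.items():
            if v.shape != self.time.shape:
                raise ValueError(f"column {k!r} length does not match time")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"column {k!r} contains non-finite values")

    # -- convenience -----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def names(self) -> list[str]:
        return list(self.columns)

    @property
    def dt(self) -> float:
        """Uniform sample interval; raises if sampling is not uniform."""
        steps = np.diff(self.time)
        if steps.size == 0:
            raise ValueError("need at least 2 samples")
        if np.max(np.abs(steps - steps[0])) > UNIFORM_TOL:
            raise ValueError("sampling is not uniform")
        return float(steps[0])

    def as_matrix(self, names: list[str] | None = None) -> np.ndarray:
        names = names if names is not None else self.names
        return np.column_stack([self.columns[n] for n in names])

    def copy_with(self, **kw) -> "TrajectoryTable":
        base = dict(
            time=self.time.copy(),
            columns={k: v.copy() for k, v in self.columns.items()},
            kind=self.kind,
            name=self.name,
            metadata=dict(self.metadata),
        )
        base.update(kw)
        return TrajectoryTable(**base)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, **self.columns})


# ---------------------------------------------------------------------------
# storage dialect
# ---------------------------------------------------------------------------


def read_storage(path) -> TrajectoryTable:
    """Read an STO/MOT storage file; converts degrees to radians if flagged."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    header: dict[str, str] = {}
    name = "trajectory"
    i = 0
    if lines and "=" not in lines[0] and lines[0].strip() and not lines[0].startswith("version"):
        name = lines[0].strip()
        i = 1
    body_start = None
    for j in range(i, len(lines)):
        ln = lines[j].strip()
        if ln.lower() == "endheader":
            body_start = j + 1
            break
        if "=" in ln:
            k, _, v = ln.partition("=")
            header[k.strip()] = v.strip()
    if body_start is None:
        raise StorageParseError("missing 'endheader' terminator")
    # column-name row
    while body_start < len(lines) and not lines[body_start].strip():
        body_start += 1
    if body_start >= len(lines):
        raise StorageParseError("missing column-name row", body_start)
    colnames = lines[body_start].split()
    if not colnames or colnames[0] != "time":
        raise StorageParseError("first column must be named 'time'", body_start + 1)
    rows = []
    for j in range(body_start + 1, len(lines)):
        ln = lines[j].strip()
        if not ln:
            continue
        parts = ln.split()
        if len(parts) != len(colnames):
            raise StorageParseError(
                f"expected {len(colnames)} values, found {len(parts)}", j + 1
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise StorageParseError(str(exc), j + 1) from None
    if not rows:
        raise StorageParseError("no data rows")
    data = np.asarray(rows, dtype=float)
    if "nRows" in header and int(header["nRows"]) != data.shape[0]:
        raise StorageParseError(
            f"header nRows={header['nRows']} but file has {data.shape[0]} rows"
        )
    if "nColumns" in header and int(header["nColumns"]) != data.shape[1]:
        raise StorageParseError(
            f"header nColumns={header['nColumns']} but file has {data.shape[1]} columns"
        )
    time = data[:, 0]
    if np.any(np.diff(time) <= 0):
        raise StorageParseError("time column is not strictly increasing")
    in_degrees = header.get("inDegrees", "no").lower() == "yes"
    scale = math.pi / 180.0 if in_degrees else 1.0
    columns = {c: data[:, k + 1] * scale for k, c in enumerate(colnames[1:])}
    return TrajectoryTable(
        time=time,
        columns=columns,
        kind=header.get("kind", "angles"),
        name=name,
        metadata={"inDegrees": in_degrees},
    )


def write_storage(table: TrajectoryTable, path, in_degrees: bool | None = None) -> None:
    """Write the STO dialect; 17 significant digits so round-trips are lossless."""
    if in_degrees is None:
        in_degrees = bool(table.metadata.get("inDegrees", False))
    scale = 180.0 / math.pi if in_degrees else 1.0
    names = table.names
    with open(path, "w") as fh:
        fh.write(f"{table.name}\n")
        fh.write(f"kind={table.kind}\n")
        fh.write(f"nRows={table.n_samples}\n")
        fh.write(f"nColumns={len(names) + 1}\n")
        fh.write(f"inDegrees={'yes' if in_degrees else 'no'}\n")
        fh.write("endheader\n")
        fh.write("time\t" + "\t".join(names) + "\n")
        mat = table.as_matrix(names) * scale
        for t, row in zip(table.time, mat):
            fh.write("\t".join(f"{v:.17g}" for v in (t, *row)) + "\n")


# ---------------------------------------------------------------------------
# conditioning
# ---------------------------------------------------------------------------


def lowpass_filter(
    table: TrajectoryTable, cutoff_hz: float = 3.0, order: int = 4
) -> TrajectoryTable:
    """Zero-phase Butterworth low-pass (forward-backward, DC gain exactly 1)."""
    dt = table.dt
    nyquist = 0.5 / dt
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz is not below Nyquist {nyquist} Hz")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=1.0 / dt, output="sos")
    cols = {k: signal.sosfiltfilt(sos, v) for k, v in table.columns.items()}
    return table.copy_with(columns=cols)


def differentiate(table: TrajectoryTable) -> tuple[TrajectoryTable, TrajectoryTable]:
    """Speeds and accelerations by interpolating-cubic-spline differentiation.

    Natural end conditions; accuracy at the first/last few samples is not
    guaranteed (spline boundary effect).
    """
    if table.kind != "angles":
        raise ValueError("differentiate expects an angle table")
    if table.n_samples < 4:
        raise ValueError("need at least 4 samples to differentiate")
    spd: dict[str, np.ndarray] = {}
    acc: dict[str, np.ndarray] = {}
    for k, v in table.columns.items():
        cs = CubicSpline(table.time, v, bc_type="natural")
        spd[k] = cs(table.time, 1)
        acc[k] = cs(table.time, 2)
    return (
        table.copy_with(columns=spd, kind="speeds"),
        table.copy_with(columns=acc, kind="accelerations"),
    )


def resample(table: TrajectoryTable, times: np.ndarray) -> TrajectoryTable:
    """Cubic-spline resampling onto a new time grid (within the original span)."""
    times = np.asarray(times, dtype=float)
    if times[0] < table.time[0] - 1e-12 or times[-1] > table.time[-1] + 1e-12:
        raise ValueError("resample grid extends beyond the table time span")
    cols = {
        k: CubicSpline(table.time, v, bc_type="natural")(times)
        for k, v in table.columns.items()
    }
    return table.copy_with(time=times, columns=cols)


def _bandlimited_noise_gain(sos, n_freq: int = 4096) -> float:
    """Std-dev gain of the zero-phase filter on unit white noise."""
    w, h = signal.sosfreqz(sos, worN=n_freq)
    # zero-phase application squares the magnitude response
    h2 = np.abs(h) ** 2
    return float(np.sqrt(np.mean(h2**2)))


def perturb_trajectory(
    table: TrajectoryTable,
    sigma_rad: float,
    n_ensemble: int,
    seed: int,
    cutoff_hz: float = 3.0,
) -> list[TrajectoryTable]:
    """Replicates of an angle table with band-limited Gaussian jitter.

    Each replicate adds, independently per coordinate, white Gaussian noise
    low-passed at `cutoff_hz` (so the jitter is as smooth as the kinematics)
    and rescaled so the per-sample standard deviation equals `sigma_rad`.
    Deterministic given the seed; sigma 0 returns exact copies.
    """
    if sigma_rad < 0:
        raise ValueError("sigma_rad must be non-negative")
    rng = np.random.default_rng(seed)
    if sigma_rad == 0.0:
        return [table.copy_with(name=f"{table.name}_rep{r}") for r in range(n_ensemble)]
    dt = table.dt
    sos = signal.butter(4, cutoff_hz, btype="low", fs=1.0 / dt, output="sos")
    gain = _bandlimited_noise_gain(sos)
    out = []
    for r in range(n_ensemble):
        cols = {}
        for k, v in table.columns.items():
            white = rng.standard_normal(v.size)
            noise = signal.sosfiltfilt(sos, white) * (sigma_rad / gain)
            cols[k] = v + noise
        out.append(table.copy_with(columns=cols, name=f"{table.name}_rep{r}"))
    return out
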