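"""Depth-trace handling: I/O, zero-offset correction, and dive segmentation.

A time-depth recorder (TDR) samples pressure (converted to depth, metres,
positive down) at a fixed interval, 10 s in the deployments this package
emulates.  Raw records drift because the pressure transducer's zero point
wanders; the standard remedy is a zero-offset correction (ZOC) that
re-estimates the surface baseline over a rolling window and subtracts it.
After correction, a *dive* is a maximal run of samples deeper than a surface
threshold; dives are retained for shape analysis only when they exceed a
minimum depth and contain a minimum number of samples, because very short
records do not resolve dive shape.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from datetime import datetime

import numpy as np
import pandas as pd

__all__ = [
    "DepthTrace",
    "DiveWindow",
    "zero_offset_correct",
    "detect_dives",
    "read_trace",
    "write_trace",
]


@dataclass
class DepthTrace:
    """A regularly sampled depth record for one animal.

    Parameters
    ----------
    depth : ndarray
        Depth per sample in metres, positive down.
    dt : float
        Sampling interval in seconds.
    animal_id : str
        Identifier of the tagged animal.
    time : ndarray, optional
        Elapsed seconds per sample.  Defaults to ``arange(n) * dt``.
    start : datetime, optional
        Wall-clock time of the first sample; needed only for season and
        day/night assignment downstream.
    """

    depth: np.ndarray
    dt: float
    animal_id: str = "seal"
    time: np.ndarray = field(default=None)  # type: ignore[assignment]
    start: datetime | None = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1 or self.depth.size < 2:
            raise ValueError("depth must be a 1-D array with at least 2 samples")
        if not np.all(np.isfinite(self.depth)):
            raise ValueError("depths must be finite")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.time is None:
            self.time = np.arange(self.depth.size, dtype=float) * self.dt
        else:
            self.time = np.asarray(self.time, dtype=float)
            if self.time.shape != self.depth.shape:
                raise ValueError("time and depth must have equal length")
            steps = np.diff(self.time)
            if not np.allclose(steps, self.dt, rtol=0, atol=1e-6 * self.dt):
                raise ValueError("time must increase in constant steps of dt")

    @property
    def n(self) -> int:
        return self.depth.size

    @property
    def duration(self) -> float:
        """Record span in seconds (n samples at dt each)."""
        return self.n * self.dt


@dataclass(frozen=True)
class DiveWindow:
    """Inclusive [start, end] sample indices of one submerged excursion."""

    start: int
    end: int
    max_depth: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end must be >= start")

    @property
    def n_samples(self) -> int:
        return self.end - self.start + 1


def zero_offset_correct(
    trace: DepthTrace,
    window: float = 7200.0,
    percentile: float = 5.0,
) -> DepthTrace:
    """Remove transducer drift by subtracting a rolling surface baseline.

    The baseline is the lower ``percentile`` of depth within a centred
    rolling window of ``window`` seconds; it tracks what the instrument
    reads when the animal is at the surface.  Corrected depths are clamped
    at zero (an animal cannot be above the surface).

    Parameters
    ----------
    window : float
        Baseline window in seconds; must cover at least 10 samples so the
        percentile is estimated from surface visits rather than one dive.
    percentile : float
        Lower percentile treated as the surface reading (default 5).
    """
    nwin = int(round(window / trace.dt))
    if nwin < 10:
        raise ValueError("ZOC window must span at least 10 samples")
    baseline = (
        pd.Series(trace.depth)
        .rolling(nwin, center=True, min_periods=1)
        .quantile(percentile / 100.0)
        .to_numpy()
    )
    corrected = np.maximum(trace.depth - baseline, 0.0)
    return replace(trace, depth=corrected)


def detect_dives(
    trace: DepthTrace,
    surface_threshold: float = 2.0,
    min_depth: float = 5.0,
    min_samples: int = 5,
) -> list[DiveWindow]:
    """Segment a (corrected) trace into dive windows.

    A candidate dive is a maximal run of consecutive samples with
    ``depth > surface_threshold``.  Runs are kept when their maximum depth
    strictly exceeds ``min_depth`` (shallower excursions do not resolve
    dive shape) and they contain at least ``min_samples`` samples.
    Returns disjoint, time-ordered windows; an all-surface trace yields an
    empty list.
    """
    submerged = trace.depth > surface_threshold
    if not submerged.any():
        return []
    padded = np.concatenate([[False], submerged, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2] - 1
    windows = []
    for s, e in zip(starts, ends):
        if e - s + 1 < min_samples:
            continue
        peak = float(trace.depth[s : e + 1].max())
        if peak > min_depth:
            windows.append(DiveWindow(int(s), int(e), peak))
    return windows


def write_trace(trace: DepthTrace, path) -> None:
    """Write a trace as two-column delimited text with metadata header."""
    with open(path, "w") as fh:
        fh.write(f"# animal_id={trace.animal_id}\n")
        fh.write(f"# dt={trace.dt!r}\n")
        if trace.start is not None:
            fh.write(f"# start={trace.start.isoformat()}\n")
        pd.DataFrame({"time_s": trace.time, "depth_m": trace.depth}).to_csv(
            fh, index=False, float_format="%.10g"
        )


def read_trace(path) -> DepthTrace:
    """Read a trace written by :func:`write_trace` (or any 2-column CSV).

    Plain two-column CSVs with a header row are accepted; the sampling
    interval is then inferred from the time column.
    """
    meta: dict[str, str] = {}
    lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
            else:
                lines.append(line)
    df = pd.read_csv(io.StringIO("".join(lines)))
    time = df.iloc[:, 0].to_numpy(dtype=float)
    depth = df.iloc[:, 1].to_numpy(dtype=float)
    dt = float(meta["dt"]) if "dt" in meta else float(np.median(np.diff(time)))
    start = datetime.fromisoformat(meta["start"]) if "start" in meta else None
    return DepthTrace(
        depth=depth,
        dt=dt,
        animal_id=meta.get("animal_id", "seal"),
        time=time,
        start=start,
    )
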