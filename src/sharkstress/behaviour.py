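"""Behavioural trait extraction: lateralisation, ODBA activity, hypoxia endpoint.

Three behavioural/physiological endpoints are derived here:

* turning-side preference in a detour T-maze, summarised as the relative
  (L_R, signed) and absolute (L_A) lateralisation indices;
* volitional activity from a tri-axial accelerometer tag, summarised as
  overall dynamic body acceleration (ODBA) averaged over a midday clock
  window;
* hypoxia tolerance, the % air saturation at the onset of muscle spasms
  during a nitrogen-driven drawdown trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TurnRecord",
    "LateralisationResult",
    "AccelTrace",
    "HypoxiaTrial",
    "lateralisation",
    "odba_series",
    "activity_level",
    "hypoxia_tolerance",
]


@dataclass
class TurnRecord:
    """Ordered maze-exit turn decisions for one shark.

    ``turns`` are "L"/"R"; ``maze_sides`` records which maze arm each trial
    was initiated from (to balance any structural asymmetry of the maze).
    """

    shark_id: str
    turns: list[str]
    maze_sides: list[str] | None = None

    def __post_init__(self) -> None:
        bad = set(self.turns) - {"L", "R"}
        if bad:
            raise ValueError(f"turn labels must be 'L'/'R', got {sorted(bad)}")
        if self.maze_sides is not None and len(self.maze_sides) != len(self.turns):
            raise ValueError("maze_sides must align with turns")


@dataclass(frozen=True)
class LateralisationResult:
    relative: float  # L_R in [-100, 100]; positive = right bias
    absolute: float  # L_A = |L_R| in [0, 100]


@dataclass
class AccelTrace:
    """Tri-axial acceleration (g) at a uniform sampling rate."""

    time: np.ndarray  # s, uniform
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sampling_rate: float = 25.0  # Hz
    clock_start: float = 0.0  # seconds-since-midnight of time[0]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        for ax in ("x", "y", "z"):
            arr = np.asarray(getattr(self, ax), dtype=float)
            if arr.shape != self.time.shape:
                raise ValueError(f"axis {ax} must align with time")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite samples on axis {ax}")
            setattr(self, ax, arr)
        dt = np.diff(self.time)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("acceleration trace must be uniformly sampled")


@dataclass
class HypoxiaTrial:
    """O2 drawdown trial: % air saturation vs time, with the spasm-onset time."""

    time: np.ndarray  # s
    saturation: np.ndarray  # % air saturation
    os_time: float  # onset of muscle spasms, s

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.saturation = np.asarray(self.saturation, dtype=float)
        if self.time.shape != self.saturation.shape:
            raise ValueError("time and saturation must align")
        if not (self.time[0] <= self.os_time <= self.time[-1]):
            raise ValueError("OS event time outside the recorded trace")


def lateralisation(record: TurnRecord) -> LateralisationResult:
    """L_R = (right - left) / total * 100; L_A = |L_R|."""
    n = len(record.turns)
    if n == 0:
        raise ValueError("turn record is empty")
    right = sum(1 for t in record.turns if t == "R")
    left = n - right
    l_r = (right - left) / n * 100.0
    return LateralisationResult(relative=l_r, absolute=abs(l_r))


def odba_series(trace: AccelTrace, window_s: float = 2.0) -> np.ndarray:
    """Overall dynamic body acceleration per sample (g).

    The static (postural/gravity) component of each axis is a centred
    running mean over ``window_s``; the window shrinks symmetrically at the
    trace edges.  The dynamic component is raw minus static, and ODBA sums
    its absolute value over the three axes.
    """
    n = trace.time.size
    window = int(round(window_s * trace.sampling_rate))
    if window < 1 or n < window:
        raise ValueError("trace shorter than the smoothing window")
    odba = np.zeros(n)
    for ax in ("x", "y", "z"):
        raw = getattr(trace, ax)
        static = (
            pd.Series(raw).rolling(window, center=True, min_periods=1).mean().to_numpy()
        )
        odba += np.abs(raw - static)
    return odba


def activity_level(
    trace: AccelTrace,
    odba: np.ndarray | None = None,
    clock_window: tuple[float, float] = (11 * 3600.0, 15 * 3600.0),
) -> float:
    """Mean ODBA over a half-open clock window [start, end) (s since midnight).

    The default window (1100-1500) leaves a post-tagging recovery buffer
    before activity is scored.
    """
    if odba is None:
        odba = odba_series(trace)
    clock = trace.clock_start + trace.time
    start, end = clock_window
    mask = (clock >= start) & (clock < end)
    if not mask.any():
        raise ValueError("no ODBA samples fall inside the clock window")
    return float(np.mean(odba[mask]))


def hypoxia_tolerance(trial: HypoxiaTrial) -> float:
    """% air saturation at the onset of muscle spasms (linear interpolation)."""
    return float(np.interp(trial.os_time, trial.time, trial.saturation))
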