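"""Sigmoid homotopy between consecutive carrying-capacity frames.

Between two frames K_L at t_L and K_H at t_H the capacity is interpolated
as K(x, t) = K_L(x) (1 - S(t)) + K_H(x) S(t), where S is the classical
logistic sigmoid composed with a time warp that sends t_L to -inf and t_H
to +inf.  With warp exponent nu = 1 every time derivative of S(z(t))
vanishes at both endpoints and the warp is invariant under rescaling all
times, so the nonuniform frame schedule needs no special handling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from .raster import RasterGrid, read_capacity_grid

__all__ = [
    "sigmoid",
    "warped_time",
    "SigmoidParams",
    "FrameInterval",
    "CapacitySeries",
    "load_frame_manifest",
]


def sigmoid(z: float | np.ndarray) -> float | np.ndarray:
    """Classical logistic S(z) = 1 / (1 + exp(-z)); exact at +-inf."""
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))
    if np.ndim(z) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class SigmoidParams:
    """Warp exponent nu; values below 1/2 give an oscillating curvature."""

    nu: float = 1.0

    def __post_init__(self) -> None:
        if self.nu < 0.5:
            raise ValueError("warp exponent nu must be >= 1/2")


def warped_time(t: float, t_l: float, t_h: float, nu: float = 1.0) -> float:
    """Map t in [t_L, t_H] onto the full real line.

    z = (2 dT (t - t_L) - dT^2) / ((t - t_L) (dT - (t - t_L)))^nu with
    dT = t_H - t_L; the endpoints are 0/0 forms whose analytic limits
    (-inf, +inf) are returned exactly.  With nu = 1, z is invariant under
    rescaling (t, t_L, t_H) -> (a t, a t_L, a t_H).
    """
    if not t_h > t_l:
        raise ValueError("need t_H > t_L")
    if t < t_l or t > t_h:
        raise ValueError(f"t={t} outside frame interval [{t_l}, {t_h}]")
    if t == t_l:
        return -math.inf
    if t == t_h:
        return math.inf
    dt = t_h - t_l
    s = t - t_l
    return (2.0 * dt * s - dt * dt) / (s * (dt - s)) ** nu


@dataclass
class FrameInterval:
    """Two bracketing capacity frames and their times (simulation clock)."""

    t_l: float
    t_h: float
    K_l: np.ndarray
    K_h: np.ndarray

    def __post_init__(self) -> None:
        if not self.t_h > self.t_l:
            raise ValueError("need t_H > t_L")
        if self.K_l.shape != self.K_h.shape:
            raise ValueError("frame grids must share one shape")

    def capacity_at(self, t: float, nu: float = 1.0) -> np.ndarray:
        s = sigmoid(warped_time(t, self.t_l, self.t_h, nu))
        if s == 0.0:
            return self.K_l.copy()
        if s == 1.0:
            return self.K_h.copy()
        return self.K_l * (1.0 - s) + self.K_h * s


class CapacitySeries:
    """Ordered capacity frames with sigmoid interpolation between them.

    ``frames`` is a list of ``(time, array)`` pairs with strictly increasing
    times on the forward simulation clock.  An optional callback fires
    whenever a lookup moves to a new bracketing interval (the hook used for
    resegmentation when coastlines change between frames).
    """

    def __init__(
        self,
        frames: list[tuple[float, np.ndarray]],
        params: SigmoidParams = SigmoidParams(),
        water_threshold: float = 0.0,
    ) -> None:
        if len(frames) < 2:
            raise ValueError("need at least two frames")
        times = [t for t, _ in frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        shape = frames[0][1].shape
        if any(arr.shape != shape for _, arr in frames):
            raise ValueError("all frames must share one shape")
        self.frames = [(float(t), np.asarray(arr, dtype=float)) for t, arr in frames]
        self.params = params
        self.water_threshold = water_threshold
        self._current: Optional[tuple[int, FrameInterval]] = None
        self.on_new_interval: Optional[Callable[[FrameInterval], None]] = None

    @property
    def span(self) -> tuple[float, float]:
        return self.frames[0][0], self.frames[-1][0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0][1].shape

    @property
    def max_capacity(self) -> float:
        return max(float(arr.max()) for _, arr in self.frames)

    def interval_for(self, t: float) -> FrameInterval:
        """Bracketing interval, firing the new-interval callback on change."""
        lo, hi = self.span
        if t < lo or t > hi:
            raise ValueError(f"t={t} outside frame span [{lo}, {hi}]")
        times = [ft for ft, _ in self.frames]
        idx = int(np.searchsorted(times, t, side="right")) - 1
        idx = min(max(idx, 0), len(self.frames) - 2)
        if self._current is None or self._current[0] != idx:
            interval = FrameInterval(
                times[idx],
                times[idx + 1],
                self.frames[idx][1],
                self.frames[idx + 1][1],
            )
            self._current = (idx, interval)
            if self.on_new_interval is not None:
                self.on_new_interval(interval)
        return self._current[1]

    def interval_mask(self, interval: FrameInterval) -> np.ndarray:
        """Habitable set for an interval: max(K_L, K_H) > water threshold."""
        return np.maximum(interval.K_l, interval.K_h) > self.water_threshold

    def capacity_at(self, t: float) -> np.ndarray:
        """Interpolated capacity field at time t."""
        return self.interval_for(t).capacity_at(t, self.params.nu)


def load_frame_manifest(
    path: str | Path,
    start_kya: float,
    params: SigmoidParams = SigmoidParams(),
    water_threshold: float = 0.0,
) -> tuple[CapacitySeries, RasterGrid]:
    """Load a CSV manifest of (time_kya, path-to-.asc) capacity frames.

    Frame times in kilo-years before present are converted once to the
    forward simulation clock t = (start_kya - kya) * 1000 years.  Returns
    the series plus the first frame's grid (for cell size and origin).
    """
    import pandas as pd

    path = Path(path)
    table = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in table.columns}
    if "time_kya" not in cols or "path" not in cols:
        raise ValueError("manifest needs columns time_kya, path")
    frames: list[tuple[float, np.ndarray]] = []
    first: Optional[RasterGrid] = None
    for _, rec in table.iterrows():
        grid = read_capacity_grid(path.parent / str(rec[cols["path"]]))
        if first is None:
            first = grid
        elif grid.shape != first.shape or grid.cell_size != first.cell_size:
            raise ValueError("all frames must share shape and cell size")
        t_sim = (start_kya - float(rec[cols["time_kya"]])) * 1000.0
        frames.append((t_sim, grid.filled(0.0)))
    frames.sort(key=lambda p: p[0])
    assert first is not None
    return CapacitySeries(frames, params, water_threshold), first
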