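"""Precursor isolation-window schemes for SWATH-style DIA acquisition.

Two designs are supported: fixed-width windows advancing by (width - overlap)
between stated center masses (the Orbitrap-style 35 x 24 m/z scheme), and
density-balanced variable-width windows placed at equal-target-count
quantiles of the precursor m/z distribution so that windows are narrow where
histone peptides crowd (~m/z 300-900) and wide elsewhere.  Cycle time is the
MS1 accumulation plus all window accumulations plus a per-scan overhead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["WindowScheme", "fixed_scheme", "variable_scheme", "cycle_time"]


@dataclass
class WindowScheme:
    """Ordered precursor isolation windows with a constant stated overlap."""

    windows: list[tuple[float, float]]
    overlap: float = 0.0
    ms1_ms: float = 100.0
    ms2_ms: float = 10.0
    overhead_ms: float = 5.6

    def __post_init__(self) -> None:
        self.windows = [(float(lo), float(hi)) for lo, hi in self.windows]
        self.validate()

    def validate(self) -> None:
        if not self.windows:
            raise ValueError("scheme has no windows")
        for lo, hi in self.windows:
            if hi <= lo:
                raise ValueError(f"degenerate window ({lo}, {hi})")
        lows = [w[0] for w in self.windows]
        if lows != sorted(lows):
            raise ValueError("windows not sorted by lower bound")
        for (lo0, hi0), (lo1, hi1) in zip(self.windows, self.windows[1:]):
            if abs((hi0 - lo1) - self.overlap) > 1e-6:
                raise ValueError(
                    f"windows ({lo0},{hi0}) and ({lo1},{hi1}) do not overlap "
                    f"by the stated {self.overlap}"
                )

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def precursor_range(self) -> tuple[float, float]:
        return (self.windows[0][0], self.windows[-1][1])

    def widths(self) -> np.ndarray:
        return np.array([hi - lo for lo, hi in self.windows])

    def containing(self, mz: float) -> list[tuple[float, float]]:
        """All windows whose bounds contain mz (two in an overlap region)."""
        return [(lo, hi) for lo, hi in self.windows if lo <= mz <= hi]

    def window_for(self, mz: float) -> tuple[float, float]:
        """The window containing mz, center-closest when in an overlap."""
        hits = self.containing(mz)
        if not hits:
            raise ValueError(f"m/z {mz} outside every window")
        return min(hits, key=lambda w: abs((w[0] + w[1]) / 2 - mz))

    def covers(self, mzs: Sequence[float]) -> bool:
        lo, hi = self.precursor_range
        return all(lo <= m <= hi for m in mzs)

    # -- CSV round-trip --------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window": np.arange(1, len(self) + 1),
                "low_mz": [round(lo, 1) for lo, _ in self.windows],
                "high_mz": [round(hi, 1) for _, hi in self.windows],
                "accumulation_ms": self.ms2_ms,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, overlap: float | None = None, **kwargs) -> "WindowScheme":
        """Read a scheme CSV; also accepts vendor-calculator two-column
        (start, stop) files with or without a header."""
        try:
            df = pd.read_csv(path)
            numeric = df.select_dtypes("number")
        except Exception as exc:  # pragma: no cover - defensive
            raise ValueError(f"unreadable scheme file {path}: {exc}") from exc
        if {"low_mz", "high_mz"}.issubset(df.columns):
            lows, highs = df["low_mz"].to_numpy(), df["high_mz"].to_numpy()
            if "accumulation_ms" in df.columns:
                kwargs.setdefault("ms2_ms", float(df["accumulation_ms"].iloc[0]))
        elif numeric.shape[1] >= 2:
            lows = numeric.iloc[:, 0].to_numpy(dtype=float)
            highs = numeric.iloc[:, 1].to_numpy(dtype=float)
        else:
            df = pd.read_csv(path, header=None)
            lows = df.iloc[:, 0].to_numpy(dtype=float)
            highs = df.iloc[:, 1].to_numpy(dtype=float)
        if overlap is None:
            overlap = (
                float(np.round(np.mean(highs[:-1] - lows[1:]), 6))
                if len(lows) > 1
                else 0.0
            )
        return cls(windows=list(zip(lows, highs)), overlap=overlap, **kwargs)


def fixed_scheme(
    first_center: float,
    last_center: float,
    width: float,
    overlap: float,
    **kwargs,
) -> WindowScheme:
    """Fixed-width windows with centers advancing by (width - overlap)."""
    if not width > overlap >= 0:
        raise ValueError("need width > overlap >= 0")
    step = width - overlap
    span = last_center - first_center
    n_steps = span / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(
            f"last_center - first_center = {span} is not a multiple of "
            f"width - overlap = {step}"
        )
    centers = first_center + step * np.arange(round(n_steps) + 1)
    windows = [(c - width / 2, c + width / 2) for c in centers]
    return WindowScheme(windows=windows, overlap=overlap, **kwargs)


def quantile_edges(target_mzs: Sequence[float], n_windows: int,
                   mz_range: tuple[float, float]) -> np.ndarray:
    """Contiguous window edges with equal target counts per window.

    Targets are sorted and split into n chunks whose sizes differ by at most
    one; each interior edge is the midpoint between the last target of one
    chunk and the first of the next.
    """
    targets = np.sort(np.asarray(target_mzs, dtype=float))
    if targets.size == 0:
        raise ValueError("empty target list")
    lo, hi = mz_range
    if targets[0] < lo or targets[-1] > hi:
        raise ValueError("mz_range does not cover all targets")
    chunks = np.array_split(targets, n_windows)
    edges = [lo]
    for a, b in zip(chunks, chunks[1:]):
        if len(a) == 0 or len(b) == 0:
            edges.append(edges[-1])
            continue
        edges.append((a[-1] + b[0]) / 2)
    edges.append(hi)
    return np.array(edges)


def variable_scheme(
    target_mzs: Sequence[float],
    n_windows: int,
    min_width: float = 5.0,
    overlap: float = 1.0,
    mz_range: tuple[float, float] | None = None,
    **kwargs,
) -> WindowScheme:
    """Density-balanced variable windows over the precursor range.

    Boundaries sit at equal-target-count quantiles of the precursor m/z
    distribution, each window is then widened to at least ``min_width``, and
    finally the stated overlap is applied symmetrically, so consecutive
    windows overlap by exactly ``overlap`` and the union covers the range
    without gaps.  Fully deterministic.
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    targets = np.sort(np.asarray(target_mzs, dtype=float))
    if targets.size == 0:
        raise ValueError("empty target list")
    if mz_range is None:
        pad = max(min_width, 1.0)
        mz_range = (float(targets[0] - pad), float(targets[-1] + pad))
    edges = quantile_edges(targets, n_windows, mz_range)
    lo, hi = mz_range
    if hi - lo < n_windows * min_width:
        raise ValueError("mz_range too small for n_windows * min_width")
    # enforce minimum contiguous width: forward then backward sweep
    for i in range(1, len(edges)):
        edges[i] = max(edges[i], edges[i - 1] + min_width) if i < len(edges) - 1 else edges[i]
    for i in range(len(edges) - 2, 0, -1):
        edges[i] = min(edges[i], edges[i + 1] - min_width)
    windows = [
        (edges[i] - overlap / 2, edges[i + 1] + overlap / 2)
        for i in range(n_windows)
    ]
    return WindowScheme(windows=windows, overlap=overlap, **kwargs)


def cycle_time(scheme: WindowScheme) -> float:
    """Cycle duration in seconds: MS1 + all MS2 accumulations + per-scan
    overhead for the MS1 scan and each window scan."""
    n = len(scheme)
    total_ms = (
        scheme.ms1_ms + n * scheme.ms2_ms + scheme.overhead_ms * (n + 1)
    )
    return total_ms / 1000.0
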