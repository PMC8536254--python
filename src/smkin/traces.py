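"""Trace containers and plain-text I/O.

Two trace flavours run through the package:

* :class:`IntensityTrace` — a single background-corrected photon-count stream
  (donor intensity I_Cy3) from an unwinding-induced-fluorescence-enhancement
  (UIFE) experiment.
* :class:`AlexTrace` — the three aligned streams of an alternating-laser
  excitation (ALEX) FRET experiment: donor emission under donor excitation
  (I_DD), acceptor emission under donor excitation (I_DA) and acceptor
  emission under acceptor excitation (I_AA).

Traces are stored as TSV tables with a header, one row per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["IntensityTrace", "AlexTrace", "read_trace", "write_trace"]


@dataclass
class IntensityTrace:
    """Background-corrected intensity-vs-time trajectory (counts/frame)."""

    frame_s: float
    counts: np.ndarray
    trace_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.frame_s <= 0:
            raise ValueError("frame interval must be > 0")
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise ValueError("trace must be a non-empty 1-D array")

    def __len__(self) -> int:
        return int(self.counts.size)

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self)) * self.frame_s

    def rescaled(self) -> np.ndarray:
        """I_Cy3* — photon counts divided by 1000 (exact)."""
        return self.counts / 1000.0


@dataclass
class AlexTrace:
    """ALEX trace: aligned I_DD, I_DA, I_AA streams (counts/frame).

    ``frame_s`` is the interval between consecutive donor-excitation frames,
    i.e. one full ALEX period.
    """

    frame_s: float
    i_dd: np.ndarray
    i_da: np.ndarray
    i_aa: np.ndarray
    trace_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.i_dd = np.asarray(self.i_dd, dtype=float)
        self.i_da = np.asarray(self.i_da, dtype=float)
        self.i_aa = np.asarray(self.i_aa, dtype=float)
        if self.frame_s <= 0:
            raise ValueError("frame interval must be > 0")
        if not (self.i_dd.shape == self.i_da.shape == self.i_aa.shape):
            raise ValueError("I_DD, I_DA, I_AA must have equal length")
        if self.i_dd.ndim != 1 or self.i_dd.size < 1:
            raise ValueError("trace must be non-empty")

    def __len__(self) -> int:
        return int(self.i_dd.size)

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self)) * self.frame_s

    def truncated(self, n_frames: int) -> "AlexTrace":
        return AlexTrace(
            self.frame_s,
            self.i_dd[:n_frames].copy(),
            self.i_da[:n_frames].copy(),
            self.i_aa[:n_frames].copy(),
            trace_id=self.trace_id,
            meta=dict(self.meta),
        )


def write_trace(trace: IntensityTrace | AlexTrace, path: str | Path) -> None:
    """Write a trace as TSV: (time_s, i_cy3) or (time_s, i_dd, i_da, i_aa)."""
    if isinstance(trace, AlexTrace):
        df = pd.DataFrame(
            {
                "time_s": trace.time_s,
                "i_dd": trace.i_dd,
                "i_da": trace.i_da,
                "i_aa": trace.i_aa,
            }
        )
    else:
        df = pd.DataFrame({"time_s": trace.time_s, "i_cy3": trace.counts})
    df.to_csv(path, sep="\t", index=False)


def read_trace(path: str | Path) -> IntensityTrace | AlexTrace:
    """Read a TSV trace written by :func:`write_trace`; flavour from columns."""
    df = pd.read_csv(path, sep="\t")
    t = df["time_s"].to_numpy()
    frame_s = float(t[1] - t[0]) if len(t) > 1 else 1.0
    trace_id = Path(path).stem
    if "i_cy3" in df.columns:
        return IntensityTrace(frame_s, df["i_cy3"].to_numpy(), trace_id=trace_id)
    return AlexTrace(
        frame_s,
        df["i_dd"].to_numpy(),
        df["i_da"].to_numpy(),
        df["i_aa"].to_numpy(),
        trace_id=trace_id,
    )
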