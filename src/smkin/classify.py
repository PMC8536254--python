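"""Trajectory-shape classification and initial-binding E*.

State-labelled trajectories are sorted into the observational classes used
for real-time binding data:

UIFE (states sorted 0 = dark, 1 = low ~200 counts, 2 = high ~450 counts):
  I    appears low and stays low until disappearance (no unwinding seen);
  II   appears low, later steps to high (unwinding observed);
  III  appears already high, steps down to low (unwinding missed);
  other  anything else.

FRET (states sorted by E*; closed ~0.40, locked ~0.48):
  I    starts closed, no transition;
  II   starts closed, transitions to locked;
  III  starts locked, transitions to closed;
  IV   starts closed with transient excursions toward the open-clamp range
       (E* < 0.30);
  other  anything else.

Classification depends only on the state-label sequence (plus, for Class IV,
raw-E* excursions); a transition must persist for at least 2 frames to
count, suppressing single-frame idealization flicker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hmm import HmmModel

__all__ = ["TraceClass", "classify_uife", "classify_fret", "initial_estar", "class_table"]

MIN_DWELL_FRAMES = 2
OPEN_ESTAR_THRESHOLD = 0.30
OPEN_MIN_FRAMES = 3


@dataclass
class TraceClass:
    label: str
    first_transition_frame: int | None = None
    dwell_s: float | None = None  # binding -> first low->high transition (Class II)
    binding_frame: int | None = None
    end_frame: int | None = None  # frame after the last emitting frame
    trace_id: str = ""


def _runs(path: np.ndarray) -> list[tuple[int, int, int]]:
    """Collapse a state path into (state, start, length) runs."""
    path = np.asarray(path)
    changes = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], changes])
    ends = np.concatenate([changes, [path.size]])
    return [(int(path[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def _collapse_flicker(runs, min_frames: int):
    """Drop runs shorter than min_frames and merge equal neighbours."""
    kept = [r for r in runs if r[2] >= min_frames]
    merged: list[tuple[int, int, int]] = []
    for state, start, length in kept:
        if merged and merged[-1][0] == state:
            s0, st0, ln0 = merged[-1]
            merged[-1] = (s0, st0, start + length - st0)
        else:
            merged.append((state, start, length))
    return merged


def classify_uife(
    path: np.ndarray,
    model: HmmModel,
    frame_s: float,
    trace_id: str = "",
    min_dwell_frames: int = MIN_DWELL_FRAMES,
) -> TraceClass:
    """Classify one UIFE state path (3-state model: dark/low/high)."""
    if model.n_states != 3:
        raise ValueError("UIFE classification expects a 3-state model")
    dark, low, high = 0, 1, 2
    runs = _collapse_flicker(_runs(path), min_dwell_frames)
    emit = [(s, st, ln) for s, st, ln in runs if s != dark]
    if not emit:
        return TraceClass("other", trace_id=trace_id)
    binding = emit[0][1]
    end = emit[-1][1] + emit[-1][2]
    seq = [s for s, _, _ in _collapse_flicker(emit, 1)]  # merge across dark gaps
    first_high = next((st for s, st, _ in emit if s == high), None)
    if seq == [low]:
        return TraceClass("I", binding_frame=binding, end_frame=end, trace_id=trace_id)
    if seq[0] == low and high in seq[1:]:
        dwell = (first_high - binding) * frame_s
        return TraceClass(
            "II",
            first_transition_frame=first_high,
            dwell_s=dwell,
            binding_frame=binding,
            end_frame=end,
            trace_id=trace_id,
        )
    if seq[0] == high and low in seq[1:]:
        first_low = next(st for s, st, _ in emit if s == low)
        return TraceClass(
            "III",
            first_transition_frame=first_low,
            binding_frame=binding,
            end_frame=end,
            trace_id=trace_id,
        )
    return TraceClass("other", binding_frame=binding, end_frame=end, trace_id=trace_id)


def classify_fret(
    path: np.ndarray,
    model: HmmModel,
    frame_s: float,
    estar: np.ndarray | None = None,
    trace_id: str = "",
    min_dwell_frames: int = MIN_DWELL_FRAMES,
    open_threshold: float = OPEN_ESTAR_THRESHOLD,
) -> TraceClass:
    """Classify one FRET E* state path (2-state model: closed/locked).

    ``path`` must cover the emitting (post-binding, pre-bleach) portion of
    the trace only.  Open-clamp excursions (Class IV) are detected on the
    raw E* values: at least ``OPEN_MIN_FRAMES`` consecutive frames below
    ``open_threshold``.
    """
    closed, locked = 0, model.n_states - 1
    runs = _collapse_flicker(_runs(path), min_dwell_frames)
    if not runs:
        return TraceClass("other", trace_id=trace_id)
    binding = runs[0][1]
    end = runs[-1][1] + runs[-1][2]
    seq = [s for s, _, _ in runs]

    excursion = False
    if estar is not None:
        below = np.isfinite(estar) & (np.asarray(estar, float) < open_threshold)
        run = 0
        for b in below:
            run = run + 1 if b else 0
            if run >= OPEN_MIN_FRAMES:
                excursion = True
                break

    if seq[0] == closed and excursion:
        return TraceClass("IV", binding_frame=binding, end_frame=end, trace_id=trace_id)
    if seq == [closed]:
        return TraceClass("I", binding_frame=binding, end_frame=end, trace_id=trace_id)
    if seq[0] == closed and locked in seq[1:]:
        first_locked = next(st for s, st, _ in runs if s == locked)
        return TraceClass(
            "II",
            first_transition_frame=first_locked,
            dwell_s=(first_locked - binding) * frame_s,
            binding_frame=binding,
            end_frame=end,
            trace_id=trace_id,
        )
    if seq[0] == locked and closed in seq[1:]:
        first_closed = next(st for s, st, _ in runs if s == closed)
        return TraceClass(
            "III",
            first_transition_frame=first_closed,
            binding_frame=binding,
            end_frame=end,
            trace_id=trace_id,
        )
    return TraceClass("other", binding_frame=binding, end_frame=end, trace_id=trace_id)


def initial_estar(estar: np.ndarray, window_frames: int = 5) -> float:
    """Mean E* over the first frames after binding (default five frames).

    ``estar`` must start at the binding frame.  Returns NaN (caller excludes)
    if the trace is shorter than the window or has no defined frame in it.
    """
    estar = np.asarray(estar, dtype=float)
    if estar.size < window_frames:
        return float("nan")
    head = estar[:window_frames]
    head = head[np.isfinite(head)]
    return float(head.mean()) if head.size else float("nan")


def class_table(classes: list[TraceClass]) -> pd.DataFrame:
    """Classification results as a CSV-ready table."""
    return pd.DataFrame(
        {
            "trace_id": [c.trace_id for c in classes],
            "class": [c.label for c in classes],
            "first_transition_frame": [c.first_transition_frame for c in classes],
            "dwell_s": [c.dwell_s for c in classes],
        }
    )
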