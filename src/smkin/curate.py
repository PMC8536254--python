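"""Trajectory curation: inclusion rules and photophysics filters.

Before state inference, trajectories are screened the way real-time
single-molecule binding data are screened:

* UIFE (single Cy3 channel): exclude traces that are too bright upon binding
  (aggregates / multiple fluorophores, > 750 counts), traces with multiple
  distinct binding events in the observation window, and traces showing
  photoblinking.
* ALEX FRET: exclude traces whose donor-excited or acceptor-excited
  intensities fall outside the single-fluorophore ranges (median I_DD outside
  100-1000 counts or median I_AA outside 200-1000 counts), traces showing
  multiple-step donor or acceptor photobleaching or blinking, and truncate
  kept traces at the first donor/acceptor bleach.

Step detection for the FRET filters operates on the kinetics-independent
streams — total donor-excited emission I_DD + I_DA and direct acceptor
emission I_AA — so FRET state transitions are invisible to it and only
photophysics is counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import medfilt

from .traces import AlexTrace, IntensityTrace

__all__ = [
    "CurationConfig",
    "CurationVerdict",
    "detect_bleach_step",
    "detect_blinking",
    "curate_uife",
    "curate_fret",
    "verdict_table",
]


@dataclass
class CurationConfig:
    """Thresholds for curation; defaults follow the assay's published rules."""

    background: float = 0.0
    noise_sd: float | None = 25.0  # None -> robust estimate from the trace
    max_binding_counts: float = 750.0
    idd_range: tuple[float, float] = (100.0, 1000.0)
    iaa_range: tuple[float, float] = (200.0, 1000.0)
    binding_window_frames: int = 5  # frames defining "intensity upon binding"
    min_gap_frames: int = 3  # background frames separating binding events
    min_blink_frames: int = 2


@dataclass
class CurationVerdict:
    trace_id: str
    keep: bool
    reason: str | None = None  # primary reason when excluded
    truncation_frame: int | None = None
    binding_frame: int | None = None
    binding_intensity: float | None = None


def estimate_noise_sd(values: np.ndarray) -> float:
    """Robust per-frame noise sd from scaled median absolute first difference."""
    d = np.diff(np.asarray(values, dtype=float))
    return float(1.4826 * np.median(np.abs(d)) / np.sqrt(2.0)) if d.size else 0.0


def _noise_sd(values: np.ndarray, config: CurationConfig) -> float:
    sd = config.noise_sd if config.noise_sd is not None else estimate_noise_sd(values)
    return max(float(sd), 1.0)


def _smooth(values: np.ndarray) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return medfilt(v, 3) if v.size >= 3 else v.copy()


def _plateaus(values: np.ndarray, sd: float, min_frames: int = 3) -> list[tuple[int, float]]:
    """Segment a (smoothed) stream into plateaus: (start_frame, level) pairs.

    A new plateau opens when the value departs from the running plateau level
    by more than 4 sd for at least ``min_frames`` consecutive frames.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return []
    out = [(0, v[0])]
    level = v[0]
    n_level = 1
    run_start = None
    for i in range(1, v.size):
        if abs(v[i] - level) > 4.0 * sd:
            if run_start is None:
                run_start = i
            if i - run_start + 1 >= min_frames or i == v.size - 1:
                level = float(np.mean(v[run_start : i + 1]))
                out.append((run_start, level))
                n_level = i - run_start + 1
                run_start = None
        else:
            run_start = None
            level = (level * n_level + v[i]) / (n_level + 1)
            n_level += 1
            out[-1] = (out[-1][0], level)
    return out


def detect_bleach_step(
    trace: IntensityTrace | np.ndarray,
    config: CurationConfig | None = None,
) -> tuple[int | None, int]:
    """Locate the terminal photobleaching step and count discrete drops.

    Returns ``(bleach_frame, n_steps)``: the first frame of the final
    background plateau that persists to the trace end (``None`` if the trace
    ends emitting), and the number of persistent downward steps in the final
    monotone descent to background (1 = clean single-step bleach).
    """
    config = config or CurationConfig()
    values = trace.counts if isinstance(trace, IntensityTrace) else np.asarray(trace, float)
    if values.size < 5:
        raise ValueError("trace too short for bleach detection")
    sd = _noise_sd(values, config)
    sm = _smooth(values)
    plats = _plateaus(sm, sd)
    bg_band = config.background + 3.0 * sd
    if not plats or plats[-1][1] > bg_band:
        return None, 0
    # drop short interior plateaus: partial-occupancy frames at a transition
    # edge masquerade as intermediate levels for 1-3 frames, whereas a real
    # intermediate bleach level persists; first and last plateaus always count
    starts = [s for s, _ in plats] + [values.size]
    lengths = np.diff(starts)
    core = [
        p
        for j, p in enumerate(plats)
        if j in (0, len(plats) - 1) or lengths[j] >= 4
    ]
    merged: list[tuple[int, float]] = []
    for start, level in core:  # re-merge adjacent plateaus at the same level
        if merged and abs(level - merged[-1][1]) <= 4.0 * sd:
            continue
        merged.append((start, level))
    bleach_frame = merged[-1][0]
    n_steps = 0
    for j in range(len(merged) - 1, 0, -1):
        prev, cur = merged[j - 1][1], merged[j][1]
        if prev > cur + 4.0 * sd:
            n_steps += 1
        else:
            break
    return int(bleach_frame), n_steps


def _episodes(emitting: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as [start, end) pairs."""
    idx = np.flatnonzero(emitting)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[splits + 1]])
    ends = np.concatenate([idx[splits] + 1, [idx[-1] + 1]])
    return list(zip(starts.astype(int), ends.astype(int)))


def _gap_events(values: np.ndarray, sd: float, config: CurationConfig):
    """Background gaps between emitting episodes, with pre/post levels.

    Returns a list of (gap_start, gap_end, pre_level, post_level).
    """
    sm = _smooth(values)
    emitting = sm > config.background + 3.0 * sd
    eps = _episodes(emitting)
    events = []
    for (s0, e0), (s1, _) in zip(eps[:-1], eps[1:]):
        pre = float(np.median(values[max(e0 - 5, s0) : e0]))
        post = float(np.median(values[s1 : s1 + 5]))
        events.append((int(e0), int(s1), pre, post))
    return events


def detect_blinking(
    trace: IntensityTrace | np.ndarray,
    config: CurationConfig | None = None,
) -> list[tuple[int, int]]:
    """Detect blink intervals: drops to background that recover to the prior
    emitting level.  Returns [start, end) frame intervals."""
    config = config or CurationConfig()
    values = trace.counts if isinstance(trace, IntensityTrace) else np.asarray(trace, float)
    if values.size < 5:
        raise ValueError("trace too short for blink detection")
    sd = _noise_sd(values, config)
    blinks = []
    for g0, g1, pre, post in _gap_events(values, sd, config):
        if g1 - g0 < config.min_blink_frames:
            continue
        if abs(post - pre) <= max(4.0 * sd, 0.25 * abs(pre)):  # same level => blink
            blinks.append((g0, g1))
    return blinks


def curate_uife(
    trace: IntensityTrace, config: CurationConfig | None = None
) -> CurationVerdict:
    """Apply the UIFE inclusion rules to one background-corrected trace."""
    config = config or CurationConfig()
    values = trace.counts
    sd = _noise_sd(values, config)
    sm = _smooth(values)
    emitting = sm > config.background + 3.0 * sd
    eps = _episodes(emitting)
    tid = trace.trace_id
    if not eps:
        return CurationVerdict(tid, False, "no-signal")
    b0 = eps[0][0]
    binding_int = float(np.mean(values[b0 : b0 + config.binding_window_frames]))
    if binding_int > config.max_binding_counts:
        return CurationVerdict(tid, False, "too-bright", binding_frame=b0, binding_intensity=binding_int)
    gaps = _gap_events(values, sd, config)
    for g0, g1, pre, post in gaps:
        same_level = abs(post - pre) <= max(4.0 * sd, 0.25 * abs(pre))
        if not same_level and g1 - g0 >= config.min_gap_frames:
            return CurationVerdict(tid, False, "multi-binding", binding_frame=b0, binding_intensity=binding_int)
    if detect_blinking(trace, config):
        return CurationVerdict(tid, False, "blinking", binding_frame=b0, binding_intensity=binding_int)
    return CurationVerdict(tid, True, binding_frame=b0, binding_intensity=binding_int)


def curate_fret(
    trace: AlexTrace, config: CurationConfig | None = None
) -> CurationVerdict:
    """Apply the ALEX-FRET inclusion rules; kept traces carry a truncation
    frame at the first donor or acceptor bleach."""
    config = config or CurationConfig()
    d_total = trace.i_dd + trace.i_da
    i_aa = trace.i_aa
    tid = trace.trace_id
    sd_d = _noise_sd(d_total, config)
    emitting = _smooth(d_total) > config.background + 3.0 * sd_d
    if not emitting.any():
        return CurationVerdict(tid, False, "no-signal")
    b0 = _episodes(emitting)[0][0]

    donor_bleach, donor_steps = detect_bleach_step(d_total, config)
    acc_bleach, acc_steps = detect_bleach_step(i_aa, config)
    if donor_steps > 1 or acc_steps > 1:
        return CurationVerdict(tid, False, "multi-step-bleach", binding_frame=b0)

    cut_candidates = [c for c in (donor_bleach, acc_bleach) if c is not None]
    cut = min(cut_candidates) if cut_candidates else None
    end = cut if cut is not None else len(trace)
    if end - b0 < 5:  # too short between binding and bleach to analyse
        return CurationVerdict(tid, False, "no-signal", binding_frame=b0)

    sel = slice(b0, end)
    emit_sel = emitting[sel]
    if emit_sel.any():
        med_idd = float(np.median(trace.i_dd[sel][emit_sel]))
        med_iaa = float(np.median(i_aa[sel][emit_sel]))
        lo, hi = config.idd_range
        if not lo <= med_idd <= hi:
            return CurationVerdict(tid, False, "out-of-range", binding_frame=b0)
        lo, hi = config.iaa_range
        if not lo <= med_iaa <= hi:
            return CurationVerdict(tid, False, "out-of-range", binding_frame=b0)

    if end >= 5 and (detect_blinking(d_total[:end], config) or detect_blinking(i_aa[:end], config)):
        return CurationVerdict(tid, False, "blinking", binding_frame=b0)

    reason = "truncated-at-bleach" if cut is not None else None
    return CurationVerdict(tid, True, reason=reason, truncation_frame=cut, binding_frame=b0)


def verdict_table(verdicts: list[CurationVerdict]) -> pd.DataFrame:
    """Verdicts as a CSV-ready table: trace_id, keep, reason, truncation_frame."""
    return pd.DataFrame(
        {
            "trace_id": [v.trace_id for v in verdicts],
            "keep": [v.keep for v in verdicts],
            "reason": [v.reason for v in verdicts],
            "truncation_frame": [v.truncation_frame for v in verdicts],
        }
    )
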