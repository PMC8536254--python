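"""Spot detection, 2-D Gaussian fitting, and trace extraction from movies.

Implements the standard TIRF single-molecule workflow: find candidate
emitters as local maxima above the background noise floor, refine each with
a nonlinear least-squares fit of a 2-D Gaussian plus constant background,
and integrate a background-corrected intensity-vs-time trajectory at each
localization.  ALEX movies are de-interleaved into donor- and
acceptor-excitation streams before trace extraction.

Pixel convention: pixel centres at integer coordinates, origin (0, 0) at the
top-left pixel; sub-pixel centroids are continuous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from skimage.feature import peak_local_max

from .traces import AlexTrace, IntensityTrace

__all__ = [
    "SpotFit",
    "detect_spots",
    "fit_spot",
    "extract_trace",
    "deinterleave_alex",
    "interleave_alex",
]

FIT_WINDOW = 9  # px, square window for the Gaussian fit
BG_ANNULUS = (5.5, 7.5)  # px, inner/outer radius of the background annulus
SPOT_RADIUS = 4.5  # px, integration disk (>= 99% enclosed flux at sigma 1.3)


@dataclass
class SpotFit:
    """Result of a 2-D Gaussian + background fit around one candidate spot."""

    x: float
    y: float
    amplitude: float
    sigma: float
    background: float
    residual: float
    converged: bool

    @property
    def flux(self) -> float:
        """Integrated counts above background, amplitude * 2 pi sigma^2."""
        return float(self.amplitude * 2.0 * np.pi * self.sigma**2)


def detect_spots(
    frame: np.ndarray,
    threshold_sd: float = 5.0,
    border_margin_px: int = 5,
    min_separation_px: int = 3,
) -> np.ndarray:
    """Detect candidate emitters as local maxima above background + k*sd.

    Background level and noise sd are estimated robustly (median and scaled
    MAD) from the whole frame; positions within ``border_margin_px`` of any
    edge are excluded.  Returns an (n, 2) array of (x, y) pixel positions.
    """
    frame = np.asarray(frame, dtype=float)
    if min(frame.shape) < 2 * border_margin_px:
        raise ValueError("frame smaller than twice the border margin")
    bg = float(np.median(frame))
    sd = 1.4826 * float(np.median(np.abs(frame - bg)))
    if sd == 0.0:
        sd = max(frame.std(), 1e-12)
    peaks = peak_local_max(
        frame,
        min_distance=min_separation_px,
        threshold_abs=bg + threshold_sd * sd,
        exclude_border=border_margin_px,
    )
    if peaks.size == 0:
        return np.empty((0, 2))
    # sub-pixel refinement: background-subtracted centre of mass in a 3x3 patch
    out = []
    for r, c in peaks:
        patch = np.maximum(frame[r - 1 : r + 2, c - 1 : c + 2] - bg, 0.0)
        total = patch.sum()
        if total > 0:
            dy, dx = np.mgrid[-1:2, -1:2]
            out.append((c + (patch * dx).sum() / total, r + (patch * dy).sum() / total))
        else:
            out.append((float(c), float(r)))
    return np.asarray(out, dtype=float)


def _gauss2d(coords, amp, x0, y0, sigma, bg):
    x, y = coords
    return amp * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2.0 * sigma**2)) + bg


def fit_spot(frame: np.ndarray, seed_xy: tuple[float, float], window: int = FIT_WINDOW) -> SpotFit:
    """Least-squares fit of a symmetric 2-D Gaussian in a window around a seed.

    Non-convergent or degenerate fits are returned flagged
    (``converged=False``) so callers can exclude them.
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    cx, cy = int(round(seed_xy[0])), int(round(seed_xy[1]))
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError("seed position outside frame")
    half = window // 2
    x0, x1 = max(cx - half, 0), min(cx + half + 1, w)
    y0, y1 = max(cy - half, 0), min(cy + half + 1, h)
    sub = frame[y0:y1, x0:x1]
    ys, xs = np.mgrid[y0:y1, x0:x1]
    bg0 = float(sub.min())
    amp0 = float(sub.max() - bg0)
    p0 = (max(amp0, 1e-6), float(cx), float(cy), 1.3, bg0)
    try:
        popt, _ = optimize.curve_fit(
            _gauss2d,
            (xs.ravel(), ys.ravel()),
            sub.ravel(),
            p0=p0,
            bounds=(
                [0.0, x0 - 1, y0 - 1, 0.3, -np.inf],
                [np.inf, x1, y1, window, np.inf],
            ),
            maxfev=2000,
        )
        amp, xf, yf, sigma, bg = popt
        model = _gauss2d((xs.ravel(), ys.ravel()), *popt)
        residual = float(np.sqrt(np.mean((model - sub.ravel()) ** 2)))
        converged = amp > max(3.0 * residual, 1e-6 * (abs(bg) + 1.0))
        return SpotFit(float(xf), float(yf), float(amp), float(sigma), float(bg), residual, bool(converged))
    except RuntimeError:
        return SpotFit(float(cx), float(cy), 0.0, 1.0, bg0, float("inf"), False)


def _disk_and_annulus(shape, x, y):
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    r = np.sqrt((xs - x) ** 2 + (ys - y) ** 2)
    return r <= SPOT_RADIUS, (r >= BG_ANNULUS[0]) & (r <= BG_ANNULUS[1])


def extract_trace(
    movie: np.ndarray, position: tuple[float, float], frame_s: float = 0.05
) -> IntensityTrace:
    """Integrate a background-corrected intensity trajectory at one position.

    Per frame: sum of counts in a disk of radius 3 px minus the annulus
    (4-6 px) median background scaled to the disk area.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3:
        raise ValueError("movie must be a (T, H, W) stack")
    x, y = position
    h, w = movie.shape[1:]
    if not (0 <= x < w and 0 <= y < h):
        raise ValueError("position outside the movie frame")
    disk, annulus = _disk_and_annulus((h, w), x, y)
    n_disk = int(disk.sum())
    spot = movie[:, disk].sum(axis=1)
    bg = np.median(movie[:, annulus], axis=1)
    return IntensityTrace(frame_s, spot - bg * n_disk)


def deinterleave_alex(
    donor_channel: np.ndarray,
    acceptor_channel: np.ndarray,
    frame_s: float,
    donor_first: bool = True,
) -> AlexTrace:
    """Split raw alternating-excitation streams into I_DD, I_DA, I_AA.

    ``donor_channel`` / ``acceptor_channel`` are per-frame intensities from
    the two emission channels over the raw interleaved movie.  Donor-
    excitation frames contribute I_DD (donor emission) and I_DA (acceptor
    emission); acceptor-excitation frames contribute I_AA.  ``frame_s`` is
    the raw camera frame time; the output streams are sampled once per ALEX
    period (2 raw frames).  An odd trailing frame is dropped with a warning.
    """
    donor_channel = np.asarray(donor_channel, dtype=float)
    acceptor_channel = np.asarray(acceptor_channel, dtype=float)
    if donor_channel.shape != acceptor_channel.shape or donor_channel.ndim != 1:
        raise ValueError("channel streams must be equal-length 1-D arrays")
    n = donor_channel.size
    if n % 2:
        warnings.warn("odd frame count: dropping trailing frame", stacklevel=2)
        n -= 1
    d_slice = slice(0, n, 2) if donor_first else slice(1, n, 2)
    a_slice = slice(1, n, 2) if donor_first else slice(0, n, 2)
    return AlexTrace(
        2.0 * frame_s,
        i_dd=donor_channel[d_slice].copy(),
        i_da=acceptor_channel[d_slice].copy(),
        i_aa=acceptor_channel[a_slice].copy(),
    )


def interleave_alex(trace: AlexTrace, donor_first: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`deinterleave_alex` (donor-excitation donor emission
    assumed zero-filled on acceptor-excitation frames and vice versa)."""
    n = len(trace)
    donor = np.zeros(2 * n)
    acceptor = np.zeros(2 * n)
    d = slice(0, 2 * n, 2) if donor_first else slice(1, 2 * n, 2)
    a = slice(1, 2 * n, 2) if donor_first else slice(0, 2 * n, 2)
    donor[d] = trace.i_dd
    acceptor[d] = trace.i_da
    acceptor[a] = trace.i_aa
    return donor, acceptor
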