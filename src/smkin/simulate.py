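"""Synthetic single-molecule trajectory and movie generator.

Generates ground-truth-labelled trajectories with the kinetic structure of
real-time promoter-unwinding experiments: a molecule binds, traverses ``m``
sequential exponential sub-steps in a low-signal state (closed transcription
bubble / closed RNAP clamp), switches to a high-signal state (unwound bubble
/ locked clamp), may revert, and eventually photobleaches.  The waiting time
from binding to the switch is therefore a convolution of exponentials, which
for m = 2 gives the peaked dwell distribution
``f(x) = (exp(-x/t1) - exp(-x/t2)) / (t1 - t2)``.

Two read-outs are rendered from the same hidden path:

* UIFE — a single Cy3 intensity that roughly doubles upon local unwinding
  (default levels 200 -> 450 counts/frame);
* ALEX smFRET — donor/acceptor streams encoding an apparent FRET efficiency
  E* that steps from ~0.40 (closed clamp) to ~0.48 (locked clamp).

Ensembles are mixtures of *observational* trajectory classes (the shape
taxonomy used to sort real trajectories); each trace is rejection-sampled
until its realized path actually exhibits the requested shape, so mixture
proportions are exact class proportions by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special

from .traces import AlexTrace, IntensityTrace

__all__ = [
    "KineticScheme",
    "SimulationConfig",
    "SimulatedTrace",
    "sample_state_path",
    "render_uife_trace",
    "render_fret_trace",
    "simulate_ensemble",
    "render_movie",
]

# canonical state labels
ABSENT = "absent"
BLEACHED = "bleached"
ENHANCED = "enhanced"  # unwound bubble / locked clamp
REWOUND = "rewound"  # returned to the low state after enhancement
OPEN = "open"  # transient low-E* (open-clamp) excursion, FRET only


def _bound(i: int) -> str:
    return f"bound{i + 1}"


@dataclass
class KineticScheme:
    """Generative state model for one experimental condition.

    Parameters
    ----------
    sub_step_lifetimes_s
        Mean lifetimes of the sequential pre-transition sub-steps (seconds),
        traversed strictly in order.  The mean binding->enhancement dwell is
        their sum.
    enhanced_lifetime_s
        Mean time in the enhanced (unwound/locked) state before reverting.
    rewound_lifetime_s
        Mean time in the reverted low state before re-enhancement
        (``inf`` = reverted state persists until bleaching).
    bleach_lifetime_s
        Mean time to irreversible photobleaching; bleaching competes with
        every kinetic transition from every emitting state.
    blink_on_rate, blink_off_rate
        Optional reversible dark-state kinetics (1/s); 0 disables blinking.
    uife_levels
        Emission level per state in photon counts/frame for the UIFE channel.
    estar
        Apparent FRET efficiency per state (FRET channel).
    donor_total_counts
        Total donor-excited emission I_DD + I_DA per frame (FRET).
    acceptor_level_counts
        Direct-excitation acceptor emission I_AA per frame (FRET).
    excursion_interval_s, open_lifetime_s
        Mean closed-state time between open-clamp excursions and mean
        excursion duration (used only for excursion-class trajectories).
    """

    sub_step_lifetimes_s: tuple[float, ...] = (3.0, 4.5)
    enhanced_lifetime_s: float = 20.0
    rewound_lifetime_s: float = float("inf")
    bleach_lifetime_s: float = 100.0
    blink_on_rate: float = 0.0
    blink_off_rate: float = 5.0
    uife_levels: dict = field(
        default_factory=lambda: {ENHANCED: 450.0, REWOUND: 200.0, "bound": 200.0}
    )
    estar: dict = field(
        default_factory=lambda: {
            "bound": 0.40,
            ENHANCED: 0.48,
            REWOUND: 0.40,
            OPEN: 0.20,
        }
    )
    donor_total_counts: float = 500.0
    acceptor_level_counts: float = 600.0
    excursion_interval_s: float = 8.0
    open_lifetime_s: float = 0.6

    def __post_init__(self) -> None:
        if len(self.sub_step_lifetimes_s) < 1:
            raise ValueError("need at least one sub-step")
        lifetimes = (
            *self.sub_step_lifetimes_s,
            self.enhanced_lifetime_s,
            self.rewound_lifetime_s,
            self.bleach_lifetime_s,
            self.excursion_interval_s,
            self.open_lifetime_s,
        )
        if any(not t > 0 for t in lifetimes):
            raise ValueError("all lifetimes must be > 0")
        for e in self.estar.values():
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"E* must lie in [0, 1], got {e}")
        for lv in self.uife_levels.values():
            if lv < 0:
                raise ValueError("emission levels must be >= 0")

    @property
    def n_sub_steps(self) -> int:
        return len(self.sub_step_lifetimes_s)

    def uife_level(self, state: str) -> float:
        if state in (ABSENT, BLEACHED, "blink"):
            return 0.0
        if state.startswith("bound"):
            return float(self.uife_levels.get(state, self.uife_levels["bound"]))
        return float(self.uife_levels[state])

    def estar_of(self, state: str) -> float:
        if state.startswith("bound"):
            return float(self.estar.get(state, self.estar["bound"]))
        return float(self.estar[state])


@dataclass
class SimulationConfig:
    """Rendering and ensemble parameters.

    Noise model: optional Poisson shot noise on the noiseless photon counts,
    plus additive Gaussian read noise (``read_noise_sd`` counts).  For FRET,
    noise is applied to the proximity ratio itself (``estar_noise_sd``) so
    the per-frame E* scatter is controlled directly; ``count_noise_sd`` adds
    optional Gaussian noise to the raw streams on top.
    """

    frame_s: float = 0.05
    duration_s: float = 60.0
    background: float = 0.0
    shot_noise: bool = True
    read_noise_sd: float = 25.0
    estar_noise_sd: float = 0.04
    count_noise_sd: float = 0.0
    n_traces: int = 300
    proportions: dict = field(default_factory=lambda: {"II": 1.0})
    binding_time_range: tuple[float, float] = (0.0, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_s <= 0 or self.duration_s <= 0:
            raise ValueError("frame interval and duration must be > 0")
        props = np.array(list(self.proportions.values()), dtype=float)
        if props.size and (np.any(props < 0) or not np.isclose(props.sum(), 1.0)):
            raise ValueError("class proportions must be >= 0 and sum to 1")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s / self.frame_s))


# ---------------------------------------------------------------------------
# state-path sampling
# ---------------------------------------------------------------------------


def _exp(rng: np.random.Generator, mean: float) -> float:
    if np.isinf(mean):
        return float("inf")
    return float(rng.exponential(mean))


def sample_state_path(
    scheme: KineticScheme,
    duration_s: float,
    rng: np.random.Generator,
    start_state: str | None = None,
    binding_time_s: float = 0.0,
) -> list[tuple[str, float]]:
    """Sample one continuous-time hidden path as (state, entry_time) pairs.

    The molecule is absent until ``binding_time_s``, then enters
    ``start_state`` (first bound sub-step by default) and progresses
    bound1 -> ... -> boundm -> enhanced -> rewound -> enhanced -> ...,
    with photobleaching competing at rate ``1/bleach_lifetime_s`` from every
    emitting state.  The path ends at ``duration_s`` or on entering the
    absorbing bleached state, whichever is first.
    """
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    if start_state is None:
        start_state = _bound(0)

    order = [_bound(i) for i in range(scheme.n_sub_steps)] + [ENHANCED, REWOUND]
    means = {
        **{_bound(i): scheme.sub_step_lifetimes_s[i] for i in range(scheme.n_sub_steps)},
        ENHANCED: scheme.enhanced_lifetime_s,
        REWOUND: scheme.rewound_lifetime_s,
    }

    def successor(state: str) -> str:
        if state == REWOUND:
            return ENHANCED  # re-enhancement; alternates thereafter
        i = order.index(state)
        return order[i + 1]

    path: list[tuple[str, float]] = []
    t = 0.0
    if binding_time_s > 0:
        path.append((ABSENT, 0.0))
        t = binding_time_s
    if t >= duration_s:
        return path or [(ABSENT, 0.0)]

    state = start_state
    bleach_rate = 1.0 / scheme.bleach_lifetime_s
    while t < duration_s:
        path.append((state, t))
        if state == BLEACHED:
            break
        mean = means[state]
        kin_rate = 0.0 if np.isinf(mean) else 1.0 / mean
        total = kin_rate + bleach_rate
        if total == 0.0:
            break  # absorbing emitting state: persists to the end
        t += _exp(rng, 1.0 / total)
        if t >= duration_s:
            break
        if rng.random() < bleach_rate / total:
            state = BLEACHED
        else:
            state = successor(state)
    return path


def _overlay_blinks(
    path: list[tuple[str, float]],
    scheme: KineticScheme,
    duration_s: float,
    rng: np.random.Generator,
) -> tuple[list[tuple[str, float]], list[tuple[float, float]]]:
    """Insert reversible dark ('blink') intervals into the emitting segments."""
    if scheme.blink_on_rate <= 0:
        return path, []
    # segment boundaries
    bounds = [t for _, t in path] + [duration_s]
    out: list[tuple[str, float]] = []
    blinks: list[tuple[float, float]] = []
    for (state, t0), t1 in zip(path, bounds[1:]):
        if state in (ABSENT, BLEACHED):
            out.append((state, t0))
            continue
        t = t0
        while t < t1:
            on = min(t + _exp(rng, 1.0 / scheme.blink_on_rate), t1)
            if on > t:
                out.append((state, t))
            if on >= t1:
                break
            off = min(on + _exp(rng, 1.0 / scheme.blink_off_rate), t1)
            out.append(("blink", on))
            blinks.append((on, off))
            t = off
    return out, blinks


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _frame_occupancy(
    path: list[tuple[str, float]], n_frames: int, frame_s: float
) -> tuple[np.ndarray, list[str]]:
    """Per-frame occupancy fractions (n_frames, n_segments) for each path segment."""
    starts = np.array([t for _, t in path])
    ends = np.append(starts[1:], n_frames * frame_s)
    states = [s for s, _ in path]
    edges = np.arange(n_frames + 1) * frame_s
    occ = np.zeros((n_frames, len(path)))
    for j, (a, b) in enumerate(zip(starts, ends)):
        lo = np.clip(edges[:-1], a, b)
        hi = np.clip(edges[1:], a, b)
        occ[:, j] = np.maximum(hi - lo, 0.0) / frame_s
    return occ, states


def render_uife_trace(
    path: list[tuple[str, float]],
    config: SimulationConfig,
    scheme: KineticScheme,
    rng: np.random.Generator | None = None,
    noiseless: bool = False,
) -> IntensityTrace:
    """Render a hidden path into a Cy3 intensity trace.

    Each frame's noiseless value is the occupancy-time-weighted mean of the
    state emission levels within the frame, plus background; Poisson shot
    noise and Gaussian read noise are then applied per the config.
    """
    n = config.n_frames
    occ, states = _frame_occupancy(path, n, config.frame_s)
    levels = np.array([scheme.uife_level(s) for s in states])
    clean = occ @ levels + config.background
    if noiseless or rng is None:
        counts = clean
    else:
        counts = rng.poisson(np.maximum(clean, 0.0)).astype(float) if config.shot_noise else clean.copy()
        if config.read_noise_sd > 0:
            counts = counts + rng.normal(0.0, config.read_noise_sd, size=n)
    return IntensityTrace(config.frame_s, counts)


def render_fret_trace(
    path: list[tuple[str, float]],
    config: SimulationConfig,
    scheme: KineticScheme,
    rng: np.random.Generator | None = None,
    noiseless: bool = False,
) -> AlexTrace:
    """Render a hidden path into aligned ALEX streams (I_DD, I_DA, I_AA).

    Noiseless frames obey I_DD = total * (1 - E*), I_DA = total * E* with the
    occupancy-weighted state E*; I_AA is independent of E* and reports only
    on acceptor survival.  Per-frame noise perturbs the proximity ratio by
    ``estar_noise_sd`` before splitting the donor-excited total.
    """
    n = config.n_frames
    occ, states = _frame_occupancy(path, n, config.frame_s)
    emitting = np.array([s not in (ABSENT, BLEACHED, "blink") for s in states], dtype=float)
    estars = np.array([scheme.estar_of(s) if em else 0.0 for s, em in zip(states, emitting)])
    w_emit = occ @ emitting  # emitting fraction of each frame
    with np.errstate(invalid="ignore"):
        e_frame = np.where(w_emit > 0, (occ @ (estars * emitting)) / np.where(w_emit > 0, w_emit, 1.0), 0.0)
    if not (noiseless or rng is None) and config.estar_noise_sd > 0:
        e_obs = np.where(w_emit > 0, e_frame + rng.normal(0.0, config.estar_noise_sd, size=n), 0.0)
    else:
        e_obs = e_frame
    total = scheme.donor_total_counts * w_emit
    i_da = total * e_obs + config.background
    i_dd = total * (1.0 - e_obs) + config.background
    i_aa = scheme.acceptor_level_counts * w_emit + config.background
    if not (noiseless or rng is None) and config.count_noise_sd > 0:
        i_dd = i_dd + rng.normal(0.0, config.count_noise_sd, size=n)
        i_da = i_da + rng.normal(0.0, config.count_noise_sd, size=n)
        i_aa = i_aa + rng.normal(0.0, config.count_noise_sd, size=n)
    return AlexTrace(config.frame_s, i_dd, i_da, i_aa)


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------


@dataclass
class SimulatedTrace:
    """A rendered trace with its generative ground truth."""

    trace: IntensityTrace | AlexTrace
    true_class: str
    path: list[tuple[str, float]]
    binding_time_s: float
    transition_time_s: float | None  # absolute time of first entry to enhanced
    bleach_time_s: float | None
    blink_intervals: list[tuple[float, float]] = field(default_factory=list)

    @property
    def true_dwell_s(self) -> float | None:
        """Ground-truth binding -> enhancement dwell (Class-II shapes)."""
        if self.transition_time_s is None:
            return None
        return self.transition_time_s - self.binding_time_s


def _path_events(path: list[tuple[str, float]]) -> tuple[float | None, float | None, float | None]:
    """(binding, first-enhanced, bleach) times of a path, None if absent."""
    binding = enhanced = bleach = None
    for state, t in path:
        if binding is None and state not in (ABSENT, BLEACHED):
            binding = t
        if enhanced is None and state == ENHANCED:
            enhanced = t
        if bleach is None and state == BLEACHED:
            bleach = t
    return binding, enhanced, bleach


def _sample_class_path(
    cls: str,
    scheme: KineticScheme,
    config: SimulationConfig,
    rng: np.random.Generator,
    max_tries: int = 2000,
) -> list[tuple[str, float]]:
    """Rejection-sample a path whose realized shape matches the class archetype.

    I   — appears low, no enhancement before disappearance/end;
    II  — appears low, enhancement observed before bleach and trace end;
    III — appears already enhanced, reverts to low before bleach/end;
    IV  — (FRET) low state with >=1 transient open-clamp excursion.
    """
    lo, hi = config.binding_time_range
    for _ in range(max_tries):
        tb = float(rng.uniform(lo, hi))
        if cls == "IV":
            path = _excursion_path(scheme, config.duration_s, rng, tb)
            if any(s == OPEN for s, _ in path):
                return path
            continue
        start = ENHANCED if cls == "III" else None
        path = sample_state_path(scheme, config.duration_s, rng, start_state=start, binding_time_s=tb)
        _, enh, bleach = _path_events(path)
        if cls == "I":
            ok = enh is None
        elif cls == "II":
            ok = enh is not None and (bleach is None or enh < bleach)
        elif cls == "III":
            ok = any(s == REWOUND for s, _ in path)
        else:
            raise ValueError(f"unknown class {cls!r}")
        if ok:
            return path
    raise RuntimeError(f"could not realize a class-{cls} path in {max_tries} tries")


def _excursion_path(
    scheme: KineticScheme, duration_s: float, rng: np.random.Generator, binding_time_s: float
) -> list[tuple[str, float]]:
    """Closed state with transient open-clamp excursions, then bleach."""
    path: list[tuple[str, float]] = []
    t = 0.0
    if binding_time_s > 0:
        path.append((ABSENT, 0.0))
        t = binding_time_s
    bleach_rate = 1.0 / scheme.bleach_lifetime_s
    state = _bound(0)
    while t < duration_s:
        path.append((state, t))
        mean = scheme.excursion_interval_s if state != OPEN else scheme.open_lifetime_s
        total = 1.0 / mean + bleach_rate
        t += _exp(rng, 1.0 / total)
        if t >= duration_s:
            break
        if rng.random() < bleach_rate / (1.0 / mean + bleach_rate):
            path.append((BLEACHED, t))
            break
        state = OPEN if state != OPEN else _bound(0)
    return path


def simulate_ensemble(
    config: SimulationConfig,
    scheme: KineticScheme,
    kind: str = "uife",
    schemes_by_class: dict[str, KineticScheme] | None = None,
) -> list[SimulatedTrace]:
    """Generate a labelled ensemble mixing trajectory classes per the config.

    Class identities are drawn from ``config.proportions``; each trace's
    hidden path is sampled (with rejection) so that its realized shape
    matches its class, rendered with the configured noise, and returned with
    full ground truth.  Deterministic under ``config.seed``.
    """
    if kind not in ("uife", "fret"):
        raise ValueError("kind must be 'uife' or 'fret'")
    if not config.proportions:
        raise ValueError("empty class mixture")
    if config.n_traces < 0:
        raise ValueError("n_traces must be >= 0")
    rng = np.random.default_rng(config.seed)
    classes = list(config.proportions)
    probs = np.array([config.proportions[c] for c in classes], dtype=float)
    draws = rng.choice(len(classes), size=config.n_traces, p=probs)

    out: list[SimulatedTrace] = []
    for i, ci in enumerate(draws):
        cls = classes[ci]
        sch = (schemes_by_class or {}).get(cls, scheme)
        path = _sample_class_path(cls, sch, config, rng)
        path, blinks = _overlay_blinks(path, sch, config.duration_s, rng)
        if kind == "uife":
            trace: IntensityTrace | AlexTrace = render_uife_trace(path, config, sch, rng)
        else:
            trace = render_fret_trace(path, config, sch, rng)
        trace.trace_id = f"trace{i:05d}"
        binding, enh, bleach = _path_events(path)
        out.append(
            SimulatedTrace(
                trace=trace,
                true_class=cls,
                path=path,
                binding_time_s=binding if binding is not None else 0.0,
                transition_time_s=enh,
                bleach_time_s=bleach,
                blink_intervals=blinks,
            )
        )
    return out


# ---------------------------------------------------------------------------
# movie rendering
# ---------------------------------------------------------------------------


def _gaussian_patch(shape: tuple[int, int], x: float, y: float, sigma: float) -> np.ndarray:
    """Pixel-integrated unit-flux 2-D Gaussian (pixel centres at integers)."""
    h, w = shape
    xs = np.arange(w)
    ys = np.arange(h)
    s = sigma * np.sqrt(2.0)
    fx = 0.5 * (special.erf((xs + 0.5 - x) / s) - special.erf((xs - 0.5 - x) / s))
    fy = 0.5 * (special.erf((ys + 0.5 - y) / s) - special.erf((ys - 0.5 - y) / s))
    return np.outer(fy, fx)


def render_movie(
    traces: list[IntensityTrace],
    positions: list[tuple[float, float]],
    psf_sigma_px: float,
    config: SimulationConfig,
    shape: tuple[int, int] = (64, 64),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render traces as diffraction-limited spots into a (T, H, W) stack.

    Each emitter is a pixel-integrated 2-D Gaussian whose total flux per
    frame equals the trace value (flux conserved); positions are (x, y) in
    pixels, origin at the top-left pixel centre.
    """
    if len(traces) != len(positions):
        raise ValueError("one position per trace required")
    pos = np.asarray(positions, dtype=float)
    if len(pos) > 1:
        d = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        if d.min() < 1.0:
            warnings.warn("emitters closer than 1 px will overlap", stacklevel=2)
    n_frames = min(len(t) for t in traces)
    stack = np.full((n_frames, *shape), float(config.background))
    for trace, (x, y) in zip(traces, pos):
        patch = _gaussian_patch(shape, x, y, psf_sigma_px)
        stack += trace.counts[:n_frames, None, None] * patch[None, :, :]
    if rng is not None:
        if config.shot_noise:
            stack = rng.poisson(np.maximum(stack, 0.0)).astype(float)
        if config.read_noise_sd > 0:
            stack = stack + rng.normal(0.0, config.read_noise_sd, size=stack.shape)
    return stack
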