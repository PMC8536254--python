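"""Gaussian-emission hidden Markov model for trace idealization.

Trajectories are idealized by a maximum-likelihood HMM with Gaussian
emissions, fitted globally (one model over all curated traces jointly) by
Baum-Welch EM, with the most probable state path per trace recovered by the
Viterbi algorithm.  UIFE traces use a three-state model (a near-zero dark
state plus the two emitting levels) on rescaled counts I_Cy3* = I_Cy3/1000;
FRET traces use a two-state model on the apparent FRET efficiency
E* = I_DA / (I_DD + I_DA).

Implementation notes
--------------------
* All forward/backward recursions are scaled (per-frame normalization) and
  vectorized across traces; shorter traces are padded and masked, and
  non-finite observations (e.g. undefined E* frames) are treated as missing
  (emission likelihood 1), so they inform the transition structure but not
  the emission parameters.
* The per-state emission sd is floored (default 1e-3 in rescaled units) to
  prevent variance collapse on noiseless data.
* States are always reported sorted by ascending emission mean, and Viterbi
  ties are broken toward the lower state index, so results are deterministic
  and label-permutation invariant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "HmmModel",
    "rescale_intensity",
    "compute_estar",
    "fit_hmm",
    "viterbi",
    "loglik",
    "state_level_summary",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class HmmModel:
    """Fitted Gaussian-emission HMM (states sorted by ascending mean)."""

    means: np.ndarray
    sds: np.ndarray
    transmat: np.ndarray
    startprob: np.ndarray
    loglik: float
    loglik_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True
    flags: list = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return int(self.means.size)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "means": self.means.tolist(),
                "sds": self.sds.tolist(),
                "transmat": self.transmat.tolist(),
                "startprob": self.startprob.tolist(),
                "loglik": self.loglik,
                "converged": self.converged,
                "flags": self.flags,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, src: str | Path) -> "HmmModel":
        text = Path(src).read_text() if Path(str(src)).exists() else str(src)
        d = json.loads(text)
        return cls(
            means=np.asarray(d["means"], float),
            sds=np.asarray(d["sds"], float),
            transmat=np.asarray(d["transmat"], float),
            startprob=np.asarray(d["startprob"], float),
            loglik=float(d["loglik"]),
            converged=bool(d.get("converged", True)),
            flags=list(d.get("flags", [])),
        )


def rescale_intensity(trace) -> np.ndarray:
    """I_Cy3* — photon counts divided by 1000 (exact; inverse is *1000)."""
    counts = trace.counts if hasattr(trace, "counts") else np.asarray(trace, float)
    if counts.size == 0:
        raise ValueError("empty trace")
    return counts / 1000.0


def compute_estar(i_dd: np.ndarray, i_da: np.ndarray) -> np.ndarray:
    """Apparent FRET efficiency E* = I_DA / (I_DD + I_DA), per frame.

    Frames with I_DD + I_DA <= 0 are undefined and returned as NaN; a trace
    with no defined frame raises.
    """
    i_dd = np.asarray(i_dd, dtype=float)
    i_da = np.asarray(i_da, dtype=float)
    if i_dd.shape != i_da.shape:
        raise ValueError("streams must be aligned")
    total = i_dd + i_da
    estar = np.full_like(total, np.nan)
    defined = total > 0
    estar[defined] = i_da[defined] / total[defined]
    if not defined.any():
        raise ValueError("E* undefined on every frame")
    return estar


# ---------------------------------------------------------------------------
# internals: padded batch representation
# ---------------------------------------------------------------------------


def _pad(traces: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Stack variable-length traces into (N, Tmax) with a valid-frame mask."""
    lengths = [len(t) for t in traces]
    if not lengths or min(lengths) < 1:
        raise ValueError("need at least one non-empty trace")
    tmax = max(lengths)
    x = np.full((len(traces), tmax), np.nan)
    valid = np.zeros((len(traces), tmax), dtype=bool)
    for i, t in enumerate(traces):
        x[i, : len(t)] = np.asarray(t, dtype=float)
        valid[i, : len(t)] = True
    return x, valid


def _emission_probs(x, valid, means, sds):
    """(N, T, K) emission likelihoods; missing/padded frames get 1."""
    obs = valid & np.isfinite(x)
    z = (np.where(obs, x, 0.0)[:, :, None] - means[None, None, :]) / sds[None, None, :]
    b = np.exp(-0.5 * z**2) / (np.sqrt(2.0 * np.pi) * sds[None, None, :])
    b = np.where(obs[:, :, None], b, 1.0)
    return np.maximum(b, 1e-300)


def _forward_backward(b, transmat, startprob):
    """Scaled forward-backward over a (N, T, K) emission tensor.

    Returns (gamma, xi_sum, logliks): posteriors (N, T, K), expected
    transition counts summed over time (N, K, K), and per-trace loglik.
    """
    n, t_max, k = b.shape
    alpha = np.empty((n, t_max, k))
    c = np.empty((n, t_max))
    a = alpha[:, 0] = startprob[None, :] * b[:, 0]
    c[:, 0] = a.sum(1)
    alpha[:, 0] /= c[:, 0, None]
    for t in range(1, t_max):
        a = (alpha[:, t - 1] @ transmat) * b[:, t]
        c[:, t] = a.sum(1)
        alpha[:, t] = a / c[:, t, None]
    beta = np.empty_like(alpha)
    beta[:, -1] = 1.0
    xi_sum = np.zeros((n, k, k))
    for t in range(t_max - 2, -1, -1):
        bb = b[:, t + 1] * beta[:, t + 1]
        beta[:, t] = (bb @ transmat.T) / c[:, t + 1, None]
        xi_sum += (
            alpha[:, t, :, None] * transmat[None, :, :] * bb[:, None, :] / c[:, t + 1, None, None]
        )
    gamma = alpha * beta
    gamma /= np.maximum(gamma.sum(2, keepdims=True), 1e-300)
    return gamma, xi_sum, np.log(c).sum(1)


def _init_params(x, valid, k, rng, restart_index):
    obs = x[valid & np.isfinite(x)]
    if restart_index == 0:
        q = (2.0 * np.arange(k) + 1.0) / (2.0 * k)
    else:
        q = np.sort(rng.uniform(0.02, 0.98, size=k))
    means = np.quantile(obs, q)
    means = means + rng.normal(0.0, 1e-6, size=k) if restart_index else means
    sd0 = max(obs.std() / max(k, 1), 1e-3)
    sds = np.full(k, sd0)
    transmat = np.full((k, k), 0.05 / max(k - 1, 1))
    np.fill_diagonal(transmat, 0.95 if k > 1 else 1.0)
    startprob = np.full(k, 1.0 / k)
    return means, sds, transmat, startprob


def fit_hmm(
    traces: list[np.ndarray],
    n_states: int,
    restarts: int = 10,
    sd_floor: float = 1e-3,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
    selection_iter: int = 25,
) -> HmmModel:
    """Fit a Gaussian-emission HMM to all traces jointly by Baum-Welch EM.

    The best of ``restarts`` seeded initializations is returned; restarts are
    triaged with a short EM burst (``selection_iter`` iterations) and only
    the most promising run is iterated to convergence.  The per-iteration
    total log-likelihood history of the winning run is kept in
    ``loglik_history`` (monotone non-decreasing by construction of EM).
    """
    if n_states < 1:
        raise ValueError("need n_states >= 1")
    x, valid = _pad([np.asarray(t, float) for t in traces])
    obs_mask = valid & np.isfinite(x)
    if not obs_mask.any():
        raise ValueError("no observed frames")

    def em(params, n_iter):
        means, sds, transmat, startprob = params
        history: list[float] = []
        converged = False
        for _ in range(n_iter):
            b = _emission_probs(x, valid, means, sds)
            gamma, xi_sum, logliks = _forward_backward(b, transmat, startprob)
            ll = float(logliks.sum())
            history.append(ll)
            if len(history) > 1 and abs(ll - history[-2]) <= tol * max(abs(ll), 1.0):
                converged = True
                break
            # M-step
            startprob = gamma[:, 0, :].mean(0)
            startprob /= startprob.sum()
            xi_tot = xi_sum.sum(0)
            denom = np.maximum(xi_tot.sum(1, keepdims=True), 1e-300)
            if n_states > 1:
                transmat = xi_tot / denom
            w = gamma * obs_mask[:, :, None]
            wsum = np.maximum(w.sum((0, 1)), 1e-300)
            means = (w * np.where(obs_mask, x, 0.0)[:, :, None]).sum((0, 1)) / wsum
            var = (w * (np.where(obs_mask, x, 0.0)[:, :, None] - means[None, None, :]) ** 2).sum(
                (0, 1)
            ) / wsum
            sds = np.maximum(np.sqrt(var), sd_floor)
        return (means, sds, transmat, startprob), history, converged

    n_restarts = max(restarts, 1)
    burst = max_iter if n_restarts == 1 else min(selection_iter, max_iter)
    candidates = []
    for r in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), r]))
        init = _init_params(x, valid, n_states, rng, r)
        params, history, converged = em(init, burst)
        candidates.append((history[-1], r, params, history, converged))
    _, _, params, history, converged = max(candidates, key=lambda c: (c[0], -c[1]))
    if not converged and len(history) < max_iter:
        params, history2, converged = em(params, max_iter - len(history))
        history = history + history2
    means, sds, transmat, startprob = params
    best = HmmModel(
        means=means,
        sds=sds,
        transmat=transmat,
        startprob=startprob,
        loglik=history[-1],
        loglik_history=np.asarray(history),
        converged=converged,
    )
    # report states sorted by ascending emission mean
    order = np.argsort(best.means, kind="stable")
    best.means = best.means[order]
    best.sds = best.sds[order]
    best.transmat = best.transmat[np.ix_(order, order)]
    best.startprob = best.startprob[order]
    if np.any(best.sds <= sd_floor * (1 + 1e-12)):
        best.flags.append("sd-at-floor")
    if best.n_states > 1 and np.min(np.diff(best.means)) < 10 * sd_floor:
        best.flags.append("degenerate-states")
    return best


def _log_emission(values: np.ndarray, model: HmmModel) -> np.ndarray:
    obs = np.isfinite(values)
    z = (np.where(obs, values, 0.0)[:, None] - model.means[None, :]) / model.sds[None, :]
    logb = -0.5 * z**2 - np.log(model.sds[None, :]) - 0.5 * _LOG2PI
    return np.where(obs[:, None], logb, 0.0)


def viterbi(values: np.ndarray, model: HmmModel) -> np.ndarray:
    """Most probable state path for one trace; ties go to the lower index."""
    values = np.asarray(values, dtype=float)
    t_len, k = values.size, model.n_states
    logb = _log_emission(values, model)
    log_a = np.log(np.maximum(model.transmat, 1e-300))
    delta = np.log(np.maximum(model.startprob, 1e-300)) + logb[0]
    psi = np.zeros((t_len, k), dtype=int)
    for t in range(1, t_len):
        cand = delta[:, None] + log_a
        psi[t] = np.argmax(cand, axis=0)  # first max -> lower index on ties
        delta = cand[psi[t], np.arange(k)] + logb[t]
    path = np.empty(t_len, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(t_len - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path


def loglik(values: np.ndarray, model: HmmModel) -> float:
    """Forward-algorithm log-likelihood of one trace under a model."""
    values = np.asarray(values, dtype=float)
    b = _emission_probs(values[None, :], np.ones((1, values.size), bool), model.means, model.sds)
    _, _, ll = _forward_backward(b, model.transmat, model.startprob)
    return float(ll[0])


def state_level_summary(
    model: HmmModel,
    paths: list[np.ndarray],
    traces: list[np.ndarray],
    scale: float = 1.0,
    bins: int = 50,
) -> dict:
    """Per-state pooled histograms with Gaussian fits, in original units.

    ``traces`` are the values the model was fitted on; ``scale`` converts
    back to original units (1000 for I_Cy3* -> I_Cy3).  States with fewer
    than 10 assigned frames report a mean but skip the Gaussian fit.  The
    fold ratio between the two brightest sufficiently populated states is
    reported as ``enhancement_ratio``.
    """
    from .kinetics import fit_gaussian_hist

    k = model.n_states
    pooled: list[np.ndarray] = [np.empty(0)] * k
    for path, values in zip(paths, traces):
        values = np.asarray(values, dtype=float)
        for s in range(k):
            sel = (path == s) & np.isfinite(values)
            if sel.any():
                pooled[s] = np.concatenate([pooled[s], values[sel] * scale])
    states = []
    for s in range(k):
        v = pooled[s]
        entry = {"state": s, "n_frames": int(v.size), "model_mean": float(model.means[s] * scale)}
        if v.size == 0:
            entry.update(mean=None, fitted=False, flag="empty")
        elif v.size < 10:
            entry.update(mean=float(v.mean()), fitted=False, flag="too-few-frames")
        else:
            try:
                mu, sd = fit_gaussian_hist(v, bins=bins)
                entry.update(mean=mu, sd=sd, fitted=True)
            except (RuntimeError, ValueError):
                entry.update(mean=float(v.mean()), sd=float(v.std()), fitted=False, flag="fit-failed")
        states.append(entry)
    populated = [e for e in states if e.get("mean") is not None and e["n_frames"] >= 10]
    populated.sort(key=lambda e: e["mean"])
    ratio = None
    if len(populated) >= 2 and populated[-2]["mean"]:
        ratio = populated[-1]["mean"] / populated[-2]["mean"]
    return {"states": states, "enhancement_ratio": ratio}
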