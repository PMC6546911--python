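"""Gaussian-emission hidden Markov modelling of FRET time series.

The discrete FRET states of the clamp on DNA (loading intermediates, loaded
state, unloading intermediate) are inferred from the selected traces with a
single HMM shared across all traces: per-state Gaussian emissions (mean FRET
and SD), one K x K per-frame transition matrix, and one initial distribution.
Fitting is maximum-likelihood Baum-Welch (EM) with multiple restarts, run on
all traces simultaneously with scaled forward-backward recursions; model
order is chosen by BIC.  States are always reported sorted by emission mean,
so state 0 is the lowest-FRET state.

Usage follows the model/results idiom::

    model = FretHMM(sequences, k_states=3)
    res = model.fit(seed=0)
    print(res.summary())
    path = res.decode(sequences[0])
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .qc import FretTrace

__all__ = ["FretHMM", "FretHMMResults", "DecodedPath", "fit_hmm", "decode", "select_model"]

_LOG2PI = np.log(2.0 * np.pi)
_MIN_SD = 1e-4


def _as_sequence(obj) -> np.ndarray:
    if isinstance(obj, FretTrace):
        x = obj.window_efficiency
    else:
        x = np.asarray(obj, dtype=float)
        x = x[np.isfinite(x)]
    return x


@dataclass
class DecodedPath:
    """Most-probable state path and posterior marginals for one trace."""

    trace_id: str
    states: np.ndarray        # per-frame Viterbi state index (mean-sorted)
    posterior: np.ndarray     # (n_frames, K) forward-backward marginals
    state_means: np.ndarray   # emission mean per state index

    @property
    def n_frames(self) -> int:
        return len(self.states)

    def transitions(self) -> list[tuple[int, int, int]]:
        """(frame, from_state, to_state) for every state change."""
        s = self.states
        idx = np.flatnonzero(np.diff(s) != 0) + 1
        return [(int(i), int(s[i - 1]), int(s[i])) for i in idx]


class FretHMM:
    """Shared-parameter Gaussian HMM over a collection of FRET traces.

    Parameters
    ----------
    sequences
        Iterable of 1-D observation arrays or :class:`FretTrace` objects
        (their valid-window efficiencies are used).  Each sequence must have
        at least 2 observations.
    k_states
        Number of hidden states (>= 1).
    """

    def __init__(self, sequences: Iterable, k_states: int):
        seqs = [_as_sequence(s) for s in sequences]
        seqs = [s for s in seqs if len(s) > 0]
        if not seqs:
            raise ValueError("no non-empty sequences given")
        if any(len(s) < 2 for s in seqs):
            raise ValueError("every sequence needs at least 2 observations")
        if k_states < 1:
            raise ValueError("k_states must be >= 1")
        self.sequences = seqs
        self.k = int(k_states)
        self.lengths = np.array([len(s) for s in seqs])
        tmax = int(self.lengths.max())
        self._x = np.zeros((len(seqs), tmax))
        self._mask = np.zeros((len(seqs), tmax), dtype=bool)
        for i, s in enumerate(seqs):
            self._x[i, : len(s)] = s
            self._mask[i, : len(s)] = True
        self.n_obs = int(self.lengths.sum())

    # -- internals ----------------------------------------------------------

    def _emission_prob(self, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
        """Gaussian density b[n, t, k]; padded frames get b = 1."""
        z = (self._x[:, :, None] - mu[None, None, :]) / sd[None, None, :]
        logb = -0.5 * z * z - np.log(sd)[None, None, :] - 0.5 * _LOG2PI
        b = np.exp(logb)
        b[~self._mask] = 1.0
        # guard against total underflow on outlier frames
        b = np.maximum(b, 1e-300)
        return b

    def _forward_backward(self, b, pi, a):
        n, t, k = b.shape
        alpha = np.empty_like(b)
        c = np.empty((n, t))
        alpha[:, 0] = pi[None, :] * b[:, 0]
        c[:, 0] = alpha[:, 0].sum(axis=1)
        alpha[:, 0] /= c[:, 0, None]
        for j in range(1, t):
            al = (alpha[:, j - 1] @ a) * b[:, j]
            c[:, j] = al.sum(axis=1)
            alpha[:, j] = al / c[:, j, None]
        beta = np.ones_like(b)
        for j in range(t - 2, -1, -1):
            beta[:, j] = (beta[:, j + 1] * b[:, j + 1]) @ a.T / c[:, j + 1, None]
        # padded frames have b = 1 and therefore c = 1: they add nothing
        loglik = float(np.log(c[self._mask]).sum())
        return alpha, beta, c, loglik

    def _em(self, mu, sd, pi, a, tol, max_iter):
        trail = []
        converged = False
        prev = -np.inf
        for it in range(max_iter):
            b = self._emission_prob(mu, sd)
            alpha, beta, c, loglik = self._forward_backward(b, pi, a)
            trail.append(loglik)
            if loglik + 1e-8 * (1.0 + abs(loglik)) < prev:
                raise FloatingPointError(
                    f"EM log-likelihood decreased at iteration {it}: "
                    f"{prev} -> {loglik}"
                )
            if it > 0 and abs(loglik - prev) <= tol * (1.0 + abs(loglik)):
                converged = True
                break
            prev = loglik

            gamma = alpha * beta  # scaled FB: rows already sum to 1
            gamma[~self._mask] = 0.0
            if self.k > 1:
                w = (b[:, 1:] * beta[:, 1:]) / c[:, 1:, None]
                w[~self._mask[:, 1:]] = 0.0
                src = alpha[:, :-1].copy()
                src[~self._mask[:, 1:]] = 0.0  # transition into a padded frame
                xi_num = a * np.einsum("ntk,ntl->kl", src, w)
                rows = xi_num.sum(axis=1, keepdims=True)
                a = np.where(rows > 0, xi_num / np.where(rows == 0, 1, rows), a)
            pi = gamma[:, 0].mean(axis=0)
            pi = pi / pi.sum()
            gsum = gamma.sum(axis=(0, 1))
            gsum = np.maximum(gsum, 1e-12)
            mu = np.einsum("ntk,nt->k", gamma, self._x) / gsum
            var = np.einsum("ntk,nt->k", gamma, self._x**2) / gsum - mu**2
            sd = np.sqrt(np.maximum(var, _MIN_SD**2))
        return mu, sd, pi, a, trail, converged

    def _initial_params(self, restart: int, rng: np.random.Generator, init: str):
        pooled = np.concatenate(self.sequences)
        k = self.k
        psd = max(float(pooled.std()), _MIN_SD)
        if restart == 0 and init in ("spread", "quantile"):
            # spread across the occupied range: robust to very unbalanced
            # state occupancies (a dominant state would collapse quantiles)
            lo, hi = np.percentile(pooled, [1, 99])
            mu = np.linspace(lo, hi, k) if hi > lo else np.full(k, lo)
        elif restart == 1 and init in ("spread", "quantile"):
            q = (2 * np.arange(k) + 1) / (2 * k)
            mu = np.quantile(pooled, q)
        else:
            mu = np.sort(rng.choice(pooled, size=k, replace=False))
        sd = np.full(k, max(psd / max(k, 2), _MIN_SD))
        a = np.full((k, k), 0.05 / max(k - 1, 1))
        np.fill_diagonal(a, 0.95)
        pi = np.full(k, 1.0 / k)
        return mu, sd, pi, a

    # -- public API ---------------------------------------------------------

    def fit(
        self,
        n_restarts: int = 5,
        tol: float = 1e-6,
        max_iter: int = 300,
        seed: int | np.random.Generator | None = None,
        init: str = "spread",
    ) -> "FretHMMResults":
        """Fit by EM, keeping the best of ``n_restarts`` initializations.

        Restart 0 spreads the emission means across the occupied data range,
        restart 1 uses pooled-data quantiles, and subsequent restarts draw
        means from random observations (``init='random'`` makes every
        restart random).  Returns a results object with states sorted by
        emission mean; ``converged`` is False if no restart converged within
        ``max_iter`` iterations.
        """
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        if self.k == 1:
            pooled = np.concatenate(self.sequences)
            mu = np.array([pooled.mean()])
            sd = np.array([max(pooled.std(), _MIN_SD)])
            pi, a = np.array([1.0]), np.array([[1.0]])
            b = self._emission_prob(mu, sd)
            *_, loglik = self._forward_backward(b, pi, a)
            return FretHMMResults(
                model=self, means=mu, sds=sd, transmat=a, startprob=pi,
                loglik=loglik, loglik_trail=[loglik], converged=True,
                n_restarts=1,
            )

        best = None
        for r in range(max(1, n_restarts)):
            mu0, sd0, pi0, a0 = self._initial_params(r, rng, init)
            try:
                mu, sd, pi, a, trail, conv = self._em(mu0, sd0, pi0, a0, tol, max_iter)
            except FloatingPointError:
                raise
            cand = (trail[-1], mu, sd, pi, a, trail, conv)
            if best is None or cand[0] > best[0]:
                best = cand
        loglik, mu, sd, pi, a, trail, conv = best
        order = np.argsort(mu)
        return FretHMMResults(
            model=self,
            means=mu[order],
            sds=sd[order],
            transmat=a[np.ix_(order, order)],
            startprob=pi[order],
            loglik=loglik,
            loglik_trail=trail,
            converged=conv,
            n_restarts=max(1, n_restarts),
        )


@dataclass
class FretHMMResults:
    """Fitted HMM: estimates, fit diagnostics, decoding and serialization.

    States are sorted by emission mean (state 0 = lowest FRET).  The
    ``loglik_trail`` is the per-iteration log-likelihood of the winning
    restart and is non-decreasing by construction of EM.
    """

    model: FretHMM
    means: np.ndarray
    sds: np.ndarray
    transmat: np.ndarray
    startprob: np.ndarray
    loglik: float
    loglik_trail: list[float]
    converged: bool
    n_restarts: int = 1

    @property
    def k(self) -> int:
        return len(self.means)

    @property
    def n_params(self) -> int:
        k = self.k
        return (k - 1) + k * (k - 1) + 2 * k

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.model.n_obs)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    def nearest_state(self, value: float) -> int:
        """Index of the state whose emission mean is closest to ``value``."""
        return int(np.argmin(np.abs(self.means - value)))

    # -- decoding -----------------------------------------------------------

    def decode(self, trace, trace_id: str | None = None) -> DecodedPath:
        """Viterbi path and posterior marginals for one trace."""
        if isinstance(trace, FretTrace):
            x = trace.window_efficiency
            trace_id = trace_id or trace.trace_id
        else:
            x = np.asarray(trace, dtype=float)
            x = x[np.isfinite(x)]
            trace_id = trace_id or "trace"
        if len(x) == 0:
            raise ValueError("nothing to decode: empty observation sequence")

        k = self.k
        log_a = np.log(np.maximum(self.transmat, 1e-300))
        logb = (
            -0.5 * ((x[:, None] - self.means[None, :]) / self.sds[None, :]) ** 2
            - np.log(self.sds)[None, :]
            - 0.5 * _LOG2PI
        )
        t_len = len(x)
        delta = np.empty((t_len, k))
        psi = np.zeros((t_len, k), dtype=int)
        delta[0] = np.log(np.maximum(self.startprob, 1e-300)) + logb[0]
        for t in range(1, t_len):
            cand = delta[t - 1][:, None] + log_a
            psi[t] = np.argmax(cand, axis=0)
            delta[t] = cand[psi[t], np.arange(k)] + logb[t]
        states = np.empty(t_len, dtype=int)
        states[-1] = int(np.argmax(delta[-1]))
        for t in range(t_len - 2, -1, -1):
            states[t] = psi[t + 1][states[t + 1]]

        sub = FretHMM([x], self.k) if t_len >= 2 else None
        if sub is not None:
            b = sub._emission_prob(self.means, self.sds)
            alpha, beta, _, _ = sub._forward_backward(b, self.startprob, self.transmat)
            posterior = (alpha * beta)[0, :t_len]
            posterior = posterior / posterior.sum(axis=1, keepdims=True)
        else:
            p = self.startprob * np.exp(logb[0])
            posterior = (p / p.sum())[None, :]
        return DecodedPath(
            trace_id=trace_id, states=states, posterior=posterior,
            state_means=self.means.copy(),
        )

    def decode_all(self, traces=None) -> list[DecodedPath]:
        """Decode every training sequence (or an explicit list of traces)."""
        if traces is None:
            return [
                self.decode(s, trace_id=f"seq{i:04d}")
                for i, s in enumerate(self.model.sequences)
            ]
        return [self.decode(tr) for tr in traces]

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Gaussian-emission FRET HMM (shared across traces)",
            "=" * 52,
            f"states: {self.k}    traces: {len(self.model.sequences)}    "
            f"frames: {self.model.n_obs}",
            f"log-likelihood: {self.loglik:.2f}    BIC: {self.bic:.2f}    "
            f"AIC: {self.aic:.2f}",
            f"converged: {self.converged} "
            f"({len(self.loglik_trail)} EM iterations, best of "
            f"{self.n_restarts} restarts)",
            "",
            "state   mean E    sd E    start p",
        ]
        for i in range(self.k):
            lines.append(
                f"  {i}    {self.means[i]:7.4f}  {self.sds[i]:6.4f}   "
                f"{self.startprob[i]:6.4f}"
            )
        lines.append("")
        lines.append("transition matrix (per frame):")
        for i in range(self.k):
            lines.append("   " + "  ".join(f"{v:7.5f}" for v in self.transmat[i]))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "transmat": self.transmat.tolist(),
            "startprob": self.startprob.tolist(),
            "loglik": self.loglik,
            "bic": self.bic,
            "converged": bool(self.converged),
            "n_restarts": self.n_restarts,
        }


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------


def fit_hmm(
    fret_traces: Sequence,
    k: int,
    init: str = "spread",
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int | None = None,
    n_restarts: int = 5,
) -> FretHMMResults:
    """Fit a shared Gaussian HMM to the valid windows of the given traces."""
    return FretHMM(fret_traces, k).fit(
        n_restarts=n_restarts, tol=tol, max_iter=max_iter, seed=seed, init=init
    )


def decode(model: FretHMMResults, trace) -> DecodedPath:
    """Viterbi decoding plus posterior marginals for one trace."""
    return model.decode(trace)


def select_model(
    fret_traces: Sequence,
    k_range: Iterable[int],
    criterion: str = "bic",
    **fit_kwargs,
) -> tuple[int, dict[int, FretHMMResults]]:
    """Fit each K in ``k_range``; return (best K by the criterion, all fits).

    Only converged fits compete; if none converged the best criterion value
    overall wins.
    """
    if criterion not in ("bic", "aic"):
        raise ValueError("criterion must be 'bic' or 'aic'")
    fits = {int(k): fit_hmm(fret_traces, int(k), **fit_kwargs) for k in k_range}
    pool = {k: r for k, r in fits.items() if r.converged} or fits
    best = min(pool, key=lambda k: getattr(pool[k], criterion))
    return best, fits
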