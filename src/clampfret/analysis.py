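"""Population-level kinetics from decoded traces: synchronized FRET heat
maps, transition density plots (TDP), dwell-time tables and dwell-law fits.

Loading traces are synchronized at the clamp-DNA association moment and
unloading traces at dissociation, so overlaying many molecules reveals the
ordered progression of FRET states.  Transitions harvested from the decoded
state paths populate the TDP; per-state dwell times are fitted by maximum
likelihood to an exponential (single rate-limiting step) or a gamma law
(multiple sequential sub-steps — a gamma shape above 1 and a histogram peak
at non-zero time are the signatures of hidden sub-steps).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .hmm import DecodedPath
from .qc import FretTrace

__all__ = [
    "SyncedTraces",
    "SyncHeatMap",
    "TDPHistogram",
    "DwellModel",
    "DwellFitResults",
    "synchronize",
    "heatmap",
    "tdp",
    "dwell_times",
    "fit_dwells",
    "fit_dwell_histogram",
    "lrt_exponential_vs_gamma",
    "compare_dwell_distributions",
]


# ---------------------------------------------------------------------------
# Synchronization and heat maps
# ---------------------------------------------------------------------------


@dataclass
class SyncedTraces:
    """Traces with time axes shifted so the anchor event sits at t = 0."""

    anchor: str
    trace_ids: list[str]
    times: list[np.ndarray]          # relative times of valid-window frames
    efficiencies: list[np.ndarray]   # matching finite FRET values
    dropped: pd.DataFrame            # trace_id, reason

    @property
    def n_traces(self) -> int:
        return len(self.trace_ids)


def synchronize(fret_traces: Sequence[FretTrace], anchor: str) -> SyncedTraces:
    """Align traces at their detected association or dissociation moment.

    ``anchor`` is ``'association'`` or ``'dissociation'``; the corresponding
    frame must be present in each trace's annotations (traces lacking it are
    dropped with a reason code).  Only finite valid-window FRET values are
    kept.
    """
    if anchor not in ("association", "dissociation"):
        raise ValueError("anchor must be 'association' or 'dissociation'")
    key = f"{anchor}_frame"
    ids, times, effs, dropped = [], [], [], []
    for ft in fret_traces:
        frame = ft.annotations.get(key)
        if frame is None:
            dropped.append({"trace_id": ft.trace_id, "reason": f"no_{anchor}"})
            continue
        sl = slice(ft.valid_start, ft.valid_end)
        e = ft.efficiency[sl]
        t = ft.time[sl] - ft.time[frame]
        keep = np.isfinite(e)
        if not keep.any():
            dropped.append({"trace_id": ft.trace_id, "reason": "no_valid_fret"})
            continue
        ids.append(ft.trace_id)
        times.append(t[keep])
        effs.append(e[keep])
    return SyncedTraces(
        anchor=anchor,
        trace_ids=ids,
        times=times,
        efficiencies=effs,
        dropped=pd.DataFrame(dropped, columns=["trace_id", "reason"]),
    )


@dataclass
class SyncHeatMap:
    """Column-normalized FRET population density over synchronized time.

    ``density[i, j]`` is the fraction of frames in time bin ``i`` falling in
    FRET bin ``j``; every time column with at least one observation sums
    to 1.
    """

    time_edges: np.ndarray
    e_edges: np.ndarray
    counts: np.ndarray     # (n_time_bins, n_e_bins)
    density: np.ndarray
    n_traces: int
    anchor: str

    @property
    def time_centers(self) -> np.ndarray:
        return 0.5 * (self.time_edges[:-1] + self.time_edges[1:])

    @property
    def e_centers(self) -> np.ndarray:
        return 0.5 * (self.e_edges[:-1] + self.e_edges[1:])

    def modal_e(self) -> pd.DataFrame:
        """Per time column, the FRET bin center holding the most density."""
        rows = []
        for i, t in enumerate(self.time_centers):
            if self.counts[i].sum() == 0:
                continue
            rows.append({"time_s": t, "modal_e": self.e_centers[np.argmax(self.density[i])]})
        return pd.DataFrame(rows, columns=["time_s", "modal_e"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.density, index=self.time_centers, columns=self.e_centers
        )


def heatmap(
    synced: SyncedTraces,
    t_range: tuple[float, float] | None = None,
    t_bin: float = 0.2,
    e_range: tuple[float, float] = (-0.1, 1.1),
    e_bin: float = 0.02,
) -> SyncHeatMap:
    """2-D histogram of (relative time, FRET) with per-time-column
    normalization.

    Default time range is [-2, +10] s for association-anchored sets and
    [-10, +2] s for dissociation-anchored ones.
    """
    if t_range is None:
        t_range = (-2.0, 10.0) if synced.anchor == "association" else (-10.0, 2.0)
    t_edges = np.arange(t_range[0], t_range[1] + 0.5 * t_bin, t_bin)
    e_edges = np.arange(e_range[0], e_range[1] + 0.5 * e_bin, e_bin)
    if synced.times:
        t_all = np.concatenate(synced.times)
        e_all = np.concatenate(synced.efficiencies)
        counts, _, _ = np.histogram2d(t_all, e_all, bins=[t_edges, e_edges])
    else:
        counts = np.zeros((len(t_edges) - 1, len(e_edges) - 1))
    col = counts.sum(axis=1, keepdims=True)
    density = np.divide(counts, col, out=np.zeros_like(counts), where=col > 0)
    return SyncHeatMap(
        time_edges=t_edges,
        e_edges=e_edges,
        counts=counts,
        density=density,
        n_traces=synced.n_traces,
        anchor=synced.anchor,
    )


# ---------------------------------------------------------------------------
# Transition density plot
# ---------------------------------------------------------------------------


@dataclass
class TDPHistogram:
    """2-D transition histogram over (E before, E after) bins.

    Counts sum to the number of decoded state changes inside the analysis
    window; same-state "transitions" cannot occur by construction.
    ``transitions`` keeps the raw (trace_id, frame, from_state, to_state)
    records for exact counting.
    """

    e_edges: np.ndarray
    counts: np.ndarray
    window_s: float
    side: str
    transitions: pd.DataFrame

    @property
    def e_centers(self) -> np.ndarray:
        return 0.5 * (self.e_edges[:-1] + self.e_edges[1:])

    @property
    def n_transitions(self) -> int:
        return int(self.counts.sum())

    def peaks(self, top: int = 10) -> pd.DataFrame:
        """Off-diagonal peak bins ranked by count."""
        order = np.argsort(self.counts, axis=None)[::-1]
        rows = []
        for flat in order[:top]:
            i, j = np.unravel_index(flat, self.counts.shape)
            if self.counts[i, j] == 0:
                break
            rows.append(
                {
                    "e_before": self.e_centers[i],
                    "e_after": self.e_centers[j],
                    "count": int(self.counts[i, j]),
                }
            )
        return pd.DataFrame(rows, columns=["e_before", "e_after", "count"])

    def pair_count(self, from_state: int, to_state: int) -> int:
        """Number of recorded transitions between two state indices."""
        t = self.transitions
        return int(
            ((t["from_state"] == from_state) & (t["to_state"] == to_state)).sum()
        )


def tdp(
    decoded: Sequence[DecodedPath],
    frame_interval: float,
    window_s: float = 6.0,
    side: str = "first",
    e_range: tuple[float, float] = (0.0, 1.0),
    e_bin: float = 0.02,
) -> TDPHistogram:
    """Transition density plot from decoded state paths.

    ``side='first'`` keeps transitions within the first ``window_s`` seconds
    of each decoded window (loading traces, anchored at association);
    ``side='last'`` keeps the final ``window_s`` seconds (unloading traces,
    anchored at dissociation).  Each transition increments the bin at the
    (emission mean before, emission mean after) coordinates of the fitted
    model.
    """
    if side not in ("first", "last"):
        raise ValueError("side must be 'first' or 'last'")
    w_frames = int(round(window_s / frame_interval))
    e_edges = np.arange(e_range[0], e_range[1] + 0.5 * e_bin, e_bin)
    nb = len(e_edges) - 1
    counts = np.zeros((nb, nb))
    rows = []
    for path in decoded:
        for frame, a, b in path.transitions():
            if side == "first" and frame > w_frames:
                continue
            if side == "last" and frame < path.n_frames - w_frames:
                continue
            ea, eb = path.state_means[a], path.state_means[b]
            i = min(max(np.searchsorted(e_edges, ea, side="right") - 1, 0), nb - 1)
            j = min(max(np.searchsorted(e_edges, eb, side="right") - 1, 0), nb - 1)
            counts[i, j] += 1
            rows.append(
                {
                    "trace_id": path.trace_id,
                    "frame": frame,
                    "from_state": a,
                    "to_state": b,
                    "e_before": ea,
                    "e_after": eb,
                }
            )
    transitions = pd.DataFrame(
        rows,
        columns=["trace_id", "frame", "from_state", "to_state", "e_before", "e_after"],
    )
    return TDPHistogram(
        e_edges=e_edges, counts=counts, window_s=window_s, side=side,
        transitions=transitions,
    )


# ---------------------------------------------------------------------------
# Dwell times
# ---------------------------------------------------------------------------


def dwell_times(
    decoded: Sequence[DecodedPath],
    state: int,
    frame_interval: float,
    policy: str = "drop_censored",
    start_is_entry: bool = False,
    end_is_exit: bool = False,
) -> pd.DataFrame:
    """Durations of contiguous visits to one state across decoded paths.

    Runs touching the start or end of a decoded window are censored (their
    true duration is longer than observed).  ``policy='drop_censored'``
    (default) removes them; ``'keep_flagged'`` keeps them flagged.  Windows
    bounded by *observed events* do not censor: set ``start_is_entry=True``
    when the window opens at a detected entry (loading windows open at
    association, which is the entry into the first intermediate) and
    ``end_is_exit=True`` when it closes at a detected exit (unloading windows
    close at dissociation).  Loading windows end at photobleaching, which
    does truncate the final dwell.  Returns columns
    ``trace_id, state, duration_s, censored``.
    """
    if policy not in ("drop_censored", "keep_flagged"):
        raise ValueError("policy must be 'drop_censored' or 'keep_flagged'")
    rows = []
    for path in decoded:
        s = path.states
        n = len(s)
        in_state = s == state
        if not in_state.any():
            continue
        edges = np.flatnonzero(np.diff(in_state.astype(int)) != 0) + 1
        starts = [0] if in_state[0] else []
        starts += [e for e in edges if in_state[e]]
        ends = [e for e in edges if not in_state[e]]
        if in_state[-1]:
            ends.append(n)
        for a, b in zip(starts, ends):
            left_censored = a == 0 and not start_is_entry
            right_censored = b == n and not end_is_exit
            rows.append(
                {
                    "trace_id": path.trace_id,
                    "state": state,
                    "duration_s": (b - a) * frame_interval,
                    "censored": bool(left_censored or right_censored),
                }
            )
    table = pd.DataFrame(rows, columns=["trace_id", "state", "duration_s", "censored"])
    if policy == "drop_censored":
        table = table[~table["censored"]].reset_index(drop=True)
    return table


def _durations(table) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        d = table.loc[~table["censored"].astype(bool), "duration_s"].to_numpy(float)
    else:
        d = np.asarray(table, dtype=float)
    return d[np.isfinite(d) & (d > 0)]


MIN_DWELLS = 10


@dataclass
class DwellFitResults:
    """Maximum-likelihood dwell-law fit.

    For the exponential family ``tau`` is the mean dwell and ``amplitude``
    the matching histogram-model amplitude; for the gamma family ``shape``
    and ``scale`` are reported (shape 1 recovers the exponential).  ``ci``
    holds 95% intervals.  Durations below ``t_min`` were discarded and the
    remainder shifted by ``t_min`` before fitting (left truncation; valid
    for the memoryless exponential and a guard against undersampled short
    dwells in frame-quantized data).
    """

    family: str
    n: int
    loglik: float
    t_min: float
    tau: float | None = None
    shape: float | None = None
    scale: float | None = None
    ci: dict = field(default_factory=dict)

    @property
    def mean_dwell(self) -> float:
        if self.family == "exponential":
            return self.tau
        return self.shape * self.scale

    def summary(self) -> str:
        lines = [
            f"{self.family} dwell fit  (n = {self.n}, t_min = {self.t_min} s)",
            f"log-likelihood: {self.loglik:.2f}",
        ]
        if self.family == "exponential":
            lo, hi = self.ci.get("tau", (np.nan, np.nan))
            lines.append(f"tau = {self.tau:.4f} s   95% CI [{lo:.4f}, {hi:.4f}]")
        else:
            lo, hi = self.ci.get("shape", (np.nan, np.nan))
            lines.append(
                f"shape = {self.shape:.3f}   95% CI [{lo:.3f}, {hi:.3f}]   "
                f"scale = {self.scale:.4f} s"
            )
        return "\n".join(lines)


class DwellModel:
    """Dwell-law model for a set of state durations (fit() -> results)."""

    def __init__(self, table, family: str = "exponential", t_min: float = 0.0):
        if family not in ("exponential", "gamma"):
            raise ValueError("family must be 'exponential' or 'gamma'")
        d = _durations(table)
        d = d[d > t_min] - t_min
        if len(d) < MIN_DWELLS:
            raise ValueError(
                f"need at least {MIN_DWELLS} uncensored dwells above t_min, "
                f"got {len(d)}"
            )
        self.family = family
        self.t_min = float(t_min)
        self.durations = d

    def fit(self) -> DwellFitResults:
        d = self.durations
        n = len(d)
        if self.family == "exponential":
            tau = float(d.mean())
            loglik = float(-n * np.log(tau) - d.sum() / tau)
            # exact CI from 2*n*mean/tau ~ chi2(2n)
            lo = 2 * d.sum() / stats.chi2.ppf(0.975, 2 * n)
            hi = 2 * d.sum() / stats.chi2.ppf(0.025, 2 * n)
            return DwellFitResults(
                family="exponential", n=n, loglik=loglik, t_min=self.t_min,
                tau=tau, ci={"tau": (float(lo), float(hi))},
            )
        shape, _, scale = stats.gamma.fit(d, floc=0.0)
        loglik = float(stats.gamma.logpdf(d, shape, scale=scale).sum())
        # asymptotic SE of the shape from the inverse Fisher information
        denom = shape * special.polygamma(1, shape) - 1.0
        se = np.sqrt(shape / (n * denom)) if denom > 0 else np.nan
        ci = (float(shape - 1.96 * se), float(shape + 1.96 * se))
        return DwellFitResults(
            family="gamma", n=n, loglik=loglik, t_min=self.t_min,
            shape=float(shape), scale=float(scale), ci={"shape": ci},
        )


def fit_dwells(table, model: str = "exponential", t_min: float = 0.0) -> DwellFitResults:
    """Maximum-likelihood dwell fit on the uncensored durations of a table."""
    return DwellModel(table, family=model, t_min=t_min).fit()


def fit_dwell_histogram(
    table, bin_s: float = 0.25
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Least-squares ``A * exp(-t / tau)`` fit to the dwell histogram.

    Kept for figure parity with the classic presentation; the MLE from
    :func:`fit_dwells` is the primary estimate (the histogram fit depends on
    binning).  Returns ``(A, tau, bin_centers, counts)``.
    """
    d = _durations(table)
    edges = np.arange(0.0, d.max() + bin_s, bin_s)
    counts, _ = np.histogram(d, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = (float(counts.max()) if counts.size else 1.0, max(float(d.mean()), bin_s))
    (amp, tau), _ = optimize.curve_fit(
        lambda t, a, tau: a * np.exp(-t / tau), centers, counts, p0=p0,
        maxfev=10_000,
    )
    return float(amp), float(tau), centers, counts


def histogram_mode(table, bin_s: float = 0.25) -> float:
    """Center of the fullest dwell-histogram bin (0-anchored binning)."""
    d = _durations(table)
    edges = np.arange(0.0, d.max() + bin_s, bin_s)
    counts, _ = np.histogram(d, bins=edges)
    return float(0.5 * bin_s + bin_s * int(np.argmax(counts)))


def lrt_exponential_vs_gamma(table, t_min: float = 0.0) -> dict:
    """Likelihood-ratio test of exponential (shape = 1) against gamma.

    Returns the test statistic, its chi-square(1) p-value and both fits.  A
    significant rejection together with a fitted shape above 1 indicates
    multiple sequential rate-limiting sub-steps (a peaked dwell histogram).
    """
    exp_fit = fit_dwells(table, "exponential", t_min=t_min)
    gam_fit = fit_dwells(table, "gamma", t_min=t_min)
    stat = 2.0 * (gam_fit.loglik - exp_fit.loglik)
    return {
        "statistic": float(stat),
        "pvalue": float(stats.chi2.sf(max(stat, 0.0), df=1)),
        "exponential": exp_fit,
        "gamma": gam_fit,
    }


def compare_dwell_distributions(table_a, table_b) -> dict:
    """Two-sample Kolmogorov-Smirnov comparison of two dwell sets."""
    res = stats.ks_2samp(_durations(table_a), _durations(table_b))
    return {"statistic": float(res.statistic), "pvalue": float(res.pvalue)}
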