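"""Trace quality control: FRET computation, photobleaching step counting,
trace selection, and association/dissociation detection.

The clamp carries up to six donor dyes, so an analyzable loading trace shows
six discrete downward photobleaching steps in total intensity; unloading
traces (where the molecule leaves before the dyes bleach) are instead selected
by an initial intensity comparable to the calibrated six-donor level.  The
background-corrected total intensity (donor + acceptor) is invariant to the
FRET state, which is what makes step counting on it well posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .photophysics import Trace

__all__ = [
    "FretTrace",
    "compute_fret",
    "count_photobleach_steps",
    "binary_segmentation",
    "select_traces",
    "detect_association",
    "detect_dissociation",
    "count_spots_over_time",
    "prepare_fret_trace",
]


@dataclass
class FretTrace:
    """Per-frame apparent FRET efficiency with an analyzable valid window.

    ``efficiency`` is NaN outside the valid window and on no-signal frames;
    it is *not* clamped to [0, 1] (noise may push it outside; such frames are
    listed in ``annotations['out_of_range_frames']``).
    """

    trace_id: str
    time: np.ndarray
    efficiency: np.ndarray
    total: np.ndarray            # background-corrected donor + acceptor
    valid_start: int             # first analyzable frame (inclusive)
    valid_end: int               # last analyzable frame (exclusive)
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (0 <= self.valid_start <= self.valid_end <= n):
            raise ValueError(
                f"valid window [{self.valid_start}, {self.valid_end}) outside "
                f"trace of {n} frames"
            )

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @property
    def frame_interval(self) -> float:
        return float(self.time[1] - self.time[0]) if self.n_frames > 1 else np.nan

    @property
    def window_efficiency(self) -> np.ndarray:
        """Finite FRET values inside the valid window."""
        e = self.efficiency[self.valid_start : self.valid_end]
        return e[np.isfinite(e)]

    def shifted(self, anchor_frame: int) -> "FretTrace":
        """Copy with the time axis shifted so ``anchor_frame`` sits at t = 0."""
        return FretTrace(
            trace_id=self.trace_id,
            time=self.time - self.time[anchor_frame],
            efficiency=self.efficiency,
            total=self.total,
            valid_start=self.valid_start,
            valid_end=self.valid_end,
            annotations=dict(self.annotations),
        )


def _robust_noise_sd(x: np.ndarray) -> float:
    """Noise SD from the median absolute first difference (step-insensitive)."""
    d = np.diff(np.asarray(x, dtype=float))
    if len(d) == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d))) / np.sqrt(2.0)


def compute_fret(
    trace: Trace,
    background_donor: float = 0.0,
    background_acceptor: float = 0.0,
    min_total: float | None = None,
) -> FretTrace:
    """Apparent FRET efficiency per frame.

    ``E = (A - bg_A) / [(A - bg_A) + (D - bg_D)]``.  Frames whose corrected
    total falls below ``min_total`` (default: 5x the robust noise SD of the
    total) are marked no-signal (NaN).  The valid window initially spans the
    whole trace; selection and event detection narrow it later.
    """
    if trace.n_frames == 0:
        raise ValueError("cannot compute FRET on a zero-length trace")
    d = trace.donor - background_donor
    a = trace.acceptor - background_acceptor
    total = d + a
    if min_total is None:
        min_total = 5.0 * _robust_noise_sd(total)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(total > min_total, a / total, np.nan)
    out_of_range = np.flatnonzero(np.isfinite(e) & ((e < 0) | (e > 1)))
    return FretTrace(
        trace_id=trace.trace_id,
        time=trace.time.copy(),
        efficiency=e,
        total=total,
        valid_start=0,
        valid_end=trace.n_frames,
        annotations={
            "min_total": float(min_total),
            "out_of_range_frames": out_of_range,
        },
    )


# ---------------------------------------------------------------------------
# Change-point step counting
# ---------------------------------------------------------------------------


def _best_split(x: np.ndarray) -> tuple[float, int]:
    """Best single change point by within-segment SSE reduction, O(n)."""
    n = len(x)
    c1 = np.cumsum(x)
    c2 = np.cumsum(x * x)
    total_sse = c2[-1] - c1[-1] ** 2 / n
    k = np.arange(1, n)  # split before index k
    left = c2[k - 1] - c1[k - 1] ** 2 / k
    right = (c2[-1] - c2[k - 1]) - (c1[-1] - c1[k - 1]) ** 2 / (n - k)
    sse = left + right
    best = int(np.argmin(sse))
    return float(total_sse - sse[best]), int(k[best])


def binary_segmentation(
    x: np.ndarray, penalty: float, min_size: int = 3
) -> list[int]:
    """Recursive binary segmentation of a piecewise-constant signal.

    Splits a segment whenever the reduction in within-segment sum of squared
    residuals exceeds ``penalty``; returns sorted interior breakpoints.
    """
    x = np.asarray(x, dtype=float)
    breaks: list[int] = []
    stack = [(0, len(x))]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 2 * min_size:
            continue
        gain, k = _best_split(x[lo:hi])
        if gain <= penalty or k < min_size or (hi - lo) - k < min_size:
            continue
        breaks.append(lo + k)
        stack.append((lo, lo + k))
        stack.append((lo + k, hi))
    return sorted(breaks)


def count_photobleach_steps(
    trace: Trace,
    background: float = 0.0,
    donor_unit: float | None = None,
    step_fraction: float = 0.5,
    penalty_factor: float = 10.0,
    min_size: int = 3,
) -> tuple[int, np.ndarray]:
    """Count downward photobleaching steps in total intensity.

    Change points come from penalized binary segmentation of the
    background-corrected total (donor + acceptor), with penalty
    ``penalty_factor * sigma^2 * log(n)`` (``sigma`` = robust noise SD).
    Only downward level changes of magnitude at least
    ``step_fraction * donor_unit`` count; a drop spanning several donor units
    (near-simultaneous bleaches merged into one change point) contributes
    ``round(magnitude / donor_unit)`` steps.  When ``donor_unit`` is not
    given it is estimated as the median of the smallest downward drops.

    Returns ``(step_count, step_times_s)``; a constant trace yields 0 steps.
    """
    x = np.asarray(trace.total, dtype=float) - background
    n = len(x)
    if n < 2 * min_size:
        return 0, np.array([])
    sigma = _robust_noise_sd(x)
    penalty = penalty_factor * max(sigma, 1e-12) ** 2 * np.log(n)
    breaks = binary_segmentation(x, penalty, min_size=min_size)
    if not breaks:
        return 0, np.array([])
    edges = [0, *breaks, n]
    means = np.array([x[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
    diffs = np.diff(means)
    down = -diffs[diffs < 0]
    if donor_unit is None:
        if len(down) == 0:
            return 0, np.array([])
        floor = max(3.0 * sigma, 1e-12)
        candidates = down[down > floor]
        if len(candidates) == 0:
            return 0, np.array([])
        smallest = candidates.min()
        donor_unit = float(np.median(candidates[candidates <= 1.5 * smallest]))
    count = 0
    times = []
    for i, dlev in enumerate(diffs):
        if dlev < 0 and -dlev >= step_fraction * donor_unit:
            k = max(1, int(round(-dlev / donor_unit)))
            count += k
            times.append(trace.time[breaks[i]])
    return count, np.array(times)


# ---------------------------------------------------------------------------
# Association / dissociation detection
# ---------------------------------------------------------------------------


def _signal_mask(
    total: np.ndarray, background: float | None, k: float, noise_sd: float | None
) -> tuple[np.ndarray, float]:
    x = np.asarray(total, dtype=float)
    if noise_sd is None:
        noise_sd = max(_robust_noise_sd(x), 1e-9)
    if background is None:
        # dim-cluster median: split at half range so the estimate holds even
        # when dark frames are a small minority of the trace
        cut = x.min() + 0.5 * (x.max() - x.min())
        dim = x[x <= cut]
        background = float(np.median(dim)) if dim.size else float(x.min())
    thr = background + k * noise_sd
    return x > thr, thr


def detect_association(
    trace: Trace,
    background: float | None = None,
    k: float = 5.0,
    w: int = 3,
    noise_sd: float | None = None,
) -> int | None:
    """First frame where total intensity rises and stays above background.

    The threshold is ``background + k * noise_sd``; the crossing must hold
    for ``w`` consecutive frames.  Returns ``None`` for a never-signal trace.
    ``background`` defaults to the median of the dimmest quartile of frames.
    """
    above, _ = _signal_mask(trace.total, background, k, noise_sd)
    if w > 1:
        run = np.convolve(above.astype(int), np.ones(w, dtype=int), mode="valid")
        hits = np.flatnonzero(run == w)
    else:
        hits = np.flatnonzero(above)
    return int(hits[0]) if hits.size else None


def detect_dissociation(
    trace: Trace,
    background: float | None = None,
    k: float = 5.0,
    w: int = 3,
    noise_sd: float | None = None,
    tol: float = 0.25,
) -> tuple[int | None, bool]:
    """Last sustained drop of total intensity to background.

    Returns ``(frame, single_step)`` where ``frame`` is the first dark frame
    of the final background epoch (``None`` if the signal never ends).
    ``single_step`` is True when at least ``(1 - tol)`` of the pre-drop level
    disappears within two frames — the signature of the intact trimer leaving
    DNA in one piece, as opposed to staged monomer loss or sequential
    photobleaching.
    """
    x = np.asarray(trace.total, dtype=float)
    above, _ = _signal_mask(x, background, k, noise_sd)
    hits = np.flatnonzero(above)
    if hits.size == 0 or hits[-1] == len(x) - 1:
        return None, False
    last_on = int(hits[-1])
    f = last_on + 1  # first dark frame
    # the reference level is the bound-epoch plateau, so staged loss of
    # subunits (or stepwise bleaching) before the final drop is not mistaken
    # for a one-piece departure
    plateau = float(np.median(x[hits]))
    post = float(np.mean(x[f : min(f + 2, len(x))]))
    two_before = x[max(f - 3, 0)]
    single = (
        plateau > 0
        and post <= tol * plateau
        and two_before >= (1.0 - tol) * plateau
    )
    return f, bool(single)


def count_spots_over_time(
    traces: Sequence[Trace],
    bin_s: float = 1.0,
    background: float | None = None,
    k: float = 5.0,
) -> pd.DataFrame:
    """Occupancy curve: number of traces with signal per time bin.

    A trace counts toward a bin when the majority of its frames in that bin
    sit above threshold.  Returns columns ``time_s`` (bin center), ``count``.
    """
    if not traces:
        return pd.DataFrame(columns=["time_s", "count"])
    t_max = max(tr.time[-1] for tr in traces)
    edges = np.arange(0.0, t_max + bin_s, bin_s)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.zeros(len(centers), dtype=int)
    for tr in traces:
        above, _ = _signal_mask(tr.total, background, k, None)
        idx = np.clip(np.digitize(tr.time, edges) - 1, 0, len(centers) - 1)
        for b in range(len(centers)):
            sel = idx == b
            if sel.any() and above[sel].mean() > 0.5:
                counts[b] += 1
    return pd.DataFrame({"time_s": centers, "count": counts})


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------


def select_traces(
    traces: Sequence[Trace],
    mode: str,
    background: float = 0.0,
    donor_unit: float | None = None,
    six_level: float | None = None,
    intensity_tol: float = 0.2,
    required_steps: int = 6,
    **step_kwargs,
) -> tuple[list[Trace], pd.DataFrame]:
    """Select analyzable traces and report every decision.

    ``loading`` mode keeps traces whose total intensity shows exactly
    ``required_steps`` photobleaching steps (the fully labelled trimer).
    ``unloading`` mode — where the molecule leaves before bleaching — keeps
    traces whose initial bound intensity lies within ``intensity_tol``
    (relative) of the calibrated six-donor level ``six_level``; if no
    calibration is given it is taken as the median initial intensity of the
    six-step traces in the pool, and its absence is an error.

    Returns ``(selected, report)``; the report has one row per input trace
    with columns ``trace_id, step_count, initial_intensity, passed, reason``.
    """
    if mode not in ("loading", "unloading"):
        raise ValueError(f"mode must be 'loading' or 'unloading', got {mode!r}")

    rows = []
    step_counts = []
    initial = []
    for tr in traces:
        cnt, _ = count_photobleach_steps(
            tr, background=background, donor_unit=donor_unit, **step_kwargs
        )
        step_counts.append(cnt)
        assoc = detect_association(tr, background=background if background else None)
        if assoc is None:
            initial.append(np.nan)
        else:
            hi = min(assoc + 5, tr.n_frames)
            initial.append(float(np.median(tr.total[assoc:hi])) - background)

    if mode == "unloading" and six_level is None:
        ref = [
            ini
            for cnt, ini in zip(step_counts, initial)
            if cnt == required_steps and np.isfinite(ini)
        ]
        if not ref:
            raise ValueError(
                "unloading selection needs a six-donor intensity calibration: "
                "pass six_level or include six-step traces in the pool"
            )
        six_level = float(np.median(ref))

    selected = []
    for tr, cnt, ini in zip(traces, step_counts, initial):
        if mode == "loading":
            ok = cnt == required_steps
            reason = "" if ok else f"step_count={cnt}"
        else:
            if not np.isfinite(ini):
                ok, reason = False, "no_signal"
            else:
                rel = abs(ini - six_level) / six_level
                ok = rel <= intensity_tol
                reason = "" if ok else f"intensity_off_by={rel:.2f}"
        rows.append(
            {
                "trace_id": tr.trace_id,
                "step_count": cnt,
                "initial_intensity": ini,
                "passed": ok,
                "reason": reason,
            }
        )
        if ok:
            selected.append(tr)
    report = pd.DataFrame(
        rows, columns=["trace_id", "step_count", "initial_intensity", "passed", "reason"]
    )
    return selected, report


# ---------------------------------------------------------------------------
# One-stop QC for the pipeline
# ---------------------------------------------------------------------------


def prepare_fret_trace(
    trace: Trace,
    background_donor: float = 0.0,
    background_acceptor: float = 0.0,
    donor_unit: float | None = None,
    mode: str = "loading",
    **step_kwargs,
) -> FretTrace:
    """Compute FRET and set the analyzable valid window for one trace.

    The window opens at the detected association frame (0 if the trace starts
    bound) and closes at the first photobleaching step (loading mode) or at
    the detected dissociation frame (unloading mode), whichever applies;
    annotations record the association/dissociation frames, step count and
    step times.
    """
    bg = background_donor + background_acceptor
    ft = compute_fret(trace, background_donor, background_acceptor)
    n_steps, step_times = count_photobleach_steps(
        trace, background=bg, donor_unit=donor_unit, **step_kwargs
    )
    assoc = detect_association(trace, background=bg)
    dissoc, single = detect_dissociation(trace, background=bg)

    start = assoc if assoc is not None else 0
    end = trace.n_frames
    if mode == "loading" and len(step_times):
        first_bleach = int(np.searchsorted(trace.time, step_times[0]))
        end = min(end, first_bleach)
    if mode == "unloading" and dissoc is not None:
        end = min(end, dissoc)
    if end < start:
        end = start
    ft.valid_start, ft.valid_end = start, end
    ft.annotations.update(
        {
            "association_frame": assoc,
            "dissociation_frame": dissoc,
            "single_step_dissociation": single,
            "step_count": n_steps,
            "step_times": step_times,
        }
    )
    return ft
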