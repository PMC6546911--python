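"""Forward photophysics model: state paths -> intensity traces -> movies.

The clamp carries up to six donor dyes (two labelling sites per monomer of the
homotrimer, each occupied with probability ``label_prob``); the DNA carries a
single acceptor.  With ``n`` active donors in a bound state of FRET efficiency
``E`` the expected per-frame photon counts are

    donor    = n * donor_brightness * (1 - E) + background_donor
    acceptor = n * donor_brightness * E * gamma + background_acceptor

so the background-corrected total ``donor + acceptor`` is independent of the
FRET state (gamma = 1) and drops by one ``donor_brightness`` unit each time a
donor photobleaches — the basis of photobleaching step counting.  Donors
bleach independently with exponential lifetimes; observed counts are Poisson
shot noise plus Gaussian read noise.  Unbound/released frames emit background
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .kinetics import NO_SIGNAL_STATES, StatePath

__all__ = [
    "PhotophysicsModel",
    "Trace",
    "FieldGeometry",
    "render_trace",
    "render_movie",
]


@dataclass
class PhotophysicsModel:
    """Labelling, brightness, bleaching and noise parameters.

    Defaults emulate the labelled homotrimer: 2 sites per monomer, 3 monomers,
    60% site occupancy (1.2 donors per monomer on average).  ``gamma`` is the
    acceptor/donor detection-correction factor (1 = no correction).
    """

    sites_per_monomer: int = 2
    monomers: int = 3
    label_prob: float = 0.6
    donor_brightness: float = 200.0   # photons/frame per active donor at E = 0
    donor_bleach_rate: float = 0.01   # s^-1 per donor
    acceptor_bleach_rate: float | None = None  # None = acceptor never bleaches
    background_donor: float = 50.0    # photons/frame
    background_acceptor: float = 50.0
    read_noise_sd: float = 3.0        # photons, Gaussian
    frame_interval: float = 0.1       # s
    gamma: float = 1.0

    @property
    def max_donors(self) -> int:
        return self.sites_per_monomer * self.monomers

    @property
    def six_donor_level(self) -> float:
        """Expected background-corrected total intensity with all sites labelled."""
        return self.max_donors * self.donor_brightness

    def validate(self) -> None:
        if not (0.0 <= self.label_prob <= 1.0):
            raise ValueError(f"label_prob={self.label_prob} not in [0, 1]")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        for name in (
            "donor_brightness",
            "donor_bleach_rate",
            "background_donor",
            "background_acceptor",
            "read_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class Trace:
    """Per-molecule two-channel intensity time series.

    ``meta`` records ground truth when simulated: true donor count, bleach
    times, association/dissociation frames and the per-frame state labels.
    """

    trace_id: str
    time: np.ndarray        # frame-center times, s (uniform spacing)
    donor: np.ndarray
    acceptor: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if not (len(self.time) == len(self.donor) == len(self.acceptor)):
            raise ValueError("time, donor and acceptor must have equal length")

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @property
    def frame_interval(self) -> float:
        return float(self.time[1] - self.time[0]) if self.n_frames > 1 else np.nan

    @property
    def total(self) -> np.ndarray:
        return self.donor + self.acceptor

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trace_id": self.trace_id,
                "frame": np.arange(self.n_frames),
                "time_s": self.time,
                "donor": self.donor,
                "acceptor": self.acceptor,
            }
        )


MAX_FRAMES = 5_000_000


def render_trace(
    path: StatePath,
    model: PhotophysicsModel,
    seed: int | np.random.Generator | None = None,
    n_donors: int | None = None,
    noise: bool = True,
    trace_id: str = "trace0",
    fret_mean: dict[str, float] | None = None,
) -> Trace:
    """Render a state path into a donor/acceptor intensity trace.

    The donor count is Binomial(sites, label_prob) unless fixed through
    ``n_donors``; each donor receives an independent exponential bleach time
    (clock starts at frame 0, i.e. at illumination onset).  The state is
    evaluated at frame centers.  ``fret_mean`` maps bound-state labels to
    their mean FRET efficiency (defaults to the standard scenario means).
    With ``noise=False`` the expected photon counts are returned directly
    (no shot or read noise).
    """
    model.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_frames = int(round(path.total_duration / model.frame_interval))
    if n_frames > MAX_FRAMES:
        raise ValueError(
            f"path of {path.total_duration} s at {model.frame_interval} s/frame "
            f"needs {n_frames} frames (> {MAX_FRAMES})"
        )
    t = (np.arange(n_frames) + 0.5) * model.frame_interval

    if n_donors is None:
        n0 = int(rng.binomial(model.max_donors, model.label_prob))
    else:
        n0 = int(n_donors)
    bleach_times = np.sort(
        rng.exponential(1.0 / model.donor_bleach_rate, size=n0)
        if model.donor_bleach_rate > 0
        else np.full(n0, np.inf)
    )
    n_active = (t[:, None] < bleach_times[None, :]).sum(axis=1).astype(float)

    states = path.state_at(t)
    bound = np.array([s not in NO_SIGNAL_STATES for s in states])
    if fret_mean is None:
        from .kinetics import DEFAULT_FRET_MEANS

        fret_mean = DEFAULT_FRET_MEANS
    e = np.array([fret_mean.get(s, 0.0) for s in states], dtype=float)
    e[~bound] = 0.0

    if model.acceptor_bleach_rate:
        acceptor_alive = t < rng.exponential(1.0 / model.acceptor_bleach_rate)
    else:
        acceptor_alive = np.ones(n_frames, dtype=bool)
    e_eff = np.where(acceptor_alive, e, 0.0)

    sig = n_active * model.donor_brightness * bound
    exp_donor = sig * (1.0 - e_eff) + model.background_donor
    exp_acceptor = sig * e_eff * model.gamma + model.background_acceptor

    if noise:
        donor = rng.poisson(exp_donor).astype(float)
        acceptor = rng.poisson(exp_acceptor).astype(float)
        if model.read_noise_sd > 0:
            donor += rng.normal(0.0, model.read_noise_sd, n_frames)
            acceptor += rng.normal(0.0, model.read_noise_sd, n_frames)
    else:
        donor, acceptor = exp_donor, exp_acceptor

    bound_idx = np.flatnonzero(bound)
    assoc = int(bound_idx[0]) if bound_idx.size else None
    released = np.flatnonzero(np.array([s == "RELEASED" for s in states]))
    dissoc = int(released[0]) if released.size else None

    return Trace(
        trace_id=trace_id,
        time=t,
        donor=donor,
        acceptor=acceptor,
        meta={
            "scheme": path.scheme_name,
            "seed": None if isinstance(seed, np.random.Generator) else seed,
            "n_donors": n0,
            "bleach_times": bleach_times,
            "true_assoc_frame": assoc,
            "true_dissoc_frame": dissoc,
            "true_states": states,
            "true_fret": np.where(bound, e, np.nan),
        },
    )


# ---------------------------------------------------------------------------
# Movie rendering
# ---------------------------------------------------------------------------


@dataclass
class FieldGeometry:
    """Imaging field: size in pixels and per-pixel background photon rate."""

    width: int = 128
    height: int = 128
    background_per_pixel: float = 2.0


def _place_spots(
    n: int,
    field: FieldGeometry,
    min_sep: float,
    rng: np.random.Generator,
    margin: float | None = None,
) -> np.ndarray:
    """Uniform random positions with enforced minimum pairwise separation."""
    if margin is None:
        # leave room for an extraction annulus at every spot
        margin = max(min_sep, 10.0)
    pos: list[np.ndarray] = []
    attempts = 0
    while len(pos) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise ValueError(
                f"cannot place {n} spots at separation {min_sep:.1f}px in a "
                f"{field.width}x{field.height} field"
            )
        cand = np.array(
            [
                rng.uniform(margin, field.width - margin),
                rng.uniform(margin, field.height - margin),
            ]
        )
        if all(np.hypot(*(cand - p)) >= min_sep for p in pos):
            pos.append(cand)
    return np.array(pos)


def _gaussian_spot_profiles(
    positions: np.ndarray, sigma: float, width: int, height: int
) -> list[tuple[slice, slice, np.ndarray]]:
    """Pixel-integrated unit-mass Gaussian footprint per spot (local window)."""
    half = int(np.ceil(4 * sigma))
    out = []
    for x, y in positions:
        x0, x1 = max(0, int(x) - half), min(width, int(x) + half + 1)
        y0, y1 = max(0, int(y) - half), min(height, int(y) + half + 1)
        xs = np.arange(x0, x1)
        ys = np.arange(y0, y1)
        # integral of the PSF over each pixel via the normal CDF; pixel i
        # spans [i - 0.5, i + 0.5) so integer coordinates are pixel centers
        gx = ndtr((xs + 0.5 - x) / sigma) - ndtr((xs - 0.5 - x) / sigma)
        gy = ndtr((ys + 0.5 - y) / sigma) - ndtr((ys - 0.5 - y) / sigma)
        out.append((slice(y0, y1), slice(x0, x1), np.outer(gy, gx)))
    return out


def render_movie(
    traces: Sequence[Trace],
    field: FieldGeometry,
    psf_sigma: float = 1.5,
    seed: int | np.random.Generator | None = None,
    positions: np.ndarray | None = None,
    read_noise_sd: float = 3.0,
    noise: bool = True,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render traces as immobile diffraction-limited spots in two channels.

    Each trace becomes one Gaussian spot at the same position in both
    channels (registered optics); the per-frame spot amplitude is that
    frame's channel intensity, interpreted as total photons in the point
    spread function.  Traces should be rendered noiseless with zero
    trace-level background — shot noise and read noise are applied here at
    the pixel level.  Returns (donor_stack, acceptor_stack, ground-truth
    sidecar with one row per trace).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if traces and len({tr.n_frames for tr in traces}) != 1:
        raise ValueError("all traces must have the same number of frames")
    n_frames = traces[0].n_frames if traces else 1

    if positions is None:
        positions = _place_spots(len(traces), field, 4.0 * psf_sigma, rng)
    else:
        positions = np.asarray(positions, dtype=float)
        if len(positions) != len(traces):
            raise ValueError("positions and traces length mismatch")

    stacks = []
    for channel in ("donor", "acceptor"):
        stack = np.full(
            (n_frames, field.height, field.width), field.background_per_pixel
        )
        if traces:
            profiles = _gaussian_spot_profiles(
                positions, psf_sigma, field.width, field.height
            )
            for tr, (sy, sx, prof) in zip(traces, profiles):
                amp = getattr(tr, channel)
                stack[:, sy, sx] += amp[:, None, None] * prof[None, :, :]
        if noise:
            stack = rng.poisson(stack).astype(float)
            if read_noise_sd > 0:
                stack = stack + rng.normal(0.0, read_noise_sd, stack.shape)
        stacks.append(stack)

    sidecar = pd.DataFrame(
        {
            "trace_id": [tr.trace_id for tr in traces],
            "x": positions[:, 0] if len(traces) else np.array([]),
            "y": positions[:, 1] if len(traces) else np.array([]),
        }
    )
    return stacks[0], stacks[1], sidecar
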