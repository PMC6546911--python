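"""Continuous-time Markov simulation of sliding-clamp loading and unloading.

The clamp (a homotrimeric ring such as PCNA) is loaded onto primed DNA by a
clamp loader and removed by an unloader complex.  Single-molecule FRET between
dyes on the clamp and a dye on the DNA resolves a small set of bound states:

* ``LI1`` — first loading intermediate (open clamp-loader complex on DNA),
  short-lived, mid FRET;
* ``LI2`` — second loading intermediate (closed clamp before loader release),
  longer-lived, high FRET;
* ``LS``  — loaded state (clamp alone encircling DNA), low FRET;
* ``UI``  — unloading intermediate (unloader engaged), high FRET, traversed
  through multiple hidden catalytic sub-steps so its dwell is Erlang rather
  than exponential.

``UNBOUND`` and ``RELEASED`` book-end the bound states and emit no FRET.

This module holds the generative model: a :class:`KineticScheme` (labelled
states, FRET means, first-order rate matrix, per-state sub-step counts) and an
exact stochastic (Gillespie) sampler producing :class:`StatePath` trajectories.
Dwells in a state with total exit rate ``R`` and ``m`` sub-steps are drawn
Erlang(m, m*R), preserving the mean ``1/R``; the successor state is chosen with
probability proportional to its rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KineticScheme",
    "StatePath",
    "simulate_state_path",
    "make_scenario",
    "SCENARIO_NAMES",
    "NO_SIGNAL_STATES",
]

#: states that emit no fluorescence signal (clamp absent from the DNA spot)
NO_SIGNAL_STATES = frozenset({"UNBOUND", "RELEASED"})

SCENARIO_NAMES = (
    "loading_atp",
    "loading_atpgs",
    "unloading_atp",
    "unloading_atpgs",
    "unloading_inactive",
)


class SchemeError(ValueError):
    """A kinetic scheme violated one of its invariants."""


@dataclass
class KineticScheme:
    """Labelled-state continuous-time Markov scheme for clamp cycling.

    Parameters
    ----------
    state_labels
        Ordered state names, e.g. ``("UNBOUND", "LI1", "LI2", "LS")``.
    fret_mean
        Mean FRET efficiency per *bound* state, each in [0, 1].  States in
        :data:`NO_SIGNAL_STATES` must not appear here.
    rates
        Square matrix of first-order rates (s^-1); ``rates[i, j]`` is the
        rate from state ``i`` to state ``j``.  Off-diagonal entries are
        non-negative; the diagonal is unused.
    substeps
        Number of hidden irreversible sub-steps traversed within each state
        (>= 1).  A state with ``m`` sub-steps has an Erlang(m) dwell with the
        same mean as the plain exponential.  States omitted default to 1.
    initial_state
        Label the trajectory starts in.
    """

    state_labels: tuple[str, ...]
    fret_mean: dict[str, float]
    rates: np.ndarray
    substeps: dict[str, int] = field(default_factory=dict)
    initial_state: str = "UNBOUND"
    name: str = "custom"

    def __post_init__(self) -> None:
        self.state_labels = tuple(self.state_labels)
        self.rates = np.asarray(self.rates, dtype=float)

    # -- derived quantities -------------------------------------------------

    def index(self, label: str) -> int:
        return self.state_labels.index(label)

    def exit_rate(self, label: str) -> float:
        i = self.index(label)
        out = self.rates[i].copy()
        out[i] = 0.0
        return float(out.sum())

    @property
    def absorbing(self) -> frozenset[str]:
        """States with zero total exit rate."""
        return frozenset(s for s in self.state_labels if self.exit_rate(s) == 0.0)

    def n_substeps(self, label: str) -> int:
        return int(self.substeps.get(label, 1))

    def with_rate(self, src: str, dst: str, rate: float) -> "KineticScheme":
        """Return a copy with one transition rate replaced."""
        rates = self.rates.copy()
        rates[self.index(src), self.index(dst)] = rate
        return replace(self, rates=rates)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        k = len(self.state_labels)
        if len(set(self.state_labels)) != k:
            raise SchemeError("state labels must be unique")
        if self.rates.shape != (k, k):
            raise SchemeError(
                f"rate matrix shape {self.rates.shape} does not match {k} states"
            )
        off = self.rates.copy()
        np.fill_diagonal(off, 0.0)
        if not np.all(np.isfinite(off)):
            raise SchemeError("invariant violated: rates must be finite")
        if np.any(off < 0):
            raise SchemeError("invariant violated: off-diagonal rates must be >= 0")
        if self.initial_state not in self.state_labels:
            raise SchemeError(f"initial state {self.initial_state!r} not in labels")
        for s, e in self.fret_mean.items():
            if s in NO_SIGNAL_STATES:
                raise SchemeError(
                    f"invariant violated: no-signal state {s!r} carries a FRET mean"
                )
            if s not in self.state_labels:
                raise SchemeError(f"FRET mean given for unknown state {s!r}")
            if not (0.0 <= e <= 1.0):
                raise SchemeError(f"invariant violated: fret_mean[{s!r}]={e} not in [0,1]")
        for s in self.state_labels:
            if s not in NO_SIGNAL_STATES and s not in self.fret_mean:
                raise SchemeError(f"invariant violated: bound state {s!r} lacks a FRET mean")
        for s, m in self.substeps.items():
            if s not in self.state_labels:
                raise SchemeError(f"substeps given for unknown state {s!r}")
            if int(m) < 1:
                raise SchemeError(f"invariant violated: substeps[{s!r}]={m} must be >= 1")

    def rate_table(self) -> pd.DataFrame:
        """Non-zero transition rates as a tidy table (src, dst, rate_per_s)."""
        rows = []
        for i, a in enumerate(self.state_labels):
            for j, b in enumerate(self.state_labels):
                if i != j and self.rates[i, j] > 0:
                    rows.append({"src": a, "dst": b, "rate_per_s": self.rates[i, j]})
        return pd.DataFrame(rows, columns=["src", "dst", "rate_per_s"])


@dataclass
class StatePath:
    """One sampled trajectory: ordered (entry_time_s, state) events.

    ``events`` starts at time 0 in the initial state; entry times are strictly
    increasing.  The path ends either in an absorbing state or truncated at
    ``total_duration``.
    """

    events: list[tuple[float, str]]
    total_duration: float
    seed: int | None = None
    scheme_name: str = "custom"

    @property
    def entry_times(self) -> np.ndarray:
        return np.array([t for t, _ in self.events], dtype=float)

    @property
    def states(self) -> list[str]:
        return [s for _, s in self.events]

    def state_at(self, times: np.ndarray) -> np.ndarray:
        """Occupied state label at each query time (vectorized)."""
        times = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.entry_times, times, side="right") - 1
        idx = np.clip(idx, 0, len(self.events) - 1)
        labels = np.array(self.states, dtype=object)
        return labels[idx]

    def dwell_of(self, state: str) -> list[float]:
        """Durations of every completed visit to ``state`` (truncated final
        visits are excluded)."""
        out = []
        for k, (t, s) in enumerate(self.events):
            if s != state:
                continue
            if k + 1 < len(self.events):
                out.append(self.events[k + 1][0] - t)
        return out

    def visited(self, state: str) -> bool:
        return state in self.states

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["entry_time_s", "state"])


def simulate_state_path(
    scheme: KineticScheme,
    duration: float,
    seed: int | np.random.Generator | None = None,
) -> StatePath:
    """Sample one trajectory by exact stochastic simulation.

    The dwell in a state with total exit rate ``R`` and ``m`` sub-steps is the
    sum of ``m`` independent Exponential(m*R) sub-dwells, i.e. Erlang(m, m*R),
    so the mean dwell ``1/R`` is preserved while the shape sharpens.  The
    successor is drawn with probability proportional to its rate.  The path is
    truncated at ``duration`` seconds.

    Identical ``(scheme, duration, seed)`` gives a bit-identical path.
    """
    if not np.isfinite(duration) or duration <= 0:
        raise ValueError(f"duration must be a positive finite number, got {duration}")
    scheme.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = seed if isinstance(seed, (int, np.integer)) else None

    labels = scheme.state_labels
    t = 0.0
    state = scheme.initial_state
    events: list[tuple[float, str]] = [(0.0, state)]
    while True:
        i = scheme.index(state)
        out = scheme.rates[i].copy()
        out[i] = 0.0
        total = out.sum()
        if total < 1e-300:  # absorbing (or numerically so)
            break
        m = scheme.n_substeps(state)
        # Erlang(m, m*total): numpy's gamma uses shape/scale
        dwell = rng.gamma(shape=m, scale=1.0 / (m * total))
        t += dwell
        if t >= duration:
            break
        j = rng.choice(len(labels), p=out / total)
        state = labels[j]
        events.append((t, state))
    return StatePath(
        events=events,
        total_duration=float(duration),
        seed=seed_val,
        scheme_name=scheme.name,
    )


# ---------------------------------------------------------------------------
# Named scenarios
# ---------------------------------------------------------------------------

#: default mean FRET efficiency of each bound state
DEFAULT_FRET_MEANS = {"LI1": 0.48, "LI2": 0.62, "LS": 0.34, "UI": 0.58}

#: default mean dwell times (s); rate constants are their reciprocals
DEFAULT_TAU = {"LI1": 0.5, "LI2": 1.5, "LS_unloading": 3.0, "UI": 2.0}

#: reverse transitions run at this fraction of the forward rate by default
DEFAULT_REVERSE_FRACTION = 0.1

#: association rate after flow-in (s^-1)
DEFAULT_K_ASSOC = 0.5


def make_scenario(
    name: str,
    fret_means: Mapping[str, float] | None = None,
    tau: Mapping[str, float] | None = None,
    reverse_fraction: float = DEFAULT_REVERSE_FRACTION,
    k_assoc: float = DEFAULT_K_ASSOC,
    ui_substeps: int = 2,
    rate_overrides: Mapping[tuple[str, str], float] | None = None,
) -> KineticScheme:
    """Build a fully parameterized scheme for a named experimental condition.

    Scenarios
    ---------
    ``loading_atp``
        Flow-in loading with ATP: UNBOUND -> LI1 -> LI2 -> LS, with reverse
        transitions at ``reverse_fraction`` of the forward rates.
    ``loading_atpgs``
        Loading with the non-hydrolysable analog ATP-gamma-S: the LI1 -> LI2
        step (which requires ATP hydrolysis) is removed, so the complex stalls
        at the LI1 FRET level.
    ``unloading_atp`` / ``unloading_atpgs``
        Pre-loaded clamp plus unloader: LS <-> UI -> RELEASED, with UI
        traversed through ``ui_substeps`` hidden sub-steps (Erlang dwell).
        Unloading does not require hydrolysis, so both analogs share the
        same default kinetics.
    ``unloading_inactive``
        Catalytically dead unloader: LS has no exit (absorbing).

    All rates derive from mean dwell times ``tau`` (seconds) and can be
    overridden individually through ``rate_overrides`` keyed by
    ``(src, dst)`` label pairs.
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
        )
    means = dict(DEFAULT_FRET_MEANS)
    if fret_means:
        means.update(fret_means)
    taus = dict(DEFAULT_TAU)
    if tau:
        taus.update(tau)

    if name.startswith("loading"):
        labels = ("UNBOUND", "LI1", "LI2", "LS")
        k = {s: i for i, s in enumerate(labels)}
        rates = np.zeros((4, 4))
        rates[k["UNBOUND"], k["LI1"]] = k_assoc
        k_li1 = 1.0 / taus["LI1"]
        k_li2 = 1.0 / taus["LI2"]
        rates[k["LI1"], k["LI2"]] = k_li1
        rates[k["LI2"], k["LS"]] = k_li2
        rates[k["LI2"], k["LI1"]] = reverse_fraction * k_li1
        rates[k["LS"], k["LI2"]] = reverse_fraction * k_li2
        if name == "loading_atpgs":
            # hydrolysis-dependent step removed: complex stalls in LI1
            rates[k["LI1"], k["LI2"]] = 0.0
            rates[k["LI2"], k["LI1"]] = 0.0
        scheme = KineticScheme(
            state_labels=labels,
            fret_mean={s: means[s] for s in ("LI1", "LI2", "LS")},
            rates=rates,
            substeps={},
            initial_state="UNBOUND",
            name=name,
        )
    else:
        labels = ("LS", "UI", "RELEASED")
        k = {s: i for i, s in enumerate(labels)}
        rates = np.zeros((3, 3))
        if name != "unloading_inactive":
            k_ls = 1.0 / taus["LS_unloading"]
            k_ui = 1.0 / taus["UI"]
            rates[k["LS"], k["UI"]] = k_ls
            # split the UI exit so the total keeps the configured mean dwell
            k_rev = reverse_fraction * k_ls
            rates[k["UI"], k["LS"]] = k_rev
            rates[k["UI"], k["RELEASED"]] = max(k_ui - k_rev, 0.0)
        scheme = KineticScheme(
            state_labels=labels,
            fret_mean={s: means[s] for s in ("LS", "UI")},
            rates=rates,
            substeps={"UI": int(ui_substeps)} if name != "unloading_inactive" else {},
            initial_state="LS",
            name=name,
        )

    if rate_overrides:
        for (src, dst), r in rate_overrides.items():
            scheme = scheme.with_rate(src, dst, r)
        scheme.name = name
    scheme.validate()
    return scheme
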