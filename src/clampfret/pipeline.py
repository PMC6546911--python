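"""Run configuration and the staged pipeline
(simulate -> detect -> qc -> infer -> analyze -> report).

A single master seed deterministically spawns per-stage and per-trace
substreams, so re-running with the same config reproduces identical outputs.
Stage artifacts are returned in memory and, when an output directory is set,
also written as CSV/JSON alongside a run manifest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, hmm, io, qc
from .kinetics import SCENARIO_NAMES, make_scenario, simulate_state_path
from .photophysics import PhotophysicsModel, render_trace

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "detect", "qc", "infer", "analyze", "report")


@dataclass
class RunConfig:
    """Flat, serializable configuration for one pipeline run.

    Every key round-trips losslessly through the YAML config file; ``seed``
    fully determines all stochastic stages.  ``None`` means "derive a
    sensible value from the scenario" where noted.
    """

    # scenario / kinetics
    scenario: str = "loading_atp"
    n_traces: int = 300
    duration_s: float | None = None   # None: 300 s loading, 60 s unloading
    tau_li1: float = 0.5
    tau_li2: float = 1.5
    tau_ls_unloading: float = 3.0
    tau_ui: float = 2.0
    reverse_fraction: float = 0.1
    k_assoc: float = 0.5
    ui_substeps: int = 2
    fret_li1: float = 0.48
    fret_li2: float = 0.62
    fret_ls: float = 0.34
    fret_ui: float = 0.58

    # photophysics
    label_prob: float = 0.6
    n_donors_fixed: int | None = None   # None: Binomial(6, label_prob)
    donor_brightness: float = 200.0
    donor_bleach_rate: float = 0.01
    background_donor: float = 50.0
    background_acceptor: float = 50.0
    read_noise_sd: float = 3.0
    frame_interval: float = 0.1

    # qc
    intensity_tol: float = 0.2
    step_penalty_factor: float = 10.0
    required_steps: int = 6

    # hmm
    k_states: int | None = None         # None: 3 for loading, 2 for unloading
    n_restarts: int = 5
    hmm_tol: float = 1e-6
    hmm_max_iter: int = 300

    # analysis
    tdp_window_s: float = 6.0
    heatmap_t_bin: float = 0.2
    heatmap_e_bin: float = 0.02
    tdp_e_bin: float = 0.02
    dwell_t_min: float | None = None    # None: 1.5 frame intervals
    dwell_bin_s: float = 0.25

    # bookkeeping
    seed: int = 0
    outdir: str | None = None

    # -- derived ------------------------------------------------------------

    @property
    def mode(self) -> str:
        return "loading" if self.scenario.startswith("loading") else "unloading"

    @property
    def effective_duration(self) -> float:
        if self.duration_s is not None:
            return self.duration_s
        return 300.0 if self.mode == "loading" else 60.0

    @property
    def effective_k(self) -> int:
        if self.k_states is not None:
            return self.k_states
        return 3 if self.mode == "loading" else 2

    @property
    def effective_dwell_t_min(self) -> float:
        if self.dwell_t_min is not None:
            return self.dwell_t_min
        return 1.5 * self.frame_interval

    @property
    def total_background(self) -> float:
        return self.background_donor + self.background_acceptor

    def fret_means(self) -> dict[str, float]:
        return {
            "LI1": self.fret_li1,
            "LI2": self.fret_li2,
            "LS": self.fret_ls,
            "UI": self.fret_ui,
        }

    def scheme(self):
        return make_scenario(
            self.scenario,
            fret_means=self.fret_means(),
            tau={
                "LI1": self.tau_li1,
                "LI2": self.tau_li2,
                "LS_unloading": self.tau_ls_unloading,
                "UI": self.tau_ui,
            },
            reverse_fraction=self.reverse_fraction,
            k_assoc=self.k_assoc,
            ui_substeps=self.ui_substeps,
        )

    def photophysics(self) -> PhotophysicsModel:
        return PhotophysicsModel(
            label_prob=self.label_prob,
            donor_brightness=self.donor_brightness,
            donor_bleach_rate=self.donor_bleach_rate,
            background_donor=self.background_donor,
            background_acceptor=self.background_acceptor,
            read_noise_sd=self.read_noise_sd,
            frame_interval=self.frame_interval,
        )

    # -- validation / serialization -----------------------------------------

    def validate(self) -> None:
        if self.scenario not in SCENARIO_NAMES:
            raise ValueError(
                f"config key 'scenario': unknown value {self.scenario!r}"
            )
        if self.n_traces < 1:
            raise ValueError("config key 'n_traces': must be >= 1")
        if self.frame_interval <= 0:
            raise ValueError("config key 'frame_interval': must be > 0")
        for key in ("tau_li1", "tau_li2", "tau_ls_unloading", "tau_ui"):
            if getattr(self, key) <= 0:
                raise ValueError(f"config key {key!r}: must be > 0")
        for key in ("fret_li1", "fret_li2", "fret_ls", "fret_ui"):
            v = getattr(self, key)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"config key {key!r}: {v} not in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls.from_dict(io.load_config_file(path))

    def to_file(self, path) -> None:
        io.save_config_file(self.to_dict(), path)


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: RunConfig, seed_seq: np.random.SeedSequence) -> dict:
    scheme = cfg.scheme()
    model = cfg.photophysics()
    traces = []
    children = seed_seq.spawn(cfg.n_traces)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        path = simulate_state_path(scheme, cfg.effective_duration, rng)
        traces.append(
            render_trace(
                path,
                model,
                seed=rng,
                n_donors=cfg.n_donors_fixed,
                trace_id=f"trace{i:05d}",
                fret_mean=scheme.fret_mean,
            )
        )
    return {"traces": traces, "scheme": scheme, "photophysics": model}


def _stage_qc(cfg: RunConfig, art: dict) -> dict:
    traces = art["traces"]
    bg = cfg.total_background
    model = art.get("photophysics") or cfg.photophysics()
    selected, report = qc.select_traces(
        traces,
        mode=cfg.mode,
        background=bg,
        donor_unit=cfg.donor_brightness,
        six_level=model.six_donor_level,
        intensity_tol=cfg.intensity_tol,
        required_steps=cfg.required_steps,
        penalty_factor=cfg.step_penalty_factor,
    )
    fret_traces = [
        qc.prepare_fret_trace(
            tr,
            background_donor=cfg.background_donor,
            background_acceptor=cfg.background_acceptor,
            donor_unit=cfg.donor_brightness,
            mode=cfg.mode,
            penalty_factor=cfg.step_penalty_factor,
        )
        for tr in selected
    ]
    fret_traces = [ft for ft in fret_traces if len(ft.window_efficiency) >= 2]
    return {"selected": selected, "selection_report": report, "fret_traces": fret_traces}


def _stage_infer(cfg: RunConfig, art: dict, seed_seq: np.random.SeedSequence) -> dict:
    fret_traces = art["fret_traces"]
    if not fret_traces:
        raise RuntimeError("no traces survived QC; cannot fit the HMM")
    seed = int(seed_seq.generate_state(1)[0] % (2**31))
    results = hmm.fit_hmm(
        fret_traces,
        cfg.effective_k,
        tol=cfg.hmm_tol,
        max_iter=cfg.hmm_max_iter,
        seed=seed,
        n_restarts=cfg.n_restarts,
    )
    decoded = results.decode_all(fret_traces)
    return {"hmm": results, "decoded": decoded}


def _stage_analyze(cfg: RunConfig, art: dict) -> dict:
    fret_traces = art["fret_traces"]
    results = art["hmm"]
    decoded = art["decoded"]
    anchor = "association" if cfg.mode == "loading" else "dissociation"
    synced = analysis.synchronize(fret_traces, anchor)
    hm = analysis.heatmap(
        synced, t_bin=cfg.heatmap_t_bin, e_bin=cfg.heatmap_e_bin
    )
    side = "first" if cfg.mode == "loading" else "last"
    tdp_hist = analysis.tdp(
        decoded,
        frame_interval=cfg.frame_interval,
        window_s=cfg.tdp_window_s,
        side=side,
        e_bin=cfg.tdp_e_bin,
    )
    # dwell tables + fits for the kinetically informative states
    want = ("LI1", "LI2") if cfg.mode == "loading" else ("UI",)
    means = cfg.fret_means()
    dwell_tables: dict[str, pd.DataFrame] = {}
    dwell_fits: dict[str, analysis.DwellFitResults] = {}
    for label in want:
        idx = results.nearest_state(means[label])
        table = analysis.dwell_times(
            decoded,
            idx,
            cfg.frame_interval,
            start_is_entry=(cfg.mode == "loading"),
            end_is_exit=(cfg.mode == "unloading"),
        )
        dwell_tables[label] = table
        try:
            dwell_fits[label] = analysis.fit_dwells(
                table, "exponential", t_min=cfg.effective_dwell_t_min
            )
        except ValueError:
            pass  # too few dwells; table still reported
    return {
        "synced": synced,
        "heatmap": hm,
        "tdp": tdp_hist,
        "dwell_tables": dwell_tables,
        "dwell_fits": dwell_fits,
    }


def _stage_report(cfg: RunConfig, art: dict, outdir: Path | None) -> dict:
    lines = [f"scenario: {cfg.scenario}   mode: {cfg.mode}   seed: {cfg.seed}"]
    rep = art.get("selection_report")
    if rep is not None:
        lines.append(
            f"traces: {len(rep)} simulated, {int(rep['passed'].sum())} selected"
        )
    if "hmm" in art:
        lines.append("")
        lines.append(art["hmm"].summary())
    for label, fit in art.get("dwell_fits", {}).items():
        lines.append("")
        lines.append(f"[{label}] " + fit.summary().replace("\n", "\n    "))
    text = "\n".join(lines)
    if outdir is not None:
        (outdir / "summary.txt").write_text(text + "\n")
        try:
            from . import plotting

            if "heatmap" in art:
                plotting.save_heatmap(art["heatmap"], outdir / "heatmap.png")
            if "tdp" in art:
                plotting.save_tdp(art["tdp"], outdir / "tdp.png")
        except Exception as exc:  # plotting must never sink a run
            (outdir / "plot_errors.txt").write_text(str(exc) + "\n")
    return {"summary": text}


def _write_artifacts(cfg: RunConfig, art: dict, outdir: Path, done: list[str]) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    if "traces" in art:
        io.write_traces(art["traces"], outdir / "traces.csv")
        io.write_sidecar(art["traces"], outdir / "truth.csv")
    if "selection_report" in art:
        art["selection_report"].to_csv(outdir / "selection_report.csv", index=False)
    if "hmm" in art:
        io.write_manifest(art["hmm"].to_dict(), outdir / "hmm_model.json")
        rows = []
        for path in art["decoded"]:
            rows.append(
                pd.DataFrame(
                    {
                        "trace_id": path.trace_id,
                        "frame": np.arange(path.n_frames),
                        "state": path.states,
                        "max_posterior": path.posterior.max(axis=1),
                    }
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(
            outdir / "decoded.csv", index=False
        )
    if "heatmap" in art:
        art["heatmap"].to_frame().to_csv(outdir / "heatmap.csv")
        art["tdp"].transitions.to_csv(outdir / "tdp_transitions.csv", index=False)
        for label, table in art["dwell_tables"].items():
            table.to_csv(outdir / f"dwells_{label}.csv", index=False)
        fits = {k: dataclasses.asdict(v) for k, v in art["dwell_fits"].items()}
        io.write_manifest(fits, outdir / "dwell_fits.json")


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the pipeline stages in order and return all artifacts.

    ``stages`` must be a prefix of ``STAGES`` (the stages form a linear DAG;
    running a stage without its upstream is rejected by name).  The returned
    dict holds in-memory artifacts keyed by name (``traces``, ``fret_traces``,
    ``hmm``, ``decoded``, ``heatmap``, ``tdp``, ``dwell_fits``, ...) plus a
    ``manifest``.
    """
    config.validate()
    if stages is None:
        stages = list(STAGES)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; valid: {', '.join(STAGES)}")
    wanted = [s for s in STAGES if s in stages]
    prefix = list(STAGES[: len(wanted)])
    if wanted != prefix:
        missing = [s for s in prefix if s not in wanted]
        raise ValueError(
            f"stages must form a prefix of {STAGES}; missing upstream "
            f"stage(s): {missing}"
        )

    outdir = Path(config.outdir) if config.outdir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    root_ss = np.random.SeedSequence(config.seed)
    stage_seeds = dict(zip(STAGES, root_ss.spawn(len(STAGES))))

    art: dict = {}
    counts: dict[str, int] = {}
    for stage in wanted:
        if stage == "simulate":
            art.update(_stage_simulate(config, stage_seeds["simulate"]))
            counts["simulate"] = len(art["traces"])
        elif stage == "detect":
            # traces simulated directly (movie-free path): detection is a
            # pass-through; movie workflows call spots.* explicitly
            counts["detect"] = len(art["traces"])
        elif stage == "qc":
            art.update(_stage_qc(config, art))
            counts["qc"] = len(art["fret_traces"])
        elif stage == "infer":
            art.update(_stage_infer(config, art, stage_seeds["infer"]))
            counts["infer"] = len(art["decoded"])
        elif stage == "analyze":
            art.update(_stage_analyze(config, art))
            counts["analyze"] = art["tdp"].n_transitions
        elif stage == "report":
            art.update(_stage_report(config, art, outdir))
            counts["report"] = 1

    manifest = {
        "config": config.to_dict(),
        "stages": wanted,
        "counts": counts,
        "master_seed": config.seed,
    }
    art["manifest"] = manifest
    if outdir is not None:
        _write_artifacts(config, art, outdir, wanted)
        config.to_file(outdir / "config.yaml")
        io.write_manifest(manifest, outdir / "manifest.json")
    return art
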