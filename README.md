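# clampfret

Single-molecule FRET analysis of DNA sliding-clamp loading and unloading,
with a matched kinetic/photophysics simulator.

## The problem

PCNA, the eukaryotic sliding clamp, is a homotrimeric ring that is loaded
onto primed DNA by the clamp loader RFC and removed by the unloader
ATAD5-RLC. In a TIRF smFRET assay the clamp carries up to six donor dyes
(two labelling sites per monomer, ~60% occupancy) and the surface-tethered
DNA carries a single acceptor, so the FRET efficiency

    E = I_A / (I_A + I_D)

reports the average clamp–DNA geometry and resolves a small set of bound
states: two loading intermediates **LI1** (E ≈ 0.48, open clamp–loader
complex) and **LI2** (E ≈ 0.62, closed clamp before loader release), the
loaded state **LS** (E ≈ 0.34), and an unloading intermediate **UI**
(E ≈ 0.58) traversed through multiple hidden catalytic sub-steps, so its
dwell-time distribution is Erlang-peaked rather than exponential.

Because state assignment, photobleaching-step selection, synchronization and
dwell fitting all interact, every stage here is validated by **parameter
recovery**: a generative simulator (continuous-time Markov kinetics plus a
multi-donor photophysics model) produces traces and movies with known ground
truth, and the analysis chain must recover the generating parameters.

## What is in the package

| module | contents |
|---|---|
| `clampfret.kinetics` | `KineticScheme`, exact Gillespie sampling with Erlang sub-steps, named scenarios (`loading_atp`, `loading_atpgs`, `unloading_atp`, `unloading_atpgs`, `unloading_inactive`) |
| `clampfret.photophysics` | `PhotophysicsModel`, trace rendering (binomial labelling, independent donor bleaching, shot + read noise), two-channel movie rendering with Gaussian PSFs |
| `clampfret.spots` | difference-of-Gaussians spot detection, mutual-nearest-neighbour colocalization, annulus-corrected aperture extraction |
| `clampfret.qc` | apparent FRET, change-point photobleaching step counting, six-donor trace selection, association/dissociation detection, occupancy curves |
| `clampfret.hmm` | `FretHMM(...).fit() -> FretHMMResults`: shared Gaussian-emission HMM (multi-restart Baum–Welch, BIC model selection, Viterbi + posterior decoding) |
| `clampfret.analysis` | synchronized FRET heat maps, transition density plots, dwell tables, `DwellModel` exponential/gamma MLE fits with likelihood-ratio tests |
| `clampfret.pipeline` / `clampfret.cli` | flat YAML `RunConfig`, staged pipeline `simulate → detect → qc → infer → analyze → report`, `clampfret` command-line entry point |

## Worked example

```python
from clampfret.pipeline import RunConfig, run_pipeline

cfg = RunConfig(scenario="loading_atp", n_traces=300, seed=11)
art = run_pipeline(cfg, stages=["simulate", "detect", "qc", "infer"])
print(art["hmm"].summary())
```

prints:

```
Gaussian-emission FRET HMM (shared across traces)
====================================================
states: 3    traces: 5    frames: 290
log-likelihood: 764.70    BIC: -1450.02    AIC: -1501.40
converged: True (4 EM iterations, best of 5 restarts)

state   mean E    sd E    start p
  0     0.3399  0.0149   0.0000
  1     0.4783  0.0132   1.0000
  2     0.6184  0.0159   0.0000

transition matrix (per frame):
   0.99487  0.00000  0.00513
   0.00000  0.68421  0.31579
   0.07042  0.01408  0.91549
```

Of 300 simulated traces, 5 pass the strict six-photobleaching-step selection
(≈ the Binomial(6, 0.6) mass at six donors times the fraction that bleach
completely); the three recovered emission means reproduce the generating
state efficiencies 0.34 / 0.48 / 0.62 to within a few thousandths, and the
start probabilities show loading beginning in LI1. The same run from a
shell:

```bash
clampfret infer --scenario loading_atp --n-traces 300 --seed 11 --outdir run_out
```

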