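# Methods

## Generative model

### Kinetics

Clamp cycling on DNA is modelled as a continuous-time Markov jump process
over labelled states. Bound states carry a mean FRET efficiency; `UNBOUND`
and `RELEASED` emit no signal. Trajectories are sampled exactly
(Gillespie): in a state with total exit rate `R` and `m` hidden sub-steps
the dwell is Erlang(m, m·R) — the sum of `m` exponential sub-dwells with
mean `1/(m·R)` each — preserving the mean dwell `1/R` while sharpening the
distribution; the successor state is drawn with probability proportional to
its rate. `m = 1` recovers the memoryless exponential dwell.

Named scenarios (all rates configurable through `RunConfig` / `make_scenario`):

| scenario | scheme | defaults |
|---|---|---|
| `loading_atp` | UNBOUND → LI1 ⇄ LI2 ⇄ LS | k_assoc = 0.5 s⁻¹; τ_LI1 = 0.5 s, τ_LI2 = 1.5 s (forward); reverse = 0.1 × forward |
| `loading_atpgs` | UNBOUND → LI1 (stall) | LI1 → LI2 removed (the step requires ATP hydrolysis) |
| `unloading_atp` / `_atpgs` | LS ⇄ UI → RELEASED | τ_LS = 3 s; total UI exit 0.5 s⁻¹ (τ_UI = 2 s); UI has 2 sub-steps; unloading needs no hydrolysis, so both analogs share kinetics |
| `unloading_inactive` | LS absorbing | catalytically dead unloader |

State FRET means default to LI1 0.48, LI2 0.62, LS 0.34, UI 0.58. The
reverse-rate fraction (0.1) encodes that reverse transitions are observed
much less frequently than forward ones; whether LI2 → LI1 occurs at all is
not established, so the fraction is pure configuration. Transient FRET
spikes from clamp diffusion on duplex DNA are not modelled.

Note that with reverse branches the *occupancy* mean dwell of a state is
`1/(total exit rate)`, not the forward-τ knob: for LI2 the analytic mean is
1/(0.667 + 0.2) ≈ 1.15 s. Recovery tests compare against the analytic
value.

### Photophysics

The trimeric clamp offers `2 × 3` donor sites, each labelled with
probability 0.6 (1.2 donors per monomer on average); the donor count can be
fixed for designed ensembles. Each donor bleaches independently
(exponential, default 0.01 s⁻¹, clock starting at illumination onset).
With `n` active donors in a bound state of efficiency `E`:

    E[donor]    = n·b·(1 − E) + bg_D
    E[acceptor] = n·b·E·γ + bg_A

with brightness `b` = 200 photons/frame/donor, backgrounds 50
photons/frame, γ = 1 (no detection correction), frame interval 0.1 s
(camera timing is not specified by the assay description; this is an
assumption). Observed counts are Poisson(expected) plus Gaussian read noise
(σ = 3). Donors contribute additively and bleach independently, which is
what makes total intensity a staircase and, at γ = 1, makes the
background-corrected total `n·b` independent of the FRET state. Acceptor
bleaching is off by default (an optional rate zeroes FRET while donors
persist). No triplet blinking, drift or defocus.

The per-donor bleach lifetime (100 s) is chosen so that (i) it is ≥ 10×
slower than the complete unloading reaction (~5 s), so dissociation is not
confounded with bleaching, and (ii) the pre-bleach analyzable window of a
loading trace (mean ~15 s with six donors) comfortably contains the loading
kinetics (~4 s), keeping the censoring bias of dwell estimates small.
Loading recordings default to 300 s so that all six donors bleach within
the trace (needed to count six steps); unloading recordings to 60 s.

Movies render each trace as an immobile pixel-integrated Gaussian spot
(integer coordinates are pixel centers), identically positioned in both
channels; positions enforce ≥ 4σ separation plus an edge margin for
extraction annuli. Traces destined for movies are rendered noiseless with
zero trace-level background; per-pixel background and camera noise are
applied at the pixel level so noise is not applied twice.

## Analysis chain

**Spot detection.** Difference of Gaussians (σ vs 1.6σ) on a temporal mean
(or max) projection; local maxima above `median + k·MAD` (k = 6); sub-pixel
centroid by center of mass on the background-subtracted projection window.
Channels are assumed registered (a constant-offset hook exists; affine
mapping is out of scope). Detection on the DNA (acceptor) channel defines
the reference set; colocalization is mutual nearest neighbour within a
radius, each spot in at most one pair. Extraction sums an aperture (default
radius 3–4 px) minus the annulus-median background.

**FRET and QC.** `E = (A − bg_A)/((A − bg_A) + (D − bg_D))`, not clamped to
[0, 1] (out-of-range frames are flagged); frames whose corrected total
falls below a floor (default 5× the robust noise SD) are no-signal.
Photobleaching steps are counted on the FRET-invariant total by recursive
binary segmentation minimising within-segment variance with penalty
`10·σ²·log n` (σ from the median absolute first difference; the penalty
constant was set on constructed noisy staircases); only downward level
changes of at least half the single-donor brightness count, and a merged
drop of `k` donor units counts `k` steps. Loading traces require exactly
six steps; unloading traces (which leave before bleaching) require an
initial intensity within ±20% of the calibrated six-donor level.
Association is the first sustained threshold crossing (background + 5σ for
3 frames); dissociation is the last sustained drop, flagged single-step
when the signal falls from the bound-epoch plateau to ≤ 25% of it within
two frames. The analyzable window runs from association to the first
bleach step (loading) or to dissociation (unloading).

**HMM.** One Gaussian-emission HMM is shared across all selected traces
(per-state mean and unshared variance, one K×K per-frame transition matrix,
one initial distribution), fitted by maximum-likelihood Baum–Welch with
scaled forward–backward recursions run batched over traces. Five restarts
(spread-across-range, pooled-quantile, then random draws) keep the best
likelihood; the per-iteration log-likelihood trail is stored and checked
for monotonicity on every fit. States are always reported sorted by
emission mean. Model order is chosen by BIC over converged fits. Decoding
is Viterbi plus forward–backward posterior marginals. The number of states
is fixed to 3 (loading) / 2 (unloading) in the pipeline because the
no-signal state is excluded by windowing rather than modelled. An
empirical-Bayes treatment (per-trace shrinkage of transition rates) is out
of scope; for well-separated means (Δ/σ ≈ 9 here) the maximum-likelihood
point estimates are the quantity of interest.

**Population kinetics.** Traces are synchronized at association (loading)
or dissociation (unloading); heat maps are 2-D histograms of (relative
time, E) with per-time-column normalization (FRET bins 0.02 over
[−0.1, 1.1], time bins 0.2 s over [−2, +10] s or [−10, +2] s). TDPs count
decoded state changes within the first/last 6 s window at the (mean before,
mean after) coordinates (bin 0.02); Viterbi paths are used (posterior-
weighted transitions would be the alternative; with the separations here
they agree). Dwell tables list contiguous decoded runs; runs touching a
*recording* edge (trace start, bleach) are censored and dropped by default,
while runs bounded by an *observed event* (association opens loading
windows; dissociation closes unloading windows) are complete dwells.
Dropping censored dwells biases means low by roughly τ/(τ + window); with
the default window (~15 s) this is ≈ −3% (LI1) to −5% (LI2).

**Dwell fits.** Exponential MLE is the sample mean (exact χ² CI); gamma MLE
via `scipy.stats.gamma.fit` with the asymptotic Fisher CI on the shape;
exponential vs gamma compared by likelihood ratio (χ²₁). Durations from
decoded paths are frame-quantized, and dwells shorter than ~1 frame are
unobservable while Viterbi suppresses 1–2-frame visits; fits therefore
support a left-truncation `t_min` (valid for the memoryless exponential:
`mean(T − t_min | T > t_min)` is unbiased). The pipeline uses
`t_min = 1.5` frame intervals for τ estimates; exponentiality *shape*
checks use 2.5 frames, above the decoder's short-dwell resolution. A
histogram least-squares `A·e^(−t/τ)` fit is provided for figure parity only
— it depends on binning and the MLE is the primary estimate.

## What the simulator does and does not emulate

It reproduces the statistical structure the analysis assumes: discrete
state-dependent FRET with shot-noise-limited emission, multi-donor
staircase bleaching, flow-in association, single-step trimer dissociation,
Erlang sub-step dwells. It does not emulate clamp diffusion spikes,
acceptor blinking/bleaching (by default), spectral cross-talk, γ ≠ 1
detection asymmetry, stage drift, or heavy-tailed emission noise — so
passing recovery tests demonstrates the correctness and calibration of the
analysis chain under its own assumptions, not robustness to every artifact
of real recordings.

## Numerical choices and degenerate inputs

Emission densities are floored at 1e-300 and SDs at 1e-4 to avoid
underflow/collapse; EM stops at a relative log-likelihood change of 1e-6
(cap 300 iterations) and raises if the likelihood ever decreases beyond
tolerance. K = 1 fits use the closed form. Constant images yield an empty
spot table; constant traces yield zero steps; traces lacking an anchor are
dropped with reason codes; dwell fits refuse fewer than 10 uncensored
dwells. All stochastic stages derive their streams from one master seed via
`numpy.random.SeedSequence` spawning, making every pipeline rerun
bit-reproducible.

## Problem sizes

Recovery studies use 300-trace ensembles (the scale of the published
per-condition trace counts): state-mean recovery uses the default
Binomial(6, 0.6) labelling with six-step selection; dwell-law and
τ-recovery studies simulate the fully labelled subpopulation directly
(donor count fixed at six) so that the selected set is large enough for
distribution-shape inference, and the τ-recovery study repeats 20
replicates to bound estimator bias (measured: |bias| < 0.01 FRET units for
means, ≈ 3–5% for τ).
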