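# Methods

## The model

Two layers of leaky integrate-and-fire (LIF) neurons, one neuron per
saliency-map location, integrated with explicit Euler steps of
`dt = 1e-4 s` (0.1 ms):

```
V ← V + (dt/C)·(I − G_leak(V − E_leak) − G_exc(V − E_exc) − G_inh(V − E_inh))
```

A neuron fires when `V > V_thresh` strictly, and resets to `E_leak`.
The saliency layer receives a constant current per location,
`I = G_input·(S + noise_const + noise_ampl·U)`, with `U ~ Uniform(0,1)`
drawn once at initialization (never redrawn during integration: the
noise scheme perturbs initial values only).  Each saliency-layer spike
delivers a one-step excitatory conductance pulse (`LIFParams.Gexc`) to
the corresponding winner-take-all (WTA) neuron; the first WTA threshold
crossing defines the predicted first fixation.  Global inhibition and
inhibition of return engage only after a winner has fired; since the
analysis uses first fixations only, they are implemented as no-ops and
the parameters that govern them (`WTAParams.Ginh`, `GinhDecay`) are
carried in the optimization vector but are dynamically inert.  Ties on
the integration grid (two WTA neurons crossing in one step) are broken
by the larger potential, then by row-major location order.

A published version of the update rule multiplies by `dt·C`;
dimensional analysis requires `dt/C`, which is the default here, with
the `dt·C` form selectable in `euler_step(form="dt_times_C")` for
sensitivity checks.  Likewise the integration step is sometimes quoted
as 1e-3 ms (1 µs); the 0.1 ms toolbox convention is the default and
`dt` is an ordinary parameter.

### Default parameters (src/salif/configs/defaults.yaml)

| parameter | default | role |
|---|---|---|
| `dt` | 1e-4 s | Euler step |
| `E_leak, E_exc, E_inh` | 0, 0.1, −0.02 V | reversal potentials |
| `G_leak` | 1e-8 S | leak (membrane τ = C/G_leak = 0.1 s) |
| `G_exc` | 2e-7 S | per-spike pulse to the WTA layer |
| `G_input` | 5e-2 S | saliency → current conversion |
| `V_thresh` | 1e-3 V | firing threshold |
| `C` (LIF / WTA) | 1e-9 / 1e-8 F | capacitances |
| `noise_ampl / noise_const` | 1e-17 / 1e-14 | map-unit noise |
| `map_range` | 1e-9 | nominal saliency output range |

The exact numeric constants of the original toolbox are not published
in the source being reproduced; these defaults follow its conventions
(orders of magnitude, 1e-9 map scale) and are calibrated so that maps
with peak values 0.35–1 × 10⁻⁹ yield first-fixation latencies of
~130–500 ms: the saliency neuron under current `I` spikes periodically
at `t* = −(C/G_leak)·ln(1 − V_thresh·G_leak/I)` (≈ 22 ms at the map
maximum), and the WTA neuron needs ~6 pulses of
`(dt/C_w)·G_exc·(E_exc − V) ≈ 2e-4 V` to cross threshold.  All
experiments read parameters from the config file, never constants in
code.

### Why the model is deterministic per image

Before the first WTA spike no locations interact, so the winner is the
location with the largest initial current and its crossing time is a
deterministic function of that current, quantized to the `dt` grid.
Noise at the stock amplitudes (1e-17/1e-14 on features of order 1e-9)
shifts the crossing time by ~1e-6 ms — far below one grid step — so
100 runs on one image produce one, occasionally two, distinct latency
values (two when the crossing sits next to a grid boundary).  This is
the package's central reproducible finding, and also the basis of the
fast simulation path: `batch_simulate(engine="reduced")` integrates
only the maximally driven location per run, which is algebraically
exact and bit-identical to the full-field kernel (`engine="full"`,
property-tested).  The degenerate corner — several locations sharing
the *exact* same maximal current — is resolved row-major in both
engines.  A run with no WTA spike within the 2000 ms timeout returns a
censored record, not an error.

## Synthetic human-like data

The generator emulates a visual-search eye-tracking design: 18
participants, 8-second image presentations (image onset 1000 ms after
trial start), first-fixation latency defined as the duration of the
earliest fixation whose onset and offset both fall inside the
presentation window.  Latencies are ex-Gaussian — the conventional
parametric family for skewed reaction times — plus a uniform outlier
component on [1500, 6000] ms:

* μ = 120.8 ms, σ = 30.204 ms, τ = 70 ms, per-image μ-shift ~ N(0, 15 ms):
  solved so the retained mixture has mean μ + τ = 190.8 ms and
  SD = √(σ² + τ² + 15²) = 77.7 ms.  τ sits at the high end of the
  RT-typical range so per-image samples of ~17 latencies are positively
  skewed for ≥90% of images; the 15 ms between-image spread is a free
  knob (the data being emulated show per-image distributions differ,
  without quantifying by how much).
* The dataset configurations produce exactly 782 (44 images) and 1593
  (91 images) *retained* first fixations — per-image counts drawn from
  [16, 19] and adjusted to the exact total — plus
  `round(w/(1−w)·total)` outlier records (w = 1% / 3%), so the
  post-exclusion counts match the published totals exactly and the
  pre-exclusion tail fraction matches the configured weight.  Whether
  the printed exclusion percentages refer to first fixations or to all
  fixations is ambiguous in the source; the tail weight is exposed per
  configuration rather than asserting one reading.
* All-fixation datasets (29,528 / 60,186 records; 542–794 per image)
  fill each trial with ordered fixation sequences (20–50 ms
  inter-fixation gaps); sequences that would overrun the 8000 ms window
  are uniformly compressed to fit, so late-trial durations are slightly
  shrunk relative to the first-fixation calibration — acceptable since
  these samples are only used as per-image KS ground truth.
* A `total_all_fixations` config field (not part of the minimal surface)
  pins the all-fixation totals exactly.

What the generator does *not* emulate: saccade-velocity event
detection, blinks, anticipatory saccades, spatial structure of
fixation locations (x/y are uniform), participant-level latency
differences (participants only matter for trial bookkeeping), and any
dependence of latency on image content.  Passing tests therefore show
the pipeline's statistical machinery and the model's temporal
(in)variability — not that the model was tested against real humans.

Synthetic saliency maps are Gaussian-bump fields with a weak smooth
background, top-peak heights 0.35–1 × map_range so that latency varies
across "images"; real images can be substituted through the saliency
front-end.

## Saliency front-end

Classic recipe: 9-level dyadic Gaussian pyramid; intensity = channel
mean; red-green / blue-yellow opponency; 4 Gabor orientation channels
(0°, 45°, 90°, 135°, frequency 0.2 cycles/px per level); center scales
{2,3,4}, surround deltas {3,4}; rectified across-scale differences
resampled to 1/16 resolution; per-map normalization; conspicuity maps
averaged with equal weights; final linear rescale so the map maximum
equals `map_range`.  Two deliberate simplifications: opponency maps
are rectified per level before the center-surround step, and
orientation maps are Gabor energy computed on de-meaned intensity
levels — the de-meaning makes the whole pipeline exactly invariant to
adding a constant to all channels.  Each orientation keeps its own
center-surround maps so the peak-promoting normalization can single
out an odd-one-out orientation.

Saliency maps contain no noise, but they are reproducible only to
high precision, not bitwise: numpy reductions are sensitive to memory
alignment in the last ulp, and the peak-promoting normalization
amplifies such noise discontinuously through the local-maxima set
(typically ~1e-4 relative; up to a few percent when a weak local
maximum sits exactly at the detection cutoff).  The local-maximum test
therefore uses a small tolerance rather than exact equality, and maps
are computed once per image and reused, so the temporal layer's
run-to-run determinism is unaffected.

`normalize_map` defaults to the max-based operator — rescale to [0,1],
weight by (1 − m̄)² with m̄ the mean of the local maxima other than the
global one — with an iterative difference-of-Gaussians variant
selectable (`method="iterative"`); which variant the original toolbox
used is not recorded, so the choice is explicit in config.  Maps whose
maximum falls below 1e-12 in normalized units are treated as
featureless and returned as zeros (a uniform image yields an all-zero
map rather than rescaled numerical dust).

## Statistics

* KS: two-sample `D = sup|ECDF_a − ECDF_b|`, asymptotic p-value with
  effective n = n_a·n_b/(n_a+n_b) (adequate at the sample sizes used;
  exact small-sample p is out of scope).  Verified against brute-force
  ECDF enumeration in the tests.
* z test: the source names only the statistic; the adopted reading is a
  one-sample z of the model mean against the ground-truth mean with the
  ground-truth SD as known σ — the natural use of that test here.  SD
  agreement is reported descriptively, not tested.
* Outlier rule: latencies strictly greater than 1500 ms are excluded
  (a value exactly at 1500 ms is retained); the filter is idempotent.
* Variance decomposition: pooled within-image SD vs SD of per-image
  means — the executable form of the headline finding (model within-
  image SD = 0 at stock noise; human-like ≈ 77 ms).

## Optimization

12-dimensional vector: LIF E_exc, E_inh, G_leak, G_input, V_thresh, C;
WTA C, G_leak, G_inh; noise_ampl, noise_const, map_range.  The search
space is unbounded; negative conductances are clamped to zero at
bundle construction.

* GA: mutation-only (no crossover is specified in the procedure being
  reproduced), 40 contenders, each parameter independently scaled by
  (1 ± m), m ~ U(0, 0.10); worst 10 reset to the initial vector; single
  elite carried unchanged (added so the best-fitness trace is
  well-defined and non-increasing); stop at 50 generations, at zero
  fitness, or when the best contender is statistically
  indistinguishable from the ground truth (p_KS and p_z > 0.05; set
  `alpha=0` to disable — necessary for small-sample self-consistency
  experiments where the gate fires long before convergence).
  Multiplicative mutation is chosen over additive because the
  parameters span ~10 orders of magnitude.
* Fitness `D + |z|` sums the two statistics without weights; the
  z-gate variant ranks contenders passing p_z ≥ 0.05 by D and appends
  the rest ranked by |z|; the per-image variant sums per-image D
  (non-firing images contribute a penalty of 10, whole non-firing
  parameter sets 1e6).
* Every GA evaluation gets a fresh seed derived from the master seed;
  Nelder–Mead uses one fixed evaluation seed (common random numbers) so
  the simplex sees a deterministic surface.
* NM: standard simplex coefficients (1, 2, 0.5, 0.5) with the classic
  stop defaults — parameter/fitness tolerance 1e-4, cap 200 × dimension
  — via `scipy.optimize.minimize`.

## Experiment drivers and problem sizes

Experiments default to 24×32 synthetic maps (one per image; a
notional 512×384 image at 1/16 map scale), 2000 ms timeouts, and the
dataset sizes above: Exp 1 — 44 runs; Exp 2 — GA (≤50 × 40
evaluations) + NM (≤2400) at 44 runs each; Exp 3 — 440- and 910-run
evaluations; Exp 4 — per-image KS over 91 images × 10 runs.  With the
reduced engine the full set completes in a few minutes on one CPU.
Scripts under `analysis/` are thin narrative drivers; all computation
lives in `salif.*` modules and every reported statistic is recomputed
from the archived CSVs.

One bookkeeping discrepancy in the reproduced design is kept visible
rather than resolved: the 91-image ground truth is listed in one place
with the 44-image sample size (782); the dataset2 default here uses
its own 1593 first fixations.

## Known limitations

* The coupling between the layers (one-step conductance pulse through
  `G_exc`) is one of several architectures consistent with the
  description being reproduced; the published coupling constants are
  not available.
* Optimization operates on raw parameter values; with ~10 orders of
  magnitude between coordinates, NM's absolute tolerances bind very
  unevenly across dimensions (as they would in the original setting).
* The asymptotic KS p-value is slightly conservative below n ≈ 20.
* At noise amplitudes approaching the map scale the additive-uniform
  noise raises all locations together, so latencies first spread
  (≈1e-11..1e-9) and then compress again — the model never censors
  from too much noise in this architecture.
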