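# Methods

## Model

### Mean-field nodes

Every non-spiking unit is a rate node whose firing rate is an algebraic
function of its summed input current (FI curve):

    r(I) = (λI − β) / (1 − exp(−θ(λI − β))),   r(β/λ) = 1/θ,

with λ = 270 Hz/nA (excitability), β = 108 Hz (threshold offset) and
θ = 0.154 s (curvature).  Rates are clipped at zero (the closed form can
go infinitesimally negative through floating error far below threshold).
All temporal dynamics live in the synapses and the noise: node *i*
receives

    I_i = Σ_j w_j s_j + I_base + ε_i + I_ext,

with I_base = 0.33 nA for every node, per-node Ornstein–Uhlenbeck noise
ε_i, and I_ext only at the stimulus input layer.  Each synapse carries a
saturating gating variable

    ds/dt = −s/τ + γ (1 − s) r(t − ΔT),

with five parameter classes: fast excitatory (τ = 20 ms, γ = 0.8), slow
excitatory (120 ms, 0.5), fast inhibitory (3 ms, 0.8), slow inhibitory
(120 ms, 0.1) and the pacemaker self-excitation (1 ms, 0.8).

Integration is forward Euler at dt = 1 ms.  A connection delay of k steps
is implemented so that the target's rate lags the source's by exactly k
samples (the Euler update itself contributes one step of latency, so the
read-back index is k − 1; an isolation test verifies the 12 ms
feedforward delay end to end).  Delay buffers are initialized with each
node's t = 0 rate and at least 1 s of burn-in is discarded before any
analysis.

**OU noise.**  The discrete update is
ε ← ε(1 − dt/τ_ε) + σ_ε·sqrt(1 − (1 − dt/τ_ε)²)·N(0,1).  The amplitude
differs from the Euler–Maruyama sqrt(2dt/τ_ε) (their ratio is 1 + O(dt/τ_ε))
so that the stationary SD equals σ_ε = 0.025 nA *exactly* at any step —
σ_ε is the only printed noise magnitude, so it is pinned to that
observable.  τ_ε is not a published quantity; the default is 2 ms, i.e. a
fast node-level fluctuation that is essentially white at the network's
time scales.  Simulated trials differ only through this noise, the
pacemaker noise, and the bounded white-noise drive of the top input pair.

### Infragranular pacemakers

Each IG_IB node is a homogeneous population of N = 350 Izhikevich neurons
(a = 0.0067, b = 0.2, c = −50 mV, d = 2):

    dv/dt = 0.04v² + 5v + 140 − u + I_n,    du/dt = a(bv − u),

integrated at 0.5 ms (two sub-steps per network step), with the canonical
reset ordering: neurons at v ≥ 30 mV are flagged spiked and reset
(v ← c, u ← u + d) at the start of a sub-step, before the Euler
increment, so the reset values are exact.  Neurons are not coupled
directly; each receives the scaled node input plus private Gaussian
noise,

    I_n = 4·I_node + μ_ε + σ_ε·N(0,1),    [μ_ε; σ_ε] = [6; 4],

drawn independently per neuron *and per 1 ms step* by default.  The noise
is the population's only source of heterogeneity.  A `static` mode
(offsets drawn once per neuron) exists for comparison; per-step noise is
the default because it makes the population's collective frequency nearly
insensitive to tonic drive, which is what keeps the backward-coupled
pacemaker chain close to a common baseline frequency (the areas receive
different tonic feedback currents) and keeps the frequency–current slopes
small, as observed.  With static offsets the lower areas run ~2–3 Hz
faster than the top and the chain fragments.

The node's output rate is `gain · (spiking fraction per 1 ms bin)`.  The
natural unit bridge is gain = 1/dt = 1000 (fraction per bin → Hz); the
default applies an additional coupling efficiency of 0.7 (gain = 700),
calibrated once against two qualitative constraints — the network holds
an alpha-band backward rhythm at rest and reverses to a forward wave at
the published threshold current — and not adjusted per experiment.  The
self-excitation (w = 0.7, τ = 1 ms) closes the loop from this output back
into the node's own input, at the mean-field level.

### Architecture

Each area: L4_X → SG_X, L4_X → L4_IN, SG_X → IG_IB (all w = 1, fast
exc.); IG_IB self (0.7); L4_IN → L4_X (−1.2, slow inh., the Layer-4
response adaptation); SG_IN → SG_X (−2, fast inh.).  Between areas
(delay 12 ms): feedforward SG_X → L4_X(next) (2, fast exc.); feedback
IG_IB → SG_IN(lower) (1.5, fast exc.) and IG_IB → IG_IB(lower) (1, slow
exc.).  The backward-coupled pacemaker chain is the *BW pathway*; the
closed loop SG_X → L4_X(next) → SG_X(next) → IG_IB(next) → SG_IN (an
inhibitory feedback that reduces the feedforward signal to residuals) is
the *FW pathway*.

Two input pairs bracket the hierarchy.  IL_St (an L4-like pair, LGN
analogue) receives the stimulus current and relays to Cx1.L4_X with the
feedforward class (w = 2, 12 ms) — the weight is not a published value;
the feedforward class is chosen because the layer is a relay.  IL_Pr sits
at the top; its excitatory node projects to Cx_N.IG_IB (w = 1, fast exc.,
12 ms — direction chosen because the pair's role is a top-down drive that
keeps the BW pathway active) and receives i.i.d. uniform noise on
[0, 0.3] nA per 1 ms step.

The pulvinar option inserts one relay node between consecutive areas:
IG_IB → Pul (w = 1) and Pul → L4_X(next) (w ∈ [0, 2.2]), each leg with
half the cortical delay (6 ms), i.e. an excitatory shortcut feeding
spontaneous pacemaker activity into the FW pathway.  With w = 0 the
pathway is pruned at build time, which makes the cortex-only and
zero-weight models bit-identical (verified).  Two-hemisphere
configurations duplicate the full stream with no cross connections.

Structural toggles use independent random substreams (cortical OU,
pulvinar OU, IL_Pr, pacemakers), so removing one component does not
perturb the others' noise.

## EEG projection

Per area, the source signal is the mean of the five node rates, demeaned,
zero-phase Butterworth low-passed (order 3, 20 Hz), down-sampled to
100 Hz and z-scored.  Neither the pulvinar nor IL_St/IL_Pr is projected.
Sources are radial at template positions (occipital (±8, −76, 10),
parietal (±24, −61, 58), frontal (±5, 48, 30) mm); single-stream runs
place each area bilaterally at half amplitude.

Two analytic gain kernels are provided.  Single-stream projections use
the closed-form potential of a radial dipole in a homogeneous sphere at
reduced eccentricity (0.3 of the source's nominal radius): its broad,
smooth interpolation — including the sign-flipped far field — carries the
model's large midline phase spans (~4 rad end to end) faithfully, and it
classifies the phase-lagged template-source validation fixtures
perfectly.  Dual-stream projections use a positive spherical-Gaussian
patch (half-width 0.5 rad) per source, which keeps the two hemispheres
separable at the scalp; the deep-dipole kernel cannot do this (the
sources become effectively central), while the patch kernel in turn
cancels destructively between the near-antiphase midline sources of the
single-stream model.  No single simplified kernel passed both validation
suites; a realistic boundary-element model, which is out of scope, lies
between the two.  Dipole-kernel output is average-referenced; patch-kernel
output is not (re-referencing would re-introduce far-field sign flips).

Five 1/f noise sources are added per trial at uniform random positions
within 85% of the sphere radius, each scaled so that RMS(noise at
electrodes)/RMS(signal mixture) equals a draw from U(0.4, 1.6).  The 1/f
amplitude profile rolls off below ~0.2% of Nyquist: sub-drift frequencies
would otherwise dominate the variance (and recordings are high-passed
there anyway).

## Wave fitting

Electrode positions come from the standard BioSemi-64 montage via an
azimuthal-equidistant 2D projection (x right, y anterior).  ROI
membership is frozen in a packaged file, derived once from the montage
geometry: the midline ROI is the rectangle spanning Iz–Fz by C5–C6
(38 electrodes); the lateral ROIs span the same occipito-frontal range up
to the AF row, from the midline out to C5/C6, excluding midline
electrodes (20 per side).

Per ROI: band-pass FIR (7–13 Hz, order = three cycles of the low edge,
~430 ms at 100 Hz, zero-phase), Hilbert phase, referenced to the circular
mean across the ROI per sample, then circularly averaged in 100 ms
sliding windows (every sample).  The planar model θ̂ = ax + by + ϑ is
evaluated on a polar grid (60 directions × 30 spatial frequencies from 0
to one cycle over the maximum electrode distance; the ξ = 0 column
collapses to a single degenerate entry whose direction is undefined —
spatially uniform phases are reported Null).  The best fit maximizes the
resultant length of the circular residuals; goodness of fit is the
Fisher–Lee circular correlation ρ between observed and predicted phases.

The null distribution repeats the fit with 10 random electrode-position
permutations at reduced temporal resolution (every 5th window), collated
over trials; significance is the one-sided 95% point.  A window is FW
(BW) if ρ exceeds that threshold and the gradient direction lies within
0.5 rad of the reference axis (opposite axis for BW), else Null.  Sign
convention: the layout's +y is anterior; a forward wave (posterior →
anterior propagation) has its leading phase anterior, so its fitted
*gradient* points posterior (α = −π/2).  Fixtures check both senses.  For
lateralized data the reference axis is the circular median of the
classified directions after reflecting BW fits through π.

## Experiment drivers and metric definitions

All drivers derive every random stream from one integer seed and are
bit-reproducible.  Defaults (runs per condition, durations) are desk
scale, chosen so estimator noise sits well inside the tolerances checked
by the test suite; the acceptance script uses the larger canonical sizes
(e.g. 15 currents × 20 runs for the response curve, 100 trials for the
timecourse).

* **Response curve** — P(FW) per DC amplitude over 3 s stimulations; a
  4-parameter logistic (floor, ceiling, slope, midpoint) is fit and the
  threshold is its midpoint.
* **Timecourse metrics** — across-trial P(FW) at 10 ms resolution,
  smoothed 50 ms.  The zero-phase band-pass plus the 100 ms phase window
  smear the onset transient into a plateau, so *time to first peak* is the
  centre of the post-onset region holding ≥ 95% of the onset maximum.
  *Return to baseline* detrends the post-offset curve by the linear fit
  over the final 2 s of rest and reports the first re-entry into the
  pre-stimulus mean ± 2 SD band; the last 400 ms before onset are excluded
  from the baseline (backward smearing of the onset response would
  otherwise inflate the band).
* **Impulse response** — Pearson cross-correlation of the binary FW
  sequence with a random 10 Hz-update step stimulus (blocks independently
  ON with p = 0.5), chance band from ≥ 100 shuffled trial pairings; the
  decay lag is the first post-peak lag inside the band.
* **Spectra** — Welch on burn-in-free segments (2 s windows, zero-padded
  interpolation), peak = argmax in 5–15 Hz; the "suprathreshold increase"
  is the peak-frequency difference between the top of the sweep (2 nA)
  and the threshold current.  The delay sweep compares the full model
  against the isolated FW pathway (pacemakers replaced by passive rate
  relays *and* inter-areal IG feedback removed; local wiring, including
  the now-mean-field self-connection, is retained).
* **Pacemaker bursts** — local maxima of the 20 ms-smoothed population
  rate above 50% of its robust maximum, merged within a 20 ms refractory
  window plus ~60% of the dominant period (from the rate spectrum), so
  that ragged multi-peaked bursts count once.

## What the synthetic data do and do not show

The fixtures (ideal planar scalp waves; phase-lagged template dipoles
projected through the production lead field) validate the *measurement
chain* — direction recovery, sign conventions, significance calibration —
exactly as one would validate it before applying it to recordings.  They
do not emulate real-EEG artifacts (blinks, muscle, non-stationary alpha
power), volume conduction beyond the simplified kernels, or inter-subject
variability; passing them shows the pipeline is correct, not that the
model fits any particular dataset.

## Known limitations

* The pacemaker population is only loosely synchronized: the collective
  rhythm is a noisy ~8 Hz envelope rather than sharp population bursts.
  Its isolated inter-burst interval (captured as `t3`-style summaries)
  comes out near 120–130 ms rather than ~100 ms, and the full network's
  baseline peak sits at ~8–9 Hz.  Stronger synchrony would require
  either stronger self-excitation or weaker per-neuron noise than the
  published parameters provide.
* The forward-wave state does not outlast its stimulus by more than
  ~1 alpha cycle (plus analysis smearing): classified FW probability
  returns to baseline within ~100–250 ms of offset and the
  impulse-response correlogram decays into the chance band at
  ~100–150 ms.  The slow inhibitory adaptation even produces a brief
  suppression after each stimulus block.  Longer persistence would need a
  near-critical FW loop gain that these weights do not produce.
* IG_IB and SG_X peak frequencies lock tightly above threshold, so their
  frequency–current increases are nearly equal (~1 Hz each) instead of
  dissociating, and the full model's two compartments do not diverge at
  long delays (the pacemakers follow the loop down in frequency).
* Scalp amplitude topographies are explicitly not modeled (the wave fit
  is phase-only); absolute classification probabilities depend on the
  noise-mixture SNR and should be read as relative changes.
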