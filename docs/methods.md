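# Methods

`dropsort` models a fluorescence-activated droplet sorting (FADS) platform
for filamentous fungi: single spores encapsulated in ~1 nL water-in-oil
droplets with a fluorogenic glycoside-hydrolase substrate, incubated for
days on a colloidal-chitin solid support, reinjected past a fibre-coupled
spectrometer, and routed at an electrostatic Y-junction by a short
pulsing-electrode (PE) burst. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
data can and cannot show.

## Droplet-train and encapsulation model (`stream_sim`)

**Encapsulation.** Spore occupancy per droplet is Poisson with mean
λ = concentration × droplet volume (0.35 × 10⁶ spores·mL⁻¹ × 1 nL = 0.35
by default), so ~70.5% of droplets are empty, ~24.7% hold exactly one
spore, and ~4.8% hold more. Droplet volumes are lognormal with a 5% CV at
generation; the CV grows by 0.08 per incubation day (`cv_growth_per_day`)
to emulate the polydispersity that growth, merging and evaporation create
over multi-day incubation.

**Arrivals.** The default arrival process is quasi-regular: droplets at
the mean spacing 1/rate with Gaussian timing jitter of 10% of the spacing
(clipped at 3.5 σ so ordering and physical separation are preserved). A
T-junction emits a near-periodic train; a homogeneous Poisson process at
7 Hz would imply physically overlapping 40 ms transits in ~a quarter of
the gaps, which no real reinjection line produces. `regular` (for
deterministic tests) and `poisson` modes remain available.

**Fluorescence.** Each occupied droplet draws a clone activity rate from
a lognormal (median 0.3 µM·h⁻¹ fluorescein release, σ = 0.5); a
configurable `mutant_fraction` of clones multiplies this by a second
lognormal factor (σ = 1.0), producing the right-skewed intensity
populations that UV-mutagenised libraries show. Fluorescein accumulates
linearly at that rate over the incubation time on top of a 0.5 µM
substrate background and saturates at the 100 µM in-droplet substrate
concentration. Note that at 96 h incubation a visible fraction of active
clones reaches the ceiling; a quantile gate placed inside that saturated
plateau is degenerate (it sits within measurement noise of the ceiling),
which is a real property of endpoint assays, not an artifact.

**Detector.** Frames arrive every 10 ms on a 450–650 nm grid at 0.5 nm
(the recording band 500–600 nm plus the 470 nm excitation bleed-through).
A transit is a rectangular pulse lasting 40% of the mean droplet spacing;
during it, frames carry a Gaussian fluorescein emission band (center
515 nm, sd 15 nm, 20 RFU/µM) plus an excitation bleed-through band
(470 nm, 60 RFU), riding on a flat 100 RFU dark level with 5 RFU Gaussian
read noise. The bleed-through is what makes *empty* droplets countable:
every transit is detected near 470 nm, while only fluorescein-positive
droplets produce in-gate peaks near 515 nm. The 10 ms integration time is
a stand-in; the instrument's value is not published.

**Hyphal exit.** Occupied droplets receive an exit time drawn as a
media-dependent onset delay plus an exponential: glucose-only media
starts exiting at 24 h; colloidal chitin with 0.1% glucose (and minimal
media) hold hyphae in until ~96 h, reflecting chitin's structural-support
role. Rates are package data (`MEDIA_EXIT_PARAMS`), calibrated to those
qualitative anchors only — per-day exit percentages are not reproduced.

**Reproducibility.** All draws derive from one seed; per-droplet
attributes use substreams keyed on `(seed, droplet id, purpose)` so
results are independent of evaluation order and bit-reproducible.

## Signal chain (`sigproc`)

Background subtraction defaults to `plain` (|I − I_dark|), which keeps
the baseline stationary for thresholding. The literal running recurrence
I = |I_{n−1} + (I_n − I_dark)| ships as `accumulate` for parity with the
instrument convention; it integrates signal (and folded noise) without
bound and carries no reset rule, so it is not the default — a dedicated
test documents this behaviour.

Denoising is a third-order Butterworth low-pass at 0.1 normalised cutoff
applied **along the wavelength axis**, single-pass causal (the live
system ran in real time; zero-phase filtering would be anticausal). The
filter state is initialised at steady state for each row's first sample,
so DC gain is exactly 1 with no start-up transient. Two consequences are
worth knowing: (1) the causal group delay (~6.3 samples = 3.2 nm at
default settings) shifts detected peak wavelengths red by ~3 nm, which is
small against the 510–520 nm gate window; (2) the digital filter's
attenuation follows the bilinear-transform magnitude response, which at
4× the cutoff is |H| ≈ 0.0104, not the analog-prototype value
1/√(1+4⁶) ≈ 0.0156 — at the cutoff itself both give 1/√2.

Peak detection (scipy `find_peaks`) enforces all four criteria — height,
base width (measured at the prominence base), spacing, topographic
prominence. Processing whole sessions skips frames whose subtracted
maximum is below 0.8 × the height threshold before filtering: a gain-≤1
low-pass cannot raise such a frame above the threshold, so this is a pure
speed optimisation.

Consecutive hot frames closer than a 50 ms refractory merge into one
droplet event (7 Hz spacing is 143 ms, transits 40 ms); the event peak is
the maximum-intensity peak across its frames. Gates are closed intervals
on wavelength and intensity with a strictly-greater noise floor;
`quantile_gate` uses the type-7 (linear-interpolation) quantile, so a
0.9-quantile gate passes ~10% of a continuous population. Two named
windows ship: 510–520 nm (default) and 500–520 nm.

## Controller (`controller`)

Travel time is τ = k/Q with k = 3 nL fixed once from the measured anchor
(0.1 s at 30 nL·s⁻¹). Each gated event schedules a 0.3 s, 10 kHz PE pulse
at detection time + τ; the refractory period equals the pulse duration
(an electrode cannot double-fire), and a gated event during an active
pulse is flagged `merge_risk` instead. Detection latency is one frame
period (10 ms) plus optional Gaussian jitter (sd 10 ms); a droplet is
captured if a pulse is active while it dwells at the junction, where a
pulse starting up to 25 ms after the droplet's arrival there
(`commit_window`) still captures it. With zero jitter the 10 ms latency
is always inside the window (sensitivity exactly 100%); with the default
jitter, ~10–15% of pulses start too late, reproducing the qualitative
sub-100% device sensitivity. Specificity is unaffected because ungated
droplets never schedule pulses.

Closed-loop fidelity scenarios run at 2 Hz reinjection: the 0.3 s pulse
implies a ~3.3 Hz actuation ceiling, so sorting-fidelity characterisation
uses droplet spacing longer than the pulse (as calibration sorts do),
while raw detection throughput is characterised separately at 7 Hz.

## Routing model (`sorter_physics`)

Actuated success is logistic in potential V, flow Q, their interaction,
and droplet volume (centred at 1 nL). The five default coefficients (data,
in `data/routing_defaults.yaml`) are pinned by: P = 0.5 at (27.4 V_RMS,
51.5 nL·s⁻¹, 1 nL); P = 0.99 at (40 V_RMS, 60 nL·s⁻¹); success
decreasing in volume (β_vol = −3 per nL, so sub-nanolitre droplets sort
more easily). The two remaining degrees of freedom were set so the
success region has the observed topology — efficient sorting needs both
sufficient potential and sufficient flow; below the voltage threshold a
failed pulse is drag-dominated (E1, droplet carries into the main
channel); below the flow threshold the droplet stalls or switches back
(E2) or, when the next droplet arrives within the pulse at high
potential, merges (E3). A single logistic surface cannot also honour
every printed operating point (notably perfect sorting at 12.5 V_RMS,
50 nL·s⁻¹, and a volume inflection at 36.34 V_RMS/60 nL·s⁻¹); those are
reproduced as topology, not as exact probabilities.

Unpulsed droplets take the main channel with a passive fidelity linear in
flow through the anchors 0.992 at 60 and 0.995 at 80 nL·s⁻¹; below
10 nL·s⁻¹ droplet plugs raise the main channel's resistance and fidelity
degrades linearly toward chance.

## Statistics (`screen_stats`)

The sorter-efficiency GLM is a logit-link binomial regression on V, Q and
V×Q fitted by hand-written IRLS (deviance convergence 10⁻⁸), with
standard errors from the inverse Fisher information, two-sided Wald
p-values, deviance against the saturated model, and
AIC = −2ℓ + 2k using the full per-cell binomial likelihood including the
combinatorial term (per-attempt Bernoulli coding gives identical
coefficients but a different AIC; the per-cell convention is used).
Complete separation is detected (|linear predictor| > 30 or
non-convergence) and flagged with a warning rather than returned
silently. The implementation agrees with an independent reference fit to
~10⁻¹³ and recovers generating coefficients within 3 SE in ≥95% of
simulated 7×20, N = 10 grids.

The variance comparison between parent and mutant intensity populations
is the median-centred Levene (Brown–Forsythe) test — robust for skewed
fluorescence data; skewness is the Pearson second coefficient
3(mean − median)/sd (the mode-based first coefficient is ill-defined on
continuous data). Binomial lower confidence bounds are one-sided exact
Clopper–Pearson. Enzymatic activity follows the 4-MU endpoint formula
1.9 · V_F · DF · (FLU − FLU_blank) / (FLU_std · t · V_sample) in U·mL⁻¹,
with negative blank-corrected fluorescence clamped to zero activity (an
assay cannot show negative release) under a warning.

## Problem sizes and tolerances

Whole-session checks use one 1800 s session at 7 Hz (~12,600 droplets,
180,000 frames); routing fidelity uses 10⁴ draws per condition; GLM
recovery uses 100 replicate grids; closed-loop fidelity uses 500-droplet
calibration mixes; the null-calibration of the variance test uses 2,000
replicates of 30-vs-30 normals. IRLS converges at 10⁻⁸ in deviance;
probabilities are clipped at 10⁻¹⁰ inside the fit; the P = 0.5 anchor is
honoured to <10⁻⁹.

## What the synthetic data does not show

The generator reproduces operating-point statistics (throughput,
occupancy, gate fractions, routing probabilities), not instrument
physics: no wavelength calibration drift, no droplet-shape or
surfactant effects, no spectral unmixing of multiple fluorophores, no
crosstalk between droplets, and rectangular (not ramped) transit
profiles. Passing tests therefore validate the algorithms and the
statistical machinery under the stated operating conditions, not the
behaviour of any particular physical device; wet-lab figures such as
fold-change improvements of recovered mutants are outside what a
simulator can establish.
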