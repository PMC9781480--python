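# Methods

This note documents the models behind `smtrack`, the defaults and why
they were chosen, the numerical decisions that matter, and what the
simulation-based tests do and do not demonstrate about real data.

## Simulator

Each molecule carries a motion state from a user-defined set (bound
non-specific, bound specific, diffusing), switching as a continuous-time
Markov chain with exact exponential waiting times. Sojourn times are
realized in continuous time and only *emission* is discretized to frame
boundaries, so simulated dwell-time distributions carry no frame-rate
bias beyond the unavoidable floor-to-frame quantization of the observed
dwell. Within a frame interval the displacement integrates the
piecewise-constant diffusion coefficient segment by segment (per-axis
variance 2·D·dt per segment), which is exact for Brownian motion.

Positions live in 3D inside a reflecting sphere of radius
`nucleus_radius` (default 1 µm, a diploid yeast nucleus). A state may
add its own reflecting confinement sphere, centred where the state was
entered. Reflection preserves the uniform stationary distribution and is
far cheaper than rejection sampling. The axial coordinate exists solely
to drive defocalization: a molecule whose |z| exceeds half the
`depth_of_field` (≈ 0.4 µm for HILO objectives) is lost permanently;
only x, y are emitted, with additive Gaussian localization error
(`localization_sigma`, default regime ~30 nm).

Photobleaching is Bernoulli per *exposure*, not per second: in
time-lapse imaging the fluorophore is dark between exposures, so
survival against bleaching is geometric in the exposure count. The
exposure in which the molecule bleaches is still observed (mean observed
track length 1/p). Wall-clock timestamps advance by
`frame_exposure + dark_interval`.

Not emulated: fluorophore blinking and other dark-state photophysics,
photoactivation scheduling, 3D PSF structure, illumination gradients
across the field, stage drift, and nuclear movement. Synthetic movies
render pixel-integrated 2D Gaussian spots (error-function integration,
so the photon count is exact) plus uniform background and Poisson shot
noise.

## Detection and linking

Spots are enhanced by a difference-of-Gaussians bandpass (defaults 1 and
4 px), local maxima above an absolute threshold are refined by
least-squares fitting of a symmetric 2D Gaussian with constant offset in
a 7-px window, and diverged fits are discarded and tallied. A
noise-relative threshold helper (k × 1.4826 × MAD of the bandpassed
frame, default k = 5) is provided because detection thresholds are
otherwise instrument-specific.

Linking is deliberately plain greedy nearest-neighbour: candidate pairs
between consecutive frames sorted by (distance, track index, detection
index) — fully deterministic — assigned greedily, rejected beyond
`max_disp`. Gap closing (`memory`) defaults to 0 because bridging dark
gaps concatenates distinct binding events and inflates apparent dwell
times, biasing the survival analysis this package exists to serve; it
can be enabled explicitly, with the allowed displacement scaled by the
gap length. Assignment-optimal (LAP/Hungarian) and multi-target tracing
linkers are out of scope; track tables from external trackers can be
imported through the plain CSV format (µm coordinates, 0-based frames).

## Bound-segment classification

"Bound" has no universal definition in SMT; the package uses the common
geometric one: a maximal run of ≥ `n_min` consecutive localizations all
within `r_max` of the run's centroid. Defaults r_max = 0.22 µm (≈ 2
pixels at 0.11 µm/px) and n_min = 3 frames; both are recorded in every
report. The dwell of an L-frame run is (L−1) × frame interval — only
elapsed time is observed. Runs touching the last movie frame are flagged
censored; censored segments still contribute to survival counts up to
their observed dwell (no Kaplan–Meier machinery — a documented
limitation; with bleach-limited observation the censored fraction is
ordinarily well below 1%).

Two properties of this classifier are worth knowing. First, fast-moving
molecules occasionally produce spurious short segments by chance
clustering; a brute-force estimate at D = 1 µm²/s, Δt = 0.2 s,
r_max = 0.2 µm gives ≈ 0.012 per 3-frame window (≈ 0.3 expected
clusters per 30-frame track) — not negligible, which is why a finite
depth of field (which removes diffusing molecules from view within a
frame or two) matters for clean dwell statistics. Second, a segment can
be extended by roughly one frame when a molecule unbinds early in a
frame interval and has not yet moved r_max; this shifts component
amplitudes by well under a percent in typical regimes.

## Survival analysis

S_raw(t) = #(dwell ≥ t)/n₀ on a grid of frame-interval multiples
spanning the observed dwells, scaled so the first grid point equals the
bound fraction

    C_eq = (detections inside bound segments) / (all detections in all frames).

When a particle binds more than once, each binding is a separate
segment; C_eq counts bound *frames* over all frames either way. The
per-frame detection counts are stored on the curve for the intrinsic
correction.

### Photobleaching correction

All corrections work on the cumulative *exposure count* axis and convert
to seconds only for reporting, so continuous and time-lapse regimes are
handled identically.

* **intrinsic** — weighted log-linear fit of per-frame detection counts
  vs exposure count; divide S by exp(−λ̂·k). Tends to under-correct for
  stably bound proteins (mobile molecules exchange out of view before
  bleaching), which is visible in the package's own simulations when the
  survival of a two-state factor is intrinsically corrected.
* **whole_reference** — divide pointwise by a stable reference species'
  survival normalized to 1 at its first point. Self-correction of the
  reference is identically flat, which also means genuine mobile
  sub-populations of the reference are erased — over-correction.
* **immobile_fraction** — tri-exponential fit of the reference survival;
  the slowest component, normalized to 1 at t = 0, is the bleaching
  curve. Components with amplitude < 10⁻³ of the total are ignored
  before picking the slowest (an unconstrained spare component can
  otherwise carry a huge meaningless tau at zero amplitude), and a
  provenance warning is recorded when the slowest tau is separated from
  the next by less than 2×. Note the method presumes the reference
  really has a dominant immobile fraction plus distinguishable mobile
  components; with a reference whose survival is a clean *two*-component
  decay, the spare third exponential is unidentified and tends to split
  the slow decay, biasing the bleach estimate. Real histone references
  are multi-modal, which is the regime the method was designed for and
  the one the test suite emulates.

After division the corrected curve is rescaled so its first point does
not exceed C_eq, and the correction method, fitted bleach parameters and
warnings are recorded in provenance. The applied bleach factor is kept
on the curve so model selection (below) can predict observed counts.

### Dwell-model fitting

Families: Σᵢ Aᵢ e^(−t/τᵢ) for 1–3 components, A·t^(−β), and the hybrid
A₁e^(−t/τ₁) + A₂t^(−β). Parameters are estimated by weighted least
squares on log S. Weights are the inverse variance of log S under
binomial counting noise, counts/(1 − S̄) with S̄ the raw surviving
fraction (∝ counts once S̄ is well below 1), regularized by +1/n₀ at the
first point. Grid points with fewer than 3 surviving segments are
excluded from the fit: below a few counts the log-S noise is strongly
skewed and systematically inflates the slow tau. Each family is fitted
from 5 starts (taus log-spaced over the grid span, jittered by a seeded
RNG, seed 0 by default); a family whose every start fails is marked
failed and excluded from selection.

Model comparison deliberately does **not** use a residual-based
likelihood: survival-curve points are cumulative counts, their residuals
are random-walk-correlated, and a Gaussian residual likelihood
overstates the evidence for extra components so badly that the
generating family is rarely selected. Instead the BIC likelihood is the
multinomial likelihood of the *binned dwell counts* — the independent
increments of the surviving counts, with the final grid point holding
the tail mass — evaluated at the curve-fit parameters (re-multiplied by
the recorded bleach factor for corrected curves, so the model predicts
what was actually observed). The penalty is k·ln(n₀) with n₀ the number
of segments. The hybrid model is additionally accepted only if its BIC
beats both of its parents (exp_1 and power_law) by ≥ 2 — a guard
against its weak identifiability.

Fractions are amplitude ratios at t = 0 for exponential mixtures
(extrapolated through the left truncation imposed by n_min); for the
hybrid, at the first grid point, where the power-law component is
finite. MLE on the dwell samples would be the statistically efficient
alternative to curve fitting for *parameter estimation* and remains an
open alternative.

### Derived kinetics

From an exp_2 fit with C_eq ∈ (0, 1): τ_res is the fraction-weighted
mean of τ_NS and τ_S (asserted to be a convex combination on every
call), τ_search = (1−C_eq)/C_eq·τ_res, N_trials = (F_S+F_NS)/F_S,
k_on\* = 1/τ_search, and k_on = k_on\*/S_eq when the accessible-motif
fraction is supplied. Power-law fits are refused with an explicit
message — no residence time is defined for a power-law dwell
distribution.

### Statistical resolution

The recovery studies in the test suite run at ≈ 3000 segments with
τ = 2 s / 10 s, fractions 0.6/0.4, bleach 0.02/exposure, and bound calls
left-truncated at 3 frames. At those conditions the *information limit*
(direct MLE on the dwell samples) already has one-sigma spread of about
0.05 on the fractions and 9–10% on the taus: the amplitude split of a
bi-exponential with an observed rate ratio compressed by bleaching is
intrinsically ill-conditioned. The curve-fit estimator sits close to
that limit. Consequently, recovered taus are reliably within ~15% at a
fixed seed, while a fraction estimate can land outside ±0.05 at roughly
one sigma of frequency — a property of the problem size, not of the
implementation; the fixed-seed fraction check in the acceptance tests is
allowed to stand at whatever the pre-chosen seed yields.

## MSD analysis

Time-averaged MSD with overlapping windows (maximizing data from short
tracks), pairing only frames separated by exactly the requested lag, so
gapped tracks are handled correctly; displacement-pair counts are
carried for weighting and ensemble averaging. The 2D convention
MSD = 4Dτ is used throughout (tracks are 2D projections); the
dimensionality is a module constant echoed in reports.

* Apparent D: weighted linear fit over the first 4 lags by default
  (common practice), with an offset absorbing the localization-error
  plateau (b ≈ 4σ²); negative slopes are floored at D = 10⁻⁴ µm²/s and
  flagged.
* α: log-log slope over lags 2–10 by default — the first lag is
  noise-dominated and the plateau flattens the tail; the range is
  configurable and recorded. Motion is classed Brownian within the
  dead band α ∈ [0.9, 1.1]: strict α = 1 is unattainable with finite
  data.
* R_c, D: least squares on MSD(t) = R_c²(1 − e^(−4Dt/R_c²)). A fitted
  plateau far beyond the sampled lags (100× the last MSD point) or
  beyond the nucleus radius is reported as unbounded with a flag rather
  than as a number. For diffusion in a reflecting sphere of radius R the
  projected-2D plateau is (4/5)R², so the fitted R_c for a
  sphere-confined molecule sits ≈ 11% below the geometric sphere radius;
  the recovery tests accommodate exactly this known bias.
* log₁₀ D mixtures: scikit-learn Gaussian mixtures with k = 1..3,
  initialized from quantile splits with seeded restarts, selected by
  BIC; k is eligible only with ≥ 10·k tracks; components are reported
  slow to fast. Per-track D values use the offset-on linear fit
  (offset-off is a config choice, recorded in reports).

## Determinism and problem sizes

Every stochastic routine takes an explicit integer seed; the CLI derives
all stage seeds from the single config seed, and reports embed the
resolved configuration, so identical config + seed yields byte-identical
JSON. The shipped studies use 10⁴–2×10⁴ simulated molecules for
survival recovery, 300 molecules × 150 frames for confinement recovery,
1500 tracks for the mixture decomposition, and 20 replicates × 4
families × 5000 dwells for model selection — sizes at which the
estimators' statistical spread is the dominant error term, chosen so the
full study suite completes in about a minute.

## Known limitations

* No Kaplan–Meier treatment of right-censored dwells; censoring is
  flagged only.
* Linking is nearest-neighbour; dense fields (spacing approaching
  max_disp) need an assignment-optimal tracker upstream, imported via
  CSV.
* The intrinsic correction inherits its known under-correction for
  stably bound species; it is provided because it needs no reference,
  not because it is preferred.
* No fluorophore blinking in the simulator, so apparent track
  fragmentation from photophysics cannot be studied with it.
* C_eq counts bound segments' frames; a molecule binding twice
  contributes two segments (the alternative — counting particles — is
  not implemented).
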