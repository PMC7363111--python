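# Methods

This note documents the models and procedures implemented in `neuraxis`,
the assumptions behind them, the parameters that matter, and what the
synthetic validation does and does not demonstrate.

## Data model

A subject's acquisition is a pair of 4D grids sharing one TR: a brain
volume (default 20×20×12 voxels at 2 mm, standing in for a whole-brain
EPI) and a cervical-cord volume (6×6×10 voxels at 1.2 × 1.2 × 5 mm).
The two fields of view are never resampled onto a common lattice; every
cross-structure operation works on the pair. Voxel indices are 0-based,
and left/right is always an explicit mask attribute — never inferred
from axis direction — which removes any RAS/LAS ambiguity.

Temporal preprocessing applied before every analysis: removal of the
first two (pre-equilibrium) volumes, then a discrete-cosine high-pass at
0.01 Hz. The DCT filter is an orthogonal projection (zero phase): all
basis components with frequency k/(2·n_T·TR) below the cutoff, the mean
included, are zeroed. Because a sinusoid that is not aligned with the
retained basis leaks a few percent of its energy across components,
stop-band attenuation at the study length (n_T = 153) is ~6–8% RMS
rather than arbitrarily small; the test suite checks the filter against
an explicit projection oracle rather than an idealised attenuation
figure.

## Physiological noise model

Cardiac and respiratory fluctuations are far above the volume Nyquist
frequency (1/2TR ≈ 0.16 Hz), so they are modelled in the phase domain,
per slice. Cardiac phase is linear position within the beat
(2π·(t−t_prev)/(t_next−t_prev)); evaluation times outside the trigger
span extend the nearest inter-beat interval outward. Respiratory phase
follows the histogram-equalisation convention: magnitude is
π times the cumulative-histogram rank of the centred waveform's absolute
amplitude (100 bins by default; the bin count is configurable since no
canonical value exists), signed by the waveform slope (central
difference over one sample step). For each slice, evaluated at that
slice's own acquisition times, the regressor set is sin/cos of the first
3 cardiac and 4 respiratory harmonics plus the four first-order
sin/cos product pairs for the cardiac×respiratory interaction:
2·3 + 2·4 + 4 = 18 columns per slice. The four-product expansion is the
only reading of "one multiplicative term" consistent with that count.

## Seed-based GLM

For each spinal ROI the mean BOLD series and its temporal derivative
(central differences; the derivative absorbs haemodynamic latency
differences between cortical targets) are regressors of interest.
Confounds: the 18 slice-specific physiological regressors, 6 motion
parameters, and mean white-matter and CSF series. Designs are assembled
per slice (the physiological columns differ by slice) and every column
is mean-centred; rank deficiency is an error, not a warning.

Noise is modelled as voxel-wise AR(1). The fit estimates ρ from OLS
residuals, discretises it to a 0.01 grid (so voxels sharing a bin share
one whitened design factorisation — this is what makes whole-cohort
Monte-Carlo runs cheap), applies the full-sample AR(1) whitening
transform (first row scaled by √(1−ρ²), later rows y_t − ρ·y_{t−1}),
and refits. The full-sample variant keeps all n_T rows so the residual
dof is exactly n_T − p. With ρ = 0 the transform is the identity and the
fit reduces to OLS to machine precision. t statistics are mapped to
z through the t→normal quantile transform; voxels with numerically zero
residual variance but nonzero effect are capped at |z| = 8 and flagged.

The exclusive-variance two-seed model places both hemicord seeds (plus
derivatives) in a single design. Ordinary least squares then attributes
to each seed only its unique variance — the shared variance goes to
neither — which is the operational meaning of mutual orthogonalisation;
seeds with |r| > 0.999 are rejected as collinear.

Group inference is the summary-statistics route: voxel-wise one-sample
t over subject betas, z-transformed. This is the standard asymptotic
stand-in for a full variance-weighted mixed-effects model; with
balanced, homoscedastic synthetic cohorts the two coincide.

## Cluster inference

Suprathreshold clusters use 26-connectivity. Smoothness is estimated
from standardised model residuals: along each axis the mean squared
first difference v gives the lag-1 spatial correlation ρ = 1 − v/2, and
under a Gaussian autocorrelation exp(−d²/4σ²) the equivalent kernel is
σ = √(−1/(4 ln ρ)), FWHM = √(8 ln 2)·σ, floored at 0.5 voxel (purely
white residuals are rougher than the lattice resolves). Resels are the
mask voxel count divided by the FWHM product.

Cluster-level corrected p-values use the stationary-field form: expected
cluster count E[m] from the 3D Euler-characteristic density at the
cluster-forming threshold, expected suprathreshold voxels
E[N] = S·Φ(−u), mean cluster size E[n] = E[N]/E[m], and the exponential
size law P(n ≥ k) = exp(−β·k^{2/3}) with β = (Γ(5/2)/E[n])^{2/3}, giving
p_FWE = 1 − exp(−E[m]·P(n ≥ k)). Brain and cord maps are corrected
separately over their own masks.

Calibration, measured here on stationary smooth Gaussian nulls (FWHM 3
voxels, 24³ grid, u = 2.3): the size law's tail decays empirically like
exp(−0.38·k^{2/3}) against the model's exp(−0.30·k^{2/3}), so corrected
p-values run conservative by roughly 1.5–2× in the far tail and the
realised family-wise error is ≈ 0.026–0.036 at a nominal 0.05. The
alternative formulation with full boundary resel counts brackets nominal
from the other side (≈ 0.07–0.09). The stationary 3D form is kept
because it matches the correction's stated assumptions; an independent
sign-flip permutation cluster-mass test in the suite confirms that every
cluster the GRF correction calls significant replicates at permutation
p < 0.1.

## Laterality and parcel statistics

Activation volume is the count of mask voxels with z above the one-sided
p threshold (default p < 0.01; positive tail by default, since seed
connectivity is interpreted as positive coupling — configurable),
multiplied by the voxel volume from the header (cm³ without resampling
assumptions). The laterality index (L−R)/(L+R) lives in [−1, 1]; an
optional ×100 display scale is provided because percent-style values
are common in reports. Records where both volumes are zero are dropped
with a warning (the index is undefined). Hemisphere masks are supplied
by the caller, and in the intended use exclude the cerebellum (whose
cord coupling is ipsilateral). Group tests are the paired t (left versus
right hemisphere volume within seed), the one-sample t of the index
against zero, and the cord-side × brain-side interaction: the
per-subject contrast (L−R | left seed) − (L−R | right seed), negative
under contralateral organisation, tested against zero.

## Joint ICA

Per subject, masked brain and cord voxels are flattened (C order) and
concatenated column-wise into an n_T × (n_B + n_S) matrix. Because the
cord block is ~15× smaller and differs in SNR, each block is scaled to
unit mean voxel variance before concatenation (configurable; "none"
disables it); the stored means and scales make the concatenation
exactly invertible. Temporal PCA reduces each subject to k = 40
components (desk-scale tests use less), with the retained-variance
fraction reported and a warning below the 90% target; requesting more
components than the data rank clips with a warning rather than padding.

The reduced matrices are stacked row-wise (k·n_sub rows) and FastICA —
logcosh contrast, symmetric decorrelation, tolerance 1e-6, at most 1000
iterations — is run on the transpose so the extracted sources are
spatial maps. Five restarts are taken and the run with the largest
negentropy proxy wins; failure of every restart to converge is an error
carrying the diagnostics. Maps are z-scored over voxels and oriented so
each map's voxel distribution has positive skewness (ICA polarity is
arbitrary; activations carry the heavy tail).

Subject time courses come from stage-1 dual regression (each subject's
full joint matrix regressed on the group maps). Selection: Welch power
spectral density (Hann window, segment length min(64, n_T/2), 50%
overlap), averaged over subjects; a component is kept when mean in-band
power (0.01–0.1 Hz, edges inclusive, DC excluded) is at least 4× the
mean out-of-band power. A kept component's cord map is thresholded at
z > 3.1, GRF-corrected over the cord mask (smoothness taken from the
stack of component cord maps when not supplied; with fewer than 10
maps an unsmoothed one-voxel FWHM is assumed, the conservative
fallback), and flagged "small"
when the surviving volume is under 0.15 cm³ — at the cord resolution,
20 voxels × 7.2 mm³ = 0.144 cm³ sits just inside this bound, which is
what separates genuinely cerebrospinal components from brain-only ones.

A note on the selection rule's reach: at TR = 3.05 s the volume-rate
Nyquist is 0.164 Hz, so any coherent process at 0.25–0.45 Hz aliases
into 0–0.122 Hz, squarely overlapping the neural band. The band-power
rule therefore cannot reject such a source from volume-rate time
courses — physically, rim/motion artifact components pass the power
criterion and must be caught by review, which is why the CLI provides a
`--review` listing of borderline components rather than pretending the
rule handles them. The rule does reject high-frequency sources whenever
the sampling actually resolves them, and broadband (noise-like)
components at any TR.

## Synthetic cohorts: what they emulate, and what they do not

The generator plants six networks: two contralateral hemicord↔opposite-
hemisphere pairs, a ventral-cord↔"motor" and a dorsal-cord↔"thalamus"
network with bilaterally symmetric brain nodes, a brain-only network,
and a 0.25–0.45 Hz rim-patterned artifact source. Network time courses
are white Gaussian noise band-limited to 0.01–0.1 Hz with a zero-phase
filter, scaled by a per-network amplitude (default 1.5 in voxel-noise sd
units — chosen for recoverability at desk scale, deliberately stronger
than typical resting-state effect sizes) and a per-subject lognormal
loading (mean 1, sd 0.3). No HRF convolution is applied: planted signals
are defined directly at BOLD level, and the derivative regressor absorbs
small latencies. Cord signal is confined to compact quadrant-scale
blobs — mirroring the low SNR of real cord data, where most cord voxels
are noise — and brain nodes are focal.

Nuisance structure: AR(1) noise (ρ = 0.3, unit stationary sd), linear
drift, leakage of six random-walk motion parameters, and cardiac
(~1 Hz) / respiratory (~0.3 Hz) artifacts phase-locked to an emitted
physiological trace and evaluated at each slice's own acquisition time
within the TR (ascending slices, brain block then cord block). The
fast artifact source is likewise sampled at per-slice times, so its
slice phases are staggered exactly as a scanner would record them.

Passing tests on these cohorts show that the pipeline recovers planted
structure under realistic nuisance processes at this scale; they do not
show sensitivity at real-data effect sizes, robustness to susceptibility
artifacts, CSF pulsation geometry, imperfect registration, or any
anatomy — none of which the generator attempts.

## Numerical and degenerate-input choices

- All randomised operations take explicit seeds; per-subject seeds are
  derived deterministically from a master seed and logged.
- Mask means are unweighted; empty masks, constant respiratory
  waveforms, constant residual fields, designs with fewer than one
  interest column, and n ≥ n_T volume drops are errors.
- z values are capped at |z| = 8 where residual or between-subject
  variance is numerically zero, and at |z| = 40 in the t→z transform.
- Cluster tables are sorted descending by size, ties by peak z, then by
  peak coordinates, making outputs byte-stable across runs.

## Known limitations

- The GRF cluster p-values inherit the stationary exponential size
  law's tail conservatism quantified above.
- The one-sample group model does not down-weight high-variance
  subjects as a full mixed-effects estimator would.
- Slice-timing correction is consumed, not performed; confound series
  (motion, WM, CSF) are inputs except for mask-mean extraction.
- The desk-scale grids make cord GRF corrections operate at very low
  resel counts, where the asymptotic theory is least accurate; the
  small-cluster flag (a volume bound) is deliberately insensitive to
  this.
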