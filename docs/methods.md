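# Methods

## The model

Simultaneous EEG–fMRI of focal epilepsy patients is analyzed as a blind
source separation problem coupled across modalities.  The enhanced EEG is
represented as a third-order spectrogram tensor `X` (time points ×
frequencies × channels) and the fMRI as a matrix `Y` (time points × ROIs);
both are explained by `R` shared sources:

```
X ≈ Σ_r s_r ∘ g_r ∘ m_r                                   (rank-R CPD)
Y ≈ Σ_r Σ_k (H_k s_r) (b_k * v_r)ᵀ  +  N Pᵀ              (coupled + nuisance)
```

Each source has a temporal signature `s_r` (shared), a spectral signature
`g_r`, an EEG topography `m_r` and an fMRI spatial signature `v_r`.  The
neurovascular bridge is a convolution: `H_k` is the banded Toeplitz operator
of the k-th hemodynamic basis waveform, and every ROI's HRF is the
combination `Σ_k b_k,iv h_k` of `K` adaptive basis functions, shared across
sources (Khatri–Rao structure; `(R+K)·Iv` spatial parameters instead of
`R·K·Iv`).  `N Pᵀ` is a rank-`Q` uncoupled term absorbing structured
fMRI-only fluctuations.  All free variables — including the five
double-gamma parameters of every basis function — are estimated by
minimizing

```
J = βx ‖X − X̂‖² + βy ‖Y − Ŷ‖² + γx ‖λx‖₁ + γy ‖λy‖₁
```

with `λx,r = ‖s_r‖‖g_r‖‖m_r‖` and `λy,r = Σ_k ‖b_k * v_r‖` the modality-wise
source amplitudes.

## HRF parametrization and acausal support

Each basis waveform is a difference of two gamma densities,
`f(t) = Γ(a₁)⁻¹ b₁^{a₁} t^{a₁−1} e^{−b₁t} − c·Γ(a₂)⁻¹ b₂^{a₂} t^{a₂−1} e^{−b₂t}`,
sampled on a lag grid spanning `[−t_pre, t_post]` = [−10 s, 22 s] at the TR.
The gamma argument runs from the start of the grid, so the optimizer can
place a waveform's main lobe at negative lags: BOLD changes that *precede*
the EEG correlate of a discharge, a repeatedly reported phenomenon in
epilepsy, are representable without special-casing.  The convolution
operator carries an `offset` equal to the acausal sample count; `offset = 0`
recovers the ordinary causal (lower-triangular) Toeplitz form.

Default initialization places canonical, delayed and dispersed shapes at
their usual causal latencies (the nominal parameters are translated by
`t_pre`, `a → a + t_pre·b`, so the shapes keep their meaning on the extended
grid).

## Optimization

* Initialization: a CPD of the EEG tensor alone (ALS with truncated-HOSVD
  start) provides `S, G, M`; `V` and `B` follow from two rounds of
  alternating per-ROI least squares; `N, P` from a truncated SVD of the
  coupled-model residual.
* Restarts: the first restart starts from the canonical basis; subsequent
  restarts perturb everything by 10 % relative noise **and** draw the
  latencies of the non-canonical basis functions uniformly over the lag
  support.  The second part matters: a quasi-Newton step never moves a gamma
  mode by ~10 s, so purely local perturbations cannot discover acausal HRFs.
* Solver: L-BFGS-B over all variables (analytic gradients for the factor
  blocks, central finite differences for the 5K HRF parameters, box
  constraints keeping the gamma parameters in a sane regime), run in cycles
  of ≤300 iterations.  Between cycles the representation is rebalanced
  exactly along the cost-invariant scale manifolds (the CP scale split and
  the global `B↔V`, `N↔P` exchanges).  Without rebalancing the optimizer
  drifts along these flat directions until one block collapses numerically
  and the ℓ1 kinks stall the line search far from any minimum.
* Weights: `βx = 1/‖X‖²`, `βy = 1/‖Y‖²` equalize the modalities;
  `γx = γy = 0.001·(βx‖X‖² + βy‖Y‖²)/R` by default.  The ℓ1 term is a
  degeneracy guard, and its scale matters: at ~10× this value the penalty on
  `λy` exceeds the entire fMRI fit gain and the optimum simply zeroes the
  coupled BOLD term.
* Stopping: relative cost change < 1e−8 across cycles or 2000 total
  iterations.  Restarts with non-finite cost are discarded; near-degenerate
  components (`λx,r < 1e−6·max λx`) are logged.

Calibration resolves the remaining ambiguities without changing the model
output: unit-norm `s_r, g_r, m_r` with amplitudes in `λx` (temporal scale
compensated in `v_r`), largest-magnitude entries of `g_r` and `m_r`
positive, each ROI HRF's main lobe positive (sign shared between the `B` and
`V` rows), unit-norm basis waveforms with scales pushed into `B`.

## Model selection and the IED component

Candidate ranks (default 1–5) are scored on: *stability* — mean pairwise
factor congruence (greedy-matched product of absolute column cosines over
the three EEG modes) among the five lowest-cost restarts; *relevance* — the
best Pearson correlation between a temporal signature and the broadband
power envelope of the Wiener-filtered EEG; *parsimony* — the relative cost
gain obtained by moving to the next candidate rank.  The smallest rank with
stability ≥ 0.9, relevance ≥ 0.3 and next-rank gain < 0.3 is selected (the
gain condition rejects ranks before the fit elbow); if none qualifies, the
rank with maximal relevance.  Scoring operates on calibrated solutions —
with arbitrary signs the signed envelope correlation is meaningless.  The
IED source within a solution is the argmax of that correlation, ties to the
lowest index.

## EEG enhancement

The multi-channel Wiener filter is trained on annotated IED segments after
time-delay embedding with τ = 4 lags: with `Rxx` the embedded covariance
inside annotations and `Rnn` outside, `W = Rxx⁻¹(Rxx − Rnn)` is computed
through the generalized eigendecomposition of `(Rxx, Rnn)` keeping
generalized eigenvalues > 1 — the rank truncation that makes the estimated
IED covariance positive semidefinite.  Covariances get diagonal shrinkage
`1e−6·trace/dim` by default.  The filter is square (embedded dimension);
the per-TR reference envelope sums the mean-squared amplitude of *all*
filtered output channels in nonoverlapping TR windows (how the multichannel
output should be collapsed is not prescribed anywhere; summing in quadrature
uses all of it).  The lag-0 block of the filtered output serves as the
enhanced channel-space EEG for spectrogram construction.

## Tensorization

Thomson multitaper spectra (time–bandwidth NW = 3.5, ≈6 tapers) on
nonoverlapping TR-length segments, averaged into 1-Hz bins (1–40 Hz by
default), give one spectrogram per channel synchronized to the fMRI
volumes.  Each (frequency, channel) fiber is log-transformed and z-scored
over time — every channel and frequency then contributes equally and the
factorization sees relative power changes; a plain z-score (no log) is
available as a switch.  BOLD preprocessing: confound regression (motion
parameters with squares and derivatives, unit scrubbing regressors at >1 mm
scan-to-scan displacement, five CompCor components), then zero-phase
Butterworth band-pass 0.008–0.20 Hz, then parcel averaging over an integer
atlas and per-ROI z-scoring.  Empty parcels are dropped and recorded so
maps can be re-expanded.

## Statistical inference

Surrogate BOLD datasets are built from the nuisance-adjusted data
`Y − NPᵀ` by wavelet resampling: db4 DWT (periodized, so the transform is
orthonormal and variance is preserved exactly) to the deepest level keeping
≥8 coefficients per scale, independent permutation of the detail
coefficients within each scale — one permutation shared by all ROIs, which
preserves the spatial correlation structure — and inverse transform.  The
approximation coefficients are kept.  For every ROI, the design matrix
stacks the temporal signatures convolved with that ROI's fitted HRF; OLS
betas divided by their standard errors give pseudo-t values (perfect fits
capped at 1e6 with a log record).  Per source, the activation threshold is
the `⌈0.95(L+1)⌉`-th order statistic of the surrogate maximum-t over ROIs
(the exact permutation order statistic — interpolated percentiles are
slightly anticonservative), and the deactivation threshold its mirror image,
L = 250, α = 0.05.  Thresholds are applied to the observed pseudo-t by
default; thresholding the raw `v_r` ("betas") is available behind a flag and
both statistics are always reported.

Calibration of the procedure is checked by a fully null Monte-Carlo
simulation (`simulate_null_fwe`): white-noise BOLD independent of the
signatures, so the within-scale permutation is exactly exchangeable and the
empirical familywise rate isolates the procedure itself.  At 400 runs the
per-source, per-side rates are 0.04–0.06.  With strongly autocorrelated
noise (AR(1), φ = 0.6–0.8) the permutation wavestrap shows the mild
inflation known from the resampling literature (up to ~0.09 for a smooth
regressor, regardless of wavelet choice) — a property of the published
scheme users should be aware of, not of this implementation.  Activation
and deactivation are each controlled at α; the union of both sides is
nominally ~2α.

## HRF deviance metrics

*Extremity*: one minus the mean absolute correlation of an ROI's HRF
waveform with all other ROIs' waveforms (bounded in [0, 1]; constant
waveforms get 1 with a warning).  *Entropy*: waveforms are sign-aligned to
the pointwise median waveform and unit-norm scaled, projected on the top
`p = min(5, Iv−2)` principal axes; for each ROI a Gaussian with
leave-one-out mean and ridge-regularized covariance (`1e−3·trace/p`, floor
1e−10) is fitted on the other ROIs, and the entropy is the negative log
density of the held-out projection.  A leave-one-out KDE is available as an
alternative estimator.  Both metrics are invariant to global rescaling and
to any single waveform's polarity flip by construction, so high values are
interpretable even where the sign calibration of the fMRI signatures is
uncertain.  Inspection is limited to the top 20 ROIs; overlap with a
candidate zone is scored by the exact binomial tail
`P(Bin(20, f) ≥ hits)`, where `f` is the zone's share of ROIs.

## The synthetic generator

`generate_dataset` draws factors with the structure the method assumes and
composes `X` and `Y` exactly from the model before adding noise (verified
to 1e−10 at construction).  Defaults describe a ten-minute single-run
session: 270 volumes at TR 2.2 s, 50 ROIs, 20 frequency bins, 16 channels,
`R = 2` sources, `K = 2` basis functions, rank-1 nuisance, 10 dB SNR in
both modalities.  The first source is the IED source: per-TR Poisson spike
counts (2/min) smoothed with a short asymmetric kernel, a low-frequency-
dominant spectrum and a focal topography.  All ROIs couple to the sources at
unit scale (brain-wide resting fluctuations); 10 % of ROIs form the planted
zone with ~2.5× loading on the IED source and a deviant HRF whose main lobe
peaks near −6 s (acausal), versus +5 s elsewhere.  A raw 16-channel EEG
realization at 200 Hz (filtered-noise background at unit variance, a 0.3-s
spike template stamped at the spike times with the IED topography, boolean
annotation mask) feeds the Wiener-filter stage.  Same seed ⇒ bit-identical
dataset.

What the generator does *not* emulate: volume conduction via a leadfield,
nonlinear neurovascular coupling, scanner artifacts, inter-run boundaries,
non-Gaussian BOLD noise, spatially correlated noise between ROIs.  Passing
recovery tests therefore show correctness and calibration of the
*algorithms* under the model's own assumptions — not clinical performance
on patient data.

## Monte-Carlo problem sizes

The validation suite runs the null-calibration check at 60 runs (bound
recomputed at that n), joint-recovery at 4 seeds, the planted-deviant
detection at 100 runs, and the end-to-end localization at 3 seeds;
`scripts/acceptance.py` runs the null calibration at the full 200 runs with
L = 250 surrogates.  These sizes are the package's declared validation
conditions; rerunning with larger counts only narrows the binomial error
bars.

## Known limitations

* Wavelet-permutation surrogates mildly inflate the FWE for smooth
  regressors under strong serial correlation (see above); band-pass
  filtering of the BOLD data upstream reduces, but does not remove, the
  mismatch.
* The per-ROI HRF is shared across sources by design; datasets whose
  sources genuinely have different HRFs in the same region will show
  compromise waveforms.
* Model selection is heuristic; the score table is returned for audit
  rather than hiding the choice.
* With `Q > 0`, a sufficiently rich nuisance term can absorb coupled signal
  that resembles a single temporal pattern; keep `Q` small (default 2,
  generator truth 1).
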