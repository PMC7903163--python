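# scmtf — structured coupled matrix-tensor factorization of EEG–fMRI

`scmtf` localizes epileptogenic brain regions from simultaneous EEG–fMRI
recordings of interictal (between-seizure) activity.  It is written for
researchers in EEG–fMRI data fusion and epilepsy imaging who want a
multivariate, symmetric alternative to mass-univariate EEG-correlated fMRI
analysis — one that does not assume a fixed, canonical hemodynamic response.

## The method

The enhanced EEG is represented as a third-order spectrogram tensor
`X ∈ R^{Is×Ig×Im}` (TR-synchronized time points × 1-Hz frequency bins ×
channels) and the fMRI as a parcellated BOLD matrix `Y ∈ R^{Is×Iv}`
(time points × ROIs).  Both are decomposed jointly into `R` sources that
share the temporal mode:

```
X ≈ Σ_r s_r ∘ g_r ∘ m_r
Y ≈ Σ_r Σ_k (H_k s_r) (b_k * v_r)ᵀ + N Pᵀ
```

Each source has a time course `s_r`, an EEG spectrum `g_r`, an EEG
topography `m_r` and an fMRI spatial signature `v_r`.  The EEG-to-BOLD
bridge is a convolution with a *region-specific* hemodynamic response
function (HRF): `H_k` is the Toeplitz operator of the k-th adaptive
double-gamma basis waveform and `b_k` holds its per-ROI weights, so every
ROI gets its own HRF `Σ_k b_k,iv h_k` — including *acausal* ones whose BOLD
response precedes the EEG discharge.  `N Pᵀ` absorbs fMRI-only structured
nuisance.  Everything is estimated by multi-start L-BFGS on the regularized
cost `βx‖X−X̂‖² + βy‖Y−Ŷ‖² + γx‖λx‖₁ + γy‖λy‖₁`.

Two families of localization read-outs follow:

1. **Statistical nonparametric maps (SnPM)** of the spatial signatures:
   wavelet-resampled surrogate BOLD data give per-ROI pseudo-t null
   distributions, and maximum-statistic thresholds control the familywise
   error over ROIs at α = 0.05 per source (activation and deactivation).
2. **HRF-deviance biomarkers**: per-ROI *extremity* (one minus the mean
   absolute waveform correlation with all other ROIs) and *entropy*
   (negative log conditional Gaussian density of the waveform given all
   other ROIs' waveforms), both immune to waveform polarity; the top-20
   ROIs are scored against a candidate zone by an exact binomial tail test.

The pipeline stages — Wiener-filter spike enhancement of the EEG,
multitaper tensorization, joint factorization with rank selection,
inference, HRF metrics — are importable modules and `scmtf` CLI
subcommands (`simulate`, `enhance`, `tensorize`, `fit`, `infer`,
`hrf-metrics`, `run`).  See `docs/methods.md` for the full model,
parameter defaults and limitations.

## Worked example

Patient data of this kind cannot be shared, so the package ships a
generator that draws datasets from the model itself with known ground
truth: an IED source driven by a Poisson spike train (2/min), 50 ROIs of
which five form a planted "epileptogenic zone" with strong IED coupling and
an acausal HRF peaking ~6 s *before* the discharge, plus nuisance and
10 dB noise.

```python
from scmtf.pipeline import PipelineConfig, run_synthetic

cfg = PipelineConfig(rank_list=(1, 2, 3), K=2, Q=1, n_inits=3,
                     n_surrogates=250, seed=0)
out = run_synthetic(seed=0, config=cfg)
rep = out["report"]
zone = out["dataset"].truth.zone_mask
ied = rep["ied_component"]["index"]
print("selected rank:", rep["selected_rank"])
print("IED component:", ied,
      f"(envelope correlation {rep['ied_component']['correlation']:.3f})")
print("active ROIs per source:", rep["snpm"]["n_active_per_source"])
print("planted-zone ROIs in the IED activation map:",
      f"{int(out['snpm'].act_mask[ied][zone].sum())}/{int(zone.sum())}")
ent = rep["enrichment"]["entropy"]
print(f"entropy top-20 hits in zone: {ent['hits']} "
      f"(binomial p = {ent['p_value']:.2e})")
```

prints, in a few minutes on one CPU:

```
selected rank: 2
IED component: 0 (envelope correlation 0.999)
active ROIs per source: [26, 21]
planted-zone ROIs in the IED activation map: 5/5
entropy top-20 hits in zone: 5 (binomial p = 4.32e-02)
```

Reading this: model selection picked the true number of sources (2); the
first component's time course tracks the spike-train reference envelope
almost perfectly; all five planted zone ROIs are significantly activated in
that component's FWE-thresholded map; and five of the twenty most deviant
HRFs (by entropy) fall in the zone, an overlap unlikely under random ROI
sampling (p ≈ 0.04).  The same run from the shell:

```sh
scmtf run --seed 0 --rank-list 1,2,3 --inits 3 --out report.json
```

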