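"""Per-ROI HRF deviance metrics: extremity, entropy, top-k, enrichment.

Regions whose hemodynamic response deviates from the rest of the brain are
candidate epileptogenic tissue.  Two polarity-immune scores quantify this:

* extremity: one minus the mean absolute correlation between an ROI's HRF
  waveform and all other ROIs' waveforms (in [0, 1]);
* entropy: the negative log of the conditional Gaussian density of the
  waveform given all other waveforms, evaluated in a low-dimensional
  principal subspace after sign alignment and unit-norm scaling.

The k most deviant ROIs (default k = 20) are compared against a candidate
zone mask with an exact binomial tail p-value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "HRFVariabilityMap",
    "extremity",
    "entropy",
    "top_k",
    "binomial_enrichment",
    "hrf_variability",
]


@dataclass
class HRFVariabilityMap:
    """Extremity and entropy per ROI, with the top-k indices of each."""

    extremity: np.ndarray
    entropy: np.ndarray
    top_k_extremity: np.ndarray
    top_k_entropy: np.ndarray
    k: int


def _as_waveforms(hrfs: np.ndarray) -> np.ndarray:
    hrfs = np.asarray(hrfs, dtype=float)
    if hrfs.ndim != 2:
        raise ValueError("expected an Iv x n_lags waveform matrix")
    return hrfs


def extremity(hrfs: np.ndarray) -> np.ndarray:
    """e_iv = 1 - mean_{j != iv} |corr(h_iv, h_j)|.

    Constant waveforms cannot be correlated; they receive extremity 1 with a
    warning (maximally unusual by convention).
    """
    h = _as_waveforms(hrfs)
    iv = h.shape[0]
    if iv < 2:
        raise ValueError("extremity needs at least two ROIs")
    centered = h - h.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    flat = norms < 1e-300
    if np.any(flat):
        warnings.warn(f"{int(flat.sum())} constant HRF waveform(s): extremity set to 1")
    safe = np.where(flat, 1.0, norms)
    unit = centered / safe[:, None]
    corr = np.abs(unit @ unit.T)
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    np.fill_diagonal(corr, 0.0)
    e = 1.0 - corr.sum(axis=1) / (iv - 1)
    e[flat] = 1.0
    return np.clip(e, 0.0, 1.0)


def _sign_align(h: np.ndarray) -> np.ndarray:
    """Flip waveform polarities to correlate positively with the median waveform."""
    med = np.median(h, axis=0)
    if np.linalg.norm(med) == 0:  # pathological: align to the first waveform
        med = h[0]
    signs = np.sign(h @ med)
    signs[signs == 0] = 1.0
    return h * signs[:, None]


def entropy(
    hrfs: np.ndarray,
    n_components: int | None = None,
    ridge: float = 1e-3,
    estimator: str = "gaussian",
) -> np.ndarray:
    """Negative log conditional density of each ROI's HRF given all others.

    Waveforms are sign-aligned (polarity-immune) and unit-norm scaled, then
    projected on the top-p principal axes (p = min(5, Iv - 2) by default).
    For each ROI a Gaussian is fitted on the remaining Iv - 1 projections
    (leave-one-out mean and ridge-regularized covariance); the entropy is
    the negative log density of the held-out projection.  ``estimator="kde"``
    substitutes a leave-one-out Gaussian kernel density estimate.
    """
    h = _as_waveforms(hrfs)
    iv = h.shape[0]
    p = n_components if n_components is not None else min(5, iv - 2)
    if p < 1:
        raise ValueError("too few ROIs for the requested subspace dimension")
    if iv <= p:
        raise ValueError("need more ROIs than subspace components")
    h = _sign_align(h)
    norms = np.linalg.norm(h, axis=1, keepdims=True)
    h = h / np.where(norms > 0, norms, 1.0)
    centered = h - h.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    x = centered @ vt[:p].T  # Iv x p scores
    out = np.empty(iv)
    if estimator == "kde":
        for i in range(iv):
            rest = np.delete(x, i, axis=0)
            kde = stats.gaussian_kde(rest.T)
            dens = max(float(kde(x[i])[0]), 1e-300)
            out[i] = -np.log(dens)
        return out
    if estimator != "gaussian":
        raise ValueError("estimator must be 'gaussian' or 'kde'")
    for i in range(iv):
        rest = np.delete(x, i, axis=0)
        mu = rest.mean(axis=0)
        dev = rest - mu
        cov = dev.T @ dev / (rest.shape[0] - 1)
        lam = max(ridge * np.trace(cov) / p, 1e-10)
        cov = cov + lam * np.eye(p)
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            raise np.linalg.LinAlgError("singular covariance despite ridge")
        diff = x[i] - mu
        maha = diff @ np.linalg.solve(cov, diff)
        out[i] = 0.5 * (p * np.log(2 * np.pi) + logdet + maha)
    return out


def top_k(values: np.ndarray, k: int = 20) -> np.ndarray:
    """Indices of the k largest values, descending; ties break to lower index."""
    values = np.asarray(values, dtype=float)
    if k > values.size:
        raise ValueError(f"k={k} exceeds the number of ROIs ({values.size})")
    order = np.argsort(-values, kind="stable")[:k]
    dup = np.unique(values[order]).size < min(k, values.size)
    if dup:
        logger.info("ties among the top-%d values; broken by lower index", k)
    return order


def binomial_enrichment(k_hits: int, k_total: int, zone_fraction: float) -> float:
    """Exact binomial tail p-value P(Bin(k_total, f) >= k_hits)."""
    if not (0 < zone_fraction < 1):
        raise ValueError("zone_fraction must lie strictly between 0 and 1")
    if not (0 <= k_hits <= k_total):
        raise ValueError("require 0 <= k_hits <= k_total")
    if k_hits == 0:
        return 1.0
    return float(stats.binom.sf(k_hits - 1, k_total, zone_fraction))


def hrf_variability(
    hrfs: np.ndarray,
    k: int = 20,
    zone_mask: np.ndarray | None = None,
    **entropy_kwargs,
) -> tuple[HRFVariabilityMap, dict | None]:
    """Convenience wrapper: both metrics, top-k, and optional zone enrichment.

    When ``zone_mask`` (boolean per ROI) is given, the zone fraction is the
    masked share of ROIs and an exact binomial p-value is computed for the
    number of top-k ROIs falling inside the zone, per metric.
    """
    e = extremity(hrfs)
    h = entropy(hrfs, **entropy_kwargs)
    k = min(k, e.size)
    vmap = HRFVariabilityMap(e, h, top_k(e, k), top_k(h, k), k)
    enrich = None
    if zone_mask is not None:
        zone_mask = np.asarray(zone_mask, dtype=bool)
        frac = zone_mask.mean()
        enrich = {}
        for name, idx in (("extremity", vmap.top_k_extremity),
                          ("entropy", vmap.top_k_entropy)):
            hits = int(zone_mask[idx].sum())
            enrich[name] = {
                "hits": hits,
                "k": k,
                "zone_fraction": float(frac),
                "p_value": binomial_enrichment(hits, k, float(frac))
                if 0 < frac < 1 else float("nan"),
            }
    return vmap, enrich
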