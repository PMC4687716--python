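"""SNR estimation, map smoothing, and voxel-wise shell-trend statistics.

* SNR: noise is the mean (over a mask) of the per-voxel standard deviation
  across the b0 volumes; each shell's SNR is its mask-mean weighted signal
  divided by that noise, and a cumulative k-shell scheme's SNR is the mean
  of its member shells' SNRs.
* Smoothing: separable Gaussian with σ = FWHM / (2√(2 ln 2)) per axis,
  NaN-aware (mask-renormalized), applied to anisotropy maps before
  voxel-wise analyses.  The default FWHM of 3 voxels mirrors the
  "Gaussian kernel of 3" used in the reference analysis; whether that
  kernel is σ or FWHM, voxels or mm, is not nailed down there — this
  package reads it as FWHM in voxels and keeps it configurable.
* Voxel-wise regression: per voxel, OLS of anisotropy on the cumulative
  scheme code 1..5 with an optional age covariate (subjects pooled),
  two-sided p from the t distribution, Benjamini–Hochberg FDR over
  in-mask voxels at q (default 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .deviation import shell_trend
from .dti import ScalarMap

__all__ = [
    "SNRReport",
    "VoxelRegressionResult",
    "snr",
    "gaussian_smooth",
    "fdr_bh",
    "voxelwise_shell_regression",
    "roi_mean_trend",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


@dataclass(frozen=True)
class SNRReport:
    noise: float
    per_shell: dict  # shell id -> SNR
    per_scheme: dict  # cumulative k -> mean of member-shell SNRs
    mask_name: str = "mask"


def snr(dataset, mask: np.ndarray, mask_name: str = "mask") -> SNRReport:
    """Estimate per-shell and per-cumulative-scheme SNR from the b0 spread.

    Requires ≥2 b0 volumes (the noise is their per-voxel standard
    deviation, averaged over the mask).  Zero noise (identical b0 volumes)
    yields +inf SNR with a warning.
    """
    gtab = dataset.gtab
    b0 = dataset.signal[..., gtab.b0_mask][mask]
    if b0.shape[-1] < 2:
        raise ValueError("SNR estimation needs at least 2 b0 volumes")
    noise = float(b0.std(axis=-1, ddof=1).mean())
    if noise == 0.0:
        warnings.warn("identical b0 volumes: noise = 0, SNR reported as inf")
    per_shell = {}
    for shell in range(1, gtab.n_shells + 1):
        sel = gtab.shell_id == shell
        mean_sig = float(dataset.signal[..., sel][mask].mean())
        per_shell[shell] = mean_sig / noise if noise > 0 else float("inf")
    per_scheme = {
        k: float(np.mean([per_shell[s] for s in range(1, k + 1)]))
        for k in range(1, gtab.n_shells + 1)
    }
    return SNRReport(noise, per_shell, per_scheme, mask_name)


def gaussian_smooth(scalar_map: ScalarMap, fwhm_voxels: float = 3.0) -> ScalarMap:
    """NaN-aware separable Gaussian smoothing of a scalar map.

    The map is smoothed as (G∗(m·v)) / (G∗m) with m the finite-value mask,
    which renormalizes the kernel at mask edges; FWHM 0 is the identity.
    """
    if fwhm_voxels < 0:
        raise ValueError("fwhm must be nonnegative")
    if fwhm_voxels == 0:
        return scalar_map
    sigma = fwhm_voxels * FWHM_TO_SIGMA
    values = scalar_map.values
    finite = np.isfinite(values)
    filled = np.where(finite, values, 0.0)
    num = ndimage.gaussian_filter(filled, sigma)
    den = ndimage.gaussian_filter(finite.astype(float), sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = num / den
    smoothed[~finite] = np.nan
    return ScalarMap(name=scalar_map.name, values=smoothed, mask=scalar_map.mask)


def fdr_bh(pvalues, q: float = 0.05):
    """Benjamini–Hochberg step-up procedure.

    Returns ``(critical_p, reject)``: the largest p_(i) ≤ (i/m)·q and a
    boolean array flagging every p ≤ critical_p.  ``critical_p`` is 0.0
    (nothing rejected) when no ordered p-value clears its line.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.sort(p)
    line = q * np.arange(1, m + 1) / m
    passing = np.flatnonzero(order <= line)
    if passing.size == 0:
        return 0.0, np.zeros(m, dtype=bool)
    critical_p = float(order[passing[-1]])
    return critical_p, p <= critical_p


@dataclass(frozen=True)
class VoxelRegressionResult:
    slope: np.ndarray
    t: np.ndarray
    p: np.ndarray
    critical_p: float
    significant: np.ndarray
    mask: np.ndarray
    q: float


def voxelwise_shell_regression(
    maps, scheme_codes, mask: np.ndarray, ages=None, q: float = 0.05
) -> VoxelRegressionResult:
    """Voxel-wise OLS of anisotropy on the cumulative scheme code, with FDR.

    Parameters
    ----------
    maps : sequence of 3D arrays or ScalarMap
        One map per observation (subject × scheme), all on one grid.
    scheme_codes : sequence of int
        The cumulative scheme code (1..5) of each observation.
    ages : sequence of float, optional
        Per-observation age covariate (subjects pooled).
    """
    arrays = [m.values if isinstance(m, ScalarMap) else np.asarray(m, float) for m in maps]
    codes = np.asarray(scheme_codes, dtype=float)
    if len(arrays) != codes.size:
        raise ValueError("one scheme code per map required")
    if np.unique(codes).size < 2:
        raise ValueError("need at least 2 distinct scheme codes")
    y = np.stack([a[mask] for a in arrays])  # (n_obs, nvox)
    cols = [np.ones_like(codes), codes]
    if ages is not None:
        ages = np.asarray(ages, dtype=float)
        if np.unique(ages).size > 1:
            cols.append(ages)
    x = np.column_stack(cols)
    n_obs, n_par = x.shape
    if n_obs <= n_par:
        raise ValueError("not enough observations for the design")

    usable = np.all(np.isfinite(y), axis=0)
    beta = np.full((n_par, y.shape[1]), np.nan)
    tmap = np.full(y.shape[1], np.nan)
    pmap = np.full(y.shape[1], np.nan)
    if np.any(usable):
        yu = y[:, usable]
        pinv = np.linalg.pinv(x)
        b = pinv @ yu
        resid = yu - x @ b
        dof = n_obs - n_par
        sigma2 = np.sum(resid**2, axis=0) / dof
        xtx_inv = np.linalg.inv(x.T @ x)
        se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            t = b[1] / se
        t = np.where(se > 0, t, np.where(b[1] == 0, 0.0, np.inf * np.sign(b[1])))
        pv = 2.0 * sps.t.sf(np.abs(t), dof)
        beta[:, usable] = b
        tmap[usable] = t
        pmap[usable] = pv

    critical_p, reject = fdr_bh(pmap[usable], q) if np.any(usable) else (0.0, None)
    shape = mask.shape
    slope_map = np.full(shape, np.nan)
    t_map = np.full(shape, np.nan)
    p_map = np.full(shape, np.nan)
    sig_map = np.zeros(shape, dtype=bool)
    idx = np.flatnonzero(mask.ravel())
    slope_map.ravel()[idx] = beta[1]
    t_map.ravel()[idx] = tmap
    p_map.ravel()[idx] = pmap
    if reject is not None:
        sig_map.ravel()[idx[usable]] = reject
    return VoxelRegressionResult(slope_map, t_map, p_map, critical_p, sig_map, mask, q)


def roi_mean_trend(maps, scheme_codes, roi_mask: np.ndarray, ages=None):
    """ROI means per observation plus their OLS trend on the scheme code.

    Returns ``(table, TrendResult)`` where ``table`` is a pandas DataFrame
    with one row per observation (scheme code, optional age, ROI mean).
    """
    import pandas as pd

    if not np.any(roi_mask):
        raise ValueError("empty ROI")
    rows = []
    codes = np.asarray(scheme_codes)
    for i, m in enumerate(maps):
        values = m.values if isinstance(m, ScalarMap) else np.asarray(m, float)
        sel = roi_mask & np.isfinite(values)
        row = {"scheme": int(codes[i]), "mean": float(values[sel].mean())}
        if ages is not None:
            row["age"] = float(ages[i])
        rows.append(row)
    table = pd.DataFrame(rows)
    trend = shell_trend(
        table["scheme"], table["mean"], ages=table["age"] if ages is not None else None
    )
    return table, trend
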