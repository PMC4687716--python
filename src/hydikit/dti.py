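"""Diffusion tensor estimation and the classic scalar maps.

The tensor model writes the per-voxel signal as
``log S(g, b) = log S0 − b gᵀ D g`` with D a symmetric 3×3 diffusion
tensor.  One tensor is fitted jointly to **all** volumes of whatever
shell subset the dataset carries (a pooled multi-shell fit); estimation
is linear least squares on the log signal with one reweighting pass
(weights = squared predicted signal), the standard WLS scheme that
counters the log transform's heteroscedasticity.

Scalar maps from the eigenvalues λ1 ≥ λ2 ≥ λ3:

* ``FA  = sqrt(3/2 · Σ(λi − MD)² / Σλi²)`` (0 where the denominator is 0)
* ``MD  = (λ1 + λ2 + λ3) / 3``
* ``RD  = (λ2 + λ3) / 2``
* ``AX  = λ1``
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .gradients import DWIDataset

__all__ = ["TensorField", "ScalarMap", "fit_tensor", "tensor_scalars", "fa_from_eigenvalues"]

log = logging.getLogger(__name__)


class TensorFitError(ValueError):
    pass


@dataclass(frozen=True)
class ScalarMap:
    """A named 3D scalar map; NaN outside the mask."""

    name: str
    values: np.ndarray
    mask: np.ndarray

    def roi_mean(self, roi: np.ndarray) -> float:
        sel = roi & self.mask & np.isfinite(self.values)
        return float(self.values[sel].mean())


@dataclass(frozen=True)
class TensorField:
    """Per-voxel eigen-system of the fitted diffusion tensor.

    ``eigenvalues`` (x,y,z,3) sorted descending and clamped at 0;
    ``eigenvectors`` (x,y,z,3,3) with ``eigenvectors[..., i]`` the unit
    eigenvector of λ_{i+1}.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    log_s0: np.ndarray
    mask: np.ndarray
    n_clamped: int = 0
    n_floored_signal: int = 0

    @property
    def principal_direction(self) -> np.ndarray:
        return self.eigenvectors[..., 0]


def _design_matrix(gtab) -> np.ndarray:
    b = gtab.bvals
    g = gtab.bvecs
    return np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )


def _tensors_from_params(params: np.ndarray) -> np.ndarray:
    """(N, 7) fit parameters → (N, 3, 3) symmetric tensors."""
    d = np.empty((params.shape[0], 3, 3))
    d[:, 0, 0] = params[:, 1]
    d[:, 1, 1] = params[:, 2]
    d[:, 2, 2] = params[:, 3]
    d[:, 0, 1] = d[:, 1, 0] = params[:, 4]
    d[:, 0, 2] = d[:, 2, 0] = params[:, 5]
    d[:, 1, 2] = d[:, 2, 1] = params[:, 6]
    return d


def fit_tensor(dataset: DWIDataset, mask: np.ndarray | None = None) -> TensorField:
    """Fit one diffusion tensor per in-mask voxel (WLS, one reweighting pass).

    Requires at least 6 unique weighted directions plus a b0 volume.
    Nonpositive signal values are floored at a small positive constant
    (flagged and counted) so the log transform is defined.
    """
    gtab = dataset.gtab
    weighted = ~gtab.b0_mask
    if not np.any(gtab.b0_mask):
        raise TensorFitError("dataset has no b0 volume")
    unique_dirs = np.unique(np.round(np.abs(gtab.bvecs[weighted]), 6), axis=0)
    if unique_dirs.shape[0] < 6:
        raise TensorFitError("need at least 6 unique weighted directions")
    if len(gtab) < 7:
        raise TensorFitError("need at least 7 usable volumes")

    if mask is None:
        mask = np.ones(dataset.shape, dtype=bool)
    signal = dataset.signal[mask]  # (nvox, nvol)
    floor = max(dataset.signal.max() * 1e-10, 1e-300)
    n_floored = int(np.count_nonzero(signal <= 0))
    if n_floored:
        log.warning("floored %d nonpositive signal values before log", n_floored)
    y = np.log(np.maximum(signal, floor))

    design = _design_matrix(gtab)
    # ordinary pass (shared design: one lstsq for every voxel)
    params, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    params = params.T  # (nvox, 7)
    # one reweighting pass, weights = squared predicted signal
    pred = params @ design.T
    w = np.exp(2.0 * np.clip(pred, -700, 700))
    dtw = np.einsum("ni,vn,nj->vij", design, w, design)
    rhs = np.einsum("ni,vn,vn->vi", design, w, y)
    params = np.linalg.solve(dtw, rhs[..., None])[..., 0]

    tensors = _tensors_from_params(params)
    evals, evecs = np.linalg.eigh(tensors)  # ascending
    evals = evals[:, ::-1]
    evecs = evecs[:, :, ::-1]  # columns follow the descending order
    n_clamped = int(np.count_nonzero(evals < 0))
    if n_clamped:
        log.info("clamped %d negative eigenvalues to 0", n_clamped)
    evals = np.maximum(evals, 0.0)

    shape = dataset.shape
    out_evals = np.full((*shape, 3), np.nan)
    out_evecs = np.full((*shape, 3, 3), np.nan)
    out_s0 = np.full(shape, np.nan)
    out_evals[mask] = evals
    out_evecs[mask] = evecs
    out_s0[mask] = params[:, 0]
    return TensorField(
        eigenvalues=out_evals,
        eigenvectors=out_evecs,
        log_s0=out_s0,
        mask=mask,
        n_clamped=n_clamped,
        n_floored_signal=n_floored,
    )


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy of (..., 3) eigenvalue arrays; 0 where λ ≡ 0."""
    evals = np.asarray(evals, dtype=float)
    md = evals.mean(axis=-1, keepdims=True)
    num = 1.5 * np.sum((evals - md) ** 2, axis=-1)
    denom = np.sum(evals**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(num / denom)
    return np.where(denom > 0, fa, 0.0)


def tensor_scalars(tf: TensorField) -> dict:
    """FA, MD, RD, AX maps from a fitted :class:`TensorField`."""
    evals = tf.eigenvalues
    maps = {
        "FA": fa_from_eigenvalues(evals),
        "MD": evals.mean(axis=-1),
        "RD": (evals[..., 1] + evals[..., 2]) / 2.0,
        "AX": evals[..., 0],
    }
    out = {}
    for name, values in maps.items():
        vals = np.where(tf.mask, values, np.nan)
        out[name] = ScalarMap(name=name, values=vals, mask=tf.mask)
    return out
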