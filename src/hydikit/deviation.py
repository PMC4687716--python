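"""Angular deviation between fiber reconstructions and its shell trend.

Compares the dominant per-voxel fiber direction of one reconstruction
(e.g. a k-shell scheme) against a reference (the full 5-shell scheme):

    θ = arccos(|u_target · u_reference|)   (degrees, in [0, 90])

The absolute value makes θ invariant to the sign/antipodal ambiguity of
fiber directions.  ROI means feed an ordinary least-squares trend of mean
θ on the scheme code 1..5 (optionally with an age covariate), matching
the analysis that asks whether each added shell moves a reconstruction
closer to the full-scheme reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .dti import TensorField
from .qbi import PeakField

__all__ = [
    "DirectionField",
    "DeviationResult",
    "TrendResult",
    "dominant_direction",
    "angular_deviation",
    "shell_trend",
]

#: eigenvalue contrast below which a tensor voxel counts as isotropic
ISOTROPY_RTOL = 1e-3


@dataclass(frozen=True)
class DirectionField:
    """Per-voxel dominant unit direction, canonicalized antipodally."""

    directions: np.ndarray  # (x, y, z, 3); NaN where invalid
    valid: np.ndarray  # bool; False for degenerate/excluded voxels
    source: str  # "DTI" or "QBI"
    scheme_k: int | None = None

    @property
    def n_excluded(self) -> int:
        return int(np.count_nonzero(~self.valid))


@dataclass(frozen=True)
class DeviationResult:
    """Voxel-wise angular deviation map with ROI summaries."""

    theta: np.ndarray  # degrees, NaN outside the evaluated voxels
    mask: np.ndarray  # voxels that entered the ROI statistics
    roi_mean: float
    roi_max: float
    n_excluded: int
    scheme_k: int | None = None


def canonicalize(directions: np.ndarray) -> np.ndarray:
    """Flip each vector so its first nonzero component is positive."""
    d = np.array(directions, dtype=float)
    flat = d.reshape(-1, 3)
    for axis in range(3):
        prior_zero = np.all(np.abs(flat[:, :axis]) <= 1e-12, axis=1)
        flip = prior_zero & (flat[:, axis] < -1e-12)
        flat[flip] *= -1.0
    return flat.reshape(d.shape)


def dominant_direction(
    recon: TensorField | PeakField, mask: np.ndarray, scheme_k: int | None = None
) -> DirectionField:
    """Dominant fiber direction per in-mask voxel.

    DTI → principal eigenvector e1; QBI → the highest-QA ODF peak.
    Near-isotropic tensors (λ1 ≈ λ2) and flat-ODF voxels are excluded
    (marked invalid) rather than contributing arbitrary directions.
    """
    if not np.any(mask):
        raise ValueError("empty mask")
    if isinstance(recon, TensorField):
        dirs = recon.principal_direction.copy()
        lam = recon.eigenvalues
        with np.errstate(invalid="ignore", divide="ignore"):
            contrast = (lam[..., 0] - lam[..., 1]) / np.where(
                lam[..., 0] > 0, lam[..., 0], 1.0
            )
        valid = mask & recon.mask & (contrast > ISOTROPY_RTOL)
        source = "DTI"
    elif isinstance(recon, PeakField):
        dirs = recon.principal_direction.copy()
        valid = mask & recon.mask & ~recon.degenerate
        source = "QBI"
    else:
        raise TypeError(f"unsupported reconstruction type {type(recon)!r}")
    dirs = canonicalize(dirs)
    norms = np.linalg.norm(dirs, axis=-1)
    valid = valid & np.isfinite(norms) & (norms > 0)
    out = np.full(dirs.shape, np.nan)
    out[valid] = dirs[valid] / norms[valid, None]
    return DirectionField(out, valid, source, scheme_k)


def angular_deviation(
    target: DirectionField, reference: DirectionField, mask: np.ndarray
) -> DeviationResult:
    """Per-voxel inner angle between two direction fields over a ROI.

    Voxels invalid in either field are excluded from the ROI statistics
    (their count is reported), never assigned θ = 0.
    """
    if target.directions.shape != reference.directions.shape:
        raise ValueError("direction fields live on different grids")
    if mask.shape != target.directions.shape[:-1]:
        raise ValueError("mask grid does not match the direction fields")
    both = mask & target.valid & reference.valid
    dots = np.abs(np.sum(target.directions * reference.directions, axis=-1))
    theta = np.degrees(np.arccos(np.clip(dots, -1.0, 1.0)))
    theta = np.where(both, theta, np.nan)
    n_excluded = int(np.count_nonzero(mask & ~(target.valid & reference.valid)))
    if not np.any(both):
        raise ValueError("no valid voxels in the ROI")
    return DeviationResult(
        theta=theta,
        mask=both,
        roi_mean=float(np.nanmean(theta[both])),
        roi_max=float(np.nanmax(theta[both])),
        n_excluded=n_excluded,
        scheme_k=target.scheme_k,
    )


@dataclass(frozen=True)
class TrendResult:
    """OLS trend of a response on the scheme code (plus optional age)."""

    slope: float
    t: float
    p: float
    intercept: float
    n: int


def shell_trend(scheme_codes, values, ages=None) -> TrendResult:
    """OLS of a per-scheme summary on the scheme code 1..5.

    ``ages`` adds a covariate column (one age per observation); the slope,
    t and two-sided p reported are those of the scheme-code predictor.
    """
    codes = np.asarray(scheme_codes, dtype=float)
    y = np.asarray(values, dtype=float)
    if codes.size != y.size:
        raise ValueError("codes and values differ in length")
    if codes.size < 3:
        raise ValueError("need at least 3 points for a trend")
    cols = [np.ones_like(codes), codes]
    if ages is not None:
        cols.append(np.asarray(ages, dtype=float))
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design (constant predictor?)")
    if np.ptp(y) == 0.0:
        # exactly constant response: zero slope, no evidence of a trend
        return TrendResult(slope=0.0, t=0.0, p=1.0, intercept=float(y[0]), n=int(codes.size))
    fit = sm.OLS(y, design).fit()
    t_val, p_val = float(fit.tvalues[1]), float(fit.pvalues[1])
    if not np.isfinite(t_val) and fit.params[1] == 0.0:
        # exactly constant response: no trend, maximal p
        t_val, p_val = 0.0, 1.0
    return TrendResult(
        slope=float(fit.params[1]),
        t=t_val,
        p=p_val,
        intercept=float(fit.params[0]),
        n=int(codes.size),
    )
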