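"""Deterministic streamline tractography with anisotropy stopping criteria.

FACT-style tracking: at each step the direction is taken from the nearest
voxel's peak set (or tensor e1), sign-flipped and — when several peaks
exist — selected to best align with the incoming heading by absolute dot
product.  Integration is bidirectional Euler from each seed with a fixed
step (default half the smallest voxel dimension).  A streamline ends when

* the stopping map (trilinear-interpolated) falls below the threshold,
* the turn between consecutive steps exceeds the maximum angle (60° by
  default), or
* it leaves the volume.

Seeds are drawn uniformly at random (seeded RNG) inside the seed mask
until the target fiber count (default 300) is collected or the seed
budget runs out.  ``paper_threshold_policy`` returns the stopping
thresholds used for the FA/GFA/NQA-aided analyses: FA 0.25 single-shell /
0.20 multi-shell, GFA 0.02 / 0.03, NQA 0.25 / 0.30.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dti import ScalarMap, TensorField
from .qbi import PeakField

__all__ = [
    "TrackingParams",
    "Streamline",
    "track",
    "paper_threshold_policy",
    "streamline_summary",
    "save_trk",
]

THRESHOLD_TABLE = {
    "FA": {"single": 0.25, "multi": 0.20},
    "GFA": {"single": 0.02, "multi": 0.03},
    "NQA": {"single": 0.25, "multi": 0.30},
}


def paper_threshold_policy(stop_map_name: str, scheme_k: int) -> float:
    """Stopping threshold for a map and cumulative shell scheme k ∈ 1..5."""
    if stop_map_name not in THRESHOLD_TABLE:
        raise KeyError(f"unknown stopping map {stop_map_name!r}")
    if not 1 <= scheme_k <= 5:
        raise ValueError(f"scheme k={scheme_k} out of range 1..5")
    row = THRESHOLD_TABLE[stop_map_name]
    return row["single"] if scheme_k == 1 else row["multi"]


@dataclass(frozen=True)
class TrackingParams:
    stop_threshold: float
    stop_map_name: str = "FA"
    max_turn_deg: float = 60.0
    step_mm: float | None = None  # None -> half the smallest voxel dimension
    target_fiber_count: int = 300
    min_points: int = 3  # streamlines shorter than 2 steps are discarded
    max_points_per_side: int = 2000
    seed: int = 0
    seed_budget_factor: int = 100

    def __post_init__(self):
        if not 0 < self.stop_threshold < 1:
            raise ValueError("stop_threshold must lie in (0, 1)")
        if not 0 < self.max_turn_deg <= 90:
            raise ValueError("max_turn_deg must lie in (0, 90]")
        if self.step_mm is not None and self.step_mm <= 0:
            raise ValueError("step_mm must be positive")


@dataclass(frozen=True)
class Streamline:
    """Ordered polyline in physical (mm) coordinates."""

    points: np.ndarray  # (n, 3)
    values: np.ndarray  # stopping-map value at each point
    termination: tuple  # reasons at (backward end, forward end)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def length_mm(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


def _peak_directions(recon) -> np.ndarray:
    """(x, y, z, n_peaks, 3) candidate directions from either model."""
    if isinstance(recon, TensorField):
        return recon.principal_direction[..., None, :]
    if isinstance(recon, PeakField):
        return recon.directions
    raise TypeError(f"unsupported reconstruction type {type(recon)!r}")


def _trilinear(volume: np.ndarray, xyz: np.ndarray):
    """Trilinear interpolation at one voxel-space point; NaN outside."""
    lo = np.floor(xyz).astype(int)
    frac = xyz - lo
    shape = volume.shape
    if np.any(xyz < 0) or np.any(xyz > np.array(shape) - 1):
        return np.nan
    val = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (frac[0] if dx else 1 - frac[0])
                    * (frac[1] if dy else 1 - frac[1])
                    * (frac[2] if dz else 1 - frac[2])
                )
                if w == 0.0:
                    continue
                val += w * volume[
                    min(lo[0] + dx, shape[0] - 1),
                    min(lo[1] + dy, shape[1] - 1),
                    min(lo[2] + dz, shape[2] - 1),
                ]
    return val


def _march(start_vox, heading, peaks, stop_vals, threshold, step_vox, cos_turn, max_pts):
    """March one direction from a seed in voxel coordinates."""
    shape = stop_vals.shape
    points = []
    pos = start_vox.copy()
    prev_dir = heading
    reason = "max_points"
    for _ in range(max_pts):
        vox = np.round(pos).astype(int)
        if np.any(vox < 0) or np.any(vox >= shape):
            reason = "out_of_bounds"
            break
        cand = peaks[tuple(vox)]  # (n_peaks, 3)
        finite = np.isfinite(cand[:, 0])
        if not np.any(finite):
            reason = "no_direction"
            break
        cand = cand[finite]
        dots = cand @ prev_dir
        best = np.argmax(np.abs(dots))
        direction = cand[best] * (1.0 if dots[best] >= 0 else -1.0)
        if direction @ prev_dir < cos_turn:
            reason = "angle"
            break
        nxt = pos + step_vox * direction
        val = _trilinear(stop_vals, nxt)
        if not np.isfinite(val):
            reason = "out_of_bounds"
            break
        if val < threshold:
            reason = "low_anisotropy"
            break
        points.append((nxt.copy(), val))
        pos = nxt
        prev_dir = direction
    return points, reason


def track(
    directions: TensorField | PeakField,
    stop_map: ScalarMap,
    seeds_mask: np.ndarray,
    params: TrackingParams,
    affine: np.ndarray | None = None,
    voxel_size_mm=(1.0, 1.0, 1.0),
) -> list[Streamline]:
    """Deterministic bidirectional streamline tracking.

    Integration runs in voxel coordinates with an isotropic-equivalent
    step (``step_mm`` divided per-axis by the voxel size); emitted points
    are mapped to physical mm through ``affine`` (voxel-size diagonal if
    omitted).
    """
    peaks = _peak_directions(directions)
    stop_vals = np.where(
        np.isfinite(stop_map.values) & stop_map.mask, stop_map.values, 0.0
    )
    voxel_size = np.asarray(voxel_size_mm, dtype=float)
    if affine is None:
        affine = np.diag([*voxel_size, 1.0])
    step_mm = params.step_mm if params.step_mm is not None else voxel_size.min() / 2.0
    step_vox = step_mm / voxel_size  # anisotropic voxels: per-axis scaling
    cos_turn = np.cos(np.radians(params.max_turn_deg))

    eligible = seeds_mask & (stop_vals >= params.stop_threshold)
    seed_voxels = np.argwhere(eligible)
    if seed_voxels.shape[0] == 0:
        raise ValueError("no seed voxel at or above the stopping threshold")

    rng = np.random.default_rng(params.seed)
    streamlines: list[Streamline] = []
    budget = params.seed_budget_factor * params.target_fiber_count
    for _ in range(budget):
        if len(streamlines) >= params.target_fiber_count:
            break
        vox = seed_voxels[rng.integers(seed_voxels.shape[0])]
        pos = vox + rng.uniform(-0.5, 0.5, 3)
        ivox = np.round(pos).astype(int)
        np.clip(ivox, 0, np.array(stop_vals.shape) - 1, out=ivox)
        cand = peaks[tuple(ivox)]
        if not np.isfinite(cand[0, 0]):
            continue
        v0 = _trilinear(stop_vals, pos)
        if not np.isfinite(v0) or v0 < params.stop_threshold:
            continue
        heading = cand[0]
        fwd, r_fwd = _march(
            pos, heading, peaks, stop_vals, params.stop_threshold,
            step_vox, cos_turn, params.max_points_per_side,
        )
        bwd, r_bwd = _march(
            pos, -heading, peaks, stop_vals, params.stop_threshold,
            step_vox, cos_turn, params.max_points_per_side,
        )
        pts = [p for p, _ in reversed(bwd)] + [pos] + [p for p, _ in fwd]
        vals = [v for _, v in reversed(bwd)] + [v0] + [v for _, v in fwd]
        if len(pts) < params.min_points:
            continue
        vox_pts = np.asarray(pts)
        phys = vox_pts @ affine[:3, :3].T + affine[:3, 3]
        streamlines.append(
            Streamline(points=phys, values=np.asarray(vals), termination=(r_bwd, r_fwd))
        )
    return streamlines


def streamline_summary(streamlines: list[Streamline]) -> dict:
    """Count, length statistics, and termination-reason histogram."""
    lengths = [s.length_mm for s in streamlines]
    reasons: dict[str, int] = {}
    for s in streamlines:
        for r in s.termination:
            reasons[r] = reasons.get(r, 0) + 1
    return {
        "count": len(streamlines),
        "mean_length_mm": float(np.mean(lengths)) if lengths else 0.0,
        "min_length_mm": float(np.min(lengths)) if lengths else 0.0,
        "max_length_mm": float(np.max(lengths)) if lengths else 0.0,
        "termination_reasons": dict(sorted(reasons.items())),
    }


def save_trk(streamlines: list[Streamline], affine: np.ndarray, shape, path) -> None:
    """Write streamlines as a TrackVis .trk file (physical/RAS mm points)."""
    import nibabel as nib
    from nibabel.streamlines import Tractogram

    tractogram = Tractogram(
        [s.points for s in streamlines], affine_to_rasmm=np.eye(4)
    )
    header = {
        "voxel_to_rasmm": np.asarray(affine, dtype=float),
        "dimensions": np.asarray(shape, dtype=np.int16),
    }
    nib.streamlines.save(tractogram, str(path), header=header)
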