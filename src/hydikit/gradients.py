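"""Gradient tables, multi-shell detection, DWI dataset I/O and shell subsets.

A multi-shell ("hybrid") diffusion acquisition samples q-space on several
concentric shells, each a fixed b-value with many gradient directions, plus
a handful of unweighted (b0) volumes.  This module holds the two containers
everything downstream consumes — :class:`GradientTable` and
:class:`DWIDataset` — together with shell labeling and the cumulative
shell-subset construction (scheme *k* keeps the *k* lowest-b shells).

File I/O uses NIfTI-1 for the 4D signal and the FSL text dialect for the
gradient table: ``bvals`` is one whitespace-separated row of b-values and
``bvecs`` three rows with the x/y/z components of each direction.
Directions are expressed in the same frame as the affine's rotation;
voxel indices are 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "GradientTable",
    "DWIDataset",
    "ShellScheme",
    "detect_shells",
    "read_dataset",
    "write_dataset",
    "select_subset",
]

#: b-values at or below this are treated as unweighted (shell 0).
DEFAULT_B0_TOLERANCE = 50.0
#: maximum distance from a declared shell center when labeling volumes.
DEFAULT_SHELL_TOLERANCE = 100.0


class GradientTableError(ValueError):
    """Malformed gradient table or mismatch with the signal volume."""


@dataclass(frozen=True)
class GradientTable:
    """Per-volume b-values, unit directions, and shell labels.

    Parameters
    ----------
    bvals : (N,) array
        Diffusion weighting per volume in s/mm².
    bvecs : (N, 3) array
        Gradient directions; unit norm for weighted volumes, zero rows are
        accepted for b0 entries.
    shell_id : (N,) int array, optional
        0 for b0 volumes, 1..S for shells in ascending b order.  Detected
        from ``bvals`` when omitted.
    metadata : dict
        Optional acquisition metadata (small_delta_ms, big_delta_ms, TE...).
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    shell_id: np.ndarray = None  # type: ignore[assignment]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.shape != (bvals.size, 3):
            raise GradientTableError(
                f"bvecs shape {bvecs.shape} does not match {bvals.size} b-values"
            )
        if np.any(bvals < 0):
            raise GradientTableError("negative b-values")
        weighted = bvals > DEFAULT_B0_TOLERANCE
        norms = np.linalg.norm(bvecs, axis=1)
        if np.any(norms[weighted] == 0):
            raise GradientTableError("weighted volume with zero gradient direction")
        if np.any(np.abs(norms[weighted] - 1.0) > 1e-4):
            warnings.warn("renormalizing non-unit gradient directions", stacklevel=2)
        bvecs = bvecs.copy()
        bvecs[weighted] /= norms[weighted, None]
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        if self.shell_id is None:
            object.__setattr__(self, "shell_id", detect_shells(bvals))
        else:
            object.__setattr__(
                self, "shell_id", np.asarray(self.shell_id, dtype=int)
            )
        if not np.any(self.shell_id == 0):
            raise GradientTableError("gradient table has no b0 volume")

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.shell_id == 0

    @property
    def shell_bvalues(self) -> np.ndarray:
        """Ascending nonzero shell centers (mean b within each shell)."""
        ids = np.unique(self.shell_id)
        return np.array(
            [self.bvals[self.shell_id == s].mean() for s in ids if s != 0]
        )

    @property
    def n_shells(self) -> int:
        return int(self.shell_id.max())

    def subset(self, index: np.ndarray) -> "GradientTable":
        return GradientTable(
            self.bvals[index],
            self.bvecs[index],
            shell_id=self.shell_id[index],
            metadata=dict(self.metadata),
        )


def detect_shells(
    bvalues,
    tolerance: float = DEFAULT_SHELL_TOLERANCE,
    b0_tolerance: float = DEFAULT_B0_TOLERANCE,
    shell_centers=None,
) -> np.ndarray:
    """Label each volume with a shell id (0 = b0, then ascending b).

    Nonzero b-values are clustered by rounding to the nearest declared shell
    center; without declared centers, clusters are grown greedily over the
    sorted unique b-values with gap ``tolerance``.

    Raises
    ------
    GradientTableError
        If a b-value lies farther than ``tolerance`` from every center.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    bvalues = np.atleast_1d(np.asarray(bvalues, dtype=float))
    labels = np.zeros(bvalues.size, dtype=int)
    weighted = bvalues > b0_tolerance
    if not np.any(weighted):
        return labels
    if shell_centers is None:
        centers: list[float] = []
        for b in np.unique(bvalues[weighted]):
            if centers and b - centers[-1] <= tolerance:
                # fold into the running cluster (mean center)
                members = bvalues[weighted & (np.abs(bvalues - centers[-1]) <= tolerance)]
                centers[-1] = float(members.mean())
            else:
                centers.append(float(b))
    else:
        centers = sorted(float(c) for c in shell_centers)
    centers_arr = np.asarray(centers)
    dist = np.abs(bvalues[weighted, None] - centers_arr[None, :])
    nearest = np.argmin(dist, axis=1)
    off = dist[np.arange(nearest.size), nearest] > tolerance
    if np.any(off):
        bad = bvalues[weighted][off][0]
        raise GradientTableError(
            f"b-value {bad} is farther than {tolerance} from every shell center"
        )
    labels[weighted] = nearest + 1
    return labels


@dataclass(frozen=True)
class DWIDataset:
    """4D diffusion signal plus grid geometry and its gradient table."""

    signal: np.ndarray
    affine: np.ndarray
    gtab: GradientTable
    voxel_size_mm: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        signal = np.asarray(self.signal, dtype=float)
        if signal.ndim != 4:
            raise GradientTableError("signal must be 4D (x, y, z, volume)")
        if signal.shape[3] != len(self.gtab):
            raise GradientTableError(
                f"{signal.shape[3]} volumes but gradient table has {len(self.gtab)}"
            )
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4) or abs(np.linalg.det(affine)) < 1e-12:
            raise GradientTableError("affine must be an invertible 4x4 matrix")
        object.__setattr__(self, "signal", signal)
        object.__setattr__(self, "affine", affine)
        if self.voxel_size_mm is None:
            vs = np.linalg.norm(affine[:3, :3], axis=0)
        else:
            vs = np.asarray(self.voxel_size_mm, dtype=float)
        object.__setattr__(self, "voxel_size_mm", vs)

    @property
    def shape(self):
        return self.signal.shape[:3]


@dataclass(frozen=True)
class ShellScheme:
    """Cumulative scheme *k*: the *k* lowest-b shells (plus all b0 volumes)."""

    k: int

    def included_bvalues(self, gtab: GradientTable) -> np.ndarray:
        shells = gtab.shell_bvalues
        if not 1 <= self.k <= shells.size:
            raise ValueError(f"scheme k={self.k} out of range 1..{shells.size}")
        return shells[: self.k]


def select_subset(dataset: DWIDataset, scheme: ShellScheme | int) -> DWIDataset:
    """Restrict a dataset to cumulative scheme *k*, preserving volume order.

    Keeps every b0 volume plus all volumes whose shell rank is ≤ k; scheme
    k subsets are supersets of scheme k−1 subsets by construction.
    """
    if isinstance(scheme, int):
        scheme = ShellScheme(scheme)
    n_shells = dataset.gtab.n_shells
    if not 1 <= scheme.k <= n_shells:
        raise ValueError(f"scheme k={scheme.k} out of range 1..{n_shells}")
    keep = dataset.gtab.shell_id <= scheme.k
    return DWIDataset(
        dataset.signal[..., keep],
        dataset.affine,
        dataset.gtab.subset(keep),
        voxel_size_mm=dataset.voxel_size_mm,
    )


def read_dataset(nifti_path, bvals_path, bvecs_path) -> DWIDataset:
    """Read a 4D NIfTI plus FSL-dialect bvals/bvecs into a :class:`DWIDataset`."""
    img = nib.load(str(nifti_path))
    signal = np.asarray(img.get_fdata(), dtype=float)
    bvals = np.loadtxt(bvals_path, ndmin=1)
    bvecs = np.loadtxt(bvecs_path, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        bvecs = bvecs.T  # FSL convention: 3 rows of N
    if bvecs.shape[0] != bvals.size:
        raise GradientTableError(
            f"bvecs has {bvecs.shape[0]} columns but bvals has {bvals.size} entries"
        )
    gtab = GradientTable(bvals, bvecs)
    if signal.ndim != 4 or signal.shape[3] != bvals.size:
        raise GradientTableError(
            "volume count mismatch between NIfTI and gradient table"
        )
    return DWIDataset(signal, img.affine, gtab)


def write_dataset(dataset: DWIDataset, nifti_path, bvals_path, bvecs_path) -> None:
    """Write the dataset as 4D NIfTI plus FSL-dialect bvals/bvecs text files."""
    img = nib.Nifti1Image(dataset.signal.astype(np.float64), dataset.affine)
    img.header.set_zooms((*dataset.voxel_size_mm, 1.0))
    nib.save(img, str(nifti_path))
    np.savetxt(bvals_path, dataset.gtab.bvals[None, :], fmt="%.6g")
    np.savetxt(bvecs_path, dataset.gtab.bvecs.T, fmt="%.8f")


def save_map(values: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a 3D scalar map as NIfTI-1."""
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine), str(path))
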