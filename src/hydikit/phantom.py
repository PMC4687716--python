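"""Synthetic multi-shell diffusion phantoms.

Emulates an ex vivo rodent-brain HYDI acquisition at desk scale: five
q-space shells (b = 1000/3000/4000/8000/12000 s/mm²), 60 directions per
shell reused across shells, 5 b0 volumes, on a small grid containing

* a single-fiber white-matter **bundle** running left–right (x axis),
* a 90° **crossing** region mixing x- and y-oriented fibers,
* a low-anisotropy **gray-matter-like** slab,
* an isotropic **background**.

Tissue voxels decay non-monoexponentially: each region mixes a fast and a
slow Gaussian compartment, S(g,b) = S0 · Σ_k f_k exp(−b gᵀ D_k g), so the
apparent tensor metrics fall as higher shells are included while the ODF
angular contrast rises — the qualitative regime the downstream analyses
probe.  Noise is Rician (magnitude MRI).  Three pseudo-subjects at "ages"
10, 15 and 24 months carry a monotone decline in bundle anisotropy
(eigenvalue ratio λ1:λ2 shrinks by a configurable factor per age step).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gradients import DWIDataset, GradientTable

__all__ = [
    "AcquisitionSpec",
    "CompartmentSpec",
    "PhantomSpec",
    "PhantomTruth",
    "make_gradient_scheme",
    "compartment_signal",
    "add_rician_noise",
    "build_phantom",
]

AGE_CODES = (10, 15, 24)

REGION_LABELS = {"background": 0, "bundle": 1, "crossing": 2, "gray": 3}


class PhantomSpecError(ValueError):
    pass


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition geometry of the emulated scan.

    Defaults reproduce the study design: 5 shells at b = 1000, 3000, 4000,
    8000, 12000 s/mm², 60 directions per shell, 5 b0 volumes; δ and Δ are
    stored as metadata only.
    """

    shell_bvalues: tuple = (1000.0, 3000.0, 4000.0, 8000.0, 12000.0)
    directions_per_shell: int = 60
    n_b0: int = 5
    voxel_size_mm: tuple = (0.15, 0.15, 0.15)
    grid_shape: tuple = (20, 20, 10)
    small_delta_ms: float | None = 11.0
    big_delta_ms: float | None = 16.0

    def __post_init__(self):
        b = np.asarray(self.shell_bvalues, dtype=float)
        if b.size == 0 or np.any(b <= 0) or np.any(np.diff(b) <= 0):
            raise PhantomSpecError("shell_bvalues must be positive, strictly increasing")
        if self.directions_per_shell < 6:
            raise PhantomSpecError("need at least 6 directions per shell")
        if self.n_b0 < 1:
            raise PhantomSpecError("need at least one b0 volume")


@dataclass(frozen=True)
class CompartmentSpec:
    """One Gaussian diffusion compartment: a 3×3 tensor and volume fraction."""

    tensor: np.ndarray  # symmetric 3x3, mm²/s
    volume_fraction: float

    def __post_init__(self):
        t = np.asarray(self.tensor, dtype=float)
        if t.shape != (3, 3) or not np.allclose(t, t.T, atol=1e-12):
            raise PhantomSpecError("compartment tensor must be symmetric 3x3")
        if np.linalg.eigvalsh(t).min() < -1e-12:
            raise PhantomSpecError("compartment tensor must be positive semi-definite")
        if not 0.0 <= self.volume_fraction <= 1.0:
            raise PhantomSpecError("volume fraction outside [0, 1]")
        object.__setattr__(self, "tensor", t)

    @classmethod
    def from_axis(cls, eigenvalues, axis, volume_fraction) -> "CompartmentSpec":
        """Axially oriented tensor from (λ1, λ2, λ3) and the λ1 direction."""
        lam = np.asarray(eigenvalues, dtype=float)
        e1 = np.asarray(axis, dtype=float)
        e1 = e1 / np.linalg.norm(e1)
        # complete an orthonormal frame
        probe = np.array([1.0, 0.0, 0.0])
        if abs(e1 @ probe) > 0.9:
            probe = np.array([0.0, 1.0, 0.0])
        e2 = np.cross(e1, probe)
        e2 /= np.linalg.norm(e2)
        e3 = np.cross(e1, e2)
        basis = np.stack([e1, e2, e3], axis=1)
        tensor = basis @ np.diag(lam) @ basis.T
        return cls(tensor, volume_fraction)


# Default tissue model (mm²/s).  The fast compartment is more anisotropic
# and more diffusive than the slow one, so high-b shells emphasize the
# slow pool: apparent tensor metrics (FA/MD/AX/RD) drop as shells are
# added while high-b angular contrast sharpens the ODF.
BUNDLE_FAST = dict(eigenvalues=(1.7e-3, 3.0e-4, 3.0e-4), fraction=0.6)
BUNDLE_SLOW = dict(eigenvalues=(3.5e-4, 1.5e-4, 1.5e-4), fraction=0.4)
GRAY_FAST = dict(eigenvalues=(1.0e-3, 7.5e-4, 7.5e-4), fraction=0.7)
GRAY_SLOW = dict(eigenvalues=(2.5e-4, 2.0e-4, 2.0e-4), fraction=0.3)
BACKGROUND_D = 2.0e-3  # isotropic, free-water-like


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom description: acquisition, tissue, noise, age, seed.

    ``nominal_snr`` sets the Rician scale σ so that the bundle-mean
    noiseless signal in the lowest shell divided by σ equals it (the
    shell-1 SNR a b0-based estimator should recover).  ``noise_sigma``
    overrides it directly when given; both ``None`` → noiseless.
    """

    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    s0: float = 1000.0
    nominal_snr: float | None = 40.0
    noise_sigma: float | None = None
    age_months: int = 10
    anisotropy_decline: float = 0.10  # λ1:λ2 ratio shrink per age step
    seed: int = 0

    def __post_init__(self):
        if self.age_months not in AGE_CODES:
            raise PhantomSpecError(f"age_months must be one of {AGE_CODES}")
        if self.noise_sigma is not None and self.noise_sigma < 0:
            raise PhantomSpecError("noise_sigma must be nonnegative")
        if not 0.0 <= self.anisotropy_decline < 1.0:
            raise PhantomSpecError("anisotropy_decline must be in [0, 1)")

    @property
    def age_step(self) -> int:
        return AGE_CODES.index(self.age_months)


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth emitted next to the synthetic signal."""

    region_map: np.ndarray  # int labels per REGION_LABELS
    masks: dict  # region name -> bool 3D array
    principal_direction: np.ndarray  # (x,y,z,3); NaN where undefined
    true_fa: np.ndarray  # FA of the fraction-weighted composite tensor
    noise_sigma: float
    compartments: dict  # region name -> list of CompartmentSpec

    @property
    def brain_mask(self) -> np.ndarray:
        return np.ones(self.region_map.shape, dtype=bool)


def make_gradient_scheme(spec: AcquisitionSpec, seed: int = 0) -> GradientTable:
    """Build the phantom's gradient table.

    One quasi-uniform direction set is generated by iterative pairwise
    (electrostatic) repulsion with antipodal symmetry and reused across
    every shell, after n_b0 unweighted entries.
    """
    dirs = repulsion_directions(spec.directions_per_shell, seed=seed)
    bvals = [0.0] * spec.n_b0
    bvecs = [np.zeros(3)] * spec.n_b0
    for b in spec.shell_bvalues:
        bvals.extend([b] * spec.directions_per_shell)
        bvecs.extend(dirs)
    metadata = {
        "small_delta_ms": spec.small_delta_ms,
        "big_delta_ms": spec.big_delta_ms,
    }
    return GradientTable(np.array(bvals), np.array(bvecs), metadata=metadata)


def repulsion_directions(n: int, seed: int = 0, n_iter: int = 200) -> np.ndarray:
    """Spread ``n`` unit vectors quasi-uniformly over the sphere.

    Gradient descent on the electrostatic energy of the antipodally
    symmetrized set (each point interacts with all others and their
    antipodes), from a seeded random start, fixed iteration count.
    """
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    step = 0.05
    for it in range(n_iter):
        forces = np.zeros_like(pts)
        for sign in (1.0, -1.0):
            diff = pts[:, None, :] - sign * pts[None, :, :]  # (n, n, 3)
            dist2 = np.sum(diff**2, axis=-1)
            np.fill_diagonal(dist2, np.inf)
            dist2[dist2 < 1e-12] = np.inf
            forces += np.sum(diff / dist2[..., None] ** 1.5, axis=1)
        # project onto the tangent plane and take a damped step
        forces -= np.sum(forces * pts, axis=1, keepdims=True) * pts
        pts = pts + step * forces / n
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        step *= 0.99
    return pts


def compartment_signal(gtab: GradientTable, compartments, s0: float) -> np.ndarray:
    """Noiseless multi-compartment signal, one value per gradient entry.

    S(g, b) = S0 · Σ_k f_k · exp(−b gᵀ D_k g); b0 entries return S0.
    """
    fractions = np.array([c.volume_fraction for c in compartments])
    if abs(fractions.sum() - 1.0) > 1e-8:
        raise PhantomSpecError("compartment fractions must sum to 1")
    b = gtab.bvals
    g = gtab.bvecs
    signal = np.zeros(len(gtab))
    for c in compartments:
        adc = np.einsum("ni,ij,nj->n", g, c.tensor, g)
        signal += c.volume_fraction * np.exp(-b * adc)
    return s0 * signal


def add_rician_noise(signal: np.ndarray, sigma: float, seed: int = 0) -> np.ndarray:
    """Corrupt a magnitude signal with Rician noise: sqrt((S+ε₁)² + ε₂²)."""
    if sigma < 0:
        raise PhantomSpecError("sigma must be nonnegative")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    rng = np.random.default_rng(seed)
    e1 = rng.normal(0.0, sigma, signal.shape)
    e2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + e1) ** 2 + e2**2)


def _region_map(grid_shape) -> np.ndarray:
    nx, ny, nz = grid_shape
    region = np.zeros(grid_shape, dtype=int)
    # gray-matter-like slab along one face
    region[:, : max(1, round(0.15 * ny)), :] = REGION_LABELS["gray"]
    # left-right bundle spanning the full x extent
    y0, y1 = round(0.25 * ny), round(0.45 * ny)
    z0, z1 = round(0.3 * nz), round(0.7 * nz)
    region[:, y0:y1, z0:z1] = REGION_LABELS["bundle"]
    # crossing block mixing x- and y-oriented fibers
    cy0, cy1 = round(0.6 * ny), round(0.8 * ny)
    cx0, cx1 = round(0.3 * nx), round(0.7 * nx)
    region[cx0:cx1, cy0:cy1, z0:z1] = REGION_LABELS["crossing"]
    return region


def _aged(eigenvalues, step: int, decline: float):
    """Shrink the λ1:λ2 ratio by ``decline`` per age step (raises λ2, λ3)."""
    lam = np.asarray(eigenvalues, dtype=float).copy()
    scale = (1.0 / (1.0 - decline)) ** step
    lam[1:] *= scale
    return lam


def region_compartments(spec: PhantomSpec) -> dict:
    """Per-region compartment lists for a given phantom spec."""
    s = spec.age_step
    d = spec.anisotropy_decline
    x, y = (1.0, 0.0, 0.0), (0.0, 1.0, 0.0)
    bundle = [
        CompartmentSpec.from_axis(_aged(BUNDLE_FAST["eigenvalues"], s, d), x,
                                  BUNDLE_FAST["fraction"]),
        CompartmentSpec.from_axis(_aged(BUNDLE_SLOW["eigenvalues"], s, d), x,
                                  BUNDLE_SLOW["fraction"]),
    ]
    crossing = [
        CompartmentSpec.from_axis(_aged(BUNDLE_FAST["eigenvalues"], s, d), x,
                                  BUNDLE_FAST["fraction"] / 2),
        CompartmentSpec.from_axis(_aged(BUNDLE_SLOW["eigenvalues"], s, d), x,
                                  BUNDLE_SLOW["fraction"] / 2),
        CompartmentSpec.from_axis(_aged(BUNDLE_FAST["eigenvalues"], s, d), y,
                                  BUNDLE_FAST["fraction"] / 2),
        CompartmentSpec.from_axis(_aged(BUNDLE_SLOW["eigenvalues"], s, d), y,
                                  BUNDLE_SLOW["fraction"] / 2),
    ]
    gray = [
        CompartmentSpec.from_axis(_aged(GRAY_FAST["eigenvalues"], s, d), x,
                                  GRAY_FAST["fraction"]),
        CompartmentSpec.from_axis(_aged(GRAY_SLOW["eigenvalues"], s, d), x,
                                  GRAY_SLOW["fraction"]),
    ]
    background = [CompartmentSpec(BACKGROUND_D * np.eye(3), 1.0)]
    return {
        "background": background,
        "bundle": bundle,
        "crossing": crossing,
        "gray": gray,
    }


def _composite_fa(compartments) -> float:
    """FA of the fraction-weighted mean tensor (the b→0 effective tensor)."""
    mean_t = sum(c.volume_fraction * c.tensor for c in compartments)
    lam = np.linalg.eigvalsh(mean_t)
    md = lam.mean()
    denom = np.sum(lam**2)
    if denom == 0:
        return 0.0
    return float(np.sqrt(1.5 * np.sum((lam - md) ** 2) / denom))


def build_phantom(spec: PhantomSpec):
    """Generate the synthetic dataset and its ground truth.

    Returns
    -------
    (DWIDataset, PhantomTruth)
        Signal built per region via :func:`compartment_signal` then
        corrupted with Rician noise; deterministic for a fixed seed.
    """
    acq = spec.acquisition
    gtab = make_gradient_scheme(acq, seed=spec.seed)
    region = _region_map(acq.grid_shape)
    comps = region_compartments(spec)

    n_vol = len(gtab)
    signal = np.zeros((*acq.grid_shape, n_vol))
    truth_dir = np.full((*acq.grid_shape, 3), np.nan)
    true_fa = np.zeros(acq.grid_shape)
    masks = {}
    for name, label in REGION_LABELS.items():
        mask = region == label
        masks[name] = mask
        if not np.any(mask):
            continue
        signal[mask] = compartment_signal(gtab, comps[name], spec.s0)
        true_fa[mask] = _composite_fa(comps[name])
        if name in ("bundle", "crossing"):
            truth_dir[mask] = np.array([1.0, 0.0, 0.0])

    # noise scale: reference the bundle-mean noiseless signal of the lowest shell
    if spec.noise_sigma is not None:
        sigma = float(spec.noise_sigma)
    elif spec.nominal_snr is not None:
        shell1 = gtab.shell_id == 1
        ref = signal[masks["bundle"]][:, shell1].mean()
        sigma = float(ref / spec.nominal_snr)
    else:
        sigma = 0.0
    signal = add_rician_noise(signal, sigma, seed=spec.seed + 1)

    affine = np.diag([*acq.voxel_size_mm, 1.0])
    dataset = DWIDataset(signal, affine, gtab, voxel_size_mm=np.asarray(acq.voxel_size_mm))
    truth = PhantomTruth(
        region_map=region,
        masks=masks,
        principal_direction=truth_dir,
        true_fa=true_fa,
        noise_sigma=sigma,
        compartments=comps,
    )
    return dataset, truth
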