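"""Analytic q-ball imaging: spherical-harmonic ODFs, GFA, QA/NQA, peaks.

Per shell, the diffusion signal sampled over the sphere is expanded in a
real, symmetric (even-order) spherical-harmonic basis with a
Laplace–Beltrami penalty, and the orientation distribution function (ODF)
is obtained analytically through the Funk–Radon transform, which scales
each order-l coefficient by 2π·P_l(0).  Defaults follow the reconstruction
settings used throughout the package's target analysis: SH order 8 (45
coefficients) and regularization weight 0.006.

When several shells are included, each shell gets its own analytic ODF;
the per-shell ODFs are rescaled to unit voxel-mean (the ODF carries a 1/Z
normalization by definition) and averaged with equal weights.  This keeps
the sharp high-b shells from being drowned out by the high-amplitude low-b
shell and is how "k-shell" q-ball reconstructions are formed here.

Scalar outputs:

* ``GFA = sqrt( n Σ(ψ_i − ⟨ψ⟩)² / ((n−1) Σ ψ_i²) )`` — normalized ODF
  standard deviation, in [0, 1];
* ``QA(u) = Z0 (ψ(u) − Iψ)`` at each ODF peak, with Iψ the voxel's
  isotropic (minimum) ODF level and Z0 = 1 / max over the volume of Iψ;
* ``NQA`` — the largest-peak QA rescaled so the volume maximum is 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import eval_legendre, sph_harm_y

from .dti import ScalarMap
from .gradients import DWIDataset

__all__ = [
    "SphereGrid",
    "SHField",
    "ODFField",
    "PeakField",
    "sh_basis",
    "fit_sh",
    "frt_odf",
    "gfa",
    "find_peaks",
    "qa_nqa",
]

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# sphere tessellation


def _icosahedron():
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ]
    )
    return verts, faces


def icosphere(subdivisions: int = 3):
    """Subdivided icosahedron: unit vertices and triangular faces."""
    verts, faces = _icosahedron()
    verts = [v for v in verts]
    cache: dict = {}

    def midpoint(i, j):
        key = (min(i, j), max(i, j))
        if key not in cache:
            m = verts[i] + verts[j]
            m /= np.linalg.norm(m)
            cache[key] = len(verts)
            verts.append(m)
        return cache[key]

    for _ in range(subdivisions):
        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces.extend([[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]])
        faces = np.asarray(new_faces)
    return np.asarray(verts), faces


def _canonical_keep(v: np.ndarray, eps: float = 1e-9) -> bool:
    """Hemisphere representative rule: first nonzero component positive."""
    for comp in v:
        if comp > eps:
            return True
        if comp < -eps:
            return False
    return True


@dataclass(frozen=True)
class SphereGrid:
    """Antipodally symmetric direction set reduced to one hemisphere.

    ``vertices`` are the hemisphere representatives; ``neighbors[i]`` are
    the hemisphere indices adjacent to vertex i on the full-sphere mesh
    (antipodes mapped back), giving the connected graph used for
    local-maximum tests.
    """

    vertices: np.ndarray
    neighbors: list
    min_neighbor_angle_deg: float = field(default=0.0)

    @classmethod
    def icosphere(cls, subdivisions: int = 3) -> "SphereGrid":
        verts, faces = icosphere(subdivisions)
        keep = np.array([_canonical_keep(v) for v in verts])
        hemi = verts[keep]
        # map every full-sphere vertex to its hemisphere representative
        rep = np.full(len(verts), -1)
        kept_idx = np.flatnonzero(keep)
        rep[kept_idx] = np.arange(kept_idx.size)
        from scipy.spatial import cKDTree

        tree = cKDTree(hemi)
        others = np.flatnonzero(~keep)
        dist, idx = tree.query(-verts[others])
        if np.any(dist > 1e-6):
            raise ValueError("tessellation is not antipodally symmetric")
        rep[others] = idx
        nbr_sets: list[set] = [set() for _ in range(kept_idx.size)]
        for a, b, c in faces:
            for i, j in ((a, b), (b, c), (c, a)):
                ri, rj = rep[i], rep[j]
                if ri != rj:
                    nbr_sets[ri].add(rj)
                    nbr_sets[rj].add(ri)
        neighbors = [np.array(sorted(s)) for s in nbr_sets]
        angles = [
            np.degrees(
                np.arccos(np.clip(np.abs(hemi[i] @ hemi[n].T), -1, 1))
            ).min()
            for i, n in enumerate(neighbors)
        ]
        return cls(hemi, neighbors, float(np.mean(angles)))

    def __len__(self) -> int:
        return len(self.vertices)


# --------------------------------------------------------------------------
# real symmetric spherical-harmonic basis


def sh_degrees(order: int):
    """(l, m) pairs of the even-order real symmetric basis up to ``order``."""
    return [(l, m) for l in range(0, order + 1, 2) for m in range(-l, l + 1)]


def n_coefficients(order: int) -> int:
    return (order + 1) * (order + 2) // 2


def sh_basis(order: int, directions: np.ndarray) -> np.ndarray:
    """Design matrix of the real, even-order symmetric SH basis.

    Convention (real basis from the complex Y_l^m):
    ``m < 0 → √2·(−1)^m·Im(Y_l^|m|)``, ``m = 0 → Y_l^0``,
    ``m > 0 → √2·(−1)^m·Re(Y_l^m)``.  Rows follow ``directions``.
    """
    directions = np.atleast_2d(directions)
    x, y, z = directions.T
    theta = np.arccos(np.clip(z, -1.0, 1.0))  # polar
    phi = np.arctan2(y, x)  # azimuth
    cols = []
    for l, m in sh_degrees(order):
        ylm = sph_harm_y(l, abs(m), theta, phi)
        if m < 0:
            col = np.sqrt(2.0) * (-1) ** m * ylm.imag
        elif m == 0:
            col = ylm.real
        else:
            col = np.sqrt(2.0) * (-1) ** m * ylm.real
        cols.append(col)
    return np.column_stack(cols)


def _laplace_beltrami(order: int) -> np.ndarray:
    return np.diag([(l * (l + 1)) ** 2 for l, _ in sh_degrees(order)])


@dataclass(frozen=True)
class SHField:
    """Per-shell spherical-harmonic coefficients over the masked grid."""

    coefficients: dict  # shell id -> (x, y, z, n_coef) array
    orders: dict  # shell id -> fitted order
    mask: np.ndarray
    regularization: float


def fit_sh(
    dataset: DWIDataset,
    shells=None,
    order: int = 8,
    regularization: float = 0.006,
    mask: np.ndarray | None = None,
) -> SHField:
    """Penalized least-squares SH fit of each requested shell's signal.

    Coefficients solve ``(BᵀB + λL) c = Bᵀ s`` with L the Laplace–Beltrami
    diagonal l²(l+1)².  A shell with fewer directions than order-``order``
    coefficients gets its order reduced in steps of 2 (logged).
    """
    gtab = dataset.gtab
    if shells is None:
        shells = [int(s) for s in np.unique(gtab.shell_id) if s != 0]
    elif np.isscalar(shells):
        shells = [int(shells)]
    if mask is None:
        mask = np.ones(dataset.shape, dtype=bool)

    coefficients, orders = {}, {}
    for shell in shells:
        sel = gtab.shell_id == shell
        if not np.any(sel):
            raise ValueError(f"no volumes in shell {shell}")
        dirs = gtab.bvecs[sel]
        n_dirs = dirs.shape[0]
        fit_order = order
        while fit_order > 0 and n_coefficients(fit_order) > n_dirs:
            fit_order -= 2
        if fit_order < order:
            log.warning(
                "shell %d: order reduced %d -> %d (%d directions)",
                shell, order, fit_order, n_dirs,
            )
        if n_coefficients(fit_order) > n_dirs:
            raise ValueError(
                f"shell {shell}: {n_dirs} directions cannot support any SH order"
            )
        basis = sh_basis(fit_order, dirs)
        reg = regularization * _laplace_beltrami(fit_order)
        solver = np.linalg.solve(basis.T @ basis + reg, basis.T)  # (ncoef, ndirs)
        signal = dataset.signal[..., sel][mask]
        coefs = signal @ solver.T
        out = np.full((*dataset.shape, coefs.shape[1]), np.nan)
        out[mask] = coefs
        coefficients[shell] = out
        orders[shell] = fit_order
    return SHField(coefficients, orders, mask, regularization)


@dataclass(frozen=True)
class ODFField:
    """Per-voxel ODF amplitudes ψ(u_i) sampled on a :class:`SphereGrid`.

    ``sh_coefficients``/``sh_order`` carry the band-limited SH expansion of
    the (shell-averaged) ODF, which lets peak directions be refined off the
    discrete grid.
    """

    values: np.ndarray  # (x, y, z, n_dirs)
    sphere: SphereGrid
    mask: np.ndarray
    n_floored: int = 0
    sh_coefficients: np.ndarray | None = None  # (x, y, z, n_coef)
    sh_order: int = 0

    @property
    def mean(self) -> np.ndarray:
        return self.values.mean(axis=-1)


def frt_coefficients(coefs: np.ndarray, order: int) -> np.ndarray:
    """Apply the analytic Funk–Radon transform: scale order l by 2π·P_l(0)."""
    scale = np.array([2.0 * np.pi * eval_legendre(l, 0.0) for l, _ in sh_degrees(order)])
    return coefs * scale


def frt_odf(sh: SHField, sphere: SphereGrid) -> ODFField:
    """Analytic q-ball ODF of each shell, normalized and shell-averaged.

    Each shell's SH coefficients pass through the Funk–Radon transform and
    are evaluated on the sphere grid; negative samples are floored at 0
    (count logged).  Each shell's ODF is rescaled to unit voxel-mean before
    the equal-weight average across shells.
    """
    mask = sh.mask
    acc = None
    n_floored = 0
    max_order = max(sh.orders.values())
    coef_acc = np.zeros((int(mask.sum()), n_coefficients(max_order)))
    for shell, coefs in sh.coefficients.items():
        order = sh.orders[shell]
        basis = sh_basis(order, sphere.vertices)  # (ndirs, ncoef)
        frt = frt_coefficients(coefs[mask], order)
        odf = frt @ basis.T  # (nvox, ndirs)
        n_floored += int(np.count_nonzero(odf < 0))
        odf = np.maximum(odf, 0.0)
        means = odf.mean(axis=1, keepdims=True)
        odf = np.divide(odf, means, out=np.zeros_like(odf), where=means > 0)
        acc = odf if acc is None else acc + odf
        # lower-order (l, m) lists are prefixes of higher-order ones, so the
        # band-limited average accumulates into a zero-padded block
        scaled = np.divide(frt, means, out=np.zeros_like(frt), where=means > 0)
        coef_acc[:, : scaled.shape[1]] += scaled
    n_shells = len(sh.coefficients)
    acc /= n_shells
    coef_acc /= n_shells
    if n_floored:
        log.info("floored %d negative ODF samples", n_floored)
    values = np.full((*mask.shape, len(sphere)), np.nan)
    values[mask] = acc
    sh_coef = np.full((*mask.shape, coef_acc.shape[1]), np.nan)
    sh_coef[mask] = coef_acc
    return ODFField(values, sphere, mask, n_floored, sh_coef, max_order)


def gfa(odf: ODFField) -> ScalarMap:
    """Generalized fractional anisotropy of the sampled ODF (0 if ψ ≡ 0)."""
    psi = odf.values[odf.mask]
    n = psi.shape[-1]
    if n < 2:
        raise ValueError("GFA needs at least 2 ODF samples")
    mean = psi.mean(axis=-1, keepdims=True)
    num = n * np.sum((psi - mean) ** 2, axis=-1)
    denom = (n - 1) * np.sum(psi**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.sqrt(num / denom)
    g = np.where(denom > 0, g, 0.0)
    values = np.full(odf.mask.shape, np.nan)
    values[odf.mask] = g
    return ScalarMap(name="GFA", values=values, mask=odf.mask)


def _sh_eval(coefs: np.ndarray, order: int, dirs: np.ndarray) -> np.ndarray:
    """ψ(u) for per-point coefficient rows: (P, ncoef) × (P, 3) → (P,)."""
    return np.sum(coefs * sh_basis(order, dirs), axis=1)


def refine_directions(
    coefs: np.ndarray,
    order: int,
    dirs: np.ndarray,
    n_iter: int = 2,
    max_step_rad: float = 0.15,
) -> np.ndarray:
    """Newton refinement of ODF maxima off the discrete sphere grid.

    The sampled grid quantizes peak directions to vertex spacing (several
    degrees); since the ODF is a band-limited SH expansion, each grid
    maximum can be polished by Newton steps in the local tangent plane
    (finite-difference gradient/Hessian of ψ).  Steps are clipped to
    ``max_step_rad`` and skipped where the Hessian is not negative
    definite, so a refined direction never leaves its grid maximum's
    neighborhood.  Fully vectorized over peaks.
    """
    u = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    h = 1e-3
    for _ in range(n_iter):
        probe = np.where(
            np.abs(u[:, [0]]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]]
        )
        e1 = np.cross(u, probe)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(u, e1)

        def psi_at(a, b):
            p = u + (a * h) * e1 + (b * h) * e2
            p /= np.linalg.norm(p, axis=1, keepdims=True)
            return _sh_eval(coefs, order, p)

        f0 = psi_at(0, 0)
        fpa, fma = psi_at(1, 0), psi_at(-1, 0)
        fpb, fmb = psi_at(0, 1), psi_at(0, -1)
        fab = psi_at(1, 1)
        ga = (fpa - fma) / (2 * h)
        gb = (fpb - fmb) / (2 * h)
        haa = (fpa - 2 * f0 + fma) / h**2
        hbb = (fpb - 2 * f0 + fmb) / h**2
        hab = (fab - fpa - fpb + f0) / h**2
        det = haa * hbb - hab**2
        ok = (det > 0) & (haa < 0)
        safe_det = np.where(ok, det, 1.0)
        da = np.where(ok, -(hbb * ga - hab * gb) / safe_det, 0.0)
        db = np.where(ok, -(-hab * ga + haa * gb) / safe_det, 0.0)
        step = np.sqrt(da**2 + db**2)
        scale = np.where(step > max_step_rad, max_step_rad / np.maximum(step, 1e-30), 1.0)
        u = u + (scale * da)[:, None] * e1 + (scale * db)[:, None] * e2
        u /= np.linalg.norm(u, axis=1, keepdims=True)
    return u


@dataclass(frozen=True)
class PeakField:
    """Ordered ODF local maxima per voxel.

    ``directions`` (x,y,z,max_peaks,3) unit vectors (NaN pads),
    ``amplitudes`` the corresponding ψ values, ``n_peaks`` per voxel, and
    ``degenerate`` flags voxels whose ODF had no strict local maximum
    (flat); those keep one arbitrary-but-deterministic direction.
    """

    directions: np.ndarray
    amplitudes: np.ndarray
    n_peaks: np.ndarray
    degenerate: np.ndarray
    mask: np.ndarray
    sphere: SphereGrid
    odf_min: np.ndarray = None  # type: ignore[assignment]  # per-voxel Iψ

    @property
    def principal_direction(self) -> np.ndarray:
        return self.directions[..., 0, :]


def find_peaks(
    odf: ODFField,
    min_separation_deg: float = 25.0,
    max_peaks: int = 3,
    relative_threshold: float = 0.0,
    refine: bool = True,
) -> PeakField:
    """Greedy extraction of ODF local maxima on the sphere graph.

    A sample is a candidate if it is ≥ all neighbors and > at least one
    (antipodal neighbors included).  Candidates are taken in decreasing
    amplitude (ties broken by lexicographic direction order) subject to a
    pairwise separation of ``min_separation_deg``.  Flat ODFs are flagged
    degenerate and keep vertex 0 as a deterministic placeholder.

    With ``refine`` (and an ODF that carries its SH expansion), each kept
    maximum is polished off-grid by :func:`refine_directions`.
    """
    sphere = odf.sphere
    verts = sphere.vertices
    n_dir = len(sphere)
    max_deg = max(len(n) for n in sphere.neighbors)
    nbr = np.full((n_dir, max_deg), -1)
    for i, n in enumerate(sphere.neighbors):
        nbr[i, : len(n)] = n

    psi = odf.values[odf.mask]  # (nvox, ndir)
    nvox = psi.shape[0]
    padded = np.concatenate([psi, np.full((nvox, 1), -np.inf)], axis=1)
    nbr_vals = padded[:, nbr]  # (nvox, ndir, max_deg)
    ge_all = np.all(psi[:, :, None] >= nbr_vals, axis=2)
    gt_any = np.any(psi[:, :, None] > np.where(nbr >= 0, nbr_vals, np.inf), axis=2)
    is_max = ge_all & gt_any

    cos_sep = np.cos(np.radians(min_separation_deg))
    # lexicographic key for deterministic tie-breaks
    lex = np.lexsort((verts[:, 2], verts[:, 1], verts[:, 0]))
    lex_rank = np.empty(n_dir)
    lex_rank[lex] = np.arange(n_dir)

    directions = np.full((nvox, max_peaks, 3), np.nan)
    amplitudes = np.full((nvox, max_peaks), np.nan)
    n_peaks = np.zeros(nvox, dtype=int)
    degenerate = np.zeros(nvox, dtype=bool)
    for v in range(nvox):
        cand = np.flatnonzero(is_max[v])
        if cand.size == 0:
            degenerate[v] = True
            directions[v, 0] = verts[0]
            amplitudes[v, 0] = psi[v, 0]
            n_peaks[v] = 1
            continue
        if relative_threshold > 0:
            cand = cand[psi[v, cand] >= relative_threshold * psi[v].max()]
        order = cand[np.lexsort((lex_rank[cand], -psi[v, cand]))]
        kept: list[int] = []
        for i in order:
            if len(kept) >= max_peaks:
                break
            if all(
                abs(verts[i] @ verts[j]) < cos_sep for j in kept
            ):
                kept.append(i)
        for rank, i in enumerate(kept):
            directions[v, rank] = verts[i]
            amplitudes[v, rank] = psi[v, i]
        n_peaks[v] = len(kept)

    if refine and odf.sh_coefficients is not None:
        coefs_masked = odf.sh_coefficients[odf.mask]
        vox_idx, rank_idx = np.nonzero(
            np.isfinite(amplitudes) & ~degenerate[:, None]
        )
        if vox_idx.size:
            refined = refine_directions(
                coefs_masked[vox_idx], odf.sh_order, directions[vox_idx, rank_idx]
            )
            directions[vox_idx, rank_idx] = refined
            amplitudes[vox_idx, rank_idx] = _sh_eval(
                coefs_masked[vox_idx], odf.sh_order, refined
            )

    shape = odf.mask.shape
    out_dir = np.full((*shape, max_peaks, 3), np.nan)
    out_amp = np.full((*shape, max_peaks), np.nan)
    out_n = np.zeros(shape, dtype=int)
    out_deg = np.zeros(shape, dtype=bool)
    out_dir[odf.mask] = directions
    out_amp[odf.mask] = amplitudes
    out_n[odf.mask] = n_peaks
    out_deg[odf.mask] = degenerate
    out_min = np.full(shape, np.nan)
    out_min[odf.mask] = psi.min(axis=1)
    if degenerate.any():
        log.info("flagged %d degenerate (flat-ODF) voxels", int(degenerate.sum()))
    return PeakField(out_dir, out_amp, out_n, out_deg, odf.mask, sphere, out_min)


def qa_nqa(peaks: PeakField, qa_max: float | None = None):
    """Quantitative anisotropy at each peak and the normalized NQA map.

    Per voxel the isotropic level Iψ is the minimum ODF sample; the global
    scale Z0 = 1 / max over the volume of Iψ.  QA(u) = Z0·(ψ(u) − Iψ),
    floored at 0; the NQA map divides the largest-peak QA by the volume
    maximum so max(NQA) = 1 exactly.

    When reconstructions must share a scale (e.g. comparing shell schemes
    within one subject), pass ``qa_max`` — the normalization constant then
    comes from the caller instead of this volume's own maximum, so NQA
    values remain comparable across the reconstructions.

    Returns ``(nqa_map, qa)`` with ``qa`` shaped like ``peaks.amplitudes``.
    """
    mask = peaks.mask
    i_psi = peaks.odf_min
    finite = mask & np.isfinite(i_psi)
    if not np.any(finite) or np.nanmax(i_psi[finite]) <= 0:
        raise ValueError("cannot scale QA: volume has no positive isotropic level")
    z0 = 1.0 / np.nanmax(i_psi[finite])
    qa = z0 * (peaks.amplitudes - i_psi[..., None])
    qa = np.maximum(qa, 0.0)
    top = qa[..., 0]
    top_max = float(qa_max) if qa_max is not None else np.nanmax(top[mask])
    if top_max <= 0:
        nqa = np.where(mask, 0.0, np.nan)
    else:
        nqa = top / top_max
    nqa = np.where(mask, nqa, np.nan)
    return ScalarMap(name="NQA", values=nqa, mask=mask), qa
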