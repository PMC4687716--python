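# Methods

This note records the models, conventions and numerical choices behind
`hydikit`, in the spirit of a package reference manual: what is computed,
under what assumptions, and where the design was genuinely open.

## Synthetic phantom

**What it emulates.** A 5-shell ex vivo small-animal acquisition:
b = 1000/3000/4000/8000/12000 s/mm², 60 directions per shell (the same
direction set on every shell), 5 b0 volumes — 305 volumes in all — on a
20×20×10 grid of 0.15 mm isotropic voxels (δ = 11 ms, Δ = 16 ms are
stored as metadata only). Regions: a left–right single-fiber bundle
(spanning the full x extent; 320 voxels at the default grid), a 90°
crossing block mixing x- and y-oriented fibers, a low-anisotropy
gray-matter-like slab, and an isotropic free-water-like background
(d = 2.0×10⁻³ mm²/s).

**Signal model.** Each tissue voxel mixes Gaussian compartments,
S(g,b) = S0 · Σₖ fₖ·exp(−b gᵀDₖg). The bundle combines a fast, more
anisotropic compartment (λ = (1.7, 0.3, 0.3)×10⁻³ mm²/s, f = 0.6) with a
slow, less anisotropic one (λ = (0.35, 0.15, 0.15)×10⁻³, f = 0.4); the
gray slab uses a milder pair. The deliberate asymmetry — the fast pool is
both more diffusive and more anisotropic — is what produces the two
shell effects the package studies: as high-b shells enter a pooled tensor
fit the surviving slow-pool signal drags all apparent tensor metrics
down, while the slow pool's retained angular contrast at high b sharpens
the ODFs, raising GFA and QA. A two-tensor mixture is the simplest model
with this phenomenology; no restricted-cylinder geometry is simulated.

**Directions.** No direction table was available to copy, so the
generator spreads points by iterative electrostatic repulsion on the
antipodally symmetrized set (200 fixed iterations, damped steps, seeded
random start). The 60-point set reaches a minimum pairwise (antipodal)
angle of ≈17°.

**Noise.** Magnitude-MRI (Rician): √((S+ε₁)² + ε₂²) with independent
zero-mean Gaussians of scale σ. The nominal SNR parameter (default 40,
the order of the study condition it emulates) fixes σ as the noiseless
bundle-mean shell-1 signal divided by that SNR. Everything is
deterministic given the seed.

**Aging.** Three pseudo-subjects at "ages" 10/15/24 months; each age step
shrinks the λ1:λ2 ratio of the anisotropic compartments by 10% (raising
the transverse eigenvalues), giving a monotone anisotropy decline.

**What the phantom does not contain** — and hence what passing tests do
not show about real data: no susceptibility/eddy artifacts, no partial
volume beyond the explicit mixtures, no spatial heterogeneity within a
region, no registration error (subjects are generated pre-aligned), no
T1/T2 relaxation. The homogeneous bundle in particular makes
extreme-value statistics (e.g. per-volume map maxima) purely
noise-driven; see the NQA note below.

## DTI

Pooled fit of one tensor per voxel to **all** volumes of the selected
cumulative scheme: log S = log S0 − b gᵀDg solved by linear least squares
with one reweighting pass (weights = squared predicted signal), the
standard correction for the log transform's heteroscedasticity. The
estimator choice is ours; nothing deeper than WLS-1 is warranted at these
SNRs. Nonpositive samples are floored at a small positive constant and
counted; negative eigenvalues are clamped to zero and counted. FA is
defined as 0 where the eigenvalue norm vanishes.

## QBI

Per shell: real symmetric (even-order) spherical-harmonic fit of the
signal, order 8 (45 coefficients; auto-reduced in steps of 2 when a shell
has fewer directions), Laplace–Beltrami penalty λ·l²(l+1)² with λ = 0.006.
The basis convention is m<0 → √2(−1)ᵐIm(Y_l^{|m|}), m=0 → Y_l⁰,
m>0 → √2(−1)ᵐRe(Y_l^m), indexed l-major so lower orders are a prefix of
higher ones. The analytic Funk–Radon transform scales each order-l
coefficient by 2π·P_l(0); sampled negative ODF values are floored at 0
(counted).

**Multi-shell combination (open design point).** Monoexponential q-ball
theory holds per shell, so each included shell gets its own analytic ODF;
the per-shell ODFs are rescaled to unit voxel-mean and averaged with
equal weights. The unit-mean rescaling mirrors the 1/Z normalization in
the ODF's definition and keeps the high-amplitude low-b shell from
dominating the average; a pooled multi-shell SH fit was rejected because
the FRT scaling is shell-specific.

**Sphere grid and peaks.** Subdivided icosahedron (3 levels), 321
hemisphere directions, neighbor graph from the mesh edges with antipodes
mapped to their hemisphere representatives. Local maxima (≥ all
neighbors, > at least one) are kept greedily by amplitude with a 25°
minimum separation and deterministic lexicographic tie-breaks; flat ODFs
are flagged degenerate and excluded from direction statistics. Because
the grid quantizes directions to several degrees, each kept maximum is
refined off-grid by two Newton steps in its tangent plane on the ODF's
band-limited SH expansion (finite-difference gradient/Hessian; steps
clipped, non-concave points left untouched). Sub-degree direction
accuracy on noiseless single-fiber voxels comes from this refinement.

**GFA, QA, NQA.** GFA is the normalized ODF standard deviation (0 for an
all-zero ODF). QA(u) = Z₀·(ψ(u) − Iψ) with Iψ the per-voxel ODF minimum
and Z₀ = 1/max over the volume of Iψ; the NQA map divides the
largest-peak QA by the volume maximum, so max NQA = 1 per reconstruction.
For comparisons **across** reconstructions of one subject (the shell
trends and the voxel-wise analyses) a single QA normalization constant is
shared across that subject's schemes: per-reconstruction renormalization
would force every scheme's maximum to 1 and reduce the homogeneous-ROI
mean to a noise-extreme ratio, erasing the very contrast under study.
Tracking thresholds apply to the per-reconstruction NQA maps.

## Angular deviation

θ = arccos |u_target·u_ref| in degrees (dot products clipped to [−1,1]),
antipodally and sign invariant; dominant directions are tensor e1 (DTI)
or the highest-amplitude refined ODF peak (QBI), canonicalized so the
first nonzero component is positive. Degenerate voxels (near-isotropic
tensors, flat ODFs) are excluded from ROI means — assigning them θ = 0
would deflate the statistic — and their count is reported. The trend is
an OLS of ROI-mean θ on the scheme code 1..5 (the reference scheme
contributes θ = 0), optionally with an age covariate; an exactly constant
response returns slope 0, p = 1 by convention.

## Tractography

FACT-style deterministic streamlines: nearest-voxel candidate directions,
the best-aligned peak by |dot| with the incoming heading (sign-flipped to
match), Euler steps of half the smallest voxel dimension (so consecutive
points are exactly one step apart in mm), bidirectional from each seed.
Termination: trilinear-interpolated stopping map below threshold, turn
above 60°, or leaving the volume; no emitted point lies below threshold.
Seeds are uniform random within the seed mask (seeded RNG, budget 100×
the target count); streamlines shorter than 2 steps are discarded. The
stopping-threshold table is fixed: FA 0.25 (1-shell) / 0.20 (multi),
GFA 0.02 / 0.03, NQA 0.25 / 0.30; the target count is 300.

## Statistics

* **SNR**: noise = mask-mean of the per-voxel SD across the b0 volumes
  (≥2 required); shell SNR = mask-mean weighted signal / noise; a
  cumulative scheme's SNR is the mean of its member shells'. The
  5-sample SD carries a known ≈6% downward bias (c₄(5) ≈ 0.94), within
  the estimator's stated 10% tolerance; identical b0 volumes yield
  noise 0 → SNR +inf with a warning.
* **Smoothing**: separable Gaussian, σ = FWHM/(2√(2 ln 2)) per axis,
  NaN-aware via mask renormalization. The default "kernel of 3" is read
  as FWHM = 3 voxels — whether such a kernel is σ or FWHM, voxels or mm,
  is ambiguous in common usage, so the value is prominently configurable.
* **Voxel-wise shell regression**: subjects pooled, OLS of anisotropy on
  scheme code with age as a covariate (three subjects cannot identify
  random effects), two-sided p from the t distribution, vectorized over
  voxels; all-NaN voxels excluded.
* **FDR**: classic Benjamini–Hochberg step-up over in-mask voxels; the
  critical p is the largest order statistic under its line, rejections
  are monotone in q.

## Experiment orchestration

`run_experiment` derives per-subject seeds from the master seed by fixed
offsets (kept below 2³¹), runs phantom → SNR → reconstruction (all
schemes, both models) → ROI trends (bundle and gray slab) → angular
deviations against the largest scheme → voxel-wise regressions (smoothed
maps, white-matter mask) → policy tractography, and writes a summary JSON
plus a human-readable report. The JSON contains no timestamps or wall
times (those go to a separate timings file), so a rerun with the same
seed is byte-identical; the config hash excludes output-location fields.
With a single scheme the deviation and trend stages are skipped with an
explicit notice. Default problem sizes — 20×20×10 voxels, 3 subjects, 5
schemes, 300 fibers, 200 null-calibration replicates on 10×10×10 grids —
keep the full study under a minute on one CPU.

## Known limitations

* Desk-scale grids and three pseudo-subjects: trend p-values come from 15
  ROI observations and should be read as design checks, not power
  analyses.
* The per-shell-average multi-shell ODF is one defensible convention
  among several (no pooled non-Gaussian model is fitted).
* No crossing-aware deviation statistic: only the single dominant peak
  per voxel enters θ, so the crossing region is excluded from that ROI.
* Rician bias is simulated but not corrected for in estimation; at the
  default SNR its effect on the reported trends is secondary to the
  compartment physics.
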