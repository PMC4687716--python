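# hydikit

Multi-shell ("hybrid") diffusion MRI analysis at desk scale: synthetic
multi-shell phantoms, diffusion-tensor (DTI) and analytic q-ball (QBI)
reconstruction under cumulative shell subsets, anisotropy mapping,
angular-deviation statistics, deterministic tractography, and voxel-wise
shell-trend statistics with FDR control.

## The scientific problem

Hybrid diffusion imaging (HYDI) samples q-space on several concentric
shells — here five, at b = 1000, 3000, 4000, 8000 and 12000 s/mm² with 60
directions per shell plus 5 unweighted (b0) volumes, 305 volumes in all.
Low-b shells carry high SNR; high-b shells carry high angular contrast.
A central design question is what each added shell buys: how do the
standard anisotropy maps and the recovered fiber orientations change as
the cumulative scheme grows from 1-shell (b = 1000 only) through 5-shell
(all data)?

`hydikit` makes that question answerable on a laptop. A synthetic phantom
emulates an ex vivo small-animal acquisition — a left–right white-matter
bundle, a 90° fiber crossing, a low-anisotropy gray-matter-like region,
an isotropic background, two-compartment (non-monoexponential) decay,
Rician noise, and three pseudo-subjects whose anisotropy declines with
"age" — and the full pipeline measures, for every cumulative scheme
k = 1..5:

* **DTI**: per-voxel tensor (pooled weighted-least-squares fit over all
  included volumes), with FA = √(3/2 · Σᵢ(λᵢ−MD)² / Σᵢλᵢ²),
  MD = (λ₁+λ₂+λ₃)/3, RD = (λ₂+λ₃)/2, AX = λ₁.
* **QBI**: per-shell spherical-harmonic fit (order 8, Laplace–Beltrami
  regularization 0.006) and analytic Funk–Radon transform (order-l
  coefficients scaled by 2π·P_l(0)), shell-averaged into an ODF ψ(u);
  GFA = √( n·Σᵢ(ψᵢ−⟨ψ⟩)² / ((n−1)·Σᵢψᵢ²) ), and quantitative anisotropy
  QA(u) = Z₀·(ψ(u) − Iψ) at each ODF peak, normalized to NQA.
* **Angular deviation**: θ = arccos |u₁·u₂| between each scheme's dominant
  fiber direction and the 5-shell reference, with an OLS trend of ROI-mean
  θ on the scheme code.
* **Tractography**: deterministic streamlines (60° turning limit, 300
  fibers) with FA/GFA/NQA stopping thresholds (0.25/0.02/0.25 single-shell,
  0.20/0.03/0.30 multi-shell).
* **Statistics**: b0-based SNR per shell, Gaussian smoothing, voxel-wise
  OLS of anisotropy on scheme code with age covariate, Benjamini–Hochberg
  FDR at q < 0.05.

The expected directional findings — tensor metrics (FA, MD, RD, AX) fall
while ODF metrics (GFA, NQA) rise with each added shell, and fiber
directions converge to the full-scheme reference — are checked end to end
by `hydikit.experiment.run_experiment`.

## Worked example

```python
from hydikit.phantom import PhantomSpec, build_phantom
from hydikit.gradients import select_subset
from hydikit.dti import fit_tensor, tensor_scalars
from hydikit.qbi import SphereGrid, fit_sh, frt_odf, gfa
from hydikit.deviation import shell_trend

ds, truth = build_phantom(PhantomSpec(seed=0))
sphere = SphereGrid.icosphere(3)
bundle = truth.masks["bundle"]
fa_means, gfa_means = [], []
for k in range(1, 6):
    sub = select_subset(ds, k)
    fa = tensor_scalars(fit_tensor(sub))["FA"]
    g = gfa(frt_odf(fit_sh(sub), sphere))
    fa_means.append(fa.roi_mean(bundle))
    gfa_means.append(g.roi_mean(bundle))
    print(f"k={k}: bundle FA = {fa_means[-1]:.3f}, GFA = {gfa_means[-1]:.3f}")
tr = shell_trend(range(1, 6), fa_means)
print(f"FA trend: slope = {tr.slope:+.4f} per shell, p = {tr.p:.2e}")
```

prints

```
k=1: bundle FA = 0.706, GFA = 0.096
k=2: bundle FA = 0.686, GFA = 0.133
k=3: bundle FA = 0.661, GFA = 0.150
k=4: bundle FA = 0.643, GFA = 0.168
k=5: bundle FA = 0.629, GFA = 0.175
FA trend: slope = -0.0196 per shell, p = 4.84e-04
```

i.e. apparent FA in the bundle drops as higher-b shells enter the pooled
tensor fit (the slow tissue compartment increasingly dominates), while
GFA rises as the sharper high-b ODFs enter the q-ball average — the two
headline shell effects, each with a significant linear trend.

A command-line interface wraps the same stages:

```bash
hydikit phantom --out data --seed 3
hydikit dti --in data --out maps --shells 5
hydikit qbi --in data --out maps --shells 5 --order 8 --reg 0.006
hydikit run --out study --seed 1     # full three-subject experiment
```

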