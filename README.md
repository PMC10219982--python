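# radialinfo

Quantitative analysis of radial morphogen gradients in the embryonic mouse
cochlea: how precisely do the SOX2 and pSMAD1/5/9 (BMP-activity) profiles
across the prosensory domain (PSD) encode radial position during the stages
(E12.5–E14.5) when the organ of Corti pattern is first laid down?

The package is written for developmental/systems biologists working with
line-scan fluorescence profiles. It provides, as composable library modules
plus a thin `radialinfo` CLI:

* **Ingestion & preprocessing** (`profile_io`, `preprocess`) — line-scan CSVs
  through a five-step ladder: nuclear-density noise regression
  (ŝ = m − βn_ref with β = mᵀn_ref / n_refᵀn_ref), 20 µm moving average,
  uniform resampling, min–max anchoring plus model-based normalization
  (argmin over per-sample affine distortions {α_i, β_i} of
  χ² = Σ_i ∫dx [G⁽ⁱ⁾(x) − (α_i + β_i ḡ(x))]²), and 10% edge cropping.
* **Positional information** (`posinfo`) — direct-method mutual information
  I_Δ,M({g_i}; x) from binned joint histograms with bootstrap bias
  extrapolation, Bayesian decoding maps
  P(x*|x) ∝ P({g_i}|x*) P_x(x*) under a (multivariate) Gaussian noise model
  with the ensemble mean ḡ(x*) and covariance Ĉ(x*), fractional redundancy
  R = (Σ_i I_i − I_joint)/I_joint, feature counts 2^I, and nuclear-density
  prior uniformization.
* **Shape analytics** (`shape_analysis`) — linear/exponential fits, FWHM,
  position-wise two-sample Kolmogorov–Smirnov stage comparisons, signal
  trajectories, and counterfactual remapping of measured residuals onto
  alternative monotone shapes (linear / exponential / sigmoid / power law)
  with an information ranking.
* **Mechanistic model** (`bmp_model`, `fitting`) — a 1D reaction–diffusion
  model of BMP (B), Follistatin (F) and their complex (BF) on Ω = [0, 600] µm,

      ∂B/∂t  = D ∂²B/∂x² + η_B φ_B − δ_B B − k_on B·F + k_off BF − k_sink S(x,b) B
      ∂F/∂t  =             η_F φ_F − δ_F F − k_on B·F + k_off BF
      ∂BF/∂t =                     − δ_BF BF + k_on B·F − k_off BF

  with no-flux boundaries, mRNA-derived synthesis profiles φ_B, φ_F, and a
  hypothetical medial sink S(x,b), fitted to pSMAD1/5/9 profiles by
  particle-swarm optimization (RMSE cost with fold-change penalty,
  log-space bounds). The classical source–sink configuration (constant
  lateral flux, perfect medial sink), whose steady state is an exact
  straight line, is built in as an analytic oracle.
* **Synthetic data** (`synthetic_data`) — a generator reproducing the
  measured statistical structure (linear pSMAD gradient m ≈ 1.53,
  b ≈ −0.18 with lateral peak at x/L ≈ 0.77; bimodal SOX2 with secondary
  peak at x/L = 0.74; post-processing variability ⟨σ_g⟩ ≈ 0.06–0.10;
  per-sample affine distortions; fluctuating nuclear channel), so the whole
  pipeline is testable without the imaging dataset.

## Worked example

```python
from radialinfo.synthetic_data import SyntheticSpec, gen_profile_ensemble
from radialinfo.preprocess import preprocess_scans, ensemble_stats
from radialinfo.shape_analysis import fit_linear
from radialinfo.posinfo import mutual_information, distinct_features

ens = gen_profile_ensemble(SyntheticSpec(seed=1))      # 15 E12.5-like cochleae
psmad, info = preprocess_scans(ens.scans, "psmad")      # full A–E ladder
sox2, _ = preprocess_scans(ens.scans, "sox2")

rep = fit_linear(psmad.x, psmad.mean)
print(f"pSMAD1/5/9 linear fit: m = {rep.params[0]:.2f}, "
      f"b = {rep.params[1]:.2f}, R^2 = {rep.r2:.3f}")

i1 = mutual_information(psmad, seed=0).value
i2 = mutual_information(sox2, seed=0).value
ij = mutual_information(ensemble_stats({"psmad": psmad, "sox2": sox2}), seed=0).value
print(f"I(pSMAD;x) = {i1:.2f} bits, I(SOX2;x) = {i2:.2f} bits, joint = {ij:.2f} bits")
print(f"distinct features ~ {distinct_features(ij)[1]}")
```

prints

```
pSMAD1/5/9 linear fit: m = 1.54, b = -0.16, R^2 = 0.999
I(pSMAD;x) = 2.05 bits, I(SOX2;x) = 1.46 bits, joint = 3.58 bits
distinct features ~ 12
```

The fitted slope/intercept recover the generator's ground-truth gradient
(1.53 / −0.18) through the full normalization ladder; the joint information
of ≈3.6 bits means these two synthetic profiles could in principle specify
about 12 distinguishable radial feature positions. (On measured data the
joint estimate is lower and ~20% redundant, because real channels share
embryo-level noise; the synthetic channels' residual noise is independent,
so their information is close to additive — see `docs/methods.md`.)

The same analyses run from the shell on a directory of line-scan CSVs:

```bash
radialinfo synth --preset E12.5 --n 15 --seed 1 --out data/
radialinfo mi --data data/ --channels psmad,sox2 --stage E12.5
radialinfo shapes --data data/ --channel psmad --stage E12.5
radialinfo fit --variant fst+sink --particles 200 --restarts 30 --seed 7
```

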