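# Methods

This note documents the models, estimators and numerical choices behind
`radialinfo`, and what its synthetic-data tests do and do not demonstrate
about measured cochlear profiles.

## Coordinate conventions

All profiles live on the radial axis of the prosensory domain (PSD):
x/L = 0 at the medial edge, 1 at the lateral edge. The PSD spans roughly
250–305 µm depending on stage. Preprocessed ensembles are cropped to
x/L ∈ [0.1, 0.9] and keep those labels (the grid is not re-stretched).
The reaction–diffusion model uses an extended physical domain
Ω = [0, 600] µm with the PSD at ω = (150, 450) µm; the flanks absorb ligand
that escapes the duct, standing in for the surrounding mesenchyme where
BMP-activity profiles decay exponentially and level off.

## Preprocessing ladder

1. **Nuclear-noise regression.** The nuclear channel n_ref is used as a
   reference for intensity fluctuations driven by variable nuclear density.
   The corrected signal is the projection ŝ = m − β·n_ref with
   β = mᵀn_ref / n_refᵀn_ref, the energy-minimizing coefficient. Note this
   removes the entire component of m along n_ref, including any constant
   background (the nuclear channel is ≈ constant plus fluctuations), which
   is why the synthetic generator models background as proportional to the
   nuclear channel.
2. **Smoothing.** 20 µm centered moving average. The window is truncated
   symmetrically at the boundaries rather than padded: no data is invented
   at edges that step 5 discards anyway.
3. **Resampling.** Linear interpolation onto a uniform 1000-point relative
   grid (raw traces are ~300–1024 px, so this is always upsampling and is
   loss-free for piecewise-linear signals).
4. **Normalization.** The ensemble mean is anchored to [0, 1] (for
   mesenchymal BMP activity only the maximum is scaled, recorded in the
   `anchor_min` flag — normalized 0 there is *not* the observed minimum;
   in the epithelium normalized 0 is the observed minimum of the mean and
   need not be zero concentration). Then model-based normalization removes
   per-sample affine distortions: (α_i, β_i) minimizing
   χ² = Σ_i ∫dx [G⁽ⁱ⁾ − (α_i + β_i ḡ)]² are fitted in closed form against
   the current mean and divided out, the mean is recomputed, and the
   procedure iterates to a fixed point (≤50 iterations, χ² tolerance
   1e-12). The joint problem is gauge-degenerate — the mean can absorb any
   affine map — so the gauge is fixed by re-anchoring the mean to [0, 1]
   after every iteration. Samples fitting with β_i ≤ 0 are flagged and left
   unscaled. Re-running the procedure on its own output changes χ² by
   < 1e-10.
5. **Cropping.** The medial and lateral 10% are discarded (ROI edges can
   leave the tissue in some sections).

Statistics use the population convention (divide by N): the same variance
enters the decoding likelihood, so estimator and decoder are consistent.

## Positional information

The direct method bins the pooled (expression, position) samples —
100 equal-width position bins, Δ expression bins per channel (default 32,
with a {8, 16, 32, 64} scan and plateau report available) — and computes
plug-in mutual information from the joint histogram. Finite-sample bias is
removed by subsampling the cochleae at fractions {0.5 … 1.0} (100 draws per
fraction), and extrapolating the mean estimate linearly in 1/(subsample
count) to infinite sample size. The estimate is clipped at 0. Bin edges
span the pooled data range per channel, which makes the estimator exactly
invariant under channel-wise affine rescaling.

The spatial prior P_x(x) is made uniform over *cells* rather than over
length by `uniformize_prior`: positions are remapped so cumulative nuclear
intensity is linear in the new coordinate; signal channels ride along by
interpolation. Decoding and information estimates consume the warped
coordinate.

Decoding maps follow the Gaussian optimal-decoding construction: for the
levels {g_i^α(x)} read at actual position x, the implied-position density is
P(x*|x) ∝ P({g_i}|x*) P_x(x*) with a (multivariate) Gaussian likelihood
using the ensemble mean and per-position covariance Ĉ(x*). Numerics:
σ_g is floored at 1e-3 (normalized units) and Ĉ receives a ridge
ε = 1e-6·trace(Ĉ)/K before inversion, since small-N covariances can be
singular; the K=1 joint path reduces exactly (to 1e-12) to the single-gene
path because both share the same core. Rows are normalized to integrate to
1 on the shared 100-point x*/x grid; reported maps average the per-sample
maps over α.

Fractional redundancy R = (Σ_i I_i − I_joint)/I_joint summarizes channel
overlap (1 = duplicate, 0 = additive); 2^I is reported raw and rounded as a
count of distinguishable radial features.

## Shape analytics and counterfactuals

Linear fits run from the medial extreme to the profile peak (argmax of the
smoothed mean; ties broken laterally, as peaks are lateral in all observed
data). Exponential fits (A·e^{kx} + c) use nonlinear least squares
multi-started from a log-linear seed. FWHM takes the outermost crossings of
(min+max)/2 around the main peak with linear interpolation; a never-crossed
side falls back to the domain edge with a warning. Stage comparisons use
the asymptotic two-sample Kolmogorov–Smirnov test per position; positions
with p < 0.05 are marked significantly different (the plotting convention
colors significant positions and fades p ≥ 0.05 to black).

The counterfactual analysis transplants measured residuals
G⁽ⁱ⁾(x) − ḡ(x) onto alternative monotone shapes connecting the ensemble's
medial minimum to its lateral maximum, preserving every per-position
residual moment exactly, then re-estimates information per shape family.
Families (all endpoint-matched, u = normalized position):

* linear;
* exponential (e^{ku}−1)/(e^k−1) with k = 2 ln 3 (quarter of the range at
  mid-domain);
* sigmoid: logistic centered at u = 0.5 spanning 1–99%, affinely
  re-anchored to the endpoints. A shallower (5–95%) logistic was rejected
  because its minimum slope is so close to linear that at the measured
  noise level it is informationally indistinguishable from the linear
  profile — it does not represent a step-like alternative at all;
* power law u².

## Reaction–diffusion model

Three species (free BMP B, free Follistatin F, complex BF, all nM) evolve
on Ω with second-order central differences (method of lines, default
dx = 5 µm) and a stiff implicit integrator (LSODA with banded Jacobian;
rtol 1e-6, atol 1e-9 nM). Binding k_on can reach 1/(nM·s) at nM
concentrations over 24 h, which is mildly stiff. Initial conditions:
B(x,0) = the normalized stage-E12.5 BMP-activity profile embedded in ω;
F(x,0) = BF(x,0) = φ_F(x) (the measured *Fst* transcript shape — initializing
the bound complex to that shape is unusual but implemented as specified,
with a configuration switch for BF(x,0) = 0). Synthesis profiles φ_B, φ_F
are the normalized transcript profiles embedded in ω and zero elsewhere
(transcripts are only measured in the duct). The medial sink S(x,b) is a
unit step (or linearly decreasing profile) confined to the PSD, from its
medial edge to PSD-relative extent b (default 0.1, explorable to 0.5);
the sink molecule is assumed in excess, binding irreversibly at rate
k_sink. Model output compared to data is B(x, T) max-normalized over ω,
taking BMP-pathway activity as proportional to free ligand.

Verification built into the solver:

* **Crick limit.** With a constant lateral influx, a medial Dirichlet-0
  sink and no decay, the steady state is the exact line J·x/D for any D and
  any initial condition; the solver reproduces it to < 1e-6 relative.
* **Mass balance.** Reaction/source integrals are co-integrated as
  auxiliary states (trapezoid weights, under which the discrete Neumann
  Laplacian conserves mass identically), so per-species balance residuals
  are available to solver accuracy rather than post-hoc quadrature error.
* **Grid convergence.** Halving dx changes B(x, 24 h) by < 0.5% (L∞) at
  representative parameters.

Negative concentrations beyond a 1e-6 nM tolerance raise an error rather
than being clipped silently (they indicate instability); sub-tolerance
undershoot from the implicit solver is clipped in outputs only.

## Parameter fitting

The cost is the RMSE between the max-normalized B(x, 24 h) and the target
profile on the window from the target's medial extreme to its peak
(window endpoints snap to grid nodes; the peak is located on the smoothed
target). Before normalization, the amplitude fold-change
max B(·,T)/max B(·,0) must lie in [0.5, 10]; violations add a constant
penalty of 10.0 — far larger than any achievable RMSE on max-normalized
profiles — so penalized solutions are rejected without producing
non-finite costs. Absolute concentrations between stages are not
measurable, hence shape-only comparison.

The particle swarm moves in log10 parameter space within bounds spanning
4+ decades (exact at the bounds), with standard constriction coefficients
(inertia 0.729, cognitive = social = 1.494), velocity clamped to 20% of
the box. "Generations" are interpreted as independent restarts (default
30), each run to stagnation (no global-best improvement > 1e-6 for 10
iterations, capped at 100); the global best carries across restarts, so
the cost history is monotone non-increasing. Both interpretations of the
restart/iteration ambiguity are reachable through configuration. Model
variants (±FST, ±sink, free/fixed D = 4 µm²/s) drop the corresponding
parameters from the search. With-FST fits also report the derived
dissociation constant K_D = k_off/k_on.

## Synthetic data generator

The generator emulates the *reported statistics* of the measured ensembles
so every stage of the pipeline has a ground-truth oracle:

* pSMAD-like truth: linear rise with slope 1.53 and intercept −0.18
  (normalized units), smoothly clipped at 0 medially, peaking where the
  line reaches 1 (x/L ≈ 0.77, inside the observed 0.7–0.8 band), then
  declining linearly to 0.65 at the lateral edge (the decline level is a
  free choice; only its existence is observed). Extrema are rounded over
  ~0.03 x/L: measured profiles have smooth turning points, and a kinked
  peak loses height under the 20 µm moving average, which would bias the
  anchored slope upward by ~2%.
* SOX2-like truth: baseline + dominant medial Gaussian (center 0.33; width
  set directly by the stage's FWHM fraction — 0.38/0.27/0.19 at
  E12.5/E13.5/E14.5) + secondary lateral Gaussian at x/L = 0.74.
* Stage presets: N = 15/16/8 samples and PSD lengths 303/254/256 µm.
* Noise: a smooth Gaussian process (Gaussian-filtered white noise,
  correlation length 20 µm) rather than per-pixel white noise. The reported
  inter-sample variability (⟨σ_g⟩ ≈ 0.06 for pSMAD, ≈ 0.10 for SOX2) is
  measured *after* the ladder, and a 20 µm moving average would annihilate
  white noise; only spatially correlated inter-embryo variation survives.
  Marginal SDs (0.075 / 0.125) are set so the post-ladder ensembles land on
  the reported values — smoothing and the per-sample affine fit absorb
  roughly a quarter of the marginal SD.
* Distortions: per-sample affine a_i + b_i·(·) with a_i ~ N(0, 0.12) and
  b_i log-normal (log-SD 0.40). True distortion magnitudes are not
  published; these defaults are set so normalization reduces inter-sample
  χ² at least five-fold on the presets, and they are adjustable.
* Nuclear channel: 1 + 8% smooth fluctuations; background proportional to
  it leaks into the signal channels (coefficient 0.5), exercising the
  regression step. Because the regression is an exact projection, doubling
  the leak leaves corrected profiles unchanged — a generator-level oracle.

**What passing these tests does not show.** The generator's residual noise
is drawn independently per channel, so synthetic pSMAD/SOX2 ensembles carry
nearly additive information (fractional redundancy ≈ 0), whereas measured
channels share embryo-level variation and overlap by ~20%. Absolute bit
counts on synthetic data are therefore not comparable to measured ones —
qualitative structure (diagonal decoding, SOX2 bimodality, shape ranking)
is. The generator also omits imaging artifacts (PSF, z-projection,
saturation) and any position dependence of σ beyond an optional linear
ramp, since the measured form of σ(x) is not published.

## Problem sizes in tests and the acceptance script

Tests and `scripts/acceptance.py` run the generator at the study's sample
sizes (N = 15), the solver at dx = 5 µm, mutual information with 100
position bins / 32 expression bins / 100 bootstrap draws, and optimizer
checks with reduced swarms (20–50 particles, 8–15 iterations, single
restart) — self-recovery is comfortably achieved at these sizes, and the
qualitative variant orderings (sink ≤ no-sink cost on a linear target;
fixed-D forcing lower δ_B) are asserted as medians over five seeds.

## Known limitations

* The χ² normalization iterates to a fixed point; whether a single pass
  was intended is unknowable from the description, so the iteration count
  is configurable (one pass ≈ first iteration).
* The exact direct-method settings (Δ, M) behind the published bit counts
  are not stated; the defaults here are the procedure's standard knobs and
  are all exposed. Reproducing printed bit counts from the deposited data
  may require matching those settings.
* For a purely linear profile with uniform variance the information is
  sometimes summarized as I = log₂ σ_g⁻¹; this omits the Gaussian
  differential-entropy constant, so it is treated as slope-only guidance
  (the implementation always computes the full estimator).
* The sink's lateral extent is described both as reaching x/L = 0.1 and as
  explored up to 0.5; it is a free configuration scalar with default 0.1.
* Whether exported line-scan values are the mean or the sum across the ROI
  width is unstated upstream; the reader ingests whatever scalar the CSV
  holds (the preprocessing is invariant to that choice up to affine maps).
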