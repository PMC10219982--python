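"""Synthetic line-scan generator emulating the measured statistical structure
of radial cochlear profiles, so every pipeline stage is testable without the
deposited imaging data.

Per stage the generator draws N cochleae.  Ground truth shapes:

* pSMAD1/5/9 — linear rise (slope m, intercept b in normalized units,
  clipped at 0 medially) up to a lateral peak at x/L = (1−b)/m ≈ 0.77, then
  a linear decline toward the lateral edge;
* SOX2 — a dominant medial Gaussian peak (width sets the FWHM fraction)
  plus a small secondary lateral peak at x/L = 0.74 and a baseline;
* nuclear — 1 plus smooth positive fluctuations, a fraction of which leaks
  into the signal channels (exercising the noise regression).

Sample-to-sample variation = a smooth Gaussian-process noise field (the
inter-embryo biological variability that survives a 20 µm moving average)
plus a per-sample affine intensity distortion a_i + b_i·(·) (experimental
staining/illumination variability removed by model-based normalization).
Every generator is a pure function of its spec + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .bmp_model import BmpModelParams, MrnaProfile, SinkSpec, SpatialDomain, simulate
from .preprocess import Profile
from .profile_io import LineScan

#: stage presets: (n_samples, PSD length µm, SOX2 FWHM fraction)
STAGE_PRESETS = {
    "E12.5": dict(n_samples=15, length_um=303.0, sox2_fwhm=0.38),
    "E13.5": dict(n_samples=16, length_um=254.0, sox2_fwhm=0.27),
    "E14.5": dict(n_samples=8, length_um=256.0, sox2_fwhm=0.19),
}

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class SyntheticSpec:
    """Generator settings for one stage-like ensemble."""

    n_samples: int = 15
    stage: str = "E12.5"
    length_um: float = 303.0
    n_points: int = 300
    # pSMAD truth (normalized units)
    psmad_slope: float = 1.53
    psmad_intercept: float = -0.18
    psmad_lateral_end: float = 0.65  # value at x/L = 1 after the peak
    # SOX2 truth
    sox2_main_center: float = 0.33
    sox2_fwhm: float = 0.38  # fraction of the domain
    sox2_secondary_center: float = 0.74
    sox2_secondary_height: float = 0.20
    sox2_baseline: float = 0.05
    # noise model: marginal SD, optionally ramping linearly in x.  Defaults
    # are calibrated so the post-ladder ensembles show the measured
    # inter-sample variability (⟨σ_g⟩ ≈ 0.06 pSMAD / 0.10 SOX2): smoothing
    # and the per-sample affine normalization absorb ~25% of the marginal SD.
    sigma_psmad: float = 0.075
    sigma_sox2: float = 0.125
    sigma_slope: float = 0.0  # sigma(x) = sigma * (1 + sigma_slope*(x-0.5))
    noise_length_um: float = 20.0  # GP correlation length
    # per-sample affine distortion: a_i ~ N(a_mean, a_sd), b_i lognormal
    distortion_a_mean: float = 0.0
    distortion_a_sd: float = 0.12
    distortion_b_logsd: float = 0.40
    # nuclear channel (leak: background proportional to nuclear density)
    nuclear_amplitude: float = 0.08
    nuclear_leak: float = 0.5
    seed: int = 0

    @property
    def psmad_peak_x(self) -> float:
        """Peak position where the linear rise reaches 1 (≈0.77 for defaults)."""
        return (1.0 - self.psmad_intercept) / self.psmad_slope

    @classmethod
    def preset(cls, stage: str, **overrides) -> "SyntheticSpec":
        base = STAGE_PRESETS[stage]
        kwargs = dict(n_samples=base["n_samples"], stage=stage,
                      length_um=base["length_um"], sox2_fwhm=base["sox2_fwhm"])
        kwargs.update(overrides)
        return cls(**kwargs)


def psmad_truth(x: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    """Linear-rise-then-decline ground-truth pSMAD shape on x/L.

    The medial floor and the lateral peak are rounded over ~0.03 x/L
    (softplus floor, logistic blend at the peak) so the extrema survive a
    20 µm moving average — measured profiles have smooth turning points,
    and kinks would bias the anchored slope.
    """
    peak = spec.psmad_peak_x
    w = 0.03
    line = spec.psmad_slope * x + spec.psmad_intercept
    rise = w * np.logaddexp(0.0, line / w)  # smooth clip at 0
    decline = 1.0 + (spec.psmad_lateral_end - 1.0) * (x - peak) / (1.0 - peak)
    blend = 1.0 / (1.0 + np.exp(-(x - peak) / w))
    return rise * (1.0 - blend) + decline * blend


def sox2_truth(x: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    """Two-Gaussian-plus-baseline ground-truth SOX2 shape on x/L."""
    sigma = spec.sox2_fwhm * _FWHM_TO_SIGMA
    main = np.exp(-0.5 * ((x - spec.sox2_main_center) / sigma) ** 2)
    secondary = np.exp(-0.5 * ((x - spec.sox2_secondary_center) / 0.04) ** 2)
    b = spec.sox2_baseline
    return b + (1.0 - b) * main + spec.sox2_secondary_height * secondary


def _gp_noise(rng: np.random.Generator, n: int, corr_points: float) -> np.ndarray:
    """Smooth unit-variance noise: Gaussian-filtered white noise."""
    pad = int(4 * corr_points) + 1
    white = rng.standard_normal(n + 2 * pad)
    smooth = gaussian_filter1d(white, corr_points, mode="reflect")[pad:-pad]
    # variance of gaussian-filtered unit white noise: 1/(2*sigma*sqrt(pi))
    return smooth * np.sqrt(2.0 * corr_points * np.sqrt(np.pi))


def _sigma_of_x(x: np.ndarray, sigma: float, slope: float) -> np.ndarray:
    return sigma * (1.0 + slope * (x - 0.5))


@dataclass
class SyntheticEnsemble:
    """Generated scans plus the ground truth they were built from."""

    scans: list[LineScan]
    truth: dict[str, np.ndarray]
    x: np.ndarray
    spec: SyntheticSpec


def gen_profile_ensemble(spec: SyntheticSpec) -> SyntheticEnsemble:
    """Draw an ensemble of line scans (psmad, sox2, nuclear channels).

    Each sample is truth + smooth GP noise, affinely distorted per sample,
    with a leaked share of its nuclear channel added on top; the scan is
    scaled to fluorescence-like units and floored at 0.
    """
    rng = np.random.default_rng(spec.seed)
    x = np.linspace(0.0, 1.0, spec.n_points)
    position = x * spec.length_um
    pixel = spec.length_um / (spec.n_points - 1)
    corr_pts = spec.noise_length_um / pixel
    truth = {"psmad": psmad_truth(x, spec), "sox2": sox2_truth(x, spec)}
    scans = []
    for i in range(spec.n_samples):
        a_i = rng.normal(spec.distortion_a_mean, spec.distortion_a_sd)
        b_i = float(np.exp(rng.normal(0.0, spec.distortion_b_logsd)))
        nuclear = 1.0 + spec.nuclear_amplitude * _gp_noise(rng, spec.n_points, corr_pts)
        nuclear = np.clip(nuclear, 0.05, None)
        channels = {}
        for name, sigma in (("psmad", spec.sigma_psmad), ("sox2", spec.sigma_sox2)):
            noise = _gp_noise(rng, spec.n_points, corr_pts)
            noise *= _sigma_of_x(x, sigma, spec.sigma_slope)
            signal = a_i + b_i * (truth[name] + noise)
            measured = signal + spec.nuclear_leak * nuclear
            channels[name] = np.clip(1000.0 * measured, 0.0, None)
        channels["nuclear"] = 1000.0 * nuclear
        scans.append(LineScan(
            sample_id=f"{spec.stage}-{i:02d}", stage=spec.stage, compartment="psd",
            position=position.copy(), channels=channels, pixel_size=pixel,
        ))
    return SyntheticEnsemble(scans, truth, x, spec)


def gen_mrna_profiles(domain: SpatialDomain | None = None) -> MrnaProfile:
    """Smooth synthetic *Bmp4*/*Fst* synthesis profiles and the pSMAD IC.

    φ_B is a smooth bump supported on PSD x/L ∈ (0.4, 1.0) with a lateral
    peak; φ_F a lateral bump medial to the φ_B peak; both are max-normalized
    and exactly zero outside their support.  f_pSMAD is the noiseless
    stage-E12.5 pSMAD shape embedded in the PSD window.
    """
    domain = domain or SpatialDomain()
    rel = domain.psd_relative()

    def bump(lo: float, hi: float, peak: float) -> np.ndarray:
        out = np.zeros(domain.n_grid)
        left = (rel >= lo) & (rel <= peak)
        right = (rel > peak) & (rel <= hi)
        out[left] = 0.5 - 0.5 * np.cos(np.pi * (rel[left] - lo) / (peak - lo))
        out[right] = 0.5 + 0.5 * np.cos(np.pi * (rel[right] - peak) / (hi - peak))
        return out

    phi_B = bump(0.4, 1.0, 0.85)
    phi_F = bump(0.45, 0.95, 0.70)
    spec = SyntheticSpec()
    f = np.zeros(domain.n_grid)
    inside = (rel >= 0.0) & (rel <= 1.0)
    f[inside] = psmad_truth(rel[inside], spec)
    return MrnaProfile(domain.x, phi_B, phi_F, f)


def gen_pde_target(
    params: BmpModelParams,
    mrna: MrnaProfile | None = None,
    domain: SpatialDomain | None = None,
    sink: SinkSpec | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    t_end: float = 86400.0,
) -> tuple[Profile, dict]:
    """Simulate a 24 h target profile from known parameters (self-consistency
    oracle for the optimizer).

    Returns the max-normalized B(x, T) over the PSD window as a Profile on
    the PSD x/L grid plus a truth record; optional additive Gaussian noise.
    """
    domain = domain or SpatialDomain()
    mrna = mrna if mrna is not None else gen_mrna_profiles(domain)
    result = simulate(params, domain, mrna, sink, t_end=t_end)
    mask = domain.psd_mask()
    x = domain.psd_relative()[mask]
    g = result.state.B[mask]
    g = g / g.max()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        g = g + rng.normal(0.0, noise_sd, size=g.size)
    truth = {"params": params, "sink": sink, "t_end": t_end, "noise_sd": noise_sd,
             "seed": seed}
    return Profile(x=x, g=g, channel="psmad", stage="synthetic"), truth
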