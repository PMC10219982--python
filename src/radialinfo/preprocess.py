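"""Profile preprocessing: the five-step ladder from raw line scans to
normalized profile ensembles.

(A) nuclear-noise regression, (B) 20 µm moving average, (C) linear-interp
resampling onto a uniform relative grid, (D) min–max anchoring of the mean
plus model-based χ² variance minimization across samples, (E) cropping the
medial and lateral 10%.

The χ² statistic minimized in step (D) is

    χ²({α_i, β_i}) = Σ_i ∫ dx [G⁽ⁱ⁾(x) − (α_i + β_i ḡ(x))]²,

i.e. each sample is assumed to differ from the ensemble mean only by an
experimental affine intensity distortion; the fitted (α_i, β_i) are divided
out.  The joint problem is gauge-degenerate (the mean can absorb a global
affine change), so the gauge is fixed by re-anchoring the mean to [0, 1]
after every outer iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .profile_io import LineScan


@dataclass
class Profile:
    """A single normalized expression profile on a uniform relative grid."""

    x: np.ndarray  # relative position x/L
    g: np.ndarray  # normalized expression (dimensionless)
    channel: str = "unknown"
    stage: str | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.x.shape != self.g.shape:
            raise ValueError("x and g must have the same shape")
        if not np.all(np.isfinite(self.g)):
            raise ValueError("profile values must be finite")


@dataclass
class ProfileEnsemble:
    """Per-stage, per-channel set of profiles sharing a common grid.

    ``samples`` is an (n_samples, n_x) array.  Mean and SD use the
    population convention (divide by N) — the same variance enters the
    Gaussian decoding likelihood.  ``anchor_min`` records the zero-level
    semantics: when False (mesenchymal pSMAD) only the maximum was scaled
    to 1 and normalized 0 is not the observed minimum.
    """

    x: np.ndarray
    samples: np.ndarray
    channel: str = "unknown"
    stage: str | None = None
    sample_ids: list[str] = field(default_factory=list)
    anchor_min: bool = True

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[1] != self.x.size:
            raise ValueError("sample rows must match the grid length")
        if not self.sample_ids:
            self.sample_ids = [str(i) for i in range(self.samples.shape[0])]
        if len(self.sample_ids) != self.samples.shape[0]:
            raise ValueError("sample_ids length mismatch")

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    @property
    def mean(self) -> np.ndarray:
        return self.samples.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.samples.std(axis=0)  # population convention

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    def profiles(self) -> list[Profile]:
        return [
            Profile(self.x, row, self.channel, self.stage, sid)
            for sid, row in zip(self.sample_ids, self.samples)
        ]


@dataclass
class MultiChannelStats:
    """Cross-channel ensemble statistics on a common grid.

    ``data`` has shape (n_samples, K, n_x); ``cov`` is the per-position
    K×K cross-channel covariance Ĉ(x) (population convention).
    """

    x: np.ndarray
    channels: list[str]
    data: np.ndarray
    stage: str | None = None

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[0])

    @property
    def mean(self) -> np.ndarray:  # (K, n_x)
        return self.data.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:  # (K, n_x)
        return self.data.std(axis=0)

    @property
    def cov(self) -> np.ndarray:  # (n_x, K, K)
        centered = self.data - self.mean  # (n, K, nx)
        return np.einsum("aik,ajk->kij", centered, centered) / self.data.shape[0]

    def single(self, channel: str) -> ProfileEnsemble:
        k = self.channels.index(channel)
        return ProfileEnsemble(self.x, self.data[:, k, :], channel, self.stage)


# --- (A) nuclear-noise regression ----------------------------------------

def regress_nuclear_noise(
    scan: LineScan, signal_channel: str = "psmad", reference_channel: str = "nuclear"
) -> tuple[np.ndarray, float]:
    """Cancel nuclear-density noise by projecting it out of the signal.

    Returns ``(s_hat, beta)`` with ``s_hat = m − β·n_ref`` and
    ``β = mᵀn_ref / n_refᵀn_ref`` — the β minimizing the energy Σ ŝ(x)².
    """
    m = scan.channel(signal_channel)
    n_ref = scan.channel(reference_channel)
    denom = float(n_ref @ n_ref)
    if denom == 0.0:
        raise ZeroDivisionError("reference channel is identically zero")
    beta = float(m @ n_ref) / denom
    return m - beta * n_ref, beta


# --- (B) moving average ---------------------------------------------------

def moving_average(values: np.ndarray, window_um: float = 20.0, pixel_size: float = 1.0) -> np.ndarray:
    """Centered moving average over a physical window.

    The window is truncated (shrunk symmetrically) at the boundaries rather
    than padded, so no data is invented at edges that are later cropped.
    Constant input is returned unchanged.
    """
    values = np.asarray(values, dtype=float)
    if window_um <= 0:
        raise ValueError("window_um must be positive")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    half = int(round(window_um / pixel_size)) // 2
    if window_um < pixel_size:
        raise ValueError("window shorter than one sample spacing")
    if half == 0:
        return values.copy()
    n = values.size
    csum = np.concatenate([[0.0], np.cumsum(values)])
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)  # symmetric shrink at boundaries
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return out


# --- (C) resampling -------------------------------------------------------

def resample_uniform(
    position: np.ndarray, values: np.ndarray, n_points: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """Linear-interpolation resampling onto a uniform grid of ``n_points``.

    Upsampling only (the default 1000 exceeds typical 300–1024 px raw
    traces); endpoints are preserved exactly.  Returns ``(x_rel, values)``
    with ``x_rel`` the uniform relative grid on [0, 1].
    """
    position = np.asarray(position, dtype=float)
    values = np.asarray(values, dtype=float)
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if n_points < position.size:
        raise ValueError("downsampling not allowed: n_points < original length")
    x_rel = np.linspace(0.0, 1.0, n_points)
    new = np.interp(x_rel * position[-1], position, values)
    return x_rel, new


# --- (D) normalization ----------------------------------------------------

def anchor_minmax(ensemble: ProfileEnsemble, anchor_min: bool = True) -> ProfileEnsemble:
    """Anchor the ensemble mean to [0, 1] by one affine map applied to all samples.

    With ``anchor_min=False`` only the maximum is scaled to 1 (mesenchymal
    pSMAD convention: the minimum is left unanchored).
    """
    mean = ensemble.mean
    lo, hi = float(mean.min()), float(mean.max())
    if hi == lo:
        raise ValueError("degenerate scale: ensemble mean is constant")
    if anchor_min:
        samples = (ensemble.samples - lo) / (hi - lo)
    else:
        samples = ensemble.samples / hi
    return replace(ensemble, samples=samples, anchor_min=anchor_min)


@dataclass
class NormalizationInfo:
    alpha: np.ndarray
    beta: np.ndarray
    chi2_initial: float
    chi2_final: float
    n_iterations: int
    converged: bool
    flagged_samples: list[str] = field(default_factory=list)


def chi2_variance(ensemble: ProfileEnsemble) -> float:
    """Σ_i ∫ dx [G⁽ⁱ⁾(x) − ḡ(x)]² — the inter-sample χ² around the mean."""
    resid = ensemble.samples - ensemble.mean
    return float(np.sum(resid**2) * ensemble.dx)


def minimize_variance(
    ensemble: ProfileEnsemble,
    max_iters: int = 50,
    tol: float = 1e-12,
) -> tuple[ProfileEnsemble, NormalizationInfo]:
    """Model-based normalization: per-sample affine fits divided out.

    Each outer iteration fits (α_i, β_i) to G⁽ⁱ⁾ ≈ α_i + β_i ḡ by closed-form
    least squares, replaces G⁽ⁱ⁾ by (G⁽ⁱ⁾ − α_i)/β_i, recomputes the mean and
    re-anchors it to the gauge of the input (min→0/max→1, or max→1 only),
    until the χ² change falls below ``tol``.
    """
    if ensemble.n_samples < 2:
        raise ValueError("need at least 2 samples on a common grid")
    current = ensemble
    chi2_init = chi2_variance(current)
    chi2_prev = chi2_init
    alpha_tot = np.zeros(current.n_samples)
    beta_tot = np.ones(current.n_samples)
    flagged: set[str] = set()
    converged = False
    it = 0
    for it in range(1, max_iters + 1):
        mean = current.mean
        mc = mean - mean.mean()
        var = float(mc @ mc)
        if var == 0.0:
            raise ValueError("degenerate mean: constant profile")
        beta = (current.samples - current.samples.mean(axis=1, keepdims=True)) @ mc / var
        alpha = current.samples.mean(axis=1) - beta * mean.mean()
        bad = beta <= 0
        if np.any(bad):
            for sid in np.array(current.sample_ids)[bad]:
                flagged.add(str(sid))
            beta = np.where(bad, 1.0, beta)  # leave flagged samples unscaled
            alpha = np.where(bad, 0.0, alpha)
        samples = (current.samples - alpha[:, None]) / beta[:, None]
        new_mean = samples.mean(axis=0)
        lo, hi = float(new_mean.min()), float(new_mean.max())
        if not ensemble.anchor_min:
            lo = 0.0
        scale = hi - lo
        if scale == 0.0:
            raise ValueError("degenerate scale during gauge fixing")
        samples = (samples - lo) / scale
        current = replace(current, samples=samples)
        # cumulative transform G -> (G - alpha_tot)/beta_tot, gauge included
        alpha_tot = alpha_tot + beta_tot * (alpha + beta * lo)
        beta_tot = beta_tot * beta * scale
        chi2 = chi2_variance(current)
        if abs(chi2_prev - chi2) < tol:
            converged = True
            chi2_prev = chi2
            break
        chi2_prev = chi2
    if not converged:
        warnings.warn(
            f"variance minimization did not converge in {max_iters} iterations; "
            "returning best iterate",
            RuntimeWarning,
        )
    info = NormalizationInfo(
        alpha=alpha_tot,
        beta=beta_tot,
        chi2_initial=chi2_init,
        chi2_final=chi2_prev,
        n_iterations=it,
        converged=converged,
        flagged_samples=sorted(flagged),
    )
    return current, info


# --- (E) cropping ---------------------------------------------------------

def crop_edges(ensemble: ProfileEnsemble, fraction: float = 0.10) -> ProfileEnsemble:
    """Drop the medial and lateral ``fraction`` of the domain.

    The retained grid keeps its original x/L labels (it is not re-stretched
    to [0, 1]), matching the plotting convention.
    """
    if not 0.0 <= fraction < 0.5:
        raise ValueError("crop fraction must be in [0, 0.5)")
    if fraction == 0.0:
        return ensemble
    span = ensemble.x[-1] - ensemble.x[0]
    lo = ensemble.x[0] + fraction * span
    hi = ensemble.x[-1] - fraction * span
    keep = (ensemble.x >= lo - 1e-12) & (ensemble.x <= hi + 1e-12)
    return replace(ensemble, x=ensemble.x[keep], samples=ensemble.samples[:, keep])


# --- ensemble statistics --------------------------------------------------

def ensemble_stats(ensembles: dict[str, ProfileEnsemble]) -> MultiChannelStats:
    """Stack per-channel ensembles into cross-channel statistics Ĉ(x).

    All ensembles must share the grid and sample count (samples are matched
    by order, i.e. by cochlea).
    """
    channels = list(ensembles)
    first = ensembles[channels[0]]
    if first.n_samples < 2:
        raise ValueError("need >=2 samples per channel")
    for name, ens in ensembles.items():
        if ens.x.shape != first.x.shape or not np.allclose(ens.x, first.x):
            raise ValueError(f"channel {name!r} grid mismatch")
        if ens.n_samples != first.n_samples:
            raise ValueError(f"channel {name!r} sample-count mismatch")
    data = np.stack([ensembles[c].samples for c in channels], axis=1)
    return MultiChannelStats(x=first.x.copy(), channels=channels, data=data, stage=first.stage)


# --- the full ladder ------------------------------------------------------

def preprocess_scans(
    scans: list[LineScan],
    signal_channel: str,
    reference_channel: str | None = "nuclear",
    smoothing_window_um: float = 20.0,
    resample_n: int = 1000,
    crop_fraction: float = 0.10,
    anchor_min: bool = True,
    max_norm_iters: int = 50,
    tol: float = 1e-12,
) -> tuple[ProfileEnsemble, NormalizationInfo]:
    """Apply the full A–E ladder to a set of raw line scans for one channel."""
    rows = []
    for scan in scans:
        if reference_channel and reference_channel in scan.channels:
            values, _ = regress_nuclear_noise(scan, signal_channel, reference_channel)
        else:
            values = scan.channel(signal_channel)
        values = moving_average(values, smoothing_window_um, scan.pixel_size)
        _, values = resample_uniform(scan.position, values, resample_n)
        rows.append(values)
    x = np.linspace(0.0, 1.0, resample_n)
    ensemble = ProfileEnsemble(
        x=x,
        samples=np.vstack(rows),
        channel=signal_channel,
        stage=scans[0].stage,
        sample_ids=[s.sample_id for s in scans],
    )
    ensemble = anchor_minmax(ensemble, anchor_min=anchor_min)
    ensemble, info = minimize_variance(ensemble, max_iters=max_norm_iters, tol=tol)
    ensemble = crop_edges(ensemble, crop_fraction)
    return ensemble, info
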