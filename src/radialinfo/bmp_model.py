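"""1D BMP–FST–sink reaction–diffusion model of radial pSMAD1/5/9 patterning.

Three species on an extended domain Ω = [0, 600] µm (the ~300 µm prosensory
domain occupies the window ω = (150, 450) µm; the flanks stand in for ligand
escape into surrounding tissue):

    ∂B/∂t  = D ∂²B/∂x² + η_B φ_B − δ_B B − k_on B·F + k_off BF − k_sink S(x,b) B
    ∂F/∂t  =             η_F φ_F − δ_F F − k_on B·F + k_off BF
    ∂BF/∂t =                     − δ_BF BF + k_on B·F − k_off BF

with no-flux boundaries at both ends.  B is the free BMP ligand (nM), taken
proportional to the pSMAD1/5/9 readout; F is free Follistatin and BF the
bound complex.  φ_B, φ_F are normalized mRNA synthesis profiles, S(x,b) a
hypothetical medial sink present in excess that binds BMP irreversibly.

Spatial discretization is second-order central differences (method of
lines); time integration uses a stiff implicit solver.  The solver also
supports a medial Dirichlet-zero boundary and a lateral constant-influx
boundary, which realize the classical source–sink configuration whose
steady state is an exact straight line — used as an analytic oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

DAY_S = 86400.0


@dataclass
class SpatialDomain:
    """Ω = [0, length_um] with the PSD inside ``psd_window``."""

    length_um: float = 600.0
    psd_window: tuple[float, float] = (150.0, 450.0)
    n_grid: int = 121

    def __post_init__(self) -> None:
        lo, hi = self.psd_window
        if not (0.0 < lo < hi < self.length_um):
            raise ValueError("PSD window must lie strictly inside the domain")
        if self.n_grid < 3:
            raise ValueError("need at least 3 grid points")

    @property
    def dx(self) -> float:
        return self.length_um / (self.n_grid - 1)

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, self.length_um, self.n_grid)

    @property
    def psd_length(self) -> float:
        return self.psd_window[1] - self.psd_window[0]

    def psd_relative(self) -> np.ndarray:
        """x/L coordinate of every grid point relative to the PSD window."""
        return (self.x - self.psd_window[0]) / self.psd_length

    def psd_mask(self) -> np.ndarray:
        lo, hi = self.psd_window
        return (self.x >= lo - 1e-9) & (self.x <= hi + 1e-9)


@dataclass
class SinkSpec:
    """Medial sink occupancy S(x, b) on the PSD-relative axis.

    ``form``: "step" (S=1 up to b), "linear_decreasing" (max at the medial
    PSD edge, 0 at b) or "none"; ``b`` is the lateral extent in PSD x/L
    units (0 ⇔ no sink; explored up to 0.5).
    """

    form: str = "step"
    b: float = 0.1

    def __post_init__(self) -> None:
        if self.form not in ("step", "linear_decreasing", "none"):
            raise ValueError(f"unknown sink form {self.form!r}")
        if not 0.0 <= self.b <= 0.5:
            raise ValueError("sink extent b must be in [0, 0.5] (PSD x/L units)")


def make_sink(spec: SinkSpec, domain: SpatialDomain) -> np.ndarray:
    """Grid realization of S(x, b) ∈ [0, 1], confined to the PSD window."""
    if spec.form == "none" or spec.b == 0.0:
        return np.zeros(domain.n_grid)
    rel = domain.psd_relative()
    inside = (rel >= 0.0) & (rel <= spec.b)
    s = np.zeros(domain.n_grid)
    if spec.form == "step":
        s[inside] = 1.0
    else:  # linear_decreasing
        s[inside] = 1.0 - rel[inside] / spec.b
    return s


#: Table of kinetic-parameter search bounds (log-uniform, spanning decades).
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "D": (1e-2, 1e2),          # µm²/s, BMP ligand diffusion constant
    "eta_B": (1e-2, 1e1),      # nM/s, BMP production rate
    "eta_F": (1e-2, 1e1),      # nM/s, FST production rate
    "k_on_BF": (1e-4, 1e0),    # 1/(nM·s), BMP–FST binding
    "k_off_BF": (1e-4, 1e0),   # 1/s, BMP–FST unbinding
    "k_on_sink": (1e-4, 1e0),  # 1/(nM·s), BMP–sink binding
    "delta_B": (1e-5, 1e-1),   # 1/s, BMP decay
    "delta_F": (1e-5, 1e-1),   # 1/s, FST decay
    "delta_BF": (1e-5, 1e-1),  # 1/s, complex decay
}

FIXED_DIFFUSION = 4.0  # µm²/s, a commonly measured ligand diffusivity

#: Published optimal fits per model variant (inputs for derived quantities
#: such as the BMP–FST dissociation constant K_D = k_off/k_on; RMSE in
#: normalized units).
REFERENCE_FITS: dict[str, dict[str, float]] = {
    "fst_nosink_free_d": dict(D=7.4e1, eta_B=4.8e-1, eta_F=2.8e0, k_on_BF=1.0e0,
                              k_off_BF=1.0e0, delta_B=4.4e-2, delta_F=8.0e-2,
                              delta_BF=1.9e-2, rmse=0.048),
    "fst_nosink_fixed_d": dict(D=4.0, eta_B=3.6e-2, eta_F=3.2e0, k_on_BF=1.0e0,
                               k_off_BF=3.1e-1, delta_B=5.3e-4, delta_F=5.2e-2,
                               delta_BF=1.0e-5, rmse=0.085),
    "fst_sink_free_d": dict(D=4.4e1, eta_B=1.3e-1, eta_F=2.0e0, k_on_BF=4.3e-2,
                            k_off_BF=3.2e-1, k_on_sink=1.0e0, delta_B=1.2e-2,
                            delta_F=1.0e-1, delta_BF=5.5e-2, rmse=0.026),
    "fst_sink_fixed_d": dict(D=4.0, eta_B=1.0e-2, eta_F=1.0e-2, k_on_BF=1.0e0,
                             k_off_BF=4.3e-1, k_on_sink=9.3e-3, delta_B=1.0e-5,
                             delta_F=4.1e-2, delta_BF=2.5e-3, rmse=0.094),
    "nofst_nosink_free_d": dict(D=6.4e1, eta_B=1.7e-1, delta_B=5.8e-3, rmse=0.119),
    "nofst_nosink_fixed_d": dict(D=4.0, eta_B=1.0e-2, delta_B=3.6e-4, rmse=0.119),
    "nofst_sink_free_d": dict(D=9.5e1, eta_B=2.2e-1, k_on_sink=1.6e-1,
                              delta_B=1.6e-3, rmse=0.091),
    "nofst_sink_fixed_d": dict(D=4.0, eta_B=1.0e-2, k_on_sink=3.5e-3,
                               delta_B=2.1e-4, rmse=0.096),
}


@dataclass
class BmpModelParams:
    """Kinetic parameters (units as in :data:`PARAM_BOUNDS`)."""

    D: float = 4.0
    eta_B: float = 0.1
    eta_F: float = 0.0
    k_on_BF: float = 0.0
    k_off_BF: float = 0.0
    k_on_sink: float = 0.0
    delta_B: float = 1e-4
    delta_F: float = 0.0
    delta_BF: float = 0.0
    include_fst: bool = False
    fix_diffusion: bool = False

    def __post_init__(self) -> None:
        if self.fix_diffusion:
            self.D = FIXED_DIFFUSION
        for name in PARAM_BOUNDS:
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be >= 0")

    def as_dict(self) -> dict:
        return asdict(self)


def dissociation_constant(params) -> float:
    """BMP–FST dissociation constant K_D = k_off/k_on in nM."""
    if isinstance(params, BmpModelParams):
        k_on, k_off = params.k_on_BF, params.k_off_BF
    else:
        k_on, k_off = params["k_on_BF"], params["k_off_BF"]
    if k_on <= 0:
        raise ZeroDivisionError("k_on must be positive to define K_D")
    return k_off / k_on


@dataclass
class MrnaProfile:
    """Normalized synthesis profiles and the initial pSMAD condition on Ω."""

    x: np.ndarray
    phi_B: np.ndarray
    phi_F: np.ndarray
    f_psmad: np.ndarray

    def __post_init__(self) -> None:
        for name in ("phi_B", "phi_F", "f_psmad"):
            v = getattr(self, name)
            if v.shape != self.x.shape:
                raise ValueError(f"{name} must live on the domain grid")
            if np.any(v < -1e-12) or np.any(v > 1.0 + 1e-9):
                raise ValueError(f"{name} must be within [0, 1]")

    @classmethod
    def zeros(cls, domain: SpatialDomain) -> "MrnaProfile":
        z = np.zeros(domain.n_grid)
        return cls(domain.x, z.copy(), z.copy(), z.copy())


@dataclass
class BmpState:
    """Concentration fields (nM) at one time."""

    t: float
    x: np.ndarray
    B: np.ndarray
    F: np.ndarray
    BF: np.ndarray


@dataclass
class SimResult:
    params: BmpModelParams
    domain: SpatialDomain
    state0: BmpState
    state: BmpState
    times: np.ndarray | None = None
    trajectory: dict[str, np.ndarray] | None = None  # species -> (nt, n_grid)
    balance: dict[str, float] | None = None


def _trapezoid_weights(n: int, dx: float) -> np.ndarray:
    w = np.full(n, dx)
    w[0] = w[-1] = dx / 2
    return w


def simulate(
    params: BmpModelParams,
    domain: SpatialDomain | None = None,
    mrna: MrnaProfile | None = None,
    sink: SinkSpec | None = None,
    t_end: float = DAY_S,
    b0: np.ndarray | None = None,
    bc_left: str = "neumann",
    flux_right: float | None = None,
    save_times: Sequence[float] | None = None,
    track_balance: bool = False,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    neg_tol: float = 1e-6,
) -> SimResult:
    """Integrate the model to ``t_end`` seconds (default 24 h).

    ICs: B(x,0) = f_pSMAD(x) (override with ``b0``); F(x,0) = BF(x,0) =
    φ_F(x) when ``params.include_fst`` else 0.  Boundaries default to
    no-flux at both ends; ``bc_left="dirichlet0"`` pins B(0)=0 and
    ``flux_right`` injects a constant influx (nM·µm/s) at x=L — together
    the Crick source–sink configuration.  ``track_balance`` co-integrates
    the reaction-term integrals so :func:`mass_balance` can verify the
    solver against species conservation.
    """
    domain = domain or SpatialDomain()
    mrna = mrna or MrnaProfile.zeros(domain)
    s_grid = make_sink(sink, domain) if sink is not None else np.zeros(domain.n_grid)
    n = domain.n_grid
    dx = domain.dx
    inv_dx2 = 1.0 / dx**2
    w = _trapezoid_weights(n, dx)
    if bc_left not in ("neumann", "dirichlet0"):
        raise ValueError(f"unknown bc_left {bc_left!r}")

    B0 = np.array(b0 if b0 is not None else mrna.f_psmad, dtype=float)
    if params.include_fst:
        F0 = mrna.phi_F.astype(float).copy()
        BF0 = mrna.phi_F.astype(float).copy()
    else:
        F0 = np.zeros(n)
        BF0 = np.zeros(n)
    if bc_left == "dirichlet0":
        B0[0] = 0.0

    p = params

    def reaction_B(B, F, BF):
        return (p.eta_B * mrna.phi_B - p.delta_B * B - p.k_on_BF * B * F
                + p.k_off_BF * BF - p.k_on_sink * s_grid * B)

    def rhs(t, y):
        B = y[0:3 * n:3]
        F = y[1:3 * n:3]
        BF = y[2:3 * n:3]
        lap = np.empty(n)
        lap[1:-1] = B[2:] - 2.0 * B[1:-1] + B[:-2]
        lap[0] = 2.0 * (B[1] - B[0])
        lap[-1] = 2.0 * (B[-2] - B[-1])
        dB = p.D * lap * inv_dx2 + reaction_B(B, F, BF)
        if flux_right is not None:
            dB[-1] += 2.0 * flux_right / dx
        if bc_left == "dirichlet0":
            dB[0] = 0.0
        dF = p.eta_F * mrna.phi_F - p.delta_F * F - p.k_on_BF * B * F + p.k_off_BF * BF
        dBF = -p.delta_BF * BF + p.k_on_BF * B * F - p.k_off_BF * BF
        out = np.empty_like(y)
        out[0:3 * n:3] = dB
        out[1:3 * n:3] = dF
        out[2:3 * n:3] = dBF
        if track_balance:
            out[3 * n] = float(w @ reaction_B(B, F, BF))
            out[3 * n + 1] = float(w @ dF)
            out[3 * n + 2] = float(w @ dBF)
        return out

    y0 = np.empty(3 * n + (3 if track_balance else 0))
    y0[0:3 * n:3] = B0
    y0[1:3 * n:3] = F0
    y0[2:3 * n:3] = BF0
    if track_balance:
        y0[3 * n:] = 0.0

    t_eval = None if save_times is None else np.asarray(save_times, dtype=float)
    if track_balance:
        idx = np.arange(3 * n)
        sp = np.zeros((y0.size, y0.size), dtype=np.int8)
        sp[:3 * n, :3 * n] = (np.abs(idx[:, None] - idx[None, :]) <= 3)
        sp[3 * n:, :3 * n] = 1
        sol = solve_ivp(rhs, (0.0, t_end), y0, method="BDF", t_eval=t_eval,
                        rtol=rtol, atol=atol, jac_sparsity=sp)
    else:
        sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", t_eval=t_eval,
                        rtol=rtol, atol=atol, lband=3, uband=3)
    if not sol.success:
        raise RuntimeError(f"solver failure: {sol.message}")
    yT = sol.y[:, -1]
    fields = {}
    for k, name in enumerate(("B", "F", "BF")):
        v = yT[k:3 * n:3]
        if not np.all(np.isfinite(v)):
            raise RuntimeError(f"non-finite {name} concentrations at t={t_end}")
        if v.min() < -neg_tol:
            raise RuntimeError(
                f"negative {name} concentration {v.min():.3e} nM exceeds tolerance "
                f"{neg_tol:.1e}: likely instability"
            )
        fields[name] = np.clip(v, 0.0, None)

    state0 = BmpState(0.0, domain.x, B0, F0, BF0)
    state = BmpState(float(sol.t[-1]), domain.x, fields["B"], fields["F"], fields["BF"])
    trajectory = None
    times = None
    if save_times is not None:
        times = sol.t
        trajectory = {name: sol.y[k:3 * n:3, :].T for k, name in
                      enumerate(("B", "F", "BF"))}
    balance = None
    if track_balance:
        balance = {}
        for k, name in enumerate(("B", "F", "BF")):
            m0 = float(w @ y0[k:3 * n:3])
            mT = float(w @ yT[k:3 * n:3])
            influx = float(yT[3 * n + k])
            if name == "B" and flux_right is not None:
                influx += flux_right * t_end
            scale = max(abs(m0), abs(mT), abs(influx), 1e-30)
            balance[name] = abs((mT - m0) - influx) / scale
    return SimResult(params, domain, state0, state, times, trajectory, balance)


def mass_balance(result: SimResult) -> dict[str, float]:
    """Relative per-species mass-balance residuals of a tracked simulation.

    The change in ∫c dx is compared against the co-integrated reaction/source
    integrals (valid with no-flux boundaries; a lateral influx is accounted
    for).  Requires ``simulate(..., track_balance=True)``.
    """
    if result.balance is None:
        raise ValueError("simulation was run without track_balance=True")
    return result.balance


def normalized_output(result: SimResult, domain: SpatialDomain | None = None) -> tuple[np.ndarray, np.ndarray]:
    """PSD-window readout: (x/L grid, B(x, T) scaled to max 1 over the window)."""
    domain = domain or result.domain
    mask = domain.psd_mask()
    b = result.state.B[mask]
    peak = b.max()
    if peak <= 0:
        raise ValueError("simulation output is non-positive over the PSD window")
    return domain.psd_relative()[mask], b / peak
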