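"""Particle-swarm parameter estimation for the BMP reaction–diffusion model.

The cost is the RMSE between the simulated free-BMP profile at 24 h
(max-normalized over the PSD window, since absolute fold-changes between
stages are not measurable) and a target pSMAD1/5/9 profile, evaluated on the
window from the medial extreme of the target to its peak.  Solutions whose
un-normalized amplitude changes by more than 10× (or less than 0.5×)
relative to the initial condition receive an additive penalty that dominates
any achievable shape error.

Parameters are sampled and moved in log10 space within the search bounds
(they span four or more decades); the swarm uses the standard constriction
coefficients (inertia 0.729, cognitive = social = 1.494).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bmp_model import (
    FIXED_DIFFUSION,
    PARAM_BOUNDS,
    BmpModelParams,
    MrnaProfile,
    SimResult,
    SinkSpec,
    SpatialDomain,
    dissociation_constant,
    normalized_output,
    simulate,
)

PENALTY = 10.0  # >> max possible RMSE (1) on max-normalized profiles
FOLD_CHANGE_RANGE = (0.5, 10.0)


@dataclass(frozen=True)
class FitVariant:
    """Model structure switches: FST binding, medial sink, fixed diffusion."""

    include_fst: bool = True
    include_sink: bool = True
    fix_diffusion: bool = False

    @property
    def free_parameters(self) -> list[str]:
        names = [] if self.fix_diffusion else ["D"]
        names += ["eta_B", "delta_B"]
        if self.include_fst:
            names += ["eta_F", "k_on_BF", "k_off_BF", "delta_F", "delta_BF"]
        if self.include_sink:
            names += ["k_on_sink"]
        return names

    def build_params(self, values: dict[str, float]) -> BmpModelParams:
        kwargs = dict(values)
        if self.fix_diffusion:
            kwargs["D"] = FIXED_DIFFUSION
        return BmpModelParams(include_fst=self.include_fst,
                              fix_diffusion=self.fix_diffusion, **kwargs)

    @property
    def name(self) -> str:
        return (("fst" if self.include_fst else "nofst") + "_"
                + ("sink" if self.include_sink else "nosink") + "_"
                + ("fixed_d" if self.fix_diffusion else "free_d"))


def window_rmse(
    sim_x: np.ndarray, sim_g: np.ndarray,
    target_x: np.ndarray, target_g: np.ndarray,
    fit_window: tuple[float, float] | None = None,
) -> float:
    """RMSE between max-normalized profiles over a medial-extreme→peak window.

    Both inputs are rescaled to max 1; the simulation is interpolated onto
    the target grid; window endpoints snap to the nearest target grid nodes.
    """
    sim_g = np.asarray(sim_g, dtype=float) / np.max(sim_g)
    target_g = np.asarray(target_g, dtype=float) / np.max(target_g)
    if fit_window is None:
        peak = int(np.argmax(target_g))
        fit_window = (float(target_x[0]), float(target_x[peak]))
    lo, hi = fit_window
    keep = (target_x >= lo - 1e-12) & (target_x <= hi + 1e-12)
    if keep.sum() < 2:
        raise ValueError("fit window contains fewer than 2 target points")
    sim_on_target = np.interp(target_x[keep], sim_x, sim_g)
    return float(np.sqrt(np.mean((sim_on_target - target_g[keep]) ** 2)))


def rmse_cost(
    result: SimResult,
    target_x: np.ndarray,
    target_g: np.ndarray,
    fit_window: tuple[float, float] | None = None,
    penalty: float = PENALTY,
) -> tuple[float, bool]:
    """Penalized shape cost of a simulation against a target profile.

    Returns ``(cost, penalized)``: the fold-change of the un-normalized
    maximum amplitude relative to the initial condition is checked first
    (outside [0.5, 10] adds ``penalty``), then B(x, T) is max-normalized
    over the PSD window and compared by :func:`window_rmse`.
    """
    if not np.all(np.isfinite(result.state.B)):
        return float("inf"), True
    b0_max = float(result.state0.B.max())
    bT_max = float(result.state.B.max())
    if b0_max <= 0 or bT_max <= 0:
        return float("inf"), True
    fold = bT_max / b0_max
    penalized = not (FOLD_CHANGE_RANGE[0] <= fold <= FOLD_CHANGE_RANGE[1])
    sim_x, sim_g = normalized_output(result)
    cost = window_rmse(sim_x, sim_g, np.asarray(target_x, float),
                       np.asarray(target_g, float), fit_window)
    if penalized:
        cost += penalty
    return cost, penalized


@dataclass
class FitResult:
    best_params: BmpModelParams
    rmse: float
    penalized: bool
    generations_run: int
    seed: int | None
    history: list[float] = field(default_factory=list)
    variant: FitVariant | None = None

    @property
    def kd_nM(self) -> float | None:
        """Derived BMP–FST dissociation constant (with-FST variants only)."""
        if self.variant is not None and not self.variant.include_fst:
            return None
        if self.best_params.k_on_BF <= 0:
            return None
        return dissociation_constant(self.best_params)


def pso_fit(
    target_x: np.ndarray,
    target_g: np.ndarray,
    mrna: MrnaProfile,
    domain: SpatialDomain | None = None,
    variant: FitVariant = FitVariant(),
    sink: SinkSpec | None = None,
    n_particles: int = 200,
    max_iters: int = 100,
    restarts: int = 30,
    patience: int = 10,
    min_improvement: float = 1e-6,
    seed: int | None = None,
    t_end: float = 86400.0,
    fit_window: tuple[float, float] | None = None,
) -> FitResult:
    """Global-best PSO over the model's kinetic parameters.

    Each restart runs an independently seeded swarm until the global best
    stops improving by more than ``min_improvement`` for ``patience``
    iterations (or ``max_iters``); the global best is carried across
    restarts, so the returned history is monotone non-increasing.
    """
    domain = domain or SpatialDomain()
    if sink is None:
        sink = SinkSpec(form="step", b=0.1) if variant.include_sink else SinkSpec(form="none", b=0.0)
    if variant.include_sink and sink.b == 0.0:
        raise ValueError("with-sink variant requires a sink extent b > 0")
    names = variant.free_parameters
    zlb = np.array([np.log10(PARAM_BOUNDS[k][0]) for k in names])
    zub = np.array([np.log10(PARAM_BOUNDS[k][1]) for k in names])
    if np.any(zlb >= zub):
        raise ValueError("infeasible bounds")
    rng = np.random.default_rng(seed)

    def decode(z: np.ndarray) -> dict[str, float]:
        vals = 10.0 ** z
        vals = np.where(z <= zlb, [PARAM_BOUNDS[k][0] for k in names], vals)
        vals = np.where(z >= zub, [PARAM_BOUNDS[k][1] for k in names], vals)
        return dict(zip(names, vals))

    def cost_of(z: np.ndarray) -> tuple[float, bool]:
        params = variant.build_params(decode(z))
        try:
            result = simulate(params, domain, mrna, sink, t_end=t_end)
        except (RuntimeError, np.linalg.LinAlgError):
            return float("inf"), True
        return rmse_cost(result, target_x, target_g, fit_window)

    w_in, c1, c2 = 0.729, 1.494, 1.494
    vmax = 0.2 * (zub - zlb)
    gbest_z, gbest_cost, gbest_pen = None, float("inf"), True
    history: list[float] = []
    total_iters = 0
    for _ in range(restarts):
        z = rng.uniform(zlb, zub, size=(n_particles, len(names)))
        v = rng.uniform(-vmax, vmax, size=z.shape) * 0.1
        costs = np.empty(n_particles)
        pens = np.empty(n_particles, dtype=bool)
        for i in range(n_particles):
            costs[i], pens[i] = cost_of(z[i])
        pbest_z, pbest_cost = z.copy(), costs.copy()
        ibest = int(np.argmin(costs))
        if costs[ibest] < gbest_cost:
            gbest_z, gbest_cost, gbest_pen = z[ibest].copy(), float(costs[ibest]), bool(pens[ibest])
        if np.all(np.isinf(costs)):
            import warnings

            warnings.warn("entire swarm penalized/invalid after warm-up", RuntimeWarning)
        history.append(gbest_cost)
        stall = 0
        last = gbest_cost
        for _ in range(max_iters):
            total_iters += 1
            r1 = rng.random(z.shape)
            r2 = rng.random(z.shape)
            v = w_in * v + c1 * r1 * (pbest_z - z) + c2 * r2 * (gbest_z - z)
            v = np.clip(v, -vmax, vmax)
            z = z + v
            below, above = z < zlb, z > zub
            z = np.clip(z, zlb, zub)
            v[below | above] *= -0.5  # reflect at bounds
            for i in range(n_particles):
                c, pen = cost_of(z[i])
                if c < pbest_cost[i]:
                    pbest_cost[i], pbest_z[i] = c, z[i].copy()
                if c < gbest_cost:
                    gbest_cost, gbest_z, gbest_pen = float(c), z[i].copy(), bool(pen)
            history.append(gbest_cost)
            if last - gbest_cost > min_improvement:
                stall = 0
            else:
                stall += 1
                if stall >= patience:
                    break
            last = gbest_cost
    best_params = variant.build_params(decode(gbest_z))
    rmse = gbest_cost - (PENALTY if gbest_pen and np.isfinite(gbest_cost) else 0.0)
    return FitResult(best_params, float(rmse), gbest_pen, total_iters, seed,
                     history, variant)
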