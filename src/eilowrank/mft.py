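"""Latent mean-field dynamics of the rank-one approximation.

The steady state of the latent variable obeys

    kappa = F_mean(kappa) + F_cov(kappa),

where ``F_mean`` collects the drive from the population means of the
connectivity vectors (the E-I mean connectivity) and ``F_cov`` the drive from
the m-n covariance generated by reciprocal motifs.  Gaussian averages over
the within-population heterogeneity are evaluated with fixed-order
Gauss-Hermite quadrature.  An alternative, non-perturbative description for
independent connectivity (superposition mean-field theory) solves
self-consistent equations for the per-population mean and variance of inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .connectivity import GaussianLocalStats, SparseLocalStats
from .dynamics import TransferFunction
from .lowrank import RankOneStats
from .populations import POPS, PopulationStructure

__all__ = [
    "LatentSolution",
    "DMFTSolution",
    "gauss_mean",
    "kappa_rhs",
    "fixed_points",
    "bifurcation_sweep",
    "dmft_solve",
]


@lru_cache(maxsize=8)
def _hermgauss(order: int):
    x, w = np.polynomial.hermite.hermgauss(order)
    return x * np.sqrt(2.0), w / np.sqrt(np.pi)


def gauss_mean(f, mu: float, Delta: float, order: int = 301) -> float:
    """Gaussian average ``<f(mu, Delta)> = E[f(mu + sqrt(Delta) z)]``, z ~ N(0,1).

    Evaluated by fixed-order Gauss-Hermite quadrature (deterministic; agrees
    with adaptive integration to ~1e-8 relative for the smooth transfer
    functions used here).  ``Delta`` is a variance and must be non-negative;
    ``Delta = 0`` returns ``f(mu)`` exactly.
    """
    if Delta < 0:
        raise ValueError("variance Delta must be non-negative")
    if Delta == 0:
        return float(f(mu))
    z, w = _hermgauss(order)
    return float(w @ f(mu + np.sqrt(Delta) * z))


@dataclass
class FixedPoint:
    kappa: float
    stable: bool
    F_mean: float
    F_cov: float
    slope: float


@dataclass
class LatentSolution:
    """Fixed points of the latent variable with stability and predictions."""

    fixed_points: list[FixedPoint]
    stats: RankOneStats

    @property
    def kappas(self) -> np.ndarray:
        return np.array([fp.kappa for fp in self.fixed_points])

    @property
    def stable_kappas(self) -> np.ndarray:
        return np.array([fp.kappa for fp in self.fixed_points if fp.stable])

    @property
    def n_stable(self) -> int:
        return sum(fp.stable for fp in self.fixed_points)

    def activity_prediction(self, kappa: float) -> dict[str, dict[str, float]]:
        """Per-population mean and variance of activations at a fixed point:
        ``mu_x_p = kappa mbar_p``, ``Delta_x_p = kappa^2 sigma2_m_p``."""
        return {
            p: {
                "mu_x": kappa * self.stats.mbar[p],
                "Delta_x": kappa**2 * self.stats.sigma2_m[p],
            }
            for p in POPS
        }


@dataclass
class DMFTSolution:
    """Self-consistent superposition mean-field solution."""

    mu_x: dict[str, float]
    Delta_x: dict[str, float]
    kappa_bar: float
    converged: bool
    n_iter: int
    residual: float
    residual_history: np.ndarray = field(default_factory=lambda: np.empty(0))


def kappa_rhs(
    kappa: float,
    stats: RankOneStats,
    phi: TransferFunction,
    order: int = 301,
) -> tuple[float, float, float]:
    """Recurrent drive on kappa, decomposed into mean and covariance parts.

    ``F_mean = sum_p alpha_p nbar_p <phi(kappa mbar_p, kappa^2 sigma2_m_p)>``
    and ``F_cov = sum_p alpha_p <phi'(...)> sigma_nm_p kappa``; the total is
    the exact sum of the two.  Zero covariances give ``F_cov = 0``.
    """
    F_mean = 0.0
    F_cov = 0.0
    for p in POPS:
        mu = kappa * stats.mbar[p]
        Delta = kappa**2 * stats.sigma2_m[p]
        a = stats.alpha[p]
        F_mean += a * stats.nbar[p] * gauss_mean(phi, mu, Delta, order)
        if stats.sigma_nm[p] != 0.0:
            F_cov += a * gauss_mean(phi.deriv, mu, Delta, order) * stats.sigma_nm[p] * kappa
    return F_mean + F_cov, F_mean, F_cov


def _default_range(stats: RankOneStats) -> tuple[float, float]:
    # phi in (0, 2) bounds |kappa_rec| by 2 sum_p alpha_p |nbar_p| (= 2(J_E+J_I))
    bound = 2.0 * sum(stats.alpha[p] * abs(stats.nbar[p]) for p in POPS) + 1.0
    return -bound, bound


def fixed_points(
    stats: RankOneStats,
    phi: TransferFunction,
    kappa_range: tuple[float, float] | None = None,
    n_grid: int = 2001,
    xtol: float = 1e-10,
    deriv_h: float = 1e-6,
    order: int = 301,
) -> LatentSolution:
    """All fixed points of the latent dynamics on a sign-change grid.

    Roots of ``kappa - RHS(kappa)`` are bracketed on a uniform grid and
    refined by bisection; stability holds iff ``dRHS/dkappa < 1`` at the root
    (central-difference derivative of the quadrature RHS).  Raises when the
    edge values prove a root outside the range (range too small).
    """
    if kappa_range is None:
        kappa_range = _default_range(stats)
    grid = np.linspace(*kappa_range, n_grid)

    def h(k: float) -> float:
        return k - kappa_rhs(k, stats, phi, order)[0]

    hv = np.array([h(k) for k in grid])
    # h -> -inf as kappa -> -inf and +inf as kappa -> +inf (RHS is bounded),
    # so a positive left edge or negative right edge proves an exterior root
    if hv[0] > 0 or hv[-1] < 0:
        raise ValueError("root beyond grid edge: enlarge kappa_range")
    fps: list[FixedPoint] = []
    sign_change = np.where(np.sign(hv[:-1]) * np.sign(hv[1:]) < 0)[0]
    roots = [grid[i] for i in np.where(hv == 0.0)[0]]
    for i in sign_change:
        lo, hi = grid[i], grid[i + 1]
        flo = hv[i]
        while hi - lo > xtol:
            mid = 0.5 * (lo + hi)
            fmid = h(mid)
            if fmid == 0.0:
                lo = hi = mid
                break
            if flo * fmid < 0:
                hi = mid
            else:
                lo, flo = mid, fmid
        roots.append(0.5 * (lo + hi))
    for k in sorted(roots):
        total, Fm, Fc = kappa_rhs(k, stats, phi, order)
        up = kappa_rhs(k + deriv_h, stats, phi, order)[0]
        dn = kappa_rhs(k - deriv_h, stats, phi, order)[0]
        slope = (up - dn) / (2 * deriv_h)
        fps.append(
            FixedPoint(kappa=k, stable=slope < 1.0, F_mean=Fm, F_cov=Fc, slope=slope)
        )
    return LatentSolution(fixed_points=fps, stats=stats)


def bifurcation_sweep(
    stats_factory,
    phi: TransferFunction,
    grid,
    **kwargs,
):
    """Fixed points along a monotone parameter sweep.

    ``stats_factory(value)`` must return the :class:`RankOneStats` at each
    control-parameter value.  Returns the list of per-value
    :class:`LatentSolution` and the first grid value with three roots
    (the onset of bistability), or None if the count never changes.
    """
    solutions = []
    onset = None
    for v in grid:
        sol = fixed_points(stats_factory(v), phi, **kwargs)
        solutions.append(sol)
        if onset is None and len(sol.fixed_points) >= 3:
            onset = v
    return solutions, onset


def dmft_solve(
    stats,
    pop: PopulationStructure,
    phi: TransferFunction,
    init: tuple[float, float, float] | None = None,
    damping: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    order: int = 301,
) -> DMFTSolution:
    """Superposition mean-field solution for independent connectivity.

    Damped fixed-point iteration on ``(mu_x, Delta_x_E, Delta_x_I)``; the mean
    equation is population-independent (``mu_x_p = kappa_bar`` for both), the
    variance carries the full second moment ``<phi^2>`` of the rates.  Run
    from a near-zero and a high-activity init to expose bistable solutions.
    Only valid for independent (motif-free) local statistics.
    """
    if isinstance(stats, GaussianLocalStats):
        JE, JI = stats.J_E, stats.J_I
        g = stats.g
        var_coef = {
            "E": (pop.alpha_E * g[0, 0] ** 2, pop.alpha_I * g[0, 1] ** 2),
            "I": (pop.alpha_E * g[1, 0] ** 2, pop.alpha_I * g[1, 1] ** 2),
        }
    elif isinstance(stats, SparseLocalStats):
        JE = pop.N_E * stats.c * stats.A_E
        JI = -pop.N_I * stats.c * stats.A_I
        v = stats.c * (1 - stats.c)
        coefE = pop.N_E * v * stats.A_E**2
        coefI = pop.N_I * v * stats.A_I**2
        var_coef = {"E": (coefE, coefI), "I": (coefE, coefI)}
    else:
        raise TypeError(f"unsupported stats type {type(stats).__name__}")

    if init is None:
        init = (0.0, 0.0, 0.0)
    mu, DE, DI = map(float, init)
    history = []
    for it in range(1, max_iter + 1):
        phiE = gauss_mean(phi, mu, DE, order)
        phiI = gauss_mean(phi, mu, DI, order)
        phi2E = gauss_mean(lambda x: phi(x) ** 2, mu, DE, order)
        phi2I = gauss_mean(lambda x: phi(x) ** 2, mu, DI, order)
        mu_new = JE * phiE - JI * phiI
        DE_new = var_coef["E"][0] * phi2E + var_coef["E"][1] * phi2I
        DI_new = var_coef["I"][0] * phi2E + var_coef["I"][1] * phi2I
        res = max(abs(mu_new - mu), abs(DE_new - DE), abs(DI_new - DI))
        history.append(res)
        mu = (1 - damping) * mu + damping * mu_new
        DE = (1 - damping) * DE + damping * DE_new
        DI = (1 - damping) * DI + damping * DI_new
        if res < tol:
            break
    return DMFTSolution(
        mu_x={"E": mu, "I": mu},
        Delta_x={"E": DE, "I": DI},
        kappa_bar=mu,
        converged=res < tol,
        n_iter=it,
        residual=res,
        residual_history=np.asarray(history),
    )
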