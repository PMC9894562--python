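"""Direct simulation of the full N-dimensional rate network.

Units follow ``x_i' = -x_i + sum_j J_ij phi(x_j)`` with the positive
saturating transfer function ``phi(x) = 1 + tanh(x - theta)``.  The latent
variable kappa is the projection of the state onto the rank-one connectivity
vector m; per-neuron deviations from the population mean are compared with
the perturbative prediction ``dx_i = kappa dm_i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .populations import POPS, PopulationStructure

__all__ = [
    "TransferFunction",
    "Trajectory",
    "ActivityStats",
    "simulate",
    "project_kappa",
    "per_neuron_deviation",
    "branch_initialization",
]


@dataclass(frozen=True)
class TransferFunction:
    """Positive sigmoidal rate function ``phi(x) = 1 + tanh(x - theta)``.

    Range (0, 2), monotone increasing, with ``phi(theta) = 1``.  The
    derivative ``phi'(x) = sech^2(x - theta)`` is available analytically.
    """

    theta: float = 1.5

    def __call__(self, x):
        return 1.0 + np.tanh(x - self.theta)

    def deriv(self, x):
        # sech^2 via exp(-|y|) to avoid cosh overflow at large |y|
        e = np.exp(-np.abs(np.asarray(x, dtype=float) - self.theta))
        return (2.0 * e / (1.0 + e**2)) ** 2


@dataclass
class Trajectory:
    """Recorded rate-network trajectory with convergence metadata."""

    times: np.ndarray
    states: np.ndarray  # (n_times, N)
    steady_state: np.ndarray
    converged: bool
    diverged: bool = False

    @property
    def final_time(self) -> float:
        return float(self.times[-1])


@dataclass
class ActivityStats:
    """Per-population steady-state activity statistics.

    ``mu_x[p]`` is the mean activation of population p, ``Delta_x[p]`` the
    across-neuron variance, and ``dx`` the per-neuron deviation from its
    population mean.
    """

    mu_x: dict[str, float]
    Delta_x: dict[str, float]
    dx: np.ndarray


def simulate(
    J: np.ndarray,
    phi: TransferFunction,
    x0: np.ndarray,
    T: float = 200.0,
    dt: float = 0.05,
    tol: float = 1e-8,
    record_every: int = 20,
    overflow: float = 1e6,
) -> Trajectory:
    """Integrate the rate network with a fixed-step explicit Euler scheme.

    Stops early once ``max|x'| < tol`` (converged) or the state norm exceeds
    the overflow guard (diverged, partial trajectory returned).  The smooth,
    saturating transfer function makes the dynamics non-stiff, so a fixed
    step of dt = 0.05 (membrane time constant 1) is ample; results are
    insensitive to halving dt.
    """
    if dt <= 0 or T < dt:
        raise ValueError("require dt > 0 and T >= dt")
    x = np.array(x0, dtype=float)
    n_steps = int(round(T / dt))
    times = [0.0]
    states = [x.copy()]
    converged = diverged = False
    for step in range(1, n_steps + 1):
        dx = -x + J @ phi(x)
        x = x + dt * dx
        if step % record_every == 0 or step == n_steps:
            times.append(step * dt)
            states.append(x.copy())
        if np.max(np.abs(x)) > overflow or not np.all(np.isfinite(x)):
            diverged = True
            break
        if np.max(np.abs(dx)) < tol:
            converged = True
            if times[-1] != step * dt:
                times.append(step * dt)
                states.append(x.copy())
            break
    return Trajectory(
        times=np.asarray(times),
        states=np.asarray(states),
        steady_state=x,
        converged=converged,
        diverged=diverged,
    )


def project_kappa(x: np.ndarray, m: np.ndarray) -> float:
    """Latent variable ``kappa = x . m / ||m||^2`` (exact when x = kappa m)."""
    nrm2 = float(np.real(m) @ np.real(m))
    if nrm2 == 0:
        raise ValueError("zero connectivity vector m")
    return float(np.real(x) @ np.real(m) / nrm2)


def per_neuron_deviation(
    x_star: np.ndarray, pop: PopulationStructure
) -> ActivityStats:
    """Population means/variances and per-neuron deviations of a steady state."""
    mu, Delta = {}, {}
    dx = np.empty(pop.N)
    for p in POPS:
        sl = pop.block_slice(p)
        mu[p] = float(x_star[sl].mean())
        Delta[p] = float(x_star[sl].var())
        dx[sl] = x_star[sl] - mu[p]
    return ActivityStats(mu_x=mu, Delta_x=Delta, dx=dx)


def branch_initialization(m: np.ndarray, kappa0: float) -> np.ndarray:
    """Initial condition ``x0 = kappa0 m`` inside the rank-one subspace.

    Integrating from a small and a large kappa0 probes the two branches of a
    bistable network.
    """
    if kappa0 != 0 and np.linalg.norm(m) == 0:
        raise ValueError("zero connectivity vector m")
    return kappa0 * np.real(m)
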