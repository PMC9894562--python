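"""Rank-one (and truncated rank-R) approximation of E-I connectivity.

The mean part ``Jbar = mbar nbar^T / N`` fixes the unperturbed connectivity
vectors; first-order perturbation theory in the fluctuation matrix ``Z``
gives the realization-specific corrections ``dm = Z mbar / lambda0`` and
``dn = Z^T nbar / lambda0``.  In the ensemble, the per-neuron entries
``(m_i, n_i)`` follow a two-component Gaussian mixture whose per-population
means, variances and covariances are predicted analytically from the local
statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse.linalg

from .connectivity import (
    ConnectivityRealization,
    GaussianLocalStats,
    SparseLocalStats,
)
from .populations import POPS, PopulationStructure
from .spectral import OutlierPrediction, predict_outliers

__all__ = [
    "MeanVectors",
    "PerturbedVectors",
    "RankOneStats",
    "mean_vectors",
    "perturbed_vectors",
    "predicted_vector_stats",
    "numerical_dominant_pair",
    "normalize_for_comparison",
    "truncated_rank_approx",
    "lowrank_to_local_stats",
    "empirical_vector_stats",
]


@dataclass
class MeanVectors:
    """Connectivity vectors of the rank-one mean matrix.

    ``mbar`` is the all-ones vector; ``nbar`` takes the value
    ``(N/N_E) J_E`` on the excitatory block and ``-(N/N_I) J_I`` on the
    inhibitory block, so that ``Jbar = mbar nbar^T / N`` exactly and
    ``nbar^T mbar / N = J_E - J_I``.  ``Rbar``/``Lbar`` are the
    bi-orthogonally normalized right/left eigenvectors.
    """

    mbar: np.ndarray
    nbar: np.ndarray
    lambda0: float
    pop: PopulationStructure

    @property
    def Rbar(self) -> np.ndarray:
        return self.mbar / np.sqrt(self.pop.N)

    @property
    def Lbar(self) -> np.ndarray:
        return self.nbar / (self.lambda0 * np.sqrt(self.pop.N))


@dataclass
class PerturbedVectors:
    """Rank-one connectivity vectors of one realization.

    ``m = mbar + dm`` and ``n = nbar + dn`` with the first-order
    perturbations ``dm = Z mbar / lambda0``, ``dn = Z^T nbar / lambda0``.
    """

    m: np.ndarray
    n: np.ndarray
    dm: np.ndarray
    dn: np.ndarray
    lambda_used: float


@dataclass
class RankOneStats:
    """Gaussian-mixture statistics of the rank-one connectivity vectors.

    Per population p: means ``mbar_p, nbar_p``, variances
    ``sigma2_m[p], sigma2_n[p]`` and covariance ``sigma_nm[p]`` of the
    per-neuron entries (m_i, n_i).
    """

    mbar: dict[str, float]
    nbar: dict[str, float]
    sigma2_m: dict[str, float]
    sigma2_n: dict[str, float]
    sigma_nm: dict[str, float]
    alpha: dict[str, float]

    def __post_init__(self) -> None:
        for p in POPS:
            if self.sigma2_m[p] < 0 or self.sigma2_n[p] < 0:
                raise ValueError("variances must be non-negative")
            bound = np.sqrt(self.sigma2_m[p] * self.sigma2_n[p])
            if abs(self.sigma_nm[p]) > bound + 1e-12:
                # The first-order recipe (variances with lambda0^2, covariances
                # with lambda^2) can overshoot the bound when |lambda| < lambda0
                # (strong negative reciprocity); keep the numbers, flag them.
                warnings.warn(
                    f"covariance sigma_nm exceeds Cauchy-Schwarz bound in {p}: "
                    "first-order statistics are not jointly realizable here"
                )

    @property
    def sigma_nm_overall(self) -> float:
        """Overall covariance, the population-fraction-weighted sum."""
        return sum(self.alpha[p] * self.sigma_nm[p] for p in POPS)

    @property
    def implied_eigenvalue(self) -> float:
        """Eigenvalue of the Gaussian-mixture rank-one model,
        ``sum_p alpha_p (mbar_p nbar_p + sigma_nm_p)``."""
        return sum(
            self.alpha[p] * (self.mbar[p] * self.nbar[p] + self.sigma_nm[p])
            for p in POPS
        )

    def to_dict(self) -> dict:
        return {
            p: {
                "mbar": self.mbar[p],
                "nbar": self.nbar[p],
                "sigma2_m": self.sigma2_m[p],
                "sigma2_n": self.sigma2_n[p],
                "sigma_nm": self.sigma_nm[p],
                "alpha": self.alpha[p],
            }
            for p in POPS
        }


def mean_vectors(
    pop: PopulationStructure, J_E: float, J_I: float
) -> MeanVectors:
    """Connectivity vectors of the rank-one mean matrix."""
    if J_E <= 0 or J_I <= 0:
        raise ValueError("mean couplings J_E, J_I must be positive")
    mbar = np.ones(pop.N)
    nbar = np.empty(pop.N)
    nbar[pop.slice_E] = pop.N / pop.N_E * J_E
    nbar[pop.slice_I] = -pop.N / pop.N_I * J_I
    return MeanVectors(mbar=mbar, nbar=nbar, lambda0=J_E - J_I, pop=pop)


def perturbed_vectors(
    realization: ConnectivityRealization, mv: MeanVectors, lambda0: float
) -> PerturbedVectors:
    """First-order perturbation-theory connectivity vectors of a realization."""
    if lambda0 == 0:
        raise ValueError("lambda0 = 0: perturbation theory invalid")
    Z = realization.Z
    dm = Z @ mv.mbar / lambda0
    dn = Z.T @ mv.nbar / lambda0
    return PerturbedVectors(
        m=mv.mbar + dm, n=mv.nbar + dn, dm=dm, dn=dn, lambda_used=lambda0
    )


def predicted_vector_stats(
    stats, pop: PopulationStructure, lambda_for_cov: float | None = None
) -> RankOneStats:
    """Predicted Gaussian-mixture statistics of the rank-one vectors.

    Variances use the unperturbed eigenvalue ``lambda0`` in the denominator;
    covariances use ``lambda_for_cov`` (by default the dominant cubic root),
    which accounts for the motif-induced shift of the outlier.  Independent
    connectivity gives zero covariances.
    """
    pred = predict_outliers(stats, pop)
    lam0 = pred.lambda0
    if lam0 == 0:
        raise ValueError("lambda0 = 0: perturbation theory invalid")
    if lambda_for_cov is None:
        dom = pred.dominant
        lambda_for_cov = abs(dom) if dom is not None else abs(lam0)
    lam2 = float(np.abs(lambda_for_cov)) ** 2
    aE, aI = pop.alpha_E, pop.alpha_I
    NE, NI = pop.N_E, pop.N_I
    N = pop.N

    if isinstance(stats, GaussianLocalStats):
        g, eta = stats.g, stats.eta
        JE, JI = stats.J_E, stats.J_I
        s2m = {
            "E": (aE * g[0, 0] ** 2 + aI * g[0, 1] ** 2) / lam0**2,
            "I": (aE * g[1, 0] ** 2 + aI * g[1, 1] ** 2) / lam0**2,
        }
        s2n = {
            "E": (JE**2 * g[0, 0] ** 2 / aE + JI**2 * g[1, 0] ** 2 / aI) / lam0**2,
            "I": (JE**2 * g[0, 1] ** 2 / aE + JI**2 * g[1, 1] ** 2 / aI) / lam0**2,
        }
        snm = {
            "E": (JE * g[0, 0] ** 2 * eta[0, 0] - JI * g[0, 1] * g[1, 0] * eta[0, 1])
            / lam2,
            "I": (JE * g[0, 1] * g[1, 0] * eta[0, 1] - JI * g[1, 1] ** 2 * eta[1, 1])
            / lam2,
        }
        nb = {"E": N / NE * JE, "I": -N / NI * JI}
    elif isinstance(stats, SparseLocalStats):
        c, AE, AI = stats.c, stats.A_E, stats.A_I
        rho = stats.rho
        v = c * (1 - c)
        common = (NE * AE**2 + NI * AI**2) * v / lam0**2
        s2m = {"E": common, "I": common}
        s2n_base = (AE**2 * NE + AI**2 * NI) * N**2 * c**3 * (1 - c) / lam0**2
        s2n = {"E": s2n_base * AE**2, "I": s2n_base * AI**2}
        snm = {
            "E": N * AE * c**2
            * (AE**2 * NE * (rho[0, 0] - c) + AI**2 * NI * (rho[0, 1] - c))
            / lam2,
            "I": N * AI * c**2
            * (AE**2 * NE * (rho[0, 1] - c) + AI**2 * NI * (rho[1, 1] - c))
            / lam2,
        }
        nb = {"E": N * c * AE, "I": N * c * AI}
    else:
        raise TypeError(f"unsupported stats type {type(stats).__name__}")

    return RankOneStats(
        mbar={"E": 1.0, "I": 1.0},
        nbar=nb,
        sigma2_m=s2m,
        sigma2_n=s2n,
        sigma_nm=snm,
        alpha=pop.fractions,
    )


def _match_left_vector(
    lam: complex, J: np.ndarray, rtol: float = 1e-8
) -> np.ndarray:
    """Left eigenvector of ``J`` for eigenvalue ``lam`` via the transpose."""
    w, V = np.linalg.eig(J.T)
    k = np.argmin(np.abs(w - lam))
    if np.abs(w[k] - lam) > rtol * max(np.abs(lam), 1.0):
        raise ValueError("no matching left eigenvalue within tolerance")
    return V[:, k]


def numerical_dominant_pair(
    J: np.ndarray,
    prediction: OutlierPrediction | None = None,
    method: str = "dense",
) -> tuple[complex, np.ndarray, np.ndarray]:
    """Dominant outlier eigenvalue with bi-orthogonal right/left eigenvectors.

    Returns ``(lambda, Rhat, Lhat)`` with ``Rhat`` unit norm and
    ``Lhat^T Rhat = 1``.  With a prediction, eigenvalues inside the predicted
    bulk are rejected (outlier-absent signal).  ``method='arpack'`` extracts
    only the largest-modulus eigenpair, which is much faster for ensembles
    when the outlier is well separated from the bulk.
    """
    N = J.shape[0]
    if method == "arpack":
        # k=1 with a ones start vector: the outlier eigenvector has a large
        # overlap with the all-ones direction, so convergence is immediate
        v0 = np.ones(N)
        w, V = scipy.sparse.linalg.eigs(J, k=1, which="LM", tol=1e-10, v0=v0)
        wl, U = scipy.sparse.linalg.eigs(J.T, k=1, which="LM", tol=1e-10, v0=v0)
        lam, Rhat = w[0], V[:, 0]
        if np.abs(wl[0] - lam) > 1e-6 * max(abs(lam), 1.0):
            # complex pair split across the two calls: match conjugates
            if np.abs(np.conj(wl[0]) - lam) <= 1e-6 * max(abs(lam), 1.0):
                wl, U = np.conj(wl), np.conj(U)
            else:
                raise ValueError("left/right eigenvalue mismatch in ARPACK path")
        Lhat = U[:, 0]
    else:
        wv, V = np.linalg.eig(J)
        kv = int(np.argmax(np.abs(wv)))
        lam, Rhat = wv[kv], V[:, kv]
        Lhat = _match_left_vector(lam, J)
    if prediction is not None and np.abs(lam) <= prediction.r_g * (
        1.0 + 2.0 / np.sqrt(N)
    ):
        raise ValueError("no visible outlier: dominant eigenvalue inside bulk")
    # realness cleanup for real dominant eigenvalues
    if abs(lam.imag) < 1e-10 * max(abs(lam), 1.0):
        lam = lam.real
        Rhat = np.real(Rhat * np.exp(-1j * np.angle(Rhat[np.argmax(np.abs(Rhat))])))
        Lhat = np.real(Lhat * np.exp(-1j * np.angle(Lhat[np.argmax(np.abs(Lhat))])))
    Rhat = Rhat / np.linalg.norm(Rhat)
    # sign/phase convention: positive overlap with the all-ones direction
    s = Rhat.sum()
    if np.abs(s) > 0 and (s.real if np.isrealobj(Rhat) else np.real(s)) < 0:
        Rhat = -Rhat
    denom = Lhat @ Rhat
    if np.abs(denom) < 1e-12:
        raise ValueError("left/right eigenvectors nearly orthogonal")
    Lhat = Lhat / denom
    return lam, Rhat, Lhat


def normalize_for_comparison(
    Rhat: np.ndarray, Lhat: np.ndarray, Rbar: np.ndarray, Lbar: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale numerical eigenvectors for entry-wise comparison with theory.

    Applies ``R = (Lhat^T Rbar / Lbar^T Rhat)^{1/2} Rhat`` and the symmetric
    expression for ``L``, after which (R, L) are statistically comparable to
    the perturbative ``(Rbar + dR, Lbar + dL)``.  The overall sign is fixed so
    that ``R^T Rbar > 0``.  Idempotent up to machine precision.
    """
    a = Lhat @ Rbar
    b = Lbar @ Rhat
    if np.abs(b) < 1e-12 * np.linalg.norm(Lbar) * np.linalg.norm(Rhat):
        warnings.warn("near-orthogonal Rhat vs Rbar: normalization unstable")
    ratio = a / b
    scale = np.sqrt(ratio.astype(complex))
    R = scale * Rhat
    L = Lhat / scale
    if np.isrealobj(Rhat) and np.isrealobj(Lhat) and abs(scale.imag) < 1e-12:
        R, L = R.real, L.real
    if np.real(R @ Rbar) < 0:
        R, L = -R, -L
    return R, L


def truncated_rank_approx(
    J: np.ndarray, R: int
) -> tuple[np.ndarray, list[tuple[complex, np.ndarray, np.ndarray]]]:
    """Rank-R truncated eigendecomposition ``J_R = sum_r lambda_r R_r L_r^T``.

    Keeps the R largest-|lambda| eigenvalues, which are then eigenvalues of
    ``J_R`` exactly (unlike an SVD truncation).  Returns the approximated
    matrix and the list of rescaled connectivity-vector triples
    ``(lambda_r, m_r, n_r)`` with ``m_r = sqrt(N) R_r``,
    ``n_r = sqrt(N) lambda_r L_r`` so ``J_R = sum_r m_r n_r^T / N``.

    For real input a dominant complex pair cannot be truncated at R=1 (the
    conjugate must be kept); this raises.
    """
    N = J.shape[0]
    if not 1 <= R <= N:
        raise ValueError("rank R must be in [1, N]")
    w, V = np.linalg.eig(J)
    order = np.argsort(-np.abs(w))
    w, V = w[order], V[:, order]
    wl, U = np.linalg.eig(J.T)

    if (
        R == 1
        and np.isrealobj(J)
        and abs(w[0].imag) > 1e-10 * max(abs(w[0]), 1.0)
    ):
        raise ValueError(
            "dominant eigenvalue is a complex pair: no real rank-one truncation"
        )

    J_R = np.zeros((N, N), dtype=complex)
    vectors = []
    used = np.zeros(len(wl), dtype=bool)
    for r in range(R):
        lam = w[r]
        Rv = V[:, r] / np.linalg.norm(V[:, r])
        dist = np.where(used, np.inf, np.abs(wl - lam))
        k = int(np.argmin(dist))
        if dist[k] > 1e-8 * max(abs(lam), 1.0):
            raise ValueError("left/right eigenvalue pairing failed")
        used[k] = True
        Lv = U[:, k]
        Lv = Lv / (Lv @ Rv)
        J_R += lam * np.outer(Rv, Lv)
        vectors.append((lam, np.sqrt(N) * Rv, np.sqrt(N) * lam * Lv))
    if np.isrealobj(J) and np.abs(J_R.imag).max() < 1e-8 * max(
        np.abs(J_R.real).max(), 1.0
    ):
        J_R = J_R.real
    return J_R, vectors


def lowrank_to_local_stats(
    stats: RankOneStats, pop: PopulationStructure
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map rank-one Gaussian-mixture statistics back to local block statistics.

    Returns 2x2 tables (row = post, col = pre) of block means
    ``Jbar_pq = mbar_p nbar_q / N``, element variances and reciprocal
    correlations eta_pq.  With zero covariances the returned eta is zero;
    blocks with zero variance raise (undefined correlation).
    """
    N = pop.N
    Jbar = np.empty((2, 2))
    var = np.empty((2, 2))
    eta = np.empty((2, 2))
    idx = {"E": 0, "I": 1}
    for p in POPS:
        for q in POPS:
            i, j = idx[p], idx[q]
            mb_p, nb_q = stats.mbar[p], stats.nbar[q]
            Jbar[i, j] = mb_p * nb_q / N
            var[i, j] = (
                stats.sigma2_m[p] * nb_q**2
                + mb_p**2 * stats.sigma2_n[q]
                + stats.sigma2_m[p] * stats.sigma2_n[q]
            ) / N**2
    for p in POPS:
        for q in POPS:
            i, j = idx[p], idx[q]
            if var[i, j] == 0 or var[j, i] == 0:
                raise ValueError("eta undefined: zero block variance")
            num = (
                stats.sigma_nm[p] * stats.mbar[q] * stats.nbar[q]
                + stats.sigma_nm[q] * stats.mbar[p] * stats.nbar[p]
                + stats.sigma_nm[p] * stats.sigma_nm[q]
            ) / N**2
            eta[i, j] = num / np.sqrt(var[i, j] * var[j, i])
    return Jbar, var, eta


def empirical_vector_stats(
    pv_or_mn: PerturbedVectors | tuple[np.ndarray, np.ndarray],
    pop: PopulationStructure,
) -> RankOneStats:
    """Per-population sample moments of rank-one vector entries."""
    if isinstance(pv_or_mn, PerturbedVectors):
        m, n = pv_or_mn.m, pv_or_mn.n
    else:
        m, n = pv_or_mn
    mbar, nbar, s2m, s2n, snm = {}, {}, {}, {}, {}
    for p in POPS:
        sl = pop.block_slice(p)
        mp, np_ = np.real(m[sl]), np.real(n[sl])
        mbar[p] = float(mp.mean())
        nbar[p] = float(np_.mean())
        s2m[p] = float(mp.var())
        s2n[p] = float(np_.var())
        snm[p] = float(((mp - mp.mean()) * (np_ - np_.mean())).mean())
    return RankOneStats(
        mbar=mbar,
        nbar=nbar,
        sigma2_m=s2m,
        sigma2_n=s2n,
        sigma_nm=snm,
        alpha=pop.fractions,
    )
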