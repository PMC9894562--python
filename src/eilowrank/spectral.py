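"""Analytic eigenvalue-outlier predictions and empirical spectrum tools.

The connectivity ``J = m n^T / N + Z`` has a spectrum made of a continuous
bulk (radius set by the variance parameters) and discrete outliers controlled
by the rank-one mean structure.  For independent fluctuations the outlier is
on average the unperturbed eigenvalue ``lambda_0 = J_E - J_I``; reciprocal
motifs shift it through the second-order coefficient ``[theta_2]``, turning
the outlier condition into the cubic

    lambda^3 = lambda_0 lambda^2 + [theta_1] lambda + [theta_2],

with ``[theta_1] = 0`` on average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import GaussianLocalStats, SparseLocalStats
from .populations import PopulationStructure

__all__ = [
    "OutlierPrediction",
    "SpectrumSummary",
    "outlier_mean_independent",
    "outlier_std_independent",
    "theta2_mean",
    "outlier_roots_reciprocal",
    "bulk_radius",
    "predict_outliers",
    "classify_spectrum",
    "default_margin",
]


@dataclass
class OutlierPrediction:
    """Predicted outlier structure of one parameter set.

    ``tau`` is the effective reciprocal correlation of the fluctuation part
    (variance-weighted average of eta_pq); it elongates the bulk from a circle
    into an ellipse with semi-axes ``r_g (1 +/- tau)``.
    """

    lambda0: float
    theta2_mean: float
    sigma_lambda: float
    r_g: float
    tau: float = 0.0
    roots: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=complex))
    visible: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=bool))

    @property
    def dominant(self) -> complex | None:
        """Visible root of largest modulus; ties broken toward the real root."""
        vis = self.roots[self.visible]
        if vis.size == 0:
            return None
        mod = np.abs(vis)
        best = mod.max()
        cand = vis[np.isclose(mod, best, rtol=1e-12)]
        real = cand[np.abs(cand.imag) < 1e-12]
        return complex(real[0]) if real.size else complex(cand[0])

    @property
    def dominant_real(self) -> float:
        dom = self.dominant
        if dom is None:
            raise ValueError("no visible outlier (all roots inside the bulk)")
        return float(dom.real)


@dataclass
class SpectrumSummary:
    """Empirical eigendecomposition split into bulk and outliers."""

    eigenvalues: np.ndarray
    outlier_mask: np.ndarray
    r_g: float
    margin: float

    @property
    def outliers(self) -> np.ndarray:
        return self.eigenvalues[self.outlier_mask]

    @property
    def bulk(self) -> np.ndarray:
        return self.eigenvalues[~self.outlier_mask]

    @property
    def bulk_radius_empirical(self) -> float:
        b = self.bulk
        return float(np.abs(b).max()) if b.size else 0.0

    @property
    def dominant(self) -> complex:
        out = self.outliers
        if out.size == 0:
            raise ValueError("no outlier outside the bulk")
        return complex(out[np.argmax(np.abs(out))])


def _lambda0(stats, pop: PopulationStructure) -> float:
    if isinstance(stats, GaussianLocalStats):
        return stats.J_E - stats.J_I
    if isinstance(stats, SparseLocalStats):
        return stats.c * (pop.N_E * stats.A_E + pop.N_I * stats.A_I)
    raise TypeError(f"unsupported stats type {type(stats).__name__}")


def outlier_mean_independent(stats, pop: PopulationStructure) -> float:
    """Ensemble-mean outlier for independent fluctuations.

    ``J_E - J_I`` for Gaussian statistics, ``c (N_E A_E + N_I A_I)`` for
    sparse; the two agree under moment matching.
    """
    return _lambda0(stats, pop)


def outlier_std_independent(stats, pop: PopulationStructure) -> float:
    """Finite-size standard deviation of the outlier (first-order theory).

    Scales as 1/sqrt(N); requires a non-zero unperturbed eigenvalue (otherwise
    the outlier sits in the bulk and the perturbative expansion is invalid).
    """
    lam0 = _lambda0(stats, pop)
    if lam0 == 0:
        raise ValueError("lambda0 = 0: outlier inside bulk, perturbation invalid")
    if isinstance(stats, GaussianLocalStats):
        g = stats.g
        var = (
            stats.J_E**2 * (g[0, 0] ** 2 + pop.N_I / pop.N_E * g[0, 1] ** 2)
            + stats.J_I**2 * (pop.N_E / pop.N_I * g[1, 0] ** 2 + g[1, 1] ** 2)
        ) / (pop.N * lam0**2)
    else:
        var = (
            (stats.A_E**2 * pop.N_E + stats.A_I**2 * pop.N_I) ** 2
            * (1 - stats.c)
            * stats.c**3
            / lam0**2
        )
    return float(np.sqrt(var))


def theta2_mean(stats, pop: PopulationStructure) -> float:
    """Ensemble mean of the second-order series coefficient ``[theta_2]``.

    Non-zero only with reciprocal motifs; the Gaussian and sparse expressions
    agree exactly under moment matching.
    """
    aE, aI = pop.alpha_E, pop.alpha_I
    if isinstance(stats, GaussianLocalStats):
        g, eta = stats.g, stats.eta
        term_E = aE * g[0, 0] ** 2 * eta[0, 0] + aI * g[0, 1] * g[1, 0] * eta[0, 1]
        term_I = aE * g[1, 0] * g[0, 1] * eta[0, 1] + aI * g[1, 1] ** 2 * eta[1, 1]
        return float(stats.J_E * term_E - stats.J_I * term_I)
    if isinstance(stats, SparseLocalStats):
        c, AE, AI = stats.c, stats.A_E, stats.A_I
        NE, NI = pop.N_E, pop.N_I
        rho = stats.rho
        return float(
            c**2
            * (
                AE**3 * NE**2 * (rho[0, 0] - c)
                + AE**2 * AI * NE * NI * (rho[0, 1] - c)
                + AE * AI**2 * NI * NE * (rho[0, 1] - c)
                + AI**3 * NI**2 * (rho[1, 1] - c)
            )
        )
    raise TypeError(f"unsupported stats type {type(stats).__name__}")


def outlier_roots_reciprocal(
    lambda0: float, theta2: float, r_g: float
) -> tuple[np.ndarray, np.ndarray]:
    """Roots of ``lambda^3 - lambda0 lambda^2 - theta2 = 0`` with visibility.

    Returns the three roots (complex pairs kept conjugate) and a boolean mask
    flagging roots of modulus larger than the bulk radius ``r_g``.
    """
    if not (np.isfinite(lambda0) and np.isfinite(theta2) and np.isfinite(r_g)):
        raise ValueError("inputs must be finite")
    roots = np.roots([1.0, -lambda0, 0.0, -theta2])
    # order: descending modulus, real roots before complex at ties
    order = np.lexsort((np.abs(roots.imag), -np.abs(roots)))
    roots = roots[order]
    visible = np.abs(roots) > r_g
    return roots, visible


def bulk_radius(stats, pop: PopulationStructure) -> float:
    """Radius of the continuous eigenvalue bulk.

    Homogeneous variances give ``r_g = g``.  With cell-type-dependent
    variances the radius is the square root of the largest eigenvalue of the
    2x2 table with entries ``alpha_q g_pq^2`` (which reduces to g in the
    homogeneous case).  Sparse statistics are mapped to their matched Gaussian
    moments first.
    """
    from .connectivity import sparse_to_gaussian_moments

    if isinstance(stats, SparseLocalStats):
        stats = sparse_to_gaussian_moments(stats, pop)
    M = stats.g**2 * np.array([pop.alpha_E, pop.alpha_I])[np.newaxis, :]
    ev = np.linalg.eigvals(M)
    return float(np.sqrt(max(ev.real.max(), 0.0)))


def effective_correlation(stats, pop: PopulationStructure) -> float:
    """Variance-weighted average reciprocal correlation of the fluctuations.

    ``tau = sum_pq alpha_p alpha_q g_pq g_qp eta_pq / sum_pq alpha_p alpha_q
    g_pq g_qp``; equals eta in the homogeneous case and 0 without motifs.
    """
    from .connectivity import sparse_to_gaussian_moments

    if isinstance(stats, SparseLocalStats):
        stats = sparse_to_gaussian_moments(stats, pop)
    alpha = np.array([pop.alpha_E, pop.alpha_I])
    w = np.outer(alpha, alpha) * stats.g * stats.g.T
    if w.sum() == 0:
        return 0.0
    return float((w * stats.eta).sum() / w.sum())


def predict_outliers(stats, pop: PopulationStructure) -> OutlierPrediction:
    """Full analytic outlier prediction for one parameter set."""
    lam0 = _lambda0(stats, pop)
    th2 = theta2_mean(stats, pop)
    r_g = bulk_radius(stats, pop)
    roots, visible = outlier_roots_reciprocal(lam0, th2, r_g)
    try:
        sig = outlier_std_independent(stats, pop)
    except ValueError:
        sig = np.nan
    return OutlierPrediction(
        lambda0=lam0,
        theta2_mean=th2,
        sigma_lambda=sig,
        r_g=r_g,
        tau=effective_correlation(stats, pop),
        roots=roots,
        visible=visible,
    )


def default_margin(N: int) -> float:
    """Separation factor above r_g for flagging outliers: 1 + 2/sqrt(N)."""
    return 1.0 + 2.0 / np.sqrt(N)


def classify_spectrum(
    J: np.ndarray,
    prediction: OutlierPrediction,
    margin: float | None = None,
    Z: np.ndarray | None = None,
    gap_factor: float = 10.0,
) -> SpectrumSummary:
    """Eigendecompose ``J`` and flag eigenvalues outside the predicted bulk.

    Without motifs (``tau = 0``) an eigenvalue is an outlier iff its modulus
    exceeds ``r_g * margin`` (circular bulk); with motifs the boundary is the
    ellipse with semi-axes ``r_g (1 + tau)`` and ``r_g (1 - tau)``, floored at
    the finite-size scale ``2 r_g / sqrt(N)``.  The default margin
    ``1 + 2/sqrt(N)`` accounts for edge fluctuations of the bulk.

    Block-structured correlations can deform the bulk beyond an ellipse; when
    the realization's fluctuation part ``Z`` is supplied, the flag is
    additionally gated on the eigenvalue being far (``gap_factor`` times the
    median displacement) from the spectrum of ``Z``, which is the bulk of the
    same realization.
    """
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValueError("J must be square")
    N = J.shape[0]
    if margin is None:
        margin = default_margin(N)
    eig = np.linalg.eigvals(J)
    # floor against the degenerate axes of the ellipse and, for a noiseless
    # matrix (r_g = 0), against eigensolver round-off
    floor = max(2.0 * prediction.r_g / np.sqrt(N), 1e-9 * max(np.abs(eig).max(), 1.0))
    a = max(prediction.r_g * (1.0 + prediction.tau), floor) * margin
    b = max(prediction.r_g * (1.0 - prediction.tau), floor) * margin
    mask = (eig.real / a) ** 2 + (eig.imag / b) ** 2 > 1.0
    if Z is not None:
        evZ = np.linalg.eigvals(Z)
        d = np.abs(eig[:, None] - evZ[None, :]).min(axis=1)
        med = np.median(d)
        mask &= d > gap_factor * max(med, 1e-12)
    return SpectrumSummary(
        eigenvalues=eig, outlier_mask=mask, r_g=prediction.r_g, margin=margin
    )
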