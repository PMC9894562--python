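"""Locally-defined E-I random connectivity: statistics, generators, moments.

Connectivity is described at the level of block-wise ("local") statistics:
means that depend only on the presynaptic population, variances g_pq^2/N and
reciprocal correlations eta_pq that depend on both pre- and post-synaptic
populations.  Two weight distributions are supported: dense Gaussian and
sparse Bernoulli.  Every sampled matrix is returned decomposed as
``J = Jbar + Z`` with ``Jbar`` the rank-one mean part.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .populations import POPS, PopulationStructure

__all__ = [
    "GaussianLocalStats",
    "SparseLocalStats",
    "ConnectivityRealization",
    "make_mean_matrix",
    "gamma_coefficient",
    "sample_gaussian",
    "sample_sparse",
    "sparse_to_gaussian_moments",
    "local_reciprocal_correlation",
]

_IDX = {"E": 0, "I": 1}


def _as_block_table(x, name: str) -> np.ndarray:
    """Coerce a scalar or 2x2 table (array or nested dict) to a float array."""
    if isinstance(x, dict):
        x = [[x[p][q] for q in POPS] for p in POPS]
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = np.full((2, 2), float(arr))
    if arr.shape != (2, 2):
        raise ValueError(f"{name} must be a scalar or 2x2 block table")
    return arr


@dataclass(frozen=True)
class GaussianLocalStats:
    """Block statistics for dense Gaussian connectivity.

    ``J_E, J_I > 0`` are the rescaled mean couplings: block means are
    ``J_E/N_E`` for excitatory (presynaptic E) columns and ``-J_I/N_I`` for
    inhibitory columns.  ``g`` is the 2x2 table of variance scales (element
    variance ``g_pq^2/N``, row = postsynaptic population) and ``eta`` the
    symmetric 2x2 table of reciprocal correlations in [-1, 1].
    """

    J_E: float
    J_I: float
    g: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    eta: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))

    def __post_init__(self) -> None:
        object.__setattr__(self, "g", _as_block_table(self.g, "g"))
        object.__setattr__(self, "eta", _as_block_table(self.eta, "eta"))
        if self.J_E <= 0 or self.J_I <= 0:
            raise ValueError("mean couplings J_E, J_I must be positive")
        if np.any(self.g < 0):
            raise ValueError("variance scales g_pq must be non-negative")
        if np.any(np.abs(self.eta) > 1 + 1e-12):
            raise ValueError("reciprocal correlations eta_pq must lie in [-1, 1]")
        if not np.isclose(self.eta[0, 1], self.eta[1, 0]):
            raise ValueError("eta must be symmetric (eta_EI = eta_IE)")

    @classmethod
    def homogeneous(
        cls, J_E: float, J_I: float, g: float = 0.0, eta: float = 0.0
    ) -> "GaussianLocalStats":
        return cls(J_E=J_E, J_I=J_I, g=np.full((2, 2), g), eta=np.full((2, 2), eta))

    def g_pq(self, p: str, q: str) -> float:
        return float(self.g[_IDX[p], _IDX[q]])

    def eta_pq(self, p: str, q: str) -> float:
        return float(self.eta[_IDX[p], _IDX[q]])

    def mean_block(self, pop: PopulationStructure) -> dict[str, float]:
        """Block means, keyed by presynaptic population."""
        return {"E": self.J_E / pop.N_E, "I": -self.J_I / pop.N_I}

    def sigma_z2(self, pop: PopulationStructure) -> np.ndarray:
        """2x2 table of element variances g_pq^2 / N."""
        return self.g**2 / pop.N

    def to_dict(self) -> dict:
        return {
            "flavor": "gaussian",
            "J_E": self.J_E,
            "J_I": self.J_I,
            "g": self.g.tolist(),
            "eta": self.eta.tolist(),
        }


@dataclass(frozen=True)
class SparseLocalStats:
    """Block statistics for sparse Bernoulli connectivity.

    Every directed edge is present with homogeneous probability ``c``; present
    excitatory edges carry weight ``A_E > 0`` and inhibitory edges
    ``A_I < 0``.  ``rho`` is the symmetric 2x2 table of reciprocal fractions:
    the probability that the mirror of a present edge is also present.
    """

    c: float
    A_E: float
    A_I: float
    rho: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))

    def __post_init__(self) -> None:
        object.__setattr__(self, "rho", _as_block_table(self.rho, "rho"))
        if not 0.0 < self.c < 1.0:
            raise ValueError("connection probability c must lie in (0, 1)")
        if self.A_E <= 0:
            raise ValueError("sign convention: A_E must be positive")
        if self.A_I >= 0:
            raise ValueError("sign convention: A_I must be negative")
        if np.any(self.rho < 0) or np.any(self.rho > 1):
            raise ValueError("reciprocal fractions rho_pq must lie in [0, 1]")
        if not np.isclose(self.rho[0, 1], self.rho[1, 0]):
            raise ValueError("rho must be symmetric (rho_EI = rho_IE)")
        # Mirror probability of an absent edge, c(1 - rho)/(1 - c), must be a
        # probability; binds only for c > 1/2.
        if np.any(self.c * (1 - self.rho) / (1 - self.c) > 1 + 1e-12):
            raise ValueError("infeasible (c, rho): requires rho >= (2c - 1)/c")

    def rho_pq(self, p: str, q: str) -> float:
        return float(self.rho[_IDX[p], _IDX[q]])

    def A(self, q: str) -> float:
        return self.A_E if q == "E" else self.A_I

    def mean_block(self) -> dict[str, float]:
        """Block means c*A_q, keyed by presynaptic population."""
        return {"E": self.c * self.A_E, "I": self.c * self.A_I}

    def sigma_z2(self) -> np.ndarray:
        """2x2 table of element variances (1-c) c A_q^2 (column-dependent)."""
        a2 = np.array([self.A_E**2, self.A_I**2])
        return np.tile(self.c * (1 - self.c) * a2, (2, 1))

    def implied_eta(self) -> np.ndarray:
        """Reciprocal correlations sign(A_p A_q) (rho_pq - c)/(1 - c)."""
        a = np.array([self.A_E, self.A_I])
        sign = np.sign(np.outer(a, a))
        return sign * (self.rho - self.c) / (1 - self.c)

    def to_dict(self) -> dict:
        return {
            "flavor": "sparse",
            "c": self.c,
            "A_E": self.A_E,
            "A_I": self.A_I,
            "rho": self.rho.tolist(),
        }


@dataclass
class ConnectivityRealization:
    """One sampled N x N connectivity matrix with its decomposition.

    ``J = Jbar + Z`` holds element-wise by construction; ``Jbar`` is the
    rank-one mean part (identical entries within each column block).
    """

    J: np.ndarray
    Jbar: np.ndarray
    Z: np.ndarray
    pop: PopulationStructure
    seed: int
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.J.shape != (self.pop.N, self.pop.N):
            raise ValueError("matrix shape does not match population structure")


def make_mean_matrix(
    pop: PopulationStructure, J_E: float, J_I: float
) -> np.ndarray:
    """Rank-one mean matrix: ``J_E/N_E`` in E columns, ``-J_I/N_I`` in I columns."""
    if J_E <= 0 or J_I <= 0:
        raise ValueError("mean couplings J_E, J_I must be positive")
    row = np.empty(pop.N)
    row[pop.slice_E] = J_E / pop.N_E
    row[pop.slice_I] = -J_I / pop.N_I
    return np.tile(row, (pop.N, 1))


def gamma_coefficient(eta_pq: float) -> float:
    """Mixing coefficient for imprinting a reciprocal correlation ``eta_pq``.

    Combining an i.i.d. standard-normal matrix Y' with its transpose as
    ``gamma * Y' + sqrt(1 - gamma^2) * Y'^T`` preserves unit marginal variance
    and yields a reciprocal correlation ``2 gamma sqrt(1 - gamma^2) = eta``.
    """
    if abs(eta_pq) > 1 + 1e-12:
        raise ValueError("|eta| must not exceed 1")
    eta_pq = float(np.clip(eta_pq, -1.0, 1.0))
    # stable form of sqrt((1 - sqrt(1 - eta^2))/2): exact for tiny eta too
    mag = abs(eta_pq) / np.sqrt(2.0 * (1.0 + np.sqrt(1.0 - eta_pq**2)))
    return float(np.copysign(mag, eta_pq)) if eta_pq != 0 else 0.0


def _block_table_matrix(pop: PopulationStructure, table: np.ndarray) -> np.ndarray:
    """Expand a 2x2 block table into an N x N matrix (row = post, col = pre)."""
    rows = np.where(np.arange(pop.N) < pop.N_E, 0, 1)
    return table[np.ix_(rows, rows)]


def sample_gaussian(
    pop: PopulationStructure, stats: GaussianLocalStats, seed: int
) -> ConnectivityRealization:
    """Sample a dense Gaussian connectivity matrix with reciprocal motifs.

    An i.i.d. standard-normal matrix is mixed with its transpose block-wise
    (mixing coefficient from :func:`gamma_coefficient`, applied to off-diagonal
    pairs only), scaled by ``g_pq/sqrt(N)``, and added to the rank-one mean.
    """
    rng = np.random.default_rng(seed)
    N = pop.N
    Y0 = rng.standard_normal((N, N))
    gamma_tab = np.vectorize(gamma_coefficient)(stats.eta)
    G = _block_table_matrix(pop, gamma_tab)
    Y = G * Y0 + np.sqrt(1.0 - G**2) * Y0.T
    # diagonal: independent entries, no self-motif
    np.fill_diagonal(Y, np.diag(Y0))
    scale = _block_table_matrix(pop, stats.g) / np.sqrt(N)
    Z = scale * Y
    Jbar = make_mean_matrix(pop, stats.J_E, stats.J_I)
    return ConnectivityRealization(
        J=Jbar + Z, Jbar=Jbar, Z=Z, pop=pop, seed=seed, provenance="gaussian"
    )


def sample_sparse(
    pop: PopulationStructure, stats: SparseLocalStats, seed: int
) -> ConnectivityRealization:
    """Sample a sparse Bernoulli connectivity matrix with reciprocal motifs.

    Each unordered pair is assigned jointly: the forward edge is present with
    probability ``c``; given presence the mirror is present with probability
    ``rho_pq``, and given absence with ``c(1 - rho_pq)/(1 - c)``.  This keeps
    the marginal density of every directed edge exactly ``c`` and gives a
    presence correlation ``(rho_pq - c)/(1 - c)``.  ``rho = c`` recovers
    independent Bernoulli sampling.  Diagonal entries are independent
    Bernoulli(c).
    """
    rng = np.random.default_rng(seed)
    N = pop.N
    u_fwd = rng.random((N, N))
    u_mir = rng.random((N, N))
    rho_mat = _block_table_matrix(pop, stats.rho)

    iu = np.triu_indices(N, k=1)
    fwd = u_fwd[iu] < stats.c
    rho_pair = rho_mat[iu]
    p_mirror = np.where(
        fwd, rho_pair, stats.c * (1 - rho_pair) / (1 - stats.c)
    )
    mir = u_mir[iu] < p_mirror

    present = np.zeros((N, N), dtype=bool)
    present[iu] = fwd
    present.T[iu] = mir
    np.fill_diagonal(present, np.diag(u_fwd) < stats.c)

    weight_col = np.where(np.arange(N) < pop.N_E, stats.A_E, stats.A_I)
    J = present * weight_col[np.newaxis, :]
    J_E = pop.N_E * stats.c * stats.A_E
    J_I = -pop.N_I * stats.c * stats.A_I
    Jbar = make_mean_matrix(pop, J_E, J_I)
    return ConnectivityRealization(
        J=J, Jbar=Jbar, Z=J - Jbar, pop=pop, seed=seed, provenance="sparse"
    )


def sample(pop, stats, seed: int) -> ConnectivityRealization:
    """Dispatch to the Gaussian or sparse generator based on the stats type."""
    if isinstance(stats, GaussianLocalStats):
        return sample_gaussian(pop, stats, seed)
    if isinstance(stats, SparseLocalStats):
        return sample_sparse(pop, stats, seed)
    raise TypeError(f"unsupported stats type {type(stats).__name__}")


def sparse_to_gaussian_moments(
    stats: SparseLocalStats, pop: PopulationStructure
) -> GaussianLocalStats:
    """Match a sparse model to Gaussian block moments.

    Returns the Gaussian description with identical block means
    (``J_E = N_E c A_E``, ``J_I = -N_I c A_I``), element variances
    (``g_pq^2/N = A_q^2 c(1-c)``) and reciprocal correlations (implied eta).
    """
    J_E = pop.N_E * stats.c * stats.A_E
    J_I = -pop.N_I * stats.c * stats.A_I
    g_col = np.sqrt(
        pop.N * stats.c * (1 - stats.c) * np.array([stats.A_E**2, stats.A_I**2])
    )
    g = np.tile(g_col, (2, 1))
    return GaussianLocalStats(J_E=J_E, J_I=J_I, g=g, eta=stats.implied_eta())


def local_reciprocal_correlation(
    J: np.ndarray, pop: PopulationStructure
) -> np.ndarray:
    """Empirical reciprocal correlations, one per block pair.

    For each block pair (p, q), the Pearson correlation of
    ``(J_ij - mean_pq, J_ji - mean_qp)`` over all cross-diagonal pairs with
    ``i != j``.  The output 2x2 table is symmetric.  Blocks with zero variance
    raise (undefined correlation, never silently reported as 0).
    """
    N = pop.N
    if J.shape != (N, N):
        raise ValueError("matrix shape does not match population structure")
    out = np.full((2, 2), np.nan)
    for p in POPS:
        for q in POPS:
            sp, sq = pop.block_slice(p), pop.block_slice(q)
            A = J[sp, sq]
            B = J[sq, sp]
            if p == q:
                n = A.shape[0]
                iu = np.triu_indices(n, k=1)
                x = A[iu]
                y = A.T[iu]
            else:
                x = A.ravel()
                y = B.T.ravel()
            mx, my = x.mean(), y.mean()
            vx, vy = x.var(), y.var()
            if vx == 0 or vy == 0:
                raise ValueError(
                    f"reciprocal correlation undefined: zero variance in block {p}{q}"
                )
            out[_IDX[p], _IDX[q]] = ((x - mx) * (y - my)).mean() / np.sqrt(vx * vy)
    # enforce exact symmetry (EI and IE estimate the same quantity)
    ei = 0.5 * (out[0, 1] + out[1, 0])
    out[0, 1] = out[1, 0] = ei
    return out
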