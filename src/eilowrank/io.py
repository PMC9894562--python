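"""Import/export of connectivity realizations and statistics summaries.

Matrices are written in Matrix Market format with a JSON sidecar holding the
population structure and local statistics, so a realization round-trips
through disk with full provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .connectivity import (
    ConnectivityRealization,
    GaussianLocalStats,
    SparseLocalStats,
    local_reciprocal_correlation,
    make_mean_matrix,
)
from .populations import POPS, PopulationStructure

__all__ = [
    "save_realization",
    "load_realization",
    "stats_from_dict",
    "block_summary",
]


def stats_from_dict(d: dict):
    """Rebuild a local-statistics object from its dict form."""
    d = dict(d)
    flavor = d.pop("flavor")
    if flavor == "gaussian":
        return GaussianLocalStats(**{k: d[k] for k in ("J_E", "J_I", "g", "eta")})
    if flavor == "sparse":
        return SparseLocalStats(**{k: d[k] for k in ("c", "A_E", "A_I", "rho")})
    raise ValueError(f"unknown stats flavor {flavor!r}")


def save_realization(
    realization: ConnectivityRealization, stats, path: str | Path
) -> None:
    """Write J as .mtx (sparse storage for Bernoulli weights) + JSON sidecar."""
    path = Path(path)
    mat = realization.J
    if realization.provenance == "sparse":
        mat = scipy.sparse.coo_matrix(mat)
    scipy.io.mmwrite(str(path.with_suffix(".mtx")), np.asarray(mat) if not scipy.sparse.issparse(mat) else mat)
    sidecar = {
        "population": realization.pop.to_dict(),
        "stats": stats.to_dict(),
        "seed": realization.seed,
        "provenance": realization.provenance,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_realization(path: str | Path) -> ConnectivityRealization:
    """Read a matrix + sidecar pair written by :func:`save_realization`."""
    path = Path(path)
    J = scipy.io.mmread(str(path.with_suffix(".mtx")))
    if scipy.sparse.issparse(J):
        J = J.toarray()
    J = np.asarray(J, dtype=float)
    meta = json.loads(path.with_suffix(".json").read_text())
    pop = PopulationStructure(**meta["population"])
    stats = stats_from_dict(meta["stats"])
    if isinstance(stats, SparseLocalStats):
        J_E = pop.N_E * stats.c * stats.A_E
        J_I = -pop.N_I * stats.c * stats.A_I
    else:
        J_E, J_I = stats.J_E, stats.J_I
    Jbar = make_mean_matrix(pop, J_E, J_I)
    return ConnectivityRealization(
        J=J,
        Jbar=Jbar,
        Z=J - Jbar,
        pop=pop,
        seed=meta["seed"],
        provenance=meta["provenance"],
    )


def block_summary(
    realization: ConnectivityRealization,
) -> pd.DataFrame:
    """Per-block empirical mean, variance and reciprocal correlation of J."""
    pop = realization.pop
    eta = local_reciprocal_correlation(realization.J, pop)
    idx = {"E": 0, "I": 1}
    rows = []
    for p in POPS:
        for q in POPS:
            blk = realization.J[pop.block_slice(p), pop.block_slice(q)]
            rows.append(
                {
                    "post": p,
                    "pre": q,
                    "mean": blk.mean(),
                    "var": blk.var(),
                    "eta": eta[idx[p], idx[q]],
                }
            )
    return pd.DataFrame(rows)
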