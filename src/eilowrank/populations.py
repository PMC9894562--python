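"""Excitatory-inhibitory population structure.

Neurons are partitioned into a contiguous excitatory block (first ``N_E``
indices) followed by an inhibitory block (``N_I`` indices), the standard
ordering for block-structured E-I connectivity matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PopulationStructure"]

POPS = ("E", "I")


@dataclass(frozen=True)
class PopulationStructure:
    """Partition of ``N = N_E + N_I`` neurons into E and I blocks.

    Parameters
    ----------
    N_E, N_I : int
        Number of excitatory / inhibitory neurons; both must be positive.

    Attributes
    ----------
    N : int
        Total network size.
    alpha_E, alpha_I : float
        Population fractions ``N_p / N``.
    """

    N_E: int
    N_I: int

    def __post_init__(self) -> None:
        if self.N_E <= 0 or self.N_I <= 0:
            raise ValueError("population sizes N_E, N_I must be positive")

    @property
    def N(self) -> int:
        return self.N_E + self.N_I

    @property
    def alpha_E(self) -> float:
        return self.N_E / self.N

    @property
    def alpha_I(self) -> float:
        return self.N_I / self.N

    @property
    def sizes(self) -> dict[str, int]:
        return {"E": self.N_E, "I": self.N_I}

    @property
    def fractions(self) -> dict[str, float]:
        return {"E": self.alpha_E, "I": self.alpha_I}

    @property
    def slice_E(self) -> slice:
        return slice(0, self.N_E)

    @property
    def slice_I(self) -> slice:
        return slice(self.N_E, self.N)

    def block_slice(self, p: str) -> slice:
        if p == "E":
            return self.slice_E
        if p == "I":
            return self.slice_I
        raise KeyError(f"unknown population {p!r}")

    @property
    def labels(self) -> np.ndarray:
        """Per-neuron population tag, ``'E'`` for the first block then ``'I'``."""
        out = np.empty(self.N, dtype="<U1")
        out[self.slice_E] = "E"
        out[self.slice_I] = "I"
        return out

    @classmethod
    def from_total(cls, N: int, alpha_E: float = 0.8) -> "PopulationStructure":
        """Build from total size with the standard cortical 80/20 E-I split."""
        N_E = int(round(alpha_E * N))
        return cls(N_E=N_E, N_I=N - N_E)

    def to_dict(self) -> dict:
        return {"N_E": self.N_E, "N_I": self.N_I}
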