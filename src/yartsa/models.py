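"""Nucleotide substitution models (JC69, HKY85).

Rate matrices are normalized to one expected substitution per site per unit
branch length. Transition probabilities come from the spectral decomposition
of the symmetrized generator, so ``P(t)`` is exact and cheap for arbitrary
``t`` (no per-branch ``expm``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

__all__ = ["SubstitutionModel", "BASES", "BASE_INDEX"]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# A<->G and C<->T are transitions
_TRANSITION = np.zeros((4, 4), dtype=bool)
_TRANSITION[0, 2] = _TRANSITION[2, 0] = True
_TRANSITION[1, 3] = _TRANSITION[3, 1] = True


@dataclass(frozen=True)
class SubstitutionModel:
    """Reversible 4-state model with equilibrium frequencies ``freqs``.

    ``kappa`` is the transition/transversion rate ratio (HKY85 only; JC69
    fixes it to 1 with equal frequencies).
    """

    name: str = "JC69"
    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    kappa: float = 1.0
    _spectral: tuple = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        name = self.name.upper()
        if name not in ("JC69", "HKY85"):
            raise ConfigError(f"unknown substitution model {self.name!r}")
        object.__setattr__(self, "name", name)
        pi = np.asarray(self.freqs, dtype=float)
        if pi.shape != (4,) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-12:
            raise ConfigError("frequencies must be positive and sum to 1")
        if self.kappa <= 0:
            raise ConfigError("kappa must be positive")
        if name == "JC69" and (self.kappa != 1.0 or not np.allclose(pi, 0.25)):
            raise ConfigError("JC69 requires equal frequencies and kappa=1")
        object.__setattr__(self, "freqs", tuple(float(x) for x in pi))
        object.__setattr__(self, "_spectral", self._decompose())

    # ------------------------------------------------------------------ setup
    def rate_matrix(self) -> np.ndarray:
        """Generator Q normalized to mean rate 1 (rows sum to zero)."""
        pi = np.asarray(self.freqs)
        Q = np.tile(pi, (4, 1)).astype(float)
        Q[_TRANSITION] *= self.kappa
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -np.dot(pi, np.diag(Q))
        return Q / rate

    def _decompose(self):
        pi = np.asarray(self.freqs)
        Q = self.rate_matrix()
        sq = np.sqrt(pi)
        B = (sq[:, None] * Q) / sq[None, :]
        eigval, U = np.linalg.eigh(0.5 * (B + B.T))
        left = U / sq[:, None]
        right = U.T * sq[None, :]
        return eigval, left, right

    # ------------------------------------------------------------- transition
    def transition_matrix(self, t) -> np.ndarray:
        """P(t); accepts scalar t (4x4) or an array of t (``(..., 4, 4)``)."""
        eigval, left, right = self._spectral
        t = np.asarray(t, dtype=float)
        ex = np.exp(np.multiply.outer(t, eigval))
        P = np.einsum("ij,...j,jk->...ik", left, ex, right)
        return np.clip(P, 0.0, 1.0)

    def expected_p_distance(self, t) -> np.ndarray:
        """Expected proportion of differing sites between two sequences whose
        paths sum to branch length ``t``."""
        P = self.transition_matrix(t)
        pi = np.asarray(self.freqs)
        same = np.einsum("a,...aa->...", pi, P)
        return 1.0 - same

    def stationary_sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(4, size=n, p=np.asarray(self.freqs))

    @classmethod
    def jc69(cls) -> "SubstitutionModel":
        return cls("JC69")

    @classmethod
    def hky85(cls, kappa: float = 2.0, freqs=(0.3, 0.2, 0.2, 0.3)) -> "SubstitutionModel":
        return cls("HKY85", tuple(freqs), kappa)
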