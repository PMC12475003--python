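"""Jensen-Shannon distance between profiles and per-protein distance matrices.

The effect-size metric of the workflow is the Jensen-Shannon distance with
logarithm base 2,

    JSD(P, Q) = sqrt( (D(P || M) + D(Q || M)) / 2 ),   M = (P + Q) / 2,

where D is the Kullback-Leibler divergence.  With base 2 the distance is a
metric bounded in [0, 1]: 0 for identical distributions and 1 for disjoint
support.  Per protein, a symmetric matrix of pairwise JSDs over all valid
samples of both conditions feeds the rank-based ANOSIM test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import rel_entr

_LN2 = np.log(2.0)


def _check_pair(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"length mismatch: {P.shape} vs {Q.shape}")
    return P, Q


def kl_divergence(P: np.ndarray, Q: np.ndarray) -> float:
    """Kullback-Leibler divergence D(P || Q) in bits.

    Terms with P(x)=0 contribute 0; P(x)>0 with Q(x)=0 yields +inf (this
    branch is unreachable when Q is a mixture containing P with positive
    weight, as in the Jensen-Shannon distance).
    """
    P, Q = _check_pair(P, Q)
    return float(rel_entr(P, Q).sum() / _LN2)


def mixture(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Elementwise average M(x) = (P(x) + Q(x)) / 2; closed on the simplex."""
    P, Q = _check_pair(P, Q)
    return 0.5 * (P + Q)


def jensen_shannon_distance(P: np.ndarray, Q: np.ndarray) -> float:
    """Jensen-Shannon distance, base 2; symmetric, finite, in [0, 1]."""
    P, Q = _check_pair(P, Q)
    M = mixture(P, Q)
    jsd_sq = 0.5 * (kl_divergence(P, M) + kl_divergence(Q, M))
    # floating-point noise can push the squared divergence a hair negative
    return float(np.sqrt(max(jsd_sq, 0.0)))


#: pluggable distance registry; only the default Jensen-Shannon distance ships
DISTANCE_REGISTRY: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "JSD": jensen_shannon_distance,
}


@dataclass
class DistanceMatrix:
    """Symmetric pairwise-distance matrix over the valid samples of one protein."""

    protein: str
    matrix: np.ndarray  # (n, n), zero diagonal
    is_treatment: np.ndarray  # (n,) bool condition tags

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def condensed(self) -> np.ndarray:
        """Strictly-lower-triangle entries, row-major (same order as labels below)."""
        i, j = np.tril_indices(self.n_samples, k=-1)
        return self.matrix[i, j]

    def pair_is_between(self) -> np.ndarray:
        """For each condensed entry, True when the pair spans both conditions."""
        i, j = np.tril_indices(self.n_samples, k=-1)
        return self.is_treatment[i] != self.is_treatment[j]


def pairwise_distance_matrix(
    profiles, protein: str, metric: str = "JSD"
) -> DistanceMatrix:
    """JSD for every unordered pair of valid samples from both conditions.

    ``profiles`` is a :class:`~fracshift.preprocessing.ProfileSet`; the
    protein must be testable (consult ``profiles.testable`` first).
    """
    i = profiles.index_of(protein)
    if not profiles.testable[i]:
        raise ValueError(
            f"protein {protein!r} is untestable "
            f"({profiles.reasons[i]}); consult the testable mask"
        )
    rows, labels = profiles.replicate_profiles(protein)
    dist = DISTANCE_REGISTRY[metric]
    n = rows.shape[0]
    mat = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d = dist(rows[a], rows[b])
            mat[a, b] = mat[b, a] = d
    return DistanceMatrix(protein=protein, matrix=mat, is_treatment=labels)
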