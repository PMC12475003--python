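"""Effect size and shift descriptors per protein.

Given the two condition-mean profiles P+ and P- and their mixture
M = (P+ + P-)/2, the position-wise relative entropy

    w_t(x) = P_t(x) * log2(P_t(x) / M(x))    (0 when P_t(x) = 0)

decomposes the KL divergence D(P_t || M) over fractions; its largest entries
mark where the distributions disagree most.  A temperature-scaled soft-argmax

    S_t = sum_x softmax(beta * w_t)(x) * x

localizes the expected position of the strongest shift (beta -> inf recovers
the hard argmax).  The relative fraction shift RPS = S+ - S- is negative for
leftward shifts (toward lower fractions); the relative distribution change
RDC = H(P+) - H(P-) (Shannon entropy, bits) is positive when treatment
broadens the distribution.  Together with the effect size JSD(P+ || P-) these
are the bubble-plot coordinates used for candidate selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import entropy as shannon_entropy

from .data import CONTROL, TREATMENT
from .distance import jensen_shannon_distance, kl_divergence, mixture
from .preprocessing import ProfileSet


def _require_testable(profiles: ProfileSet, protein: str) -> int:
    i = profiles.index_of(protein)
    if not profiles.testable[i]:
        raise ValueError(
            f"protein {protein!r} is untestable ({profiles.reasons[i]})"
        )
    return i


def effect_size_jsd(profiles: ProfileSet, protein: str) -> float:
    """Jensen-Shannon distance between the two condition-mean profiles."""
    i = _require_testable(profiles, protein)
    return jensen_shannon_distance(
        profiles.means[TREATMENT][i], profiles.means[CONTROL][i]
    )


def positionwise_relative_entropy(P: np.ndarray, M: np.ndarray) -> np.ndarray:
    """w(x) = P(x) log2(P(x)/M(x)); 0 where P(x)=0; error if P(x)>0, M(x)=0.

    Sums to the KL divergence D(P || M).  M must be the mixture of the two
    condition means, so the error branch is unreachable in normal use.
    """
    P = np.asarray(P, dtype=float)
    M = np.asarray(M, dtype=float)
    if P.shape != M.shape:
        raise ValueError("length mismatch")
    pos = P > 0
    if np.any(pos & (M <= 0)):
        raise ValueError(
            "P(x) > 0 where M(x) = 0: M is not a mixture containing P"
        )
    w = np.zeros_like(P)
    w[pos] = P[pos] * np.log2(P[pos] / M[pos])
    return w


def soft_argmax_position(
    w: np.ndarray, beta: float, positions: np.ndarray
) -> float:
    """Expected position under a softmax over temperature-scaled scores.

    S = sum_x softmax(beta * w)(x) * x, always inside [min(x), max(x)];
    shift-invariant in w and converging to argmax as beta grows.
    """
    w = np.asarray(w, dtype=float)
    positions = np.asarray(positions, dtype=float)
    z = beta * w
    z = z - z.max()  # overflow-safe; softmax is shift-invariant
    e = np.exp(z)
    return float((e * positions).sum() / e.sum())


def _mixture_of_means(profiles: ProfileSet, i: int) -> np.ndarray:
    return mixture(profiles.means[TREATMENT][i], profiles.means[CONTROL][i])


def relative_fraction_shift(
    profiles: ProfileSet, protein: str, beta: float
) -> float:
    """RPS = S+ - S-; negative = leftward shift (toward lower fractions).

    Only defined on a continuous fraction axis; positions of categorical bins
    carry no order.
    """
    if profiles.axis.mode != "continuous":
        raise ValueError(
            "relative fraction shift is not applicable to a categorical axis"
        )
    i = _require_testable(profiles, protein)
    M = _mixture_of_means(profiles, i)
    positions = profiles.axis.positions
    s = {}
    for cond in (TREATMENT, CONTROL):
        w = positionwise_relative_entropy(profiles.means[cond][i], M)
        s[cond] = soft_argmax_position(w, beta, positions)
    return s[TREATMENT] - s[CONTROL]


def relative_distribution_change(profiles: ProfileSet, protein: str) -> float:
    """Shannon-entropy difference H(P+) - H(P-) in bits; positive = broader after treatment."""
    i = _require_testable(profiles, protein)
    h_plus = shannon_entropy(profiles.means[TREATMENT][i], base=2)
    h_minus = shannon_entropy(profiles.means[CONTROL][i], base=2)
    return float(h_plus - h_minus)


def mean_within_jsd(profiles: ProfileSet, protein: str, condition: str) -> float:
    """Mean pairwise JSD among one condition's valid replicate profiles (QC).

    Returns NaN when fewer than 2 valid samples exist in the condition.
    """
    i = profiles.index_of(protein)
    rows = profiles.profiles[condition][i][profiles.valid[condition][i]]
    m = rows.shape[0]
    if m < 2:
        return float("nan")
    vals = [
        jensen_shannon_distance(rows[a], rows[b])
        for a in range(m)
        for b in range(a + 1, m)
    ]
    return float(np.mean(vals))


@dataclass
class ShiftMetrics:
    """All shift descriptors of one protein."""

    protein: str
    effect_jsd: float
    w_plus: np.ndarray
    w_minus: np.ndarray
    s_plus: float  # NaN in categorical mode
    s_minus: float
    relative_fraction_shift: float
    relative_distribution_change: float
    mean_within_jsd_treatment: float
    mean_within_jsd_control: float
    beta: float


def compute_shift_metrics(
    profiles: ProfileSet, protein: str, beta: float
) -> ShiftMetrics:
    """Bundle every shift descriptor; positional quantities are NaN in categorical mode."""
    i = _require_testable(profiles, protein)
    M = _mixture_of_means(profiles, i)
    w_plus = positionwise_relative_entropy(profiles.means[TREATMENT][i], M)
    w_minus = positionwise_relative_entropy(profiles.means[CONTROL][i], M)
    if profiles.axis.mode == "continuous":
        positions = profiles.axis.positions
        s_plus = soft_argmax_position(w_plus, beta, positions)
        s_minus = soft_argmax_position(w_minus, beta, positions)
        rps = s_plus - s_minus
    else:
        s_plus = s_minus = rps = float("nan")
    return ShiftMetrics(
        protein=protein,
        effect_jsd=effect_size_jsd(profiles, protein),
        w_plus=w_plus,
        w_minus=w_minus,
        s_plus=s_plus,
        s_minus=s_minus,
        relative_fraction_shift=rps,
        relative_distribution_change=relative_distribution_change(
            profiles, protein
        ),
        mean_within_jsd_treatment=mean_within_jsd(profiles, protein, TREATMENT),
        mean_within_jsd_control=mean_within_jsd(profiles, protein, CONTROL),
        beta=beta,
    )
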