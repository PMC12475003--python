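"""Rank-based ANOSIM statistic, permutation nulls, p-values and the R cutoff.

For each protein the pairwise sample distances are midranked and the ANOSIM
statistic

    R = (rbar_B - rbar_W) / ((n (n - 1) / 2) / 2)

contrasts the mean rank of between-condition pairs (rbar_B) against the mean
rank of within-condition pairs (rbar_W); n is the total sample count.  R lies
in [-1, 1], with 1 meaning every between-condition distance exceeds every
within-condition distance.

With two balanced groups of n replicates there are only (2n)! / (2 (n!)^2)
distinct label assignments (10 for 3 vs 3), so per-protein ("local") exact
permutation p-values are floored at 1/10 — three replicates can never reach
p <= 0.05.  The "global" mode therefore pools permuted R values across all
testable proteins into one sampling null, from which per-protein p-values
(Benjamini-Hochberg adjusted) and a percentile-based R cutoff are derived.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .distance import DistanceMatrix

#: tolerance used when counting permuted R values >= the observed one
_R_TOL = 1e-12


def rank_dissimilarities(matrix: DistanceMatrix) -> np.ndarray:
    """Midranks (average ranks for ties) of the strictly-lower-triangle distances."""
    return rankdata(matrix.condensed(), method="average")


def anosim_r_from_ranks(ranks: np.ndarray, between: np.ndarray, n: int) -> float:
    rb = ranks[between].mean()
    rw = ranks[~between].mean()
    return float((rb - rw) / ((n * (n - 1) / 2) / 2))


def anosim_r(matrix: DistanceMatrix, is_treatment: np.ndarray | None = None) -> float:
    """ANOSIM R for a two-group distance matrix (each group needs >= 2 samples)."""
    labels = matrix.is_treatment if is_treatment is None else np.asarray(is_treatment, bool)
    n = matrix.n_samples
    n_t = int(labels.sum())
    if n_t < 2 or n - n_t < 2:
        raise ValueError(
            f"both groups need >= 2 samples, got {n_t} vs {n - n_t}"
        )
    i, j = np.tril_indices(n, k=-1)
    between = labels[i] != labels[j]
    ranks = rankdata(matrix.condensed(), method="average")
    return anosim_r_from_ranks(ranks, between, n)


def n_distinct_assignments(n_treatment: int, n_control: int) -> int:
    """Closed-form count of distinct two-group label assignments.

    Balanced designs: (2n)! / (2 (n!)^2) — a group-label swap yields the same
    partition.  Unbalanced designs: the binomial coefficient C(n_t+n_c, n_t).
    """
    if n_treatment == n_control:
        n = n_treatment
        return math.factorial(2 * n) // (2 * math.factorial(n) ** 2)
    return math.comb(n_treatment + n_control, n_treatment)


def enumerate_label_assignments(
    n_treatment: int, n_control: int
) -> np.ndarray:
    """All distinct assignments of n samples to the two groups, identity first.

    Samples are indexed with the treatment samples first (0..n_t-1).  Each row
    is a boolean vector (True = treatment).  For balanced designs assignments
    that differ only by a group-label swap are collapsed by keeping the
    assignment that places sample 0 in the treatment group.
    """
    if n_treatment < 2 or n_control < 2:
        raise ValueError("both groups need >= 2 samples")
    n = n_treatment + n_control
    balanced = n_treatment == n_control
    rows = []
    for combo in itertools.combinations(range(n), n_treatment):
        if balanced and 0 not in combo:
            continue
        v = np.zeros(n, dtype=bool)
        v[list(combo)] = True
        rows.append(v)
    out = np.asarray(rows)
    identity = np.zeros(n, dtype=bool)
    identity[:n_treatment] = True
    idx = int(np.flatnonzero((out == identity).all(axis=1))[0])
    if idx != 0:
        out[[0, idx]] = out[[idx, 0]]
    return out


def _sample_assignments(
    n_treatment: int, n_control: int, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform random label assignments (may repeat; identity not excluded)."""
    n = n_treatment + n_control
    rows = np.zeros((n_draws, n), dtype=bool)
    for k in range(n_draws):
        rows[k, rng.choice(n, size=n_treatment, replace=False)] = True
    return rows


def permuted_r_values(
    matrix: DistanceMatrix, assignments: np.ndarray
) -> np.ndarray:
    """R for every label assignment; ranks are computed once (rank-based statistic)."""
    n = matrix.n_samples
    ranks = rankdata(matrix.condensed(), method="average")
    i, j = np.tril_indices(n, k=-1)
    out = np.empty(len(assignments))
    for k, labels in enumerate(assignments):
        between = labels[i] != labels[j]
        out[k] = anosim_r_from_ranks(ranks, between, n)
    return out


def local_permutation_pvalue(
    matrix: DistanceMatrix,
    *,
    mode: str = "exact",
    n_monte_carlo: int = 999,
    exact_limit: int = 10_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, int]:
    """Per-protein permutation p-value: share of assignments with R >= observed.

    The identity assignment is always included, so p >= 1/#assignments and is
    never 0.  Monte-Carlo mode evaluates ``n_monte_carlo`` seeded draws plus
    the identity.  Returns (R_observed, p, n_assignments_used).
    """
    labels = matrix.is_treatment
    n_t, n_c = int(labels.sum()), int((~labels).sum())
    n_exact = n_distinct_assignments(n_t, n_c)
    use_exact = mode == "exact" and n_exact <= exact_limit
    if use_exact:
        assignments = enumerate_label_assignments(n_t, n_c)
    else:
        if rng is None:
            rng = np.random.default_rng()
        identity = np.zeros(n_t + n_c, dtype=bool)
        identity[:n_t] = True
        assignments = np.vstack(
            [identity, _sample_assignments(n_t, n_c, n_monte_carlo, rng)]
        )
    r = permuted_r_values(matrix, assignments)
    r_obs = r[0]
    p = float((r >= r_obs - _R_TOL).sum() / len(r))
    return float(r_obs), p, len(r)


@dataclass
class NullDistribution:
    """Pooled permutation R values across proteins (the global sampling null)."""

    values: np.ndarray
    mode: str  # "exact" or "monte_carlo"
    seed: int | None = None
    include_identity: bool = False
    n_proteins: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def size(self) -> int:
        return self.values.size


def global_null_distribution(
    matrices: dict[str, DistanceMatrix],
    *,
    mode: str = "exact",
    n_monte_carlo: int = 999,
    exact_limit: int = 10_000,
    include_identity: bool = False,
    seed: int | None = None,
) -> NullDistribution:
    """Pool permuted R values over all testable proteins into one null.

    Exact enumeration is used when the per-protein assignment count is at most
    ``exact_limit`` (identity excluded by default — the observed labelling may
    carry true signal); otherwise seeded Monte-Carlo draws are pooled.
    """
    if not matrices:
        raise ValueError("no testable proteins: cannot build a null")
    rng = np.random.default_rng(seed)
    pooled: list[np.ndarray] = []
    used_mode = "exact"
    for protein, mat in matrices.items():
        labels = mat.is_treatment
        n_t, n_c = int(labels.sum()), int((~labels).sum())
        n_exact = n_distinct_assignments(n_t, n_c)
        if mode == "exact" and n_exact <= exact_limit:
            assignments = enumerate_label_assignments(n_t, n_c)
            if not include_identity:
                assignments = assignments[1:]
        else:
            used_mode = "monte_carlo"
            assignments = _sample_assignments(n_t, n_c, n_monte_carlo, rng)
        pooled.append(permuted_r_values(mat, assignments))
    return NullDistribution(
        values=np.concatenate(pooled),
        mode=used_mode if mode == "exact" else "monte_carlo",
        seed=seed,
        include_identity=include_identity,
        n_proteins=len(matrices),
    )


def global_pvalues(
    r_observed: np.ndarray, null: NullDistribution
) -> tuple[np.ndarray, np.ndarray]:
    """Per-protein global p-values and their Benjamini-Hochberg adjustment.

    Uses the add-one estimator p = (1 + #{null >= R}) / (1 + N), which keeps
    p in (0, 1].  NaN R values (untestable proteins) yield NaN p-values and
    are excluded from the BH denominator.
    """
    if null.size == 0:
        raise ValueError("empty null distribution")
    r_observed = np.asarray(r_observed, dtype=float)
    sorted_null = np.sort(null.values)
    p = np.full(r_observed.shape, np.nan)
    ok = ~np.isnan(r_observed)
    # count null values >= R_i via searchsorted on the sorted null
    n_ge = null.size - np.searchsorted(
        sorted_null, r_observed[ok] - _R_TOL, side="left"
    )
    p[ok] = (1.0 + n_ge) / (1.0 + null.size)
    p_adj = np.full(r_observed.shape, np.nan)
    if ok.any():
        p_adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return p, p_adj


def r_cutoff(null: NullDistribution, percentile: float) -> float:
    """Linear-interpolation percentile of the pooled null R values."""
    if null.size == 0:
        raise ValueError("empty null distribution")
    return float(np.percentile(null.values, percentile, method="linear"))
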