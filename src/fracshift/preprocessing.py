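"""Smoothing and normalization of raw intensity rows into probability profiles.

Each replicate's intensity vector over fractions is smoothed with a uniform
averaging kernel (zero-padded at the gradient boundaries), then normalized to
sum to 1, turning it into a probability distribution P_j(x) over fractions.
Per-condition mean distributions are arithmetic means of the valid replicate
profiles.  Samples whose smoothed vector is all zero are flagged invalid; a
protein with fewer than two valid samples in either condition is untestable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import CONTROL, TREATMENT, AnalysisConfig, ConfigError, Dataset, FractionAxis, SampleDesign

SUM_TOL = 1e-9


def smooth_profile(raw: np.ndarray, kernel_size: int) -> np.ndarray:
    """Uniform moving average of odd width ``kernel_size`` with zero padding.

    ``kernel_size=1`` is the identity.  Mass in the outer floor(kernel/2)
    fractions leaks into the (zero) padding and is lost here; the subsequent
    normalization restores unit mass.
    """
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ConfigError(
            f"kernel_size must be odd and >= 1, got {kernel_size}"
        )
    raw = np.asarray(raw, dtype=float)
    if kernel_size == 1:
        return raw.copy()
    kernel = np.full(kernel_size, 1.0 / kernel_size)
    return np.convolve(raw, kernel, mode="same")


def normalize_profile(smoothed: np.ndarray) -> np.ndarray | None:
    """Divide by the vector sum; an all-zero vector yields None (invalid sample)."""
    smoothed = np.asarray(smoothed, dtype=float)
    total = smoothed.sum()
    if total <= 0:
        return None
    return smoothed / total


@dataclass
class ProfileSet:
    """Normalized replicate profiles and per-condition means for every protein.

    ``profiles[cond]`` has shape (n_proteins, n_reps, F); rows of invalid
    samples are NaN and excluded from the means.  ``means[cond]`` holds
    arithmetic means over the *valid* replicate profiles only, so they stay on
    the probability simplex even when a replicate drops out.
    """

    proteins: tuple[str, ...]
    profiles: dict[str, np.ndarray]
    valid: dict[str, np.ndarray]  # (n_proteins, n_reps) bool
    means: dict[str, np.ndarray]  # (n_proteins, F)
    testable: np.ndarray  # (n_proteins,) bool
    reasons: tuple[str, ...]  # empty string when testable
    axis: FractionAxis
    design: SampleDesign

    def index_of(self, protein: str) -> int:
        try:
            return self.proteins.index(protein)
        except ValueError:
            raise KeyError(f"unknown protein {protein!r}") from None

    def n_valid(self, protein: str) -> dict[str, int]:
        i = self.index_of(protein)
        return {c: int(self.valid[c][i].sum()) for c in (TREATMENT, CONTROL)}

    def replicate_profiles(self, protein: str) -> tuple[np.ndarray, np.ndarray]:
        """Stacked valid replicate profiles and their condition labels.

        Returns (profiles, labels): profiles has one row per valid sample,
        treatment samples first; labels is a boolean array, True = treatment.
        """
        i = self.index_of(protein)
        rows, labs = [], []
        for cond, is_treat in ((TREATMENT, True), (CONTROL, False)):
            for j in np.flatnonzero(self.valid[cond][i]):
                rows.append(self.profiles[cond][i, j])
                labs.append(is_treat)
        return np.asarray(rows), np.asarray(labs, dtype=bool)


def build_profileset(dataset: Dataset, config: AnalysisConfig) -> ProfileSet:
    """Missing->0, smoothing, normalization per sample; means over valid samples.

    Missing intensities are treated as zero signal at this point (absence of
    MS evidence is taken as absence of protein in that fraction).  In
    categorical mode the kernel is forced to 1, i.e. smoothing is disabled.
    """
    config = config.for_axis(dataset.axis)
    P, F = dataset.n_proteins, dataset.axis.n_fractions

    profiles: dict[str, np.ndarray] = {}
    valid: dict[str, np.ndarray] = {}
    for cond in (TREATMENT, CONTROL):
        raw = np.nan_to_num(dataset.intensities[cond], nan=0.0)
        n_rep = raw.shape[1]
        prof = np.full((P, n_rep, F), np.nan)
        ok = np.zeros((P, n_rep), dtype=bool)
        for i in range(P):
            for j in range(n_rep):
                v = normalize_profile(smooth_profile(raw[i, j], config.kernel_size))
                if v is not None:
                    prof[i, j] = v
                    ok[i, j] = True
        profiles[cond] = prof
        valid[cond] = ok

    means: dict[str, np.ndarray] = {}
    for cond in (TREATMENT, CONTROL):
        m = np.full((P, F), np.nan)
        any_valid = valid[cond].any(axis=1)
        if any_valid.any():
            m[any_valid] = np.nanmean(profiles[cond][any_valid], axis=1)
        means[cond] = m

    testable = np.ones(P, dtype=bool)
    reasons = []
    for i in range(P):
        why = []
        for cond in (TREATMENT, CONTROL):
            n_ok = int(valid[cond][i].sum())
            if n_ok < 2:
                why.append(f"fewer than 2 valid samples in {cond} ({n_ok})")
        if why:
            testable[i] = False
        reasons.append("; ".join(why))

    return ProfileSet(
        proteins=dataset.proteins,
        profiles=profiles,
        valid=valid,
        means=means,
        testable=testable,
        reasons=tuple(reasons),
        axis=dataset.axis,
        design=dataset.design,
    )
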