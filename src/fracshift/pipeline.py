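"""End-to-end analysis: preprocessing -> distances -> ANOSIM -> shift metrics -> ranking."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import anosim as _anosim
from .data import CONTROL, TREATMENT, AnalysisConfig, Dataset
from .distance import DistanceMatrix, pairwise_distance_matrix
from .preprocessing import ProfileSet, build_profileset
from .ranking import rank_proteins
from .shifts import compute_shift_metrics

logger = logging.getLogger("fracshift")


@dataclass
class AnalysisResult:
    """Everything one analysis run produces."""

    ranked: pd.DataFrame
    profiles: ProfileSet
    null: _anosim.NullDistribution
    r_cutoff: float
    config: AnalysisConfig
    matrices: dict[str, DistanceMatrix]


def analyze_dataset(dataset: Dataset, config: AnalysisConfig) -> AnalysisResult:
    """Run the full workflow on a dataset and return ranked results.

    Missing intensities are treated as zero signal before smoothing (the tool
    performs no imputation); a warning is logged when any are present.
    """
    config = config.for_axis(dataset.axis)
    n_missing = sum(
        int(np.isnan(dataset.intensities[c]).sum()) for c in (TREATMENT, CONTROL)
    )
    if n_missing:
        logger.warning(
            "%d missing intensity cells treated as zero signal (no imputation)",
            n_missing,
        )

    profiles = build_profileset(dataset, config)
    testable_ids = [
        p for i, p in enumerate(profiles.proteins) if profiles.testable[i]
    ]
    logger.info(
        "%d proteins read, %d testable", len(profiles.proteins), len(testable_ids)
    )

    matrices = {
        p: pairwise_distance_matrix(profiles, p) for p in testable_ids
    }

    rows = []
    rng = np.random.default_rng(config.seed)
    for i, protein in enumerate(profiles.proteins):
        row: dict = {
            "protein_id": protein,
            "testable_flag": bool(profiles.testable[i]),
            "reason": profiles.reasons[i],
        }
        if profiles.testable[i]:
            mat = matrices[protein]
            r_obs, p_local, n_used = _anosim.local_permutation_pvalue(
                mat,
                mode=config.permutation_mode,
                n_monte_carlo=config.n_monte_carlo,
                exact_limit=config.exact_limit,
                rng=rng,
            )
            sm = compute_shift_metrics(profiles, protein, config.beta)
            row.update(
                anosim_r=r_obs,
                p_local=p_local,
                n_permutations_used=n_used,
                effect_jsd=sm.effect_jsd,
                relative_fraction_shift=sm.relative_fraction_shift,
                relative_distribution_change=sm.relative_distribution_change,
                mean_within_jsd_treatment=sm.mean_within_jsd_treatment,
                mean_within_jsd_control=sm.mean_within_jsd_control,
            )
        else:
            row.update(
                anosim_r=np.nan,
                p_local=np.nan,
                n_permutations_used=0,
                effect_jsd=np.nan,
                relative_fraction_shift=np.nan,
                relative_distribution_change=np.nan,
                mean_within_jsd_treatment=np.nan,
                mean_within_jsd_control=np.nan,
            )
        rows.append(row)
    stats = pd.DataFrame(rows)

    null = _anosim.global_null_distribution(
        matrices,
        mode=config.permutation_mode,
        n_monte_carlo=config.n_monte_carlo,
        exact_limit=config.exact_limit,
        include_identity=config.include_identity_in_null,
        seed=config.seed,
    )
    p_global, p_adj = _anosim.global_pvalues(
        stats["anosim_r"].to_numpy(), null
    )
    stats["p_global"] = p_global
    stats["p_adj"] = p_adj

    ranked = rank_proteins(stats)
    cutoff = _anosim.r_cutoff(null, config.cutoff_percentile)
    n_pass = int(
        (ranked["testable_flag"] & (ranked["anosim_r"] >= cutoff)).sum()
    )
    logger.info(
        "R cutoff at percentile %.4g: %.6g (%d proteins pass)",
        config.cutoff_percentile,
        cutoff,
        n_pass,
    )
    return AnalysisResult(
        ranked=ranked,
        profiles=profiles,
        null=null,
        r_cutoff=cutoff,
        config=config,
        matrices=matrices,
    )
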