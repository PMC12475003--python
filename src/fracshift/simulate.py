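"""Synthetic fractionation datasets with known ground truth.

The generator emulates the statistical structure of gradient-fractionation
profiles: each protein sediments as a localized bell-shaped peak; treatment
moves a portion phi of the protein's mass by a signed shift distance delta
(optionally broadening the moved peak); replicates are noisy compositional
versions of the condition mean, drawn from a Dirichlet distribution centred on
it (perturb-and-renormalize on the simplex rather than additive noise, since
profiles are compositional after normalization); whole replicate profiles can
go missing.  The ground truth (which proteins shifted, by how much) makes
every pipeline stage testable without real data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import (
    CONTROL,
    TREATMENT,
    ConfigError,
    Dataset,
    DesignEntry,
    FractionAxis,
    SampleDesign,
)

#: floor added to Dirichlet concentrations so zero-mass fractions stay valid
_ALPHA_FLOOR = 1e-8


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults emulate a bacterial gradient-fractionation screen: 20 fractions,
    3 replicates per condition, 20% of proteins redistributing leftward by 4
    fractions with their full mass, peaks ~1.5 fractions wide, mild replicate
    noise (Dirichlet concentration 150), no missing samples unless asked.
    """

    n_proteins: int = 100
    n_fractions: int = 20
    n_treatment: int = 3
    n_control: int = 3
    fraction_shifted: float = 0.2
    shift: float = -4.0  # signed shift distance delta, in fractions
    mass_fraction: float = 1.0  # phi: portion of mass that moves
    peak_width: float = 1.5  # sigma of the bell-shaped peak, in fractions
    broadening: float = 1.0  # width multiplier of the moved peak
    noise: float | None = 150.0  # Dirichlet concentration; None = noiseless
    missing_rate: float = 0.0  # probability a replicate profile is missing
    intensity_scale: float = 1e7
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_proteins, self.n_fractions, self.n_treatment, self.n_control) < 1:
            raise ConfigError("all counts must be positive")
        if not (0 < self.mass_fraction <= 1):
            raise ConfigError("mass_fraction must lie in (0, 1]")
        if not (self.peak_width > 0):
            raise ConfigError("peak_width must be positive")
        if not (0 <= self.fraction_shifted <= 1):
            raise ConfigError("fraction_shifted must lie in [0, 1]")
        if abs(self.shift) >= self.n_fractions - 1:
            raise ConfigError(
                f"shift={self.shift} pushes all mass outside the "
                f"{self.n_fractions}-fraction range"
            )


def _peak(positions: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Discretized bell-shaped density, clipped to the grid and renormalized."""
    p = np.exp(-0.5 * ((positions - mu) / sigma) ** 2)
    return p / p.sum()


def simulate_dataset(config: SimulationConfig) -> tuple[Dataset, pd.DataFrame]:
    """Generate a dataset plus its truth table; bit-identical for a given seed.

    Truth table columns: protein_id, shifted, delta, mass_fraction,
    broadening.
    """
    rng = np.random.default_rng(config.seed)
    F = config.n_fractions
    positions = np.arange(1, F + 1, dtype=float)

    n_shift = round(config.n_proteins * config.fraction_shifted)
    shifted = np.zeros(config.n_proteins, dtype=bool)
    shifted[rng.permutation(config.n_proteins)[:n_shift]] = True

    # control peak centres; for shifted proteins the moved peak must stay in range
    lo, hi = 1.0, float(F)
    lo_s = max(lo, lo - config.shift)
    hi_s = min(hi, hi - config.shift)
    if lo_s >= hi_s:
        raise ConfigError(
            f"shift={config.shift} leaves no valid peak position in 1..{F}"
        )

    reps = {TREATMENT: config.n_treatment, CONTROL: config.n_control}
    intensities = {
        c: np.empty((config.n_proteins, n, F)) for c, n in reps.items()
    }
    truth_rows = []
    for i in range(config.n_proteins):
        if shifted[i]:
            mu = rng.uniform(lo_s, hi_s)
            base = _peak(positions, mu, config.peak_width)
            moved = _peak(
                positions, mu + config.shift, config.peak_width * config.broadening
            )
            treated_mean = (
                1 - config.mass_fraction
            ) * base + config.mass_fraction * moved
        else:
            mu = rng.uniform(lo, hi)
            base = _peak(positions, mu, config.peak_width)
            treated_mean = base
        means = {TREATMENT: treated_mean, CONTROL: base}
        for cond, n_rep in reps.items():
            for j in range(n_rep):
                if config.noise is None:
                    # noiseless replicates are bit-identical copies of the
                    # condition mean (no scale jitter either), so distances
                    # between them are exactly zero
                    row = means[cond] * config.intensity_scale
                else:
                    prof = rng.dirichlet(
                        config.noise * means[cond] + _ALPHA_FLOOR
                    )
                    total = config.intensity_scale * rng.lognormal(0.0, 0.25)
                    row = prof * total
                if rng.random() < config.missing_rate:
                    row = np.full(F, np.nan)
                intensities[cond][i, j] = row
        truth_rows.append(
            {
                "protein_id": f"P{i:04d}",
                "shifted": bool(shifted[i]),
                "delta": config.shift if shifted[i] else 0.0,
                "mass_fraction": config.mass_fraction if shifted[i] else 0.0,
                "broadening": config.broadening if shifted[i] else 1.0,
            }
        )

    labels = tuple(f"F{k}" for k in range(1, F + 1))
    axis = FractionAxis(labels=labels, mode="continuous")
    entries = []
    for cond, n_rep in reps.items():
        for j in range(1, n_rep + 1):
            for frac in labels:
                entries.append(
                    DesignEntry(
                        sample=f"{cond}_rep{j}_{frac}",
                        condition=cond,
                        replicate=j,
                        fraction=frac,
                    )
                )
    design = SampleDesign(
        entries=tuple(entries),
        axis=axis,
        condition_names={TREATMENT: TREATMENT, CONTROL: CONTROL},
    )
    dataset = Dataset(
        proteins=tuple(f"P{i:04d}" for i in range(config.n_proteins)),
        intensities=intensities,
        axis=axis,
        design=design,
    )
    return dataset, pd.DataFrame(truth_rows)


def write_simulation(
    dataset: Dataset, truth: pd.DataFrame, outdir: str | Path
) -> dict[str, Path]:
    """Write intensities.tsv, design.tsv and truth.tsv in the tool's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design_rows = [
        {
            "sample": e.sample,
            "condition": dataset.design.condition_names[e.condition],
            "replicate": e.replicate,
            "fraction": e.fraction,
        }
        for e in dataset.design.entries
    ]
    design_path = outdir / "design.tsv"
    pd.DataFrame(design_rows).to_csv(design_path, sep="\t", index=False)

    table = {"protein_id": list(dataset.proteins)}
    for e in dataset.design.entries:
        cond_reps = dataset.design.replicates[e.condition]
        j = cond_reps.index(e.replicate)
        k = dataset.axis.labels.index(e.fraction)
        table[e.sample] = dataset.intensities[e.condition][:, j, k]
    intens_path = outdir / "intensities.tsv"
    pd.DataFrame(table).to_csv(
        intens_path, sep="\t", index=False, float_format="%.12g"
    )

    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return {"intensities": intens_path, "design": design_path, "truth": truth_path}


def benchmark_ranking(
    ranked: pd.DataFrame, truth: pd.DataFrame
) -> dict[str, float]:
    """AUROC of the rank ordering against shifted/unshifted truth labels.

    The score of a protein is its position in the ranked table (untestable
    proteins trail the testable ones, as ranked).  AUROC is the probability
    that a randomly chosen shifted protein is ranked above a randomly chosen
    unshifted one (ties count half).  Also reports the median rank position
    per group.  Degenerate truth (all one class) yields NaN AUROC.
    """
    order = ranked[["protein_id"]].copy()
    order["position"] = np.arange(1, len(order) + 1)
    merged = order.merge(truth[["protein_id", "shifted"]], on="protein_id")
    y = merged["shifted"].to_numpy(bool)
    pos = merged["position"].to_numpy(float)
    n1, n0 = int(y.sum()), int((~y).sum())
    out = {
        "median_position_shifted": float(np.median(pos[y])) if n1 else float("nan"),
        "median_position_unshifted": float(np.median(pos[~y])) if n0 else float("nan"),
    }
    if n1 == 0 or n0 == 0:
        out["auroc"] = float("nan")
        return out
    # Mann-Whitney formulation on the negated position (higher = better rank)
    r = rankdata(-pos, method="average")
    out["auroc"] = float((r[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))
    return out
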