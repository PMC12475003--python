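"""Core data model and tabular I/O.

A fractionation experiment measures, for every protein, an intensity in each
fraction of a gradient (or each subcellular compartment) for several replicates
of two conditions (treatment vs. control).  This module defines the in-memory
containers for such data and reads/writes the delimited-text formats the tool
consumes and produces:

* a *design table* mapping each measurement column to (condition, replicate,
  fraction),
* an *intensity table* with one row per protein and one column per design
  entry,
* the ranked *results table* and a self-contained JSON export.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SCHEMA_VERSION = "1.0"

#: Canonical condition keys used throughout the package.
TREATMENT = "treatment"
CONTROL = "control"

RESULT_COLUMNS = [
    "protein_id",
    "anosim_r",
    "effect_jsd",
    "relative_fraction_shift",
    "relative_distribution_change",
    "rank",
    "p_global",
    "p_adj",
    "testable_flag",
]


class FormatError(ValueError):
    """Raised when an input file violates the documented format."""


class ConfigError(ValueError):
    """Raised when an analysis or simulation configuration is invalid."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FractionAxis:
    """Ordered fraction labels with integer coordinates 1..F.

    ``mode`` is ``"continuous"`` for gradient fractions (positions carry
    meaning, smoothing and shift positions apply) or ``"categorical"`` for
    unordered compartment bins (smoothing disabled, shift positions
    undefined).
    """

    labels: tuple[str, ...]
    mode: str = "continuous"

    def __post_init__(self) -> None:
        if self.mode not in ("continuous", "categorical"):
            raise ConfigError(f"unknown fraction mode {self.mode!r}")
        if len(self.labels) < 2:
            raise FormatError("a fraction axis needs at least 2 fractions")
        if len(set(self.labels)) != len(self.labels):
            raise FormatError("fraction labels must be unique")
        if any(not str(l) for l in self.labels):
            raise FormatError("fraction labels must be non-empty")

    @property
    def n_fractions(self) -> int:
        return len(self.labels)

    @property
    def positions(self) -> np.ndarray:
        """Integer coordinates 1..F (continuous mode only)."""
        if self.mode != "continuous":
            raise ConfigError("positions are undefined for a categorical axis")
        return np.arange(1, len(self.labels) + 1, dtype=float)


@dataclass(frozen=True)
class DesignEntry:
    sample: str  # measurement column name in the intensity table
    condition: str  # TREATMENT or CONTROL (canonical)
    replicate: int
    fraction: str


@dataclass(frozen=True)
class SampleDesign:
    """Validated mapping of measurement columns to (condition, replicate, fraction).

    Every (condition, replicate) pair covers every fraction exactly once,
    there are exactly two conditions, and each condition has at least two
    replicates.  Condition labels from the input file are remembered in
    ``condition_names`` for reporting; internally the canonical keys
    ``"treatment"`` / ``"control"`` are used.
    """

    entries: tuple[DesignEntry, ...]
    axis: FractionAxis
    condition_names: Mapping[str, str]  # canonical -> original label

    @property
    def replicates(self) -> dict[str, tuple[int, ...]]:
        out: dict[str, list[int]] = {TREATMENT: [], CONTROL: []}
        for e in self.entries:
            if e.replicate not in out[e.condition]:
                out[e.condition].append(e.replicate)
        return {c: tuple(sorted(r)) for c, r in out.items()}

    @property
    def n_treatment(self) -> int:
        return len(self.replicates[TREATMENT])

    @property
    def n_control(self) -> int:
        return len(self.replicates[CONTROL])

    def columns_for(self, condition: str, replicate: int) -> list[str]:
        """Measurement columns of one sample, in fraction-axis order."""
        by_frac = {
            e.fraction: e.sample
            for e in self.entries
            if e.condition == condition and e.replicate == replicate
        }
        return [by_frac[f] for f in self.axis.labels]


def _validate_design(
    entries: Sequence[DesignEntry], axis: FractionAxis
) -> None:
    seen: set[tuple[str, int, str]] = set()
    for e in entries:
        key = (e.condition, e.replicate, e.fraction)
        if key in seen:
            raise FormatError(
                f"duplicate design row for condition={e.condition!r}, "
                f"replicate={e.replicate}, fraction={e.fraction!r} "
                f"(sample {e.sample!r})"
            )
        seen.add(key)
    samples = [e.sample for e in entries]
    if len(set(samples)) != len(samples):
        raise FormatError("duplicate sample column name in design")
    reps: dict[str, set[int]] = {TREATMENT: set(), CONTROL: set()}
    for e in entries:
        reps[e.condition].add(e.replicate)
    for cond, rset in reps.items():
        if len(rset) < 2:
            raise FormatError(
                f"condition {cond!r} has {len(rset)} replicate(s); "
                "at least 2 are required for testing"
            )
        for r in sorted(rset):
            fracs = {
                e.fraction
                for e in entries
                if e.condition == cond and e.replicate == r
            }
            if fracs != set(axis.labels):
                missing = sorted(set(axis.labels) - fracs)
                extra = sorted(fracs - set(axis.labels))
                raise FormatError(
                    f"incomplete sample (condition={cond!r}, replicate={r}): "
                    f"missing fractions {missing}, unexpected {extra}"
                )


@dataclass
class Dataset:
    """Per-protein intensity tensor over (condition, replicate, fraction).

    ``intensities[cond]`` has shape (n_proteins, n_replicates, n_fractions);
    missing measurements are NaN (never silently zero at read time).
    """

    proteins: tuple[str, ...]
    intensities: dict[str, np.ndarray]
    axis: FractionAxis
    design: SampleDesign
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(set(self.proteins)) != len(self.proteins):
            raise FormatError("protein identifiers must be unique")
        for cond in (TREATMENT, CONTROL):
            arr = self.intensities[cond]
            n_rep = len(self.design.replicates[cond])
            expected = (len(self.proteins), n_rep, self.axis.n_fractions)
            if arr.shape != expected:
                raise FormatError(
                    f"intensity tensor for {cond} has shape {arr.shape}, "
                    f"expected {expected}"
                )
            with np.errstate(invalid="ignore"):
                if np.any(arr < 0):
                    raise FormatError("negative intensity in dataset")

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the analysis.

    kernel_size
        Width of the uniform averaging kernel used to smooth profiles along
        the fraction axis; odd, >= 1.  Forced to 1 in categorical mode.
    beta
        Temperature of the soft-argmax used to localize the strongest shift;
        larger values approach a hard argmax.
    permutation_mode
        ``"exact"`` enumerates all distinct label assignments when their
        count is at most ``exact_limit``; ``"monte_carlo"`` always samples
        ``n_monte_carlo`` seeded assignments.
    cutoff_percentile
        Percentile of the pooled permutation null of R used to derive the
        candidate cutoff (default 95).
    include_identity_in_null
        Whether the observed labelling contributes to the pooled null
        (default False: the observed labelling may carry true signal).
    """

    kernel_size: int = 3
    beta: float = 1.0
    permutation_mode: str = "exact"
    n_monte_carlo: int = 999
    exact_limit: int = 10_000
    seed: int = 0
    cutoff_percentile: float = 95.0
    alpha: float = 0.05
    include_identity_in_null: bool = False

    #: logarithm base is fixed: base 2 keeps the Jensen-Shannon distance in [0, 1]
    log_base: int = 2

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ConfigError(
                f"kernel_size must be an odd positive integer, got {self.kernel_size}"
            )
        if not (self.beta > 0):
            raise ConfigError(f"beta must be positive, got {self.beta}")
        if self.permutation_mode not in ("exact", "monte_carlo"):
            raise ConfigError(
                f"permutation_mode must be 'exact' or 'monte_carlo', "
                f"got {self.permutation_mode!r}"
            )
        if not (0 < self.cutoff_percentile <= 100):
            raise ConfigError("cutoff_percentile must lie in (0, 100]")
        if self.log_base != 2:
            raise ConfigError("log_base is fixed to 2")

    def for_axis(self, axis: FractionAxis) -> "AnalysisConfig":
        """Return a config adjusted to the axis (kernel forced to 1 when categorical)."""
        if axis.mode == "categorical" and self.kernel_size != 1:
            return dataclasses.replace(self, kernel_size=1)
        return self


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_delim(path: str | Path) -> pd.DataFrame:
    """Read a CSV or TSV file, sniffing the delimiter from the extension."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_design(
    path: str | Path,
    *,
    treatment_label: str | None = None,
    mode: str = "continuous",
) -> SampleDesign:
    """Read and validate a design table.

    The file must have header columns ``sample``, ``condition``,
    ``replicate``, ``fraction``.  Fraction order is taken from first
    appearance unless an ``order`` column gives explicit integer positions.
    Exactly two condition labels must occur; ``treatment_label`` nominates
    which one is the treatment (required unless the labels are literally
    ``treatment``/``control``).
    """
    df = _read_delim(path)
    required = {"sample", "condition", "replicate", "fraction"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"design file lacks columns: {sorted(missing)}")

    conditions = list(dict.fromkeys(df["condition"]))
    if len(conditions) != 2:
        raise FormatError(
            f"design must contain exactly two condition labels, "
            f"found {conditions}"
        )
    if treatment_label is None:
        if set(conditions) == {TREATMENT, CONTROL}:
            treatment_label = TREATMENT
        else:
            raise FormatError(
                f"conditions are {conditions}; pass treatment_label to say "
                "which one is the treatment"
            )
    if treatment_label not in conditions:
        raise FormatError(
            f"treatment_label {treatment_label!r} not among conditions "
            f"{conditions}"
        )
    control_label = next(c for c in conditions if c != treatment_label)
    canon = {treatment_label: TREATMENT, control_label: CONTROL}

    if "order" in df.columns:
        order = df[["fraction", "order"]].drop_duplicates()
        order["order"] = order["order"].astype(int)
        labels = tuple(order.sort_values("order")["fraction"])
    else:
        labels = tuple(dict.fromkeys(df["fraction"]))
    axis = FractionAxis(labels=labels, mode=mode)

    entries = tuple(
        DesignEntry(
            sample=row["sample"],
            condition=canon[row["condition"]],
            replicate=int(row["replicate"]),
            fraction=row["fraction"],
        )
        for _, row in df.iterrows()
    )
    _validate_design(entries, axis)
    return SampleDesign(
        entries=entries,
        axis=axis,
        condition_names={TREATMENT: treatment_label, CONTROL: control_label},
    )


#: cell contents treated as missing in intensity tables
_MISSING_TOKENS = {"", "na", "nan", "n/a", "null"}


def read_intensity_table(
    path: str | Path,
    design: SampleDesign,
    *,
    key_column: str | None = None,
) -> Dataset:
    """Read a protein x sample-fraction intensity table against a design.

    The first column (or ``key_column``) holds unique protein identifiers;
    every design entry must match a column by exact name.  Empty cells and
    the usual NA spellings are stored as missing, not zero.  Negative
    intensities are rejected with the offending protein and column named.
    Extra columns are kept as annotations.
    """
    df = _read_delim(path)
    if key_column is None:
        key_column = df.columns[0]
    if key_column not in df.columns:
        raise FormatError(f"key column {key_column!r} not in table")

    design_cols = [e.sample for e in design.entries]
    absent = [c for c in design_cols if c not in df.columns]
    if absent:
        raise FormatError(
            f"design columns absent from intensity table: {absent[:5]}"
        )

    proteins = tuple(df[key_column])
    if len(set(proteins)) != len(proteins):
        raise FormatError("duplicate protein identifiers in intensity table")

    def parse_cell(v: str, protein: str, col: str) -> float:
        if v.strip().lower() in _MISSING_TOKENS:
            return math.nan
        x = float(v)
        if x < 0:
            raise FormatError(
                f"negative intensity {x} for protein {protein!r} in column {col!r}"
            )
        return x

    F = design.axis.n_fractions
    intensities: dict[str, np.ndarray] = {}
    for cond in (TREATMENT, CONTROL):
        reps = design.replicates[cond]
        arr = np.empty((len(proteins), len(reps), F))
        for j, rep in enumerate(reps):
            cols = design.columns_for(cond, rep)
            for k, col in enumerate(cols):
                arr[:, j, k] = [
                    parse_cell(v, p, col) for v, p in zip(df[col], proteins)
                ]
        intensities[cond] = arr

    extra = [c for c in df.columns if c != key_column and c not in design_cols]
    annotations = df[extra].copy() if extra else None
    if annotations is not None:
        annotations.index = pd.Index(proteins, name=key_column)

    return Dataset(
        proteins=proteins,
        intensities=intensities,
        axis=design.axis,
        design=design,
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_results_table(results: pd.DataFrame, path: str | Path) -> None:
    """Write the ranked results as a TSV with a fixed, documented column set.

    Untestable proteins keep their row but with empty statistic cells.
    Floats are written with 12 significant digits so a round-trip read
    reproduces them.
    """
    out = results.loc[:, RESULT_COLUMNS].copy()
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df


def export_json(
    dataset: Dataset,
    results: pd.DataFrame,
    config: AnalysisConfig,
    path: str | Path,
    *,
    profiles: Mapping[str, np.ndarray] | None = None,
    means: Mapping[str, np.ndarray] | None = None,
    null_values: np.ndarray | None = None,
    r_cutoff: float | None = None,
) -> None:
    """Write a single self-contained JSON document of the analysis.

    Contains a schema version, the config echo, the fraction axis, the
    per-protein normalized profiles (replicates and condition means) when
    supplied, all per-protein statistics, and optionally the pooled
    permutation null (needed to recompute cutoffs later).
    """

    def arr(a):
        return np.where(np.isnan(a), None, a.round(12)).tolist()

    doc: dict = {
        "schema_version": SCHEMA_VERSION,
        "config": dataclasses.asdict(config),
        "fraction_axis": {
            "labels": list(dataset.axis.labels),
            "mode": dataset.axis.mode,
        },
        "condition_names": dict(dataset.design.condition_names),
        "results": json.loads(
            results.to_json(orient="records", double_precision=12)
        ),
    }
    if profiles is not None and means is not None:
        doc["profiles"] = {
            cond: arr(profiles[cond]) for cond in (TREATMENT, CONTROL)
        }
        doc["means"] = {
            cond: arr(means[cond]) for cond in (TREATMENT, CONTROL)
        }
        doc["proteins"] = list(dataset.proteins)
    if null_values is not None:
        doc["null_distribution"] = np.asarray(null_values).round(12).tolist()
    if r_cutoff is not None:
        doc["r_cutoff"] = r_cutoff
    Path(path).write_text(json.dumps(doc, indent=1))


def import_json(path: str | Path) -> dict:
    """Re-load a JSON export; ``results`` is returned as a DataFrame."""
    doc = json.loads(Path(path).read_text())
    doc["results"] = pd.DataFrame(doc["results"])
    if "null_distribution" in doc:
        doc["null_distribution"] = np.asarray(doc["null_distribution"], float)
    return doc
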