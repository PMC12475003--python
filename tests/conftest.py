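import numpy as np
import pytest

import fracshift as fs


def make_profileset(
    treatment_profiles, control_profiles, mode="continuous", labels=None
):
    """Build a one-protein ProfileSet directly from probability vectors."""
    tp = np.asarray(treatment_profiles, float)[None, :, :]
    cp = np.asarray(control_profiles, float)[None, :, :]
    F = tp.shape[2]
    labels = labels or tuple(f"F{k}" for k in range(1, F + 1))
    axis = fs.FractionAxis(labels=labels, mode=mode)
    entries = []
    for cond, arr in (("treatment", tp), ("control", cp)):
        for j in range(arr.shape[1]):
            for frac in labels:
                entries.append(
                    fs.DesignEntry(
                        sample=f"{cond}_{j + 1}_{frac}",
                        condition=cond,
                        replicate=j + 1,
                        fraction=frac,
                    )
                )
    design = fs.SampleDesign(
        entries=tuple(entries),
        axis=axis,
        condition_names={"treatment": "treatment", "control": "control"},
    )
    from fracshift.preprocessing import ProfileSet

    return ProfileSet(
        proteins=("prot",),
        profiles={"treatment": tp, "control": cp},
        valid={
            "treatment": np.ones((1, tp.shape[1]), bool),
            "control": np.ones((1, cp.shape[1]), bool),
        },
        means={"treatment": tp.mean(axis=1), "control": cp.mean(axis=1)},
        testable=np.ones(1, bool),
        reasons=("",),
        axis=axis,
        design=design,
    )


def make_dataset(intens_treatment, intens_control):
    """Build a one-protein Dataset directly from raw intensity rows."""
    tp = np.asarray(intens_treatment, float)[None, :, :]
    cp = np.asarray(intens_control, float)[None, :, :]
    F = tp.shape[2]
    labels = tuple(f"F{k}" for k in range(1, F + 1))
    axis = fs.FractionAxis(labels=labels, mode="continuous")
    entries = []
    for cond, arr in (("treatment", tp), ("control", cp)):
        for j in range(arr.shape[1]):
            for frac in labels:
                entries.append(
                    fs.DesignEntry(
                        sample=f"{cond}_{j + 1}_{frac}",
                        condition=cond,
                        replicate=j + 1,
                        fraction=frac,
                    )
                )
    design = fs.SampleDesign(
        entries=tuple(entries),
        axis=axis,
        condition_names={"treatment": "treatment", "control": "control"},
    )
    return fs.Dataset(
        proteins=("prot",),
        intensities={"treatment": tp, "control": cp},
        axis=axis,
        design=design,
    )


def distance_matrix_from(values, is_treatment):
    """Build a DistanceMatrix from a condensed lower-triangle value list."""
    is_treatment = np.asarray(is_treatment, bool)
    n = len(is_treatment)
    mat = np.zeros((n, n))
    i, j = np.tril_indices(n, k=-1)
    mat[i, j] = values
    mat[j, i] = values
    return fs.DistanceMatrix(
        protein="prot", matrix=mat, is_treatment=is_treatment
    )


def separated_3v3_matrix(within=0.1, between=0.2):
    """3v3 matrix where every between-condition distance exceeds every within one."""
    labels = np.array([True, True, True, False, False, False])
    n = 6
    mat = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d = between if labels[a] != labels[b] else within
            mat[a, b] = mat[b, a] = d
    return fs.DistanceMatrix(protein="prot", matrix=mat, is_treatment=labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_simplex(rng, n):
    v = rng.dirichlet(np.ones(n))
    return v
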