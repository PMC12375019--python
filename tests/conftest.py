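import numpy as np
import pandas as pd
import pytest

from hybridscan.aim import AimMatrix, SampleMeta


def make_matrix(states, chroms=None, positions=None, z_chrom="chrZ"):
    """Build a small AimMatrix from a dense (individuals x loci) array."""
    states = np.asarray(states, dtype=float)
    n_ind, n_loci = states.shape
    if chroms is None:
        chroms = ["chr1"] * n_loci
    if positions is None:
        positions = np.arange(1, n_loci + 1) * 1000
    loci = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "is_z": [c == z_chrom for c in chroms],
        }
    )
    ids = [f"i{k}" for k in range(n_ind)]
    return AimMatrix(states, loci, ids)


def make_meta(matrix, age=None, sex=None, q=None):
    n = matrix.n_individuals
    table = pd.DataFrame(
        {
            "age": age if age is not None else [0] * n,
            "sex": sex if sex is not None else ["F"] * n,
        },
        index=pd.Index(matrix.individual_ids, name="individual_id"),
    )
    meta = SampleMeta(table)
    meta = meta.with_summaries(matrix)
    if q is not None:
        meta.table["ancestry_q"] = q
    return meta


@pytest.fixture(scope="session")
def null_cohort():
    """Session-cached no-selection cohort (shared by calibration tests)."""
    from hybridscan.simulate import null_calibration_config, simulate_cohort

    return simulate_cohort(null_calibration_config(seed=5))


@pytest.fixture(scope="session")
def inversion_cohort():
    """Session-cached cohort with the planted inversion."""
    from hybridscan.simulate import inversion_recovery_config, simulate_cohort

    return simulate_cohort(inversion_recovery_config(seed=1))
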