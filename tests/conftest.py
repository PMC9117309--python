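import numpy as np
import pytest

from netcurv.connectivity import FCMatrix
from netcurv.synthetic import CohortSpec, generate_cohort


def random_fc(n: int, seed: int, subject_id: str = "S1") -> FCMatrix:
    """A random valid correlation matrix (Gram matrix of random vectors)."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, n + 5))
    mat = np.corrcoef(X)
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 1.0)
    np.clip(mat, -1.0, 1.0, out=mat)
    return FCMatrix(subject_id, mat, list(range(1, n + 1)))


@pytest.fixture
def fc10() -> FCMatrix:
    return random_fc(10, seed=42)


@pytest.fixture
def small_cohort():
    spec = CohortSpec(
        n_rois=24,
        n_subjects_per_group=6,
        n_blocks=3,
        within_block_mu=0.25,
        between_block_mu=0.1,
        group_effect=0.15,
        noise_sd=0.05,
        seed=11,
    )
    fcs, records = generate_cohort(spec)
    return spec, fcs, records
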