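import numpy as np
import pytest

from proteopair.io import IntensityMatrix, PairedDesign
from proteopair.synthetic_data import SyntheticConfig, generate_paired_proteome


@pytest.fixture
def small_design() -> PairedDesign:
    subjects = [f"S{i}" for i in range(1, 5)]
    pairs = {s: {"A": f"{s}_A", "B": f"{s}_B"} for s in subjects}
    return PairedDesign(subjects=subjects, condition_a="A", condition_b="B", pairs=pairs)


@pytest.fixture
def small_matrix(small_design) -> IntensityMatrix:
    rng = np.random.default_rng(42)
    samples = small_design.all_samples()
    values = rng.lognormal(3, 1, size=(6, len(samples)))
    values[rng.random(values.shape) < 0.3] = 0.0
    return IntensityMatrix(
        protein_ids=[f"P{i}" for i in range(6)],
        sample_ids=samples,
        values=values,
    )


@pytest.fixture
def small_synthetic():
    cfg = SyntheticConfig(
        n_subjects=6,
        n_proteins=50,
        n_unique_a=2,
        n_unique_b=3,
        unique_fractions_a=(0.9, 0.5),
        unique_fractions_b=(0.6, 0.5, 0.5),
        n_shifted=4,
        seed=7,
    )
    return generate_paired_proteome(cfg), cfg
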