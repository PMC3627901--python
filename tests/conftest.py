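import numpy as np
import pytest

from mlspls import OmicsMatrix, RepeatedMeasuresDesign


def make_crossover(
    n_subjects: int,
    conditions: tuple[str, ...],
    n_features: int,
    rng: np.random.Generator,
    subject_sd: float = 1.0,
    noise_sd: float = 0.1,
    condition_effects: np.ndarray | None = None,
) -> tuple[OmicsMatrix, RepeatedMeasuresDesign]:
    """Small balanced cross-over dataset: subject offsets + condition effects."""
    g = len(conditions)
    if condition_effects is None:
        condition_effects = np.zeros((g, n_features))
    rows, subj, cond = [], [], []
    for s in range(n_subjects):
        offset = rng.normal(0, subject_sd, n_features)
        for j, lab in enumerate(conditions):
            rows.append(
                condition_effects[j]
                + offset
                + rng.normal(0, noise_sd, n_features)
            )
            subj.append(f"s{s + 1}")
            cond.append(lab)
    ids = [f"{s}_{c}" for s, c in zip(subj, cond)]
    x = OmicsMatrix(
        np.asarray(rows), ids, [f"g{j + 1}" for j in range(n_features)]
    )
    design = RepeatedMeasuresDesign(subj, cond, sample_ids=ids).validate()
    return x, design


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def separable_toy(rng):
    """Two groups, one strongly informative feature, four near-zero noise ones."""
    effects = np.zeros((2, 5))
    effects[0, 0] = 1.0
    effects[1, 0] = -1.0
    return make_crossover(
        6, ("A", "B"), 5, rng, subject_sd=2.0, noise_sd=0.01,
        condition_effects=effects,
    )
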