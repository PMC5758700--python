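import numpy as np
import pytest

from nirselect.core_io import SampleMeta, SpectraSet, WavenumberGrid


def make_set(
    X: np.ndarray,
    start: float = 5000.0,
    spacing: float = 4.0,
    classes=None,
    tissue: str = "BFL",
) -> SpectraSet:
    """SpectraSet around an arbitrary matrix, with a uniform descending grid."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    grid = WavenumberGrid(start - spacing * np.arange(p))
    if classes is None:
        classes = (np.arange(n) % 5) + 1
    meta = [
        SampleMeta(sample_id=f"{tissue}-{i + 1:02d}", tissue=tissue, region_class=int(c))
        for i, c in enumerate(classes)
    ]
    return SpectraSet(X, grid, meta)


@pytest.fixture
def toy_set() -> SpectraSet:
    rng = np.random.default_rng(0)
    return make_set(rng.normal(size=(12, 20)))


@pytest.fixture(scope="session")
def bfl_study():
    """Default BFL study dataset (60 x 1555) with planted-band truth."""
    from nirselect.synthetic_data import default_study_config, generate_dataset

    return generate_dataset(default_study_config("BFL", seed=42))


@pytest.fixture(scope="session")
def bfl_training():
    """Preprocessed, cropped, split BFL training set plus truth."""
    from nirselect.core_io import band_crop
    from nirselect.preprocessing import PreprocessChain
    from nirselect.qc_split import kennard_stone_split
    from nirselect.synthetic_data import (
        SDD_HIGH,
        SDD_LOW,
        default_study_config,
        generate_dataset,
    )

    s, truth = generate_dataset(default_study_config("BFL", seed=42))
    pre = band_crop(PreprocessChain().apply(s), SDD_HIGH, SDD_LOW)
    split = kennard_stone_split(pre)
    return split.training_set(), truth
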