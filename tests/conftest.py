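import numpy as np
import pandas as pd
import pytest

from steppedemo.demography import ScenarioId, default_priors, draw_parameters
from steppedemo.simulate import ReferenceTable, SampleConfig, build_reference_table


def make_toy_table(
    n_per_class: int,
    height: int = 20,
    width: int = 60,
    seed: int = 0,
    plus_fractions=(0.2, 0.45, 0.7),
    shuffle_labels: bool = False,
) -> ReferenceTable:
    """Reference table of synthetic images whose class determines the mean
    pixel value (fraction of +1 vs -1 pixels); separable by construction."""
    rng = np.random.default_rng(seed)
    images, labels, rows = [], [], []
    for label, p in enumerate(plus_fractions):
        for _ in range(n_per_class):
            img = np.where(rng.random((height, width)) < p, 1, -1).astype(np.int8)
            images.append(img)
            labels.append(label)
            params = draw_parameters(default_priors(), ScenarioId(label), int(rng.integers(1 << 30)))
            row = params.as_dict()
            row["scenario"] = label
            row["seed"] = int(rng.integers(1 << 62))
            rows.append(row)
    labels = np.asarray(labels, dtype=np.int64)
    if shuffle_labels:
        labels = rng.permutation(labels)
    return ReferenceTable(images=np.stack(images), labels=labels, params=pd.DataFrame(rows))


@pytest.fixture(scope="session")
def toy_tables():
    """Separable toy train/val/test tables sharing the image distribution."""
    return {
        "train": make_toy_table(60, seed=1),
        "val": make_toy_table(30, seed=2),
        "test": make_toy_table(30, seed=3),
    }


@pytest.fixture(scope="session")
def toy_model(toy_tables):
    from steppedemo.cnn_abc import TrainingSpec, train_classifier

    return train_classifier(
        toy_tables["train"], toy_tables["val"], TrainingSpec(epochs=25), seed=11
    )


@pytest.fixture(scope="session")
def small_sim_table():
    """A small but real simulated reference table (O. petraeus-like shape)."""
    config = SampleConfig(
        n_ind_ez=10,
        n_ind_z=10,
        n_loci=500,
        target_snps=80,
        missing_fraction=0.42,
        mu=2.8e-9,
        gen_time_years=1.0,
    )
    return build_reference_table(list(ScenarioId), default_priors(), 8, config, seed=99)
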