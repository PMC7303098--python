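import numpy as np
import pandas as pd
import pytest

from toxmetab.preprocess import FeatureTable


def make_table(values, groups, injection_indices=None, mz=None, rt=None):
    """Build a small FeatureTable from a plain matrix and group labels."""
    values = np.asarray(values, float)
    n_samples, n_features = values.shape
    if injection_indices is None:
        injection_indices = list(range(1, n_samples + 1))
    counts = {}
    sample_ids = []
    for g in groups:
        counts[g] = counts.get(g, 0) + 1
        sample_ids.append(f"{g}_{counts[g]}")
    samples = pd.DataFrame(
        {"group": groups, "injection_index": injection_indices}, index=sample_ids
    )
    feature_ids = [f"F{j}" for j in range(n_features)]
    features = pd.DataFrame(
        {
            "mz": mz if mz is not None else np.linspace(100, 600, n_features),
            "rt_seconds": rt if rt is not None else np.linspace(60, 500, n_features),
        },
        index=feature_ids,
    )
    features["name"] = [
        f"M{round(m)}T{round(t)}" for m, t in zip(features["mz"], features["rt_seconds"])
    ]
    abund = pd.DataFrame(values, index=sample_ids, columns=feature_ids)
    return FeatureTable(abundances=abund, samples=samples, features=features)


@pytest.fixture(scope="session")
def default_experiment():
    from toxmetab.synthetic_data import SyntheticConfig, generate_experiment

    return generate_experiment(SyntheticConfig(seed=0))
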