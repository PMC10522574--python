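import numpy as np
import pandas as pd
import pytest

from holopolyp import (
    DesignSpec,
    EffectSpec,
    FeatureTable,
    normalize_total,
    remove_blank_features,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_study() -> FeatureTable:
    """A compact simulated study: 4 colonies x 3 branches x 6 polyps, 80 features."""
    return simulate_study(DesignSpec(n_colonies=4, seed=7), EffectSpec(), n_features=80, seed=7)


@pytest.fixture(scope="session")
def small_norm(small_study) -> FeatureTable:
    return normalize_total(remove_blank_features(small_study))


def make_table(abundance: np.ndarray, samples: pd.DataFrame, normalized=False) -> FeatureTable:
    """Assemble a FeatureTable from a raw matrix and a sample-metadata frame."""
    n_feat = abundance.shape[1]
    fids = [f"F{i+1:03d}" for i in range(n_feat)]
    ab = pd.DataFrame(
        abundance,
        index=pd.Index(samples.index, name="sample_id"),
        columns=pd.Index(fids, name="feature_id"),
    )
    features = pd.DataFrame(
        {"mz": np.linspace(200, 800, n_feat), "rt": np.linspace(2, 8, n_feat)},
        index=ab.columns,
    )
    return FeatureTable(abundance=ab, samples=samples, features=features, normalized=normalized)


def polyp_meta(colonies, branches_per_colony, polyps_per_branch, spacing=10.0):
    """Metadata frame for a fully crossed polyp design with evenly spaced positions."""
    rows = []
    for c in range(1, colonies + 1):
        for b in range(1, branches_per_colony + 1):
            for p in range(1, polyps_per_branch + 1):
                rows.append(
                    {
                        "sample_id": f"C{c}B{b}P{p}",
                        "role": "polyp",
                        "colony_id": f"C{c}",
                        "branch_id": f"C{c}B{b}",
                        "polyp_number": p,
                        "position_mm": 10.0 + spacing * (p - 1),
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")
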