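import numpy as np
import pandas as pd
import pytest

from splicerescue import SimulationConfig, simulate_dataset
from splicerescue.rescue import AlterationTable, ComparisonTriple


@pytest.fixture(scope="session")
def small_dataset():
    """50-event dataset with mixed classes, deep enough to classify reliably."""
    cfg = SimulationConfig(
        n_events=50, n_replicates=3, frac_disease=0.3, frac_rescued=0.5,
        frac_partial=0.0, frac_treatment_only=0.1, min_true_dpsi=30.0,
        mean_depth=2000.0, overdispersion=0.0, seed=11,
    )
    counts, design, truth = simulate_dataset(cfg)
    return cfg, counts, design, truth


def make_alteration(label, feature_ids, effects, significant):
    return AlterationTable(
        label=label,
        table=pd.DataFrame(
            {"feature_id": feature_ids, "effect": effects, "significant": significant}
        ),
    )


def random_triple(rng, n_features=40):
    """A random but internally consistent comparison triple for property tests."""
    ids = [f"F{i:03d}" for i in range(n_features)]
    tables = []
    for label in ("CD", "DT", "CT"):
        present = rng.random(n_features) < 0.9
        sig = (rng.random(n_features) < 0.4) & present
        effects = np.round(rng.uniform(-40, 40, n_features), 3)
        effects[effects == 0] = 1.0  # significant features need a nonzero effect
        sub = pd.DataFrame(
            {"feature_id": ids, "effect": effects, "significant": sig}
        )[present]
        tables.append(AlterationTable(label=label, table=sub.reset_index(drop=True)))
    return ComparisonTriple(alt_cd=tables[0], alt_dt=tables[1], alt_ct=tables[2])
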