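import numpy as np
import pandas as pd
import pytest

import braintx as bt


@pytest.fixture(scope="session")
def small_study():
    """Scaled-down study with planted effects: 2000 genes, defaults otherwise."""
    cfg = bt.StudyConfig(
        n_genes=2000,
        n_de_global=100,
        n_de_regional={"caudate": 10, "NAcc": 30},
        seed=11,
    )
    counts, meta, truth = bt.generate_study(cfg)
    return cfg, counts, meta, truth


@pytest.fixture(scope="session")
def null_independent_study():
    """No planted effects and no shared subject latents: the regression's
    independence assumptions hold exactly, so p-values should be calibrated."""
    cfg = bt.StudyConfig(
        n_genes=2000,
        n_de_global=0,
        n_de_regional={},
        cortical_corr=0.0,
        between_region_corr=0.0,
        seed=7,
    )
    counts, meta, truth = bt.generate_study(cfg)
    return cfg, counts, meta, truth


@pytest.fixture()
def two_group_meta():
    """Minimal one-region metadata: 6 case + 6 comparison subjects."""
    rows = []
    rng = np.random.default_rng(5)
    for i in range(12):
        dx = "case" if i < 6 else "comparison"
        subj = f"s{i:02d}"
        rows.append(
            {
                "sample": f"{subj}_r1",
                "subject": subj,
                "region": "r1",
                "diagnosis": dx,
                "sex": "M" if i % 2 else "F",
                "age": float(40 + rng.normal(0, 5)),
                "PMI": float(15 + rng.normal(0, 3)),
                "pH": float(6.6 + rng.normal(0, 0.1)),
                "RIN": float(7.5 + rng.normal(0, 0.4)),
            }
        )
    return pd.DataFrame(rows).set_index("sample")
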