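import numpy as np
import pandas as pd
import pytest

from rexpress import (
    ExpressionMatrix,
    SampleMeta,
    default_study_config,
    generate_compendium,
)


def make_matrix(values: np.ndarray, genes, tissues_reps, day=21) -> ExpressionMatrix:
    """Build a one-day matrix from an array and a [(tissue, n_reps), ...] layout."""
    meta, sample_ids = [], []
    for tissue, n_reps in tissues_reps:
        for rep in range(1, n_reps + 1):
            sid = f"{tissue}_d{day}_r{rep}"
            sample_ids.append(sid)
            meta.append(SampleMeta(sid, tissue, day, rep))
    df = pd.DataFrame(np.asarray(values, dtype=float), index=list(genes), columns=sample_ids)
    return ExpressionMatrix(df, meta)


def random_matrix(rng, n_genes=20, day=21, focal_reps=4):
    """A random log-normal matrix with one focal and two comparison tissues."""
    layout = [("pituitary", focal_reps), ("liver", 3), ("heart", 3)]
    n_samples = sum(n for _, n in layout)
    log2val = rng.normal(3.0, 2.0, (n_genes, 1)) + rng.normal(0.0, 0.6, (n_genes, n_samples))
    genes = [f"g{i}" for i in range(n_genes)]
    return make_matrix(np.exp2(log2val), genes, layout, day=day)


@pytest.fixture(scope="session")
def study_compendium():
    """One full-size synthetic compendium under the default study design."""
    config = default_study_config(seed=0)
    matrices, truth = generate_compendium(config)
    return config, matrices, truth
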