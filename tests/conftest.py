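import numpy as np
import pandas as pd
import pytest

from senosurv import ExpressionMatrix, GeneSignature, SimConfig, generate_cohort


@pytest.fixture
def small_cohort():
    """200-sample cohort with a purely protective 10-gene signature."""
    cfg = SimConfig(
        n_samples=200,
        n_genes=60,
        n_signature_genes=10,
        beta=tuple([-0.8] * 10),
        n_batches=2,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture
def toy_matrix():
    """4 probes x 5 samples, strictly positive, hand-enumerable."""
    data = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 3.0, 4.0],
            "s2": [2.0, 4.0, 6.0, 8.0],
            "s3": [1.5, 3.0, 4.5, 6.0],
            "s4": [3.0, 6.0, 9.0, 12.0],
            "s5": [1.0, 1.0, 1.0, 1.0],
        },
        index=["p1", "p2", "p3", "p4"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def protective_signature(small_cohort):
    return GeneSignature("PROT", tuple(small_cohort.truth.signature_gene_ids))


def random_survival(rng, n, rate=0.1, censor=0.05):
    """Simple exponential survival draw for statistical unit tests."""
    t_event = rng.exponential(1.0 / rate, n)
    t_cens = rng.exponential(1.0 / censor, n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event
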