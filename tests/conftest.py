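import numpy as np
import pandas as pd
import pytest

from hifsig import (
    ExpressionMatrix,
    SeedSet,
    SurvivalTable,
    SynthOmicsConfig,
    TargetCatalogue,
    expand,
    gen_clinical,
    gen_expression,
    gen_survival,
)


@pytest.fixture(scope="session")
def planted():
    """One planted-regulon cohort shared across tests (n=300, 45-gene regulon)."""
    cfg = SynthOmicsConfig(rng_seed=11)
    mat, truth = gen_expression(cfg)
    surv = gen_survival(truth, cfg)
    clin = gen_clinical(truth, cfg)
    return {"cfg": cfg, "mat": mat, "truth": truth, "surv": surv, "clin": clin}


@pytest.fixture(scope="session")
def planted_expansion(planted):
    cat = TargetCatalogue(tuple(planted["truth"].regulon_members))
    return expand(planted["mat"], SeedSet(), cat)


@pytest.fixture
def tiny_matrix():
    """Deterministic 6-gene x 8-sample matrix with one correlated pair."""
    rng = np.random.default_rng(5)
    base = rng.standard_normal(8)
    values = np.vstack(
        [base, base + 0.01 * rng.standard_normal(8)]
        + [rng.standard_normal(8) for _ in range(4)]
    )
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=["A", "A2", "B", "C", "D", "E"],
            columns=[f"s{i}" for i in range(8)],
        )
    )


def make_survival(time, event, prefix="s"):
    return SurvivalTable.from_arrays(
        [f"{prefix}{i}" for i in range(len(time))], time, event
    )
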