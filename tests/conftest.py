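import numpy as np
import pandas as pd
import pytest

import regimenet as rn


@pytest.fixture()
def toy_expression_tsv(tmp_path):
    """3-gene x 4-sample expression table on disk."""
    path = tmp_path / "expr.tsv"
    path.write_text(
        "gene\ts1\ts2\ts3\ts4\n"
        "ERBB2\t1.5\t2.25\t-0.5\t0.125\n"
        "ESR1\t0.1\t0.2\t0.3\t0.4\n"
        "MLPH\t-1\t-2\t-3\t-4\n"
    )
    return path


@pytest.fixture()
def toy_cohort():
    """Small deterministic multi-omics cohort with aligned samples."""
    samples = [f"s{i}" for i in range(1, 5)]
    expr = rn.ExpressionMatrix(
        pd.DataFrame(
            [[0.0, 0.1, 5.0, 5.2], [1.0, 1.1, 1.2, 1.3]],
            index=["A", "B"], columns=samples,
        )
    )
    mut = rn.AberrationMatrix(
        pd.DataFrame([[0, 1, 1, 0], [0, 0, 0, 0]], index=["A", "B"],
                     columns=["s2", "s3", "s4", "s5"]),
        kind="mutation",
    )
    clin = rn.ClinicalTable(
        pd.DataFrame(
            {"time": [10.0, 20.0, 30.0, 40.0], "event": [1, 0, 1, 1],
             "age": [50.0, 60.0, 70.0, 55.0]},
            index=pd.Index(samples, name="sample"),
        )
    )
    return rn.Cohort(expression=expr, mutation=mut, clinical=clin)


@pytest.fixture(scope="session")
def bimodal_values():
    """500 draws: 250 ~ N(0,1) + 250 ~ N(6,1), with generating labels."""
    rng = np.random.default_rng(42)
    labels = np.repeat([0, 1], 250)
    values = rng.normal(6.0 * labels, 1.0)
    return values, labels


@pytest.fixture(scope="session")
def full_cohort():
    """One 'full' preset cohort, discretized once and shared read-only."""
    spec = rn.preset_spec("full", seed=11)
    expr, mut, cnv, clin, truth = rn.simulate_cohort(spec)
    rm = rn.discretize(expr, k_max=2, seed=7)
    return {"expr": expr, "mut": mut, "cnv": rn.collapse_cnv(cnv),
            "clin": clin, "truth": truth, "rm": rm}
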