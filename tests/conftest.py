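import numpy as np
import pandas as pd
import pytest

import methylmark as mm


@pytest.fixture(scope="session")
def study() -> mm.StudyData:
    """One default-configuration simulated study shared across tests."""
    return mm.simulate_study(mm.SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def small_sheet() -> mm.SampleSheet:
    """Two groups of three samples for hand-built matrices."""
    return mm.SampleSheet(
        table=pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "a3", "b1", "b2", "b3"],
                "group": ["A", "A", "A", "B", "B", "B"],
                "donor_id": ["d1", "d2", "d3", "d1", "d2", "d3"],
            }
        )
    )


def expression_from(values: np.ndarray, samples, genes=None) -> mm.ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    probes = pd.Index([f"p{i}" for i in range(values.shape[0])], name="probe_id")
    gene_names = genes or [f"G{i}" for i in range(values.shape[0])]
    return mm.ExpressionMatrix(
        values=pd.DataFrame(values, index=probes, columns=list(samples)),
        genes=pd.Series(gene_names, index=probes, name="gene"),
    )


def beta_from(values: np.ndarray, samples, cpgs=None) -> mm.BetaMatrix:
    values = np.asarray(values, dtype=float)
    index = pd.Index(cpgs or [f"cg{i}" for i in range(values.shape[0])], name="cpg_id")
    return mm.BetaMatrix(values=pd.DataFrame(values, index=index, columns=list(samples)))
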