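import numpy as np
import pandas as pd
import pytest

from circascan.io import ExpressionMatrix, SampleMeta
from circascan.simulate import SimParams, simulate

STUDY_TIMES = (4.0, 10.0, 16.0, 22.0, 28.0, 34.0)


def build_matrix(gene_values: dict, conditions=("low_salt",), n_replicates=1,
                 times=STUDY_TIMES) -> ExpressionMatrix:
    """Matrix from {gene_id: {(condition, replicate): [values...]}} or flat lists.

    A flat list per gene is broadcast to every condition/replicate.
    """
    samples, columns = [], {}
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            for j, t in enumerate(times):
                sid = f"{cond}_r{rep}_t{t:g}"
                samples.append(SampleMeta(sid, cond, rep, float(t)))
                col = []
                for g, vals in gene_values.items():
                    if isinstance(vals, dict):
                        col.append(vals[(cond, rep)][j])
                    else:
                        col.append(vals[j])
                columns[sid] = col
    values = pd.DataFrame(
        columns, index=pd.Index(list(gene_values), name="gene_id"), dtype=float
    )
    return ExpressionMatrix(values=values, samples=samples)


@pytest.fixture(scope="session")
def small_sim():
    """A 200-gene study-design simulation with planted rhythms and effects."""
    params = SimParams(
        n_genes=200, seed=11, noise_cv=0.05,
        frac_cycling_low=0.1, frac_cycling_high=0.2, n_cycling_shared=2,
        amplitude_range=(0.3, 0.5),
    )
    matrix, truth = simulate(params)
    return params, matrix, truth
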