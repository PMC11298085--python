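import numpy as np
import pandas as pd
import pytest

from robustscreen.core import PhenotypeMatrix, RobustnessRecord


def make_matrix(values, subsets=None):
    """Build a PhenotypeMatrix from {strain: {condition: value-or-list}}."""
    rows = []
    for strain, conds in values.items():
        for cond, v in conds.items():
            vals = v if isinstance(v, (list, tuple)) else [v]
            for k, x in enumerate(vals):
                rows.append((strain, cond, f"rep{k:02d}", x))
    df = pd.DataFrame(rows, columns=["strain", "condition", "replicate", "value"])
    if subsets is None:
        conds = sorted(df["condition"].unique())
        subsets = {"ALL": conds} if len(conds) >= 2 else {}
    return PhenotypeMatrix(df, subsets)


def make_records(fitness, robustness, status=None):
    """Parallel fitness/robustness arrays -> list of RobustnessRecord."""
    n = len(fitness)
    status = status or ["ok"] * n
    return [
        RobustnessRecord(
            strain_id=f"s{i:04d}",
            n_obs=14,
            strain_mean=float(fitness[i]),
            strain_variance=0.0,
            grand_mean=1.0,
            robustness=float(robustness[i]),
            status=status[i],
        )
        for i in range(n)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
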