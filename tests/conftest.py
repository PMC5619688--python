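import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from mixt import ExpressionMatrix
from mixt.synthetic import (
    Interaction,
    SyntheticConfig,
    TissueConfig,
    generate,
)

# the acceptance script doubles as a library of independent oracles
sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "scripts"))


def make_expression(values, tissue="tumor", roles="patient",
                    genes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    return ExpressionMatrix(df, tissue, pd.Series(roles, index=df.columns))


@pytest.fixture(scope="session")
def small_cohort():
    """Planted cohort shared across tests: 3 modules/tissue, 80 patients,
    20 blood controls, one basal-specific cross-tissue interaction."""
    cfg = SyntheticConfig(
        seed=42, n_patients=80, n_controls=20,
        tumor=TissueConfig(n_genes=260, module_sizes=[80, 60, 40], module_corr=0.7),
        blood=TissueConfig(n_genes=260, module_sizes=[80, 60, 40], module_corr=0.7),
        schemes={"pam50": {"basal": 30, "lumA": 30, "lumB": 20}},
        interactions=[Interaction("turquoise", "blue", "pam50", "basal", 0.8)],
    )
    return generate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
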