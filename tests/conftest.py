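import numpy as np
import pandas as pd
import pytest

from pparbias.equilibria import BindingSystem
from pparbias.motifs import DR1_CONSENSUS, MotifMatrix


@pytest.fixture(scope="session")
def assay() -> BindingSystem:
    """The assay's final in-well constants: 800 nM receptor, 50 nM tracer."""
    return BindingSystem(receptor_total=800.0, tracer_total=50.0, tracer_kd=200.0)


@pytest.fixture(scope="session")
def dr1_matrix() -> MotifMatrix:
    return MotifMatrix.from_consensus(DR1_CONSENSUS)


@pytest.fixture(scope="session")
def ki_table_balanced() -> pd.DataFrame:
    """Balanced 8-replicate Ki table with a planted PGC1a bias of +0.3 for GW1929."""
    rng = np.random.default_rng(123)
    rows = []
    for lig in ("rosiglitazone", "GW1929"):
        for coreg in ("CBP_1-127", "PGC1a_100-220", "MED1_557-870"):
            for rep in range(1, 9):
                log_ki = 3.7
                if lig == "GW1929" and coreg == "PGC1a_100-220":
                    log_ki -= 0.3
                rows.append((lig, coreg, "LBD", rep, 10 ** (log_ki + rng.normal(0, 0.05))))
    return pd.DataFrame(rows, columns=["ligand", "coregulator", "assembly", "replicate", "ki"])
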