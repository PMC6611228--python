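import math

import pandas as pd
import pytest

from sirtlq.simulate import SimulationSpec, simulate_clonogenic


@pytest.fixture
def noise_free_records() -> pd.DataFrame:
    """Exact LQ survival data (alpha=0.2, beta=0.02, no noise, two repeats)."""
    alpha, beta, pe, plated = 0.2, 0.02, 0.6, 1000
    rows = []
    for i in (1, 2):
        for dose in (0.0, 1.0, 2.0, 4.0, 6.0, 8.0):
            sf = math.exp(-(alpha * dose + beta * dose * dose))
            for j in (1, 2):
                rows.append(
                    {
                        "cell_line": "SIM",
                        "modality": "LINAC",
                        "dose_Gy": dose,
                        "colonies": plated * pe * sf,
                        "plated": plated,
                        "replicate_set": f"R{i}",
                        "well": f"R{i}-D{dose:g}-W{j}",
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def simulated_records() -> pd.DataFrame:
    """One stochastic clonogenic experiment at the default acute design."""
    return simulate_clonogenic(SimulationSpec(seed=42, sigma_b=0.15))
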