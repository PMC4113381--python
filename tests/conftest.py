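import numpy as np
import pandas as pd
import pytest

from zonemap import ExpressionMatrix, SimulationDesign, ZoneProgram


def make_matrix(values, zones, tissue="T", gene_prefix="g", platform=None):
    """Build an ExpressionMatrix from a 2-D array and per-sample zone labels."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    assert len(zones) == n_samples
    counts: dict[str, int] = {}
    records = []
    for z in zones:
        counts[z] = counts.get(z, 0) + 1
        records.append({"sample_id": f"{tissue}_{z}_r{counts[z]}", "tissue": tissue,
                        "zone": z, "replicate": f"r{counts[z]}"})
    genes = [f"{gene_prefix}{i + 1}" for i in range(n_genes)]
    df = pd.DataFrame(values, index=genes,
                      columns=[r["sample_id"] for r in records])
    return ExpressionMatrix(df, pd.DataFrame(records),
                            platform=platform or tissue)


@pytest.fixture
def two_zone_design():
    """Small one-tissue design: 2 zones x 4 replicates, one planted program."""
    program = ZoneProgram("zp", "T", {"A": 1.0}, size=30)
    return SimulationDesign(
        tissues=[("T", ("A", "B"))], n_genes=300, n_replicates=4,
        sigma=0.35, programs=[program], seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20240916)
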