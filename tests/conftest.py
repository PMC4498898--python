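import numpy as np
import pandas as pd
import pytest

import meiocross as mc


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def genome():
    return mc.default_genome()


@pytest.fixture
def one_chrom():
    return mc.single_chromosome_genome(20.0)


def tiny_matrix(calls_by_marker: dict, marker_map: pd.DataFrame) -> mc.F2GenotypeMatrix:
    """Build a small genotype matrix from per-marker call lists (None = missing)."""
    data = {
        m: [float("nan") if v is None else float(v) for v in vals]
        for m, vals in calls_by_marker.items()
    }
    n = len(next(iter(data.values())))
    genotypes = pd.DataFrame(
        data, index=pd.Index([f"p{i}" for i in range(n)], name="plant_id")
    )
    return mc.F2GenotypeMatrix(genotypes, marker_map)


def marker_map(rows: list[tuple[str, str, float]]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "marker": [s[0] for s in rows],
            "chromosome": [s[1] for s in rows],
            "position_mb": [s[2] for s in rows],
        }
    )
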