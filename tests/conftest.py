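import numpy as np
import pandas as pd
import pytest

from sigrev import ExpressionMatrix, GeneSignature, RankedProfile


@pytest.fixture
def small_signature() -> GeneSignature:
    return GeneSignature(
        name="toy",
        up=["G00000", "G00001", "G00002"],
        down=["G00003", "G00004", "G00005"],
    )


@pytest.fixture
def two_group_matrix() -> ExpressionMatrix:
    """Tiny deterministic log2 matrix: 8 genes, 3+3 samples, first two genes
    shifted up by 2 in the case group."""
    rng = np.random.default_rng(7)
    x = rng.normal(8.0, 0.3, size=(8, 6))
    x[:2, :3] += 2.0
    samples = [f"c{i}" for i in range(3)] + [f"n{i}" for i in range(3)]
    values = pd.DataFrame(x, index=[f"G{i:05d}" for i in range(8)], columns=samples)
    groups = pd.Series(["case"] * 3 + ["control"] * 3, index=samples)
    return ExpressionMatrix(values, groups, "log2")


def make_profile(order, drug="D1", pid=None):
    return RankedProfile(pid or f"{drug}_rep0", drug, "HepG2", "10uM", "6h", list(order))


@pytest.fixture
def gene_universe():
    return [f"G{i:05d}" for i in range(10)]
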