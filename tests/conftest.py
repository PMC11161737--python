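import numpy as np
import pandas as pd
import pytest

from extremoscope.core_data import ExpressionMatrix, GeneAnnotation
from extremoscope.simulate import make_gene_annotation


@pytest.fixture
def toy_annotation() -> GeneAnnotation:
    """Six genes covering the filtering cases: autosome, chrX, chrM,
    chrY-PAR flag, lincRNA."""
    df = pd.DataFrame(
        {
            "symbol": ["A", "B", "C", "D", "E", "F"],
            "chromosome": ["chr1", "chr17", "chrX", "chrM", "chrY", "chr2"],
            "strand": ["+", "-", "+", "+", "+", "-"],
            "tss_list": [(5000,), (9000,), (100,), (1,), (100,), (5000,)],
            "biotype": [
                "protein_coding", "protein_coding", "protein_coding",
                "protein_coding", "protein_coding", "lincRNA",
            ],
            "par_y": [False, False, False, False, True, False],
        },
        index=pd.Index(["g1", "g2", "g3", "g4", "g5", "g6"], name="gene_id"),
    )
    return GeneAnnotation(df)


@pytest.fixture
def toy_matrix(toy_annotation) -> ExpressionMatrix:
    rng = np.random.default_rng(0)
    vals = rng.uniform(2, 50, size=(6, 5))
    return ExpressionMatrix(
        pd.DataFrame(
            vals,
            index=toy_annotation.table.index,
            columns=[f"s{i}" for i in range(1, 6)],
        )
    )


@pytest.fixture
def random_matrix() -> ExpressionMatrix:
    """50 × 20 random FPKM matrix for round-trip and property checks."""
    rng = np.random.default_rng(7)
    vals = np.exp2(rng.uniform(0, 10, size=(50, 20))) - 1
    return ExpressionMatrix(
        pd.DataFrame(
            vals,
            index=pd.Index([f"g{i:03d}" for i in range(50)], name="gene_id"),
            columns=[f"s{i:02d}" for i in range(20)],
        )
    )
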