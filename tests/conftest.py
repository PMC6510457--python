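import numpy as np
import pandas as pd
import pytest

from imds.data import ExpressionMatrix
from imds.gsva import gsva_scores
from imds.signatures import GeneSignature, SignatureLibrary
from imds.simulate import default_design, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic design, simulated once per session."""
    expr, lib, truth = simulate_cohort(default_design(seed=1))
    return expr, lib, truth


@pytest.fixture(scope="session")
def default_es(default_cohort):
    """ES matrix of the default cohort (the expensive shared intermediate)."""
    expr, lib, _ = default_cohort
    return gsva_scores(expr, lib)


@pytest.fixture
def tiny_expr():
    """20 genes x 9 samples with simple group structure, fixed seed."""
    rng = np.random.default_rng(42)
    genes = [f"G{i:02d}" for i in range(20)]
    samples = [f"S{j}" for j in range(9)]
    values = pd.DataFrame(
        rng.normal(7.0, 1.0, size=(20, 9)), index=genes, columns=samples
    )
    annotations = pd.DataFrame(
        {
            "disease": ["none"] * 3 + ["CD"] * 6,
            "group": ["NHV"] * 3 + ["R"] * 3 + ["NR"] * 3,
            "timepoint": ["BL"] * 9,
        },
        index=samples,
    )
    return ExpressionMatrix(values, annotations)


@pytest.fixture
def small_library():
    return SignatureLibrary(
        [
            GeneSignature(id="sigA", genes=("G01", "G02", "G03", "G04", "G05"),
                          direction="UP"),
            GeneSignature(id="sigB", genes=("G06", "G07", "G08", "G09", "G10"),
                          direction="UP"),
            GeneSignature(id="sigC", genes=("G01", "G02", "G11", "G12", "G13",
                                            "G14", "G15"), direction="DOWN"),
        ]
    )
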