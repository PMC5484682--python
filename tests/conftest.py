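import numpy as np
import pytest

from mirsig import ExpressionMatrix, Signature, SyntheticSpec, generate_discovery


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    values = np.array(
        [
            [0.0, 1.0, 2.0, 3.0, 4.0],
            [4.0, 3.0, 2.0, 1.0, 0.0],
            [1.0, 1.0, 1.0, 1.0, 1.0],
        ]
    )
    return ExpressionMatrix(values, ["up", "down", "flat"], [f"s{i}" for i in range(5)], "mRNA")


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Scaled-down discovery study for fast unit tests (full-scale runs live
    in the acceptance suite)."""
    return SyntheticSpec(
        n_mirna_features=30,
        n_gene_features=60,
        n_signal_mirnas=4,
        targets_per_signal_mirna=2,
        n_extra_severity_genes=20,
        n_decoy_predictions=40,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_discovery(small_spec):
    return generate_discovery(small_spec)


@pytest.fixture
def two_feature_signature() -> Signature:
    return Signature("toy", "mRNA", [("f1", 0.5), ("f2", -0.5)])


def write_tsv(path, text: str) -> str:
    path.write_text(text)
    return str(path)
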