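import numpy as np
import pytest

from scrules.dataset import ExpressionDataset
from scrules.simulate import NEGATIVE, POSITIVE, PlantedRule, SyntheticSpec, generate


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """4 cells x 3 genes, 2 cells per class."""
    values = np.array(
        [
            [1.0, 0.0, 5.0],
            [2.0, 0.5, 4.0],
            [0.0, 3.0, 1.0],
            [0.5, 2.5, 0.0],
        ]
    )
    return ExpressionDataset(
        values=values,
        gene_ids=["g1", "g2", "g3"],
        cell_ids=["c1", "c2", "c3", "c4"],
        labels=np.array([POSITIVE, POSITIVE, NEGATIVE, NEGATIVE], dtype=object),
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """Small labeled dataset with one DE gene and two clean rule genes."""
    spec = SyntheticSpec(
        n_pos=70,
        n_neg=50,
        n_genes=60,
        dropout_rate=0.6,
        rule_gap=0.25,
        seed=5,
        planted_de_genes=[(2, 2.0)],
        planted_rule_genes=[
            PlantedRule(0, 4.0, ">=", POSITIVE),
            PlantedRule(1, 2.0, "<=", POSITIVE),
        ],
    )
    dataset, truth = generate(spec)
    return dataset, truth
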