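import numpy as np
import pytest

from tpsevol import (
    CodonAlignment,
    PhyloTree,
    SimulationSpec,
    balanced_tree,
    simulate_codon_alignment,
)
from tpsevol._codons import SENSE_CODONS


@pytest.fixture(scope="session")
def tree8():
    """Standard 8-taxon balanced test tree, root-to-tip depth 0.5."""
    return balanced_tree(8, depth=0.5)


@pytest.fixture(scope="session")
def foreground8():
    return frozenset(f"t{i + 1}" for i in range(4))


@pytest.fixture(scope="session")
def one_ratio_alignment(tree8):
    """300-codon alignment simulated under a single omega = 0.1."""
    ca, truth = simulate_codon_alignment(
        SimulationSpec(
            tree=tree8,
            kappa=2.0,
            omega_by_class={"background": 0.1},
            n_codons=300,
            seed=20260101,
        )
    )
    return ca, truth


@pytest.fixture(scope="session")
def quartet_tree():
    return PhyloTree.from_newick(
        "((a:0.1,b:0.2):0.15,(c:0.12,d:0.3):0.05);"
    )


@pytest.fixture(scope="session")
def quartet_alignment():
    rng = np.random.default_rng(1)
    return CodonAlignment(
        ids=list("abcd"),
        rows=[
            [SENSE_CODONS[i] for i in rng.integers(0, 61, 3)]
            for _ in range(4)
        ],
    )
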