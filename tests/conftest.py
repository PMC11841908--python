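import numpy as np
import pandas as pd
import pytest

from surveybbn.bbn import BayesianNetwork, DAGStructure
from surveybbn.discretize import DiscreteDataset
from surveybbn.synth import GeneratorConfig

# Arc set of the published mixed-state network: staff caring (S5) parents
# labour/birth, hospital care and after-birth care; a chain S4 -> S3 -> S2;
# S1 and S7 isolated.
PUBLISHED_ARCS = [("S5", "S4"), ("S5", "S6"), ("S5", "S8"),
                  ("S4", "S3"), ("S3", "S2")]


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig(seed=12345)


@pytest.fixture(scope="session")
def big_sections():
    """A large section-level sample at the published moments (shared)."""
    from surveybbn.synth import generate_sections

    cfg = GeneratorConfig(n_rows=200_000, seed=20240901)
    return generate_sections(cfg)


def make_discrete(codes: dict[str, np.ndarray] | pd.DataFrame,
                  k: dict[str, int] | None = None) -> DiscreteDataset:
    if not isinstance(codes, pd.DataFrame):
        codes = pd.DataFrame(codes)
    return DiscreteDataset.from_codes(codes, k)


def chain_network(p_flip: float = 0.1) -> BayesianNetwork:
    """Binary X -> Y -> Z chain with symmetric noisy-copy CPTs."""
    structure = DAGStructure(nodes=("X", "Y", "Z"),
                             parents={"X": (), "Y": ("X",), "Z": ("Y",)})
    copy = np.array([[1 - p_flip, p_flip], [p_flip, 1 - p_flip]])
    cpts = {"X": np.array([0.5, 0.5]), "Y": copy, "Z": copy}
    states = {n: ["C0", "C1"] for n in structure.nodes}
    return BayesianNetwork(structure=structure, states=states, cpts=cpts)
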