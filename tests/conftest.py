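import numpy as np
import pandas as pd
import pytest

from streamtox import ScenarioConfig, SiteDesign
from streamtox.simulate import generate_all


@pytest.fixture
def design() -> SiteDesign:
    """The nine-site paired design: five contaminated, four reference."""
    return SiteDesign(
        pairs={"S1a": "R1", "S1b": "R1", "S2": "R2", "S3": "R3", "S4": "R4"}
    )


@pytest.fixture
def taxonomy() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "taxon": ["Baetis", "Epeorus", "Hydropsyche", "Chironomidae gen.",
                      "Simulium", "Sweltsa", "Oligochaeta gen."],
            "family": ["Baetidae", "Heptageniidae", "Hydropsychidae",
                       "Chironomidae", "Simuliidae", "Chloroperlidae", None],
            "order": ["Ephemeroptera", "Ephemeroptera", "Trichoptera",
                      "Diptera", "Diptera", "Plecoptera", "Haplotaxida"],
        }
    )


@pytest.fixture
def counts_45(taxonomy) -> pd.DataFrame:
    """45 stones (9 sites × 5) of reproducible random counts."""
    rng = np.random.default_rng(42)
    sites = ["S1a", "S1b", "S2", "S3", "S4", "R1", "R2", "R3", "R4"]
    index = pd.MultiIndex.from_product(
        [sites, range(1, 6)], names=["site", "stone"]
    )
    data = rng.poisson(
        [20, 8, 6, 25, 5, 3, 2], size=(len(index), len(taxonomy))
    )
    return pd.DataFrame(data, index=index, columns=taxonomy["taxon"].tolist())


@pytest.fixture(scope="session")
def scenario_tables() -> dict[str, pd.DataFrame]:
    """One full synthetic survey under the default scenario."""
    return generate_all(ScenarioConfig(seed=7))
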