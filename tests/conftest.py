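import numpy as np
import pandas as pd
import pytest

from fmtnet import AsvTable, ScenarioConfig, TaxonomyMap, simulate_fmt_timecourse


@pytest.fixture
def tiny_table() -> AsvTable:
    return AsvTable(
        pd.DataFrame(
            {"s1": [5, 1, 0], "s2": [0, 2, 7]},
            index=["a1", "a2", "a3"],
        )
    )


@pytest.fixture
def random_table() -> AsvTable:
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 200, size=(30, 8))
    return AsvTable(
        pd.DataFrame(counts, index=[f"asv{i}" for i in range(30)],
                     columns=[f"s{i}" for i in range(8)])
    )


@pytest.fixture
def toy_taxonomy() -> TaxonomyMap:
    return TaxonomyMap({
        "a1": ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
               "Streptococcaceae", "Streptococcus", "unassigned"),
        "a2": ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
               "Streptococcaceae", "Streptococcus", "unassigned"),
        "a3": ("Bacteria", "Proteobacteria", "unassigned", "unassigned",
               "unassigned", "Klebsiella", "unassigned"),
    })


def small_scenario(seed: int = 0) -> ScenarioConfig:
    """Reduced scenario for fast pipeline-level tests."""
    return ScenarioConfig(
        n_taxa_donor=30,
        n_taxa_recipient=60,
        n_overlap=6,
        group_sizes={"P": 6, "CV": 6, "AT": 5, "AM": 4, "M": 4, "S": 4},
        timepoints=(3, 21),
        seed=seed,
    )


@pytest.fixture(scope="session")
def scenario_default():
    """One full-size simulated scenario shared across the session."""
    return simulate_fmt_timecourse(ScenarioConfig(seed=11))
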