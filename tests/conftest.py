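import numpy as np
import pandas as pd
import pytest

import twinlin as tl


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort: one family per membrane type plus one DZ pair."""
    return tl.CohortConfig(n_mcma=1, n_mcda=1, n_dcda=1, n_triplets=0, n_dz=1)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return tl.simulate_cohort(small_config, seed=11)


@pytest.fixture(scope="session")
def default_tree():
    params = tl.SimulationParams(seed=3, n_generations=8)
    tree, catalog = tl.simulate_lineage(params)
    return params, tree, catalog


def make_table(rows, parent_flags=None):
    """Build a VariantTable from (family, variant, sample, depth, alt) rows."""
    df = pd.DataFrame(rows, columns=["family", "variant", "sample", "depth", "alt"])
    df["vaf"] = np.where(df["depth"] > 0, df["alt"] / df["depth"].clip(lower=1), np.nan)
    return tl.VariantTable(df, parent_flags=parent_flags)
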