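import dataclasses

import numpy as np
import pandas as pd
import pytest

import thri


@pytest.fixture
def registry():
    return thri.default_registry()


def make_table(records, registry=None):
    df = pd.DataFrame(
        records,
        columns=["species", "condition", "timepoint", "replicate", "trait", "value"],
    )
    return thri.TraitTable(df, registry=registry)


@pytest.fixture
def small_table():
    """One species, 2x2 design, 3 replicates, two traits of opposite direction."""
    rng = np.random.default_rng(7)
    rows = []
    for tp in ("June", "August"):
        for cond in ("control", "urban"):
            for rep in (1, 2, 3):
                rows.append(("Tilia", cond, tp, rep, "PhiII", rng.uniform(0.3, 0.7)))
                rows.append(("Tilia", cond, tp, rep, "TBARS", rng.uniform(4, 30)))
    return make_table(rows)


@pytest.fixture
def table2_tilia_means():
    """Published Tilia biochemical group means as single pseudo-replicates."""
    rows = []
    means = thri.published_group_means()
    sub = means[
        (means.species == "Tilia")
        & means.trait.isin(["TBARS", "Proline", "GSH", "APX", "CAT"])
    ]
    for _, r in sub.iterrows():
        rows.append((r.species, r.condition, r.timepoint, 1, r.trait, r["mean"]))
    return make_table(rows)


@pytest.fixture
def paper_config():
    return thri.default_paper_config()


@pytest.fixture
def synthetic_table(paper_config):
    return thri.generate(dataclasses.replace(paper_config, seed=11))
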