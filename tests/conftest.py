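"""Shared fixtures: the default four-group synthetic study, computed once."""

import numpy as np
import pandas as pd
import pytest

from epidrift import discriminate as disc
from epidrift.imaging import build_feature_table
from epidrift.infinium import beta_matrix_from_probe_table, filter_probes
from epidrift.synthdata import (
    default_methylation_config,
    design_for,
    gen_methylation_dataset,
    gen_nuclear_field,
    image_config_for_group,
)

FIXTURE_SEED = 20121121


@pytest.fixture(scope="session")
def four_group_fields():
    """One synthetic field per experimental group (DAPI, marker, truth)."""
    out = {}
    for g in (1, 2, 3, 4):
        cfg = image_config_for_group(g, seed=FIXTURE_SEED + g)
        out[g] = gen_nuclear_field(cfg)
    return out


@pytest.fixture(scope="session")
def cell_table(four_group_fields):
    """Merged 25-feature per-nucleus table across the four groups."""
    fields = [
        (d, m, g, f"group{g}") for g, (d, m, t) in four_group_fields.items()
    ]
    return build_feature_table(fields)


@pytest.fixture(scope="session")
def standardized_cells(cell_table):
    with pytest.warns(UserWarning):  # euler_number is constant on solid nuclei
        return disc.standardize(disc.feature_matrix_from_table(cell_table))


@pytest.fixture(scope="session")
def methylation_study():
    """Default four-group methylation dataset plus truth and design."""
    cfg = default_methylation_config(seed=FIXTURE_SEED)
    probe_table, truth = gen_methylation_dataset(cfg)
    return cfg, probe_table, truth


@pytest.fixture(scope="session")
def filtered_betas(methylation_study):
    cfg, probe_table, _ = methylation_study
    bm = beta_matrix_from_probe_table(probe_table, design_for(cfg), normalize=False)
    return filter_probes(bm, alpha=0.01)


@pytest.fixture(scope="session")
def null_manova_pvalues():
    """MANOVA p-values for 1000 datasets simulated under the null.

    Four groups of 30 rows drawn from one 10-dimensional standard normal.
    """
    rng = np.random.default_rng(FIXTURE_SEED)
    labels = pd.Series(np.repeat([1, 2, 3, 4], 30))
    pvals = []
    for _ in range(1000):
        X = rng.standard_normal((120, 10))
        m = disc.FeatureMatrix(
            X=pd.DataFrame(X), labels=labels.copy()
        )
        pvals.append(disc.manova(m).p_value)
    return np.array(pvals)
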