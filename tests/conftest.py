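"""Shared fixtures: a small synthetic DO cohort reused across test modules.

Everything is generated programmatically with fixed seeds; no data files.
"""

import numpy as np
import pytest

import domqtl as dq


@pytest.fixture(scope="session")
def small_map():
    return dq.make_genetic_map(n_chr=5, markers_per_chr=50, chr_length_mbp=100, seed=11)


@pytest.fixture(scope="session")
def cohort(small_map):
    """200 mice on a 5x50-marker genome with LOCO kinship and covariates."""
    mosaic = dq.simulate_do_mosaics(small_map, n_mice=200, n_generations=20, seed=21)
    probs = dq.mosaics_to_probs(mosaic, small_map, softness=0.02)
    covars = dq.simulate_covariates(200, n_waves=3, seed=22)
    kin = dq.calc_kinship_loco(probs)
    return {"map": small_map, "probs": probs, "covars": covars, "kin": kin}


@pytest.fixture(scope="session")
def qtl_trait(cohort):
    """One trait with a planted QTL at chr3 ~50 Mbp (40% variance) plus
    polygenic background, and its truth record."""
    spec = dq.SimTraitSpec(
        name="planted",
        qtls=[dq.QTLSpec("3", 50.0, np.arange(8.0), 0.4)],
        h2_polygenic=0.3,
        seed=33,
    )
    traits, truth = dq.simulate_traits(cohort["probs"], cohort["map"], cohort["covars"], [spec])
    return traits["planted"], truth[0]
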