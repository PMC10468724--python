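import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from fertgwas import compute_grm, gower_scale, simulate_genotypes, simulate_study
from fertgwas.varcomp import design_matrix


@pytest.fixture(scope="session")
def small_study():
    """A moderate simulated study shared by several modules.

    n=250, m=500, two planted QTL of 5% PVE each on a 30% heritable
    liability, 4 farms x 2 seasons for quick covariate designs.
    """
    gm = simulate_genotypes(250, 500, seed=11)
    phen, truth = simulate_study(
        gm, n_qtl=2, qtl_pve_each=0.05, h2_target=0.30,
        n_farms=4, n_seasons=2, seed=11,
    )
    grm = gower_scale(compute_grm(gm))
    y = phen["ri"].to_numpy(dtype=float)
    X = design_matrix(phen, "farm_season")
    return {"gm": gm, "phen": phen, "truth": truth, "grm": grm, "y": y, "X": X}


@pytest.fixture(scope="session")
def tiny_instance():
    """n=20 instance for dense-matrix oracles."""
    gm = simulate_genotypes(20, 30, maf_low=0.1, maf_high=0.5, ld_block_size=3, seed=3)
    rng = np.random.default_rng(3)
    y = rng.normal(size=20)
    X = np.column_stack([np.ones(20), rng.normal(size=20)])
    grm = gower_scale(compute_grm(gm))
    return {"gm": gm, "y": y, "X": X, "grm": grm}
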