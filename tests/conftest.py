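import numpy as np
import pandas as pd
import pytest

from epiqtl.maps import LinkageMap
from epiqtl.simulate import (EpistaticPairSpec, QTLLocus, TraitSpec,
                             mini_config, simulate_cross, simulate_phenotypes,
                             true_ad_grid)


@pytest.fixture(scope="session")
def small_map():
    """Three markers, distinct female/male positions."""
    rows = [("1", "m1", 0.0, 0.0, 0.0),
            ("1", "m2", 24.0, 16.0, 20.0),
            ("1", "m3", 60.0, 40.0, 50.0)]
    return LinkageMap(pd.DataFrame(
        rows, columns=["chromosome", "marker", "female_cM", "male_cM",
                       "sexavg_cM"]))


@pytest.fixture(scope="session")
def qtl_study():
    """Mini cross with one additive QTL and one epistatic pair, plus a
    second trait sharing the chromosome-1 locus."""
    spec_a = TraitSpec("G_a",
                       loci=(QTLLocus("1", 30.0, a=0.4), QTLLocus("2", 70.0)),
                       pairs=(EpistaticPairSpec(0, 1, i_aa=0.5),),
                       maternal_var=0.1, residual_var=1.0)
    spec_b = TraitSpec("G_b", loci=(QTLLocus("1", 30.0, a=0.4),),
                       maternal_var=0.1, residual_var=1.0)
    cfg = mini_config(seed=42, traits=(spec_a, spec_b))
    cross = simulate_cross(cfg)
    table, truth = simulate_phenotypes(cross)
    grid = true_ad_grid(cross)
    return {"config": cfg, "cross": cross, "table": table, "truth": truth,
            "grid": grid}


@pytest.fixture(scope="session")
def null_study():
    """Mini cross with no genetic effects at all."""
    cfg = mini_config(seed=7, traits=(TraitSpec("G", maternal_var=0.1,
                                                residual_var=1.0),))
    cross = simulate_cross(cfg)
    table, truth = simulate_phenotypes(cross)
    grid = true_ad_grid(cross)
    return {"config": cfg, "cross": cross, "table": table, "truth": truth,
            "grid": grid}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
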