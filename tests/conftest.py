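import numpy as np
import pandas as pd
import pytest

from piedmap import simdata
from piedmap.simdata import CrossSpec, PanelSpec


@pytest.fixture(scope="session")
def small_cross():
    """Noise-free 2-chromosome cross: (truth, observed, true_map)."""
    spec = CrossSpec(n_individuals=200, chromosomes=[(25, 60.0), (25, 60.0)], seed=11)
    return simdata.sim_f2_cross(spec)


@pytest.fixture(scope="session")
def noisy_cross():
    """Cross with genotyping error and missingness."""
    spec = CrossSpec(
        n_individuals=150,
        chromosomes=[(30, 80.0)],
        genotyping_error_rate=0.01,
        missing_rate=0.05,
        seed=12,
    )
    return simdata.sim_f2_cross(spec)


@pytest.fixture(scope="session")
def small_panel():
    """Variant panel with two planted fixed sites (indices 5 and 6)."""
    spec = PanelSpec(n_case=10, n_background=20, n_sites=60,
                     planted_sites=(5, 6), gl_error_rate=0.02, seed=13)
    return simdata.sim_population_sites(spec)


def make_site(case_calls, bg_calls, pl_strength=255):
    """Hand-built SiteRecord with calls treated as (near-)certain."""
    from piedmap.popdiff import SiteRecord

    gt = np.array(list(case_calls) + list(bg_calls), dtype=np.int8)
    n = gt.size
    pl = np.full((n, 3), pl_strength, dtype=np.int32)
    for i, g in enumerate(gt):
        if g >= 0:
            pl[i, g] = 0
        else:
            pl[i] = 0
    return SiteRecord(
        "scf", 100, "A", "G", gt, pl,
        [f"s{i}" for i in range(n)],
        np.array(["case"] * len(case_calls) + ["background"] * len(bg_calls)),
    )
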