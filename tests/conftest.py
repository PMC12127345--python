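import numpy as np
import pandas as pd
import pytest

from oasisrisk import synthetic_data as syn
from oasisrisk.survey_io import SurveyTable


@pytest.fixture
def toy_survey() -> SurveyTable:
    """One site, one plot, five quadrats, three species with known totals."""
    rows = []
    # speciesA: counts 3,1,0,2,0 cover .30,.10,0,.20,0 -> 6 ind, cover .6
    # speciesB: counts 2,0,0,0,0 cover .10                -> 2 ind, cover .1
    # speciesC: counts 1,1,1,1,1 cover .06 each           -> 5 ind, cover .3
    a = [3, 1, 0, 2, 0]
    b = [2, 0, 0, 0, 0]
    c = [1, 1, 1, 1, 1]
    for q in range(5):
        for sp, counts, cov in (
            ("speciesA", a, [0.30, 0.10, 0.0, 0.20, 0.0]),
            ("speciesB", b, [0.10, 0.0, 0.0, 0.0, 0.0]),
            ("speciesC", c, [0.06] * 5),
        ):
            if counts[q] > 0:
                rows.append(
                    {
                        "site": "S1",
                        "plot": "P1",
                        "quadrat": f"Q{q + 1}",
                        "species": sp,
                        "count": counts[q],
                        "cover": cov[q],
                    }
                )
    return SurveyTable(records=pd.DataFrame(rows), design=(1, 1, 5))


@pytest.fixture(scope="session")
def small_config() -> syn.GeneratorConfig:
    return syn.GeneratorConfig(
        n_species=16, n_sites=15, nx=25, ny=18, presences_per_species=12, seed=11
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """Traits, truth, survey, env, presences at smoke-test scale."""
    traits, truth = syn.gen_traits(small_config)
    survey = syn.gen_survey(traits, truth, small_config)
    env = syn.gen_env(small_config)
    presences = syn.gen_presences(traits, truth, env, small_config)
    return {
        "config": small_config,
        "traits": traits,
        "truth": truth,
        "survey": survey,
        "env": env,
        "presences": presences,
    }


@pytest.fixture(scope="session")
def default_world():
    """One realisation at default (study-condition) generator settings."""
    gc = syn.GeneratorConfig(seed=1)
    traits, truth = syn.gen_traits(gc)
    survey = syn.gen_survey(traits, truth, gc)
    env = syn.gen_env(gc)
    presences = syn.gen_presences(traits, truth, env, gc)
    return {
        "config": gc,
        "traits": traits,
        "truth": truth,
        "survey": survey,
        "env": env,
        "presences": presences,
    }
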