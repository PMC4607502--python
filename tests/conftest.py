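"""Shared fixtures: published tables, mean-parameter trajectories and
small surrogate ensembles (session-scoped; everything is generated
programmatically)."""

from __future__ import annotations

import pandas as pd
import pytest

from neusep.params import complete_params, load_param_tables
from neusep.simulate import simulate
from neusep.synth import ParameterEnsemble, sample_surrogate_ensemble


@pytest.fixture(scope="session")
def tables():
    return load_param_tables()


@pytest.fixture(scope="session")
def surv(tables):
    base = tables.params_for("survivor")
    init = tables.state_for("survivor")
    return complete_params(base, init), init


@pytest.fixture(scope="session")
def nonsurv(tables):
    base = tables.params_for("nonsurvivor")
    init = tables.state_for("nonsurvivor")
    return complete_params(base, init), init


@pytest.fixture(scope="session")
def surv_traj(surv):
    params, init = surv
    return simulate(params, init, horizon=144.0)


@pytest.fixture(scope="session")
def small_ensembles(tables):
    """300-draw surrogate ensembles per outcome group."""
    es = sample_surrogate_ensemble("survivor", 300, seed=101, tables=tables)
    en = sample_surrogate_ensemble("nonsurvivor", 300, seed=102,
                                   tables=tables)
    return es, en


@pytest.fixture(scope="session")
def combined_ensemble(small_ensembles, tables):
    es, en = small_ensembles
    return ParameterEnsemble(
        pd.concat([es.draws, en.draws], ignore_index=True),
        provenance="sampled-surrogate", tables=tables)
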