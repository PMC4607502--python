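"""RS-HDMR meta-modeling and Sobol' indices against analytic and
Monte-Carlo oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neusep.gsa_hdmr import (auc_damage_gsa, fit_rshdmr, mc_sobol_oracle,
                             rank_uniform)
from neusep.synth import ParameterEnsemble


def uniform_sampler(d):
    return lambda n, rng: rng.random((n, d))


def ishigami(U, a=7.0, b=0.1):
    Z = -np.pi + 2 * np.pi * np.asarray(U)
    return (np.sin(Z[:, 0]) + a * np.sin(Z[:, 1]) ** 2
            + b * Z[:, 2] ** 4 * np.sin(Z[:, 0]))


def ishigami_indices(a=7.0, b=0.1):
    V1 = 0.5 * (1 + b * np.pi ** 4 / 5) ** 2
    V2 = a * a / 8
    V13 = 8 * b * b * np.pi ** 8 / 225
    V = V1 + V2 + V13
    return {"S1": V1 / V, "S2": V2 / V, "S3": 0.0, "S13": V13 / V}


def g_function(U, a=(0.0, 1.0, 4.5, 9.0)):
    U = np.asarray(U)
    out = np.ones(len(U))
    for i, ai in enumerate(a):
        out *= (np.abs(4 * U[:, i] - 2) + ai) / (1 + ai)
    return out


def g_function_first_order(a=(0.0, 1.0, 4.5, 9.0)):
    v = [1.0 / (3 * (1 + ai) ** 2) for ai in a]
    V = np.prod([1 + vi for vi in v]) - 1
    return [vi / V for vi in v]


def test_additive_uniform_inputs():
    rng = np.random.default_rng(0)
    X = rng.random((2000, 3))
    y = X[:, 0] + X[:, 1]
    m = fit_rshdmr(X, y)
    assert m.variance_captured > 0.99
    assert {c.vars for c in m.components} == {(0,), (1,)}
    tot = m.indices.attrs["totals"].set_index("input")
    assert tot.loc["x0", "S_first"] == pytest.approx(0.5, abs=0.03)
    assert tot.loc["x1", "S_first"] == pytest.approx(0.5, abs=0.03)
    # independent inputs: correlated contributions vanish
    assert m.indices["S_b"].abs().max() < 0.02


def test_constant_output_yields_empty_model():
    X = np.random.default_rng(1).random((500, 2))
    m = fit_rshdmr(X, np.full(500, 3.3))
    assert m.f0 == pytest.approx(3.3)
    assert m.components == []
    assert m.variance_captured == 0.0


@pytest.mark.parametrize("bench", ["linear", "ishigami", "gfunction"])
def test_benchmarks_match_independent_oracle(bench):
    """|S_RS-HDMR - S_oracle| <= 0.05 per first-order index at 4000
    samples, on every independent-input benchmark."""
    rng = np.random.default_rng(2)
    if bench == "linear":
        f = lambda U: U[:, 0] + 2.0 * U[:, 1]
        d = 3
    elif bench == "ishigami":
        f = ishigami
        d = 3
    else:
        f = g_function
        d = 4
    X = rng.random((4000, d))
    m = fit_rshdmr(X, f(X))
    got = m.indices.attrs["totals"].set_index("input")["S_first"]
    oracle = mc_sobol_oracle(f, uniform_sampler(d), 2 ** 14, seed=3)
    for i in range(d):
        assert abs(got.get(f"x{i}", 0.0)
                   - oracle.loc[i, "S_first"]) <= 0.05, f"x{i}"


def test_ishigami_against_analytic_values():
    rng = np.random.default_rng(4)
    X = rng.random((4000, 3))
    m = fit_rshdmr(X, ishigami(X))
    ref = ishigami_indices()
    got = {r["set"]: r["S"] for _, r in m.indices.iterrows()}
    assert got["x0"] == pytest.approx(ref["S1"], abs=0.05)
    assert got["x1"] == pytest.approx(ref["S2"], abs=0.05)
    assert got.get("x2", 0.0) == pytest.approx(0.0, abs=0.05)
    assert got.get("x0*x2", 0.0) == pytest.approx(ref["S13"], abs=0.05)
    assert m.variance_captured > 0.9
    # oracle totals: x0 participates in the interaction
    orc = mc_sobol_oracle(ishigami, uniform_sampler(3), 2 ** 14, seed=5)
    assert orc.loc[0, "S_total"] == pytest.approx(ref["S1"] + ref["S13"],
                                                  abs=0.05)
    assert orc.loc[2, "S_first"] == pytest.approx(0.0, abs=0.03)


def test_mc_oracle_trivial_cases():
    orc = mc_sobol_oracle(lambda U: U[:, 0], uniform_sampler(2), 2 ** 13,
                          seed=6)
    assert orc.loc[0, "S_first"] == pytest.approx(1.0, abs=0.03)
    assert orc.loc[1, "S_first"] == pytest.approx(0.0, abs=0.03)
    orc2 = mc_sobol_oracle(lambda U: U[:, 0] + U[:, 1], uniform_sampler(2),
                           2 ** 13, seed=7)
    assert orc2.loc[0, "S_first"] == pytest.approx(0.5, abs=0.04)
    assert orc2.loc[1, "S_first"] == pytest.approx(0.5, abs=0.04)


def test_correlated_inputs_shift_to_correlated_contribution():
    """A duplicated input earns its index through the correlated part,
    not the independent part."""
    rng = np.random.default_rng(8)
    x1 = rng.random(3000)
    x2 = x1 + rng.normal(0, 1e-3, 3000)    # near-perfect correlation
    X = np.column_stack([x1, x2])
    y = x1.copy()
    m = fit_rshdmr(X, y, max_order=1)
    idx = {r["set"]: r for _, r in m.indices.iterrows()}
    if "x1" in idx:
        assert abs(idx["x1"]["S_a"]) <= abs(idx["x1"]["S"]) + 0.02
        assert idx["x1"]["S"] == pytest.approx(idx["x1"]["S_a"]
                                               + idx["x1"]["S_b"], abs=1e-9)
    # the pair jointly explains the output
    assert m.variance_captured > 0.95


def test_exact_duplicate_inputs_raise_named_error():
    rng = np.random.default_rng(9)
    x = rng.random(1000)
    X = np.column_stack([x, x])
    with pytest.raises(np.linalg.LinAlgError, match="collinear"):
        fit_rshdmr(X, x.copy(), var_names=["a", "b"])


def test_variance_captured_monotone_in_order():
    rng = np.random.default_rng(10)
    X = rng.random((3000, 4))
    y = X[:, 0] * X[:, 1] + X[:, 2] * X[:, 3] ** 2 + X[:, 0]
    caps = [fit_rshdmr(X, y, max_order=k).variance_captured
            for k in (1, 2, 3)]
    assert caps[0] <= caps[1] + 1e-9
    assert caps[1] <= caps[2] + 1e-9


def test_sample_rule_enforced():
    rng = np.random.default_rng(11)
    X = rng.random((100, 5))
    with pytest.raises(ValueError, match="sample count"):
        fit_rshdmr(X, X[:, 0])


def test_rank_transform_is_uniform():
    rng = np.random.default_rng(12)
    X = rng.lognormal(0, 3, (500, 2))
    U = rank_uniform(X)
    assert U.min() > 0 and U.max() < 1
    assert stats.kstest(U[:, 0], "uniform").pvalue > 0.01


def test_zero_variance_ensemble_aborts(tables):
    mean, _ = tables.mean_sd_for("survivor")
    df = pd.DataFrame([mean] * 30)
    df["group"] = "survivor"
    ens = ParameterEnsemble(df, tables=tables)
    with pytest.raises(ValueError, match="zero-variance|no varying"):
        auc_damage_gsa(ens, n=50)


def test_damage_decreases_with_killer_decay_rate(small_ensembles):
    """Within each group, cumulative damage falls as the killer-neutrophil
    decay rate rises (rank correlation on ensemble simulations)."""
    from neusep.simulate import damage_metrics, simulate
    for ens in small_ensembles:
        times = np.arange(0.0, 144.0 + 1e-9, 0.5)
        auc = np.empty(len(ens))
        for i in range(len(ens)):
            p, y0 = ens.params_at(i)
            auc[i] = damage_metrics(simulate(p, y0, 144.0, times=times))[0]
        rho = stats.spearmanr(ens.draws["k_NK"], auc).statistic
        assert rho < -0.2


def test_killer_cell_parameters_rank_highly_in_damage_gsa(tables):
    """Within each group, killer-neutrophil kinetics (decay k_NK, damage
    rate k_D_NK) sit among the top-ranked damage drivers; the combined
    two-group analysis additionally retains the CXCR-1 transition rate
    k_NK_IL8 with appreciable total sensitivity."""
    import pandas as pd

    from neusep.synth import ParameterEnsemble
    tops = {}
    for g, seed in (("survivor", 3), ("nonsurvivor", 1003)):
        ens = sample_surrogate_ensemble_cached(g, seed, tables)
        _, m, _ = auc_damage_gsa(ens, n=2000, seed=6)
        tot = m.indices.attrs["totals"].sort_values("S_total",
                                                    ascending=False)
        tops[g] = list(tot["input"])
        assert "k_NK" in tops[g][:6], tops[g][:6]
        assert "k_D_NK" in tops[g][:6], tops[g][:6]
    es = sample_surrogate_ensemble_cached("survivor", 3, tables)
    en = sample_surrogate_ensemble_cached("nonsurvivor", 1003, tables)
    comb = ParameterEnsemble(
        pd.concat([es.draws, en.draws], ignore_index=True), tables=tables)
    _, m, _ = auc_damage_gsa(comb, n=2000, seed=6)
    tot = m.indices.attrs["totals"].sort_values("S_total", ascending=False)
    ranks = {r["input"]: i for i, (_, r) in enumerate(tot.iterrows())}
    assert "k_NK" in list(tot["input"])[:6]
    # the group-splitting transition rate carries real sensitivity in the
    # combined population (upper half of the ranking, positive total)
    assert ranks["k_NK_IL8"] < len(ranks) / 2
    assert tot.set_index("input").loc["k_NK_IL8", "S_total"] > 0.01


def sample_surrogate_ensemble_cached(group, seed, tables,
                                     _cache={}):
    from neusep.synth import sample_surrogate_ensemble
    key = (group, seed)
    if key not in _cache:
        _cache[key] = sample_surrogate_ensemble(group, 500, seed=seed,
                                                tables=tables)
    return _cache[key]
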