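"""Comparisons between survivor and non-survivor parameter ensembles.

Key-parameter screening runs three logistic-regression variable selectors
(L1-regularized with cross-validated penalty, forward conditional stepwise,
backward conditional elimination) on standardized log-scale parameters and
keeps the parameters chosen by all three — the parameters whose posterior
location most strongly predicts outcome.  Marginals are compared with
two-sample Kolmogorov-Smirnov tests and simulated phenotype peaks with
two-sample t-tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import simulate
from .synth import ParameterEnsemble

__all__ = [
    "select_key_parameters",
    "compare_marginals",
    "compare_phenotype_peaks",
    "phenotype_peaks",
    "marginal_report",
]

PHENOTYPES = ("N_B", "N_M", "N_K", "N_KM")


def _design_matrix(ens_surv: ParameterEnsemble,
                   ens_nonsurv: ParameterEnsemble
                   ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    cols = [c for c in ens_surv.param_names if c in ens_nonsurv.param_names]
    a = ens_surv.draws[cols].to_numpy(float)
    b = ens_nonsurv.draws[cols].to_numpy(float)
    X = np.vstack([a, b])
    # predictors are the FITTED parameters: columns that are constant
    # within a group (e.g. the per-group fixed neutrophil source and
    # creatinine clearance) identify the label deterministically and are
    # excluded
    keep = [i for i in range(X.shape[1])
            if np.ptp(a[:, i]) > 0 and np.ptp(b[:, i]) > 0
            and np.all(X[:, i] > 0)]
    names = [cols[i] for i in keep]
    X = np.log(X[:, keep])
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    y = np.concatenate([np.zeros(len(a)), np.ones(len(b))])
    return X, y, names


def _l1_selection(X: np.ndarray, y: np.ndarray, names: list[str],
                  seed: int = 0) -> set[str]:
    from sklearn.linear_model import LogisticRegressionCV
    clf = LogisticRegressionCV(penalty="l1", solver="liblinear", cv=5,
                               Cs=10, random_state=seed, max_iter=2000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        clf.fit(X, y)
    coefs = clf.coef_.ravel()
    return {n for n, c in zip(names, coefs) if abs(c) > 1e-8}


def _lrt_pvalue(X: np.ndarray, y: np.ndarray, cols: list[int],
                candidate: int | None) -> float:
    """Likelihood-ratio p-value for adding (or having) ``candidate`` on top
    of ``cols`` in a logistic model."""
    import statsmodels.api as sm

    def dev(idx: list[int]) -> float:
        Z = sm.add_constant(X[:, idx]) if idx else \
            np.ones((len(y), 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, Z, family=sm.families.Binomial()).fit()
            return float(res.deviance)

    if candidate is None:
        raise ValueError("candidate column required")
    base = [c for c in cols if c != candidate]
    d0 = dev(base)
    d1 = dev(sorted(set(base + [candidate])))
    lr = max(d0 - d1, 0.0)
    return float(stats.chi2.sf(lr, df=1))


def _forward_stepwise(X: np.ndarray, y: np.ndarray, names: list[str],
                      p_enter: float = 0.05) -> set[str]:
    chosen: list[int] = []
    remaining = list(range(X.shape[1]))
    while remaining:
        pvals = [(c, _lrt_pvalue(X, y, chosen + [c], c)) for c in remaining]
        best, p = min(pvals, key=lambda t: t[1])
        if p >= p_enter:
            break
        chosen.append(best)
        remaining.remove(best)
    return {names[c] for c in chosen}


def _backward_stepwise(X: np.ndarray, y: np.ndarray, names: list[str],
                       p_remove: float = 0.10) -> set[str]:
    chosen = list(range(X.shape[1]))
    while chosen:
        pvals = [(c, _lrt_pvalue(X, y, chosen, c)) for c in chosen]
        worst, p = max(pvals, key=lambda t: t[1])
        if p <= p_remove:
            break
        chosen.remove(worst)
    return {names[c] for c in chosen}


def select_key_parameters(ens_surv: ParameterEnsemble,
                          ens_nonsurv: ParameterEnsemble,
                          p_enter: float = 0.05,
                          p_remove: float = 0.10,
                          seed: int = 0) -> set[str]:
    """Parameters selected by all three logistic selectors.

    Predictors are the shared parameter columns on a standardized log
    scale; the response is the source ensemble.  Under perfect separation
    the stepwise criteria are unreliable and the regularized selection is
    returned alone, with a warning.
    """
    X, y, names = _design_matrix(ens_surv, ens_nonsurv)
    if not names:
        return set()
    l1 = _l1_selection(X, y, names, seed=seed)
    if not l1:
        return set()
    # perfect-separation guard: a single standardized predictor that
    # splits the groups exactly makes the conditional models degenerate
    sep = False
    for i in range(X.shape[1]):
        lo0, hi0 = X[y == 0, i].min(), X[y == 0, i].max()
        lo1, hi1 = X[y == 1, i].min(), X[y == 1, i].max()
        if hi0 < lo1 or hi1 < lo0:
            sep = True
            break
    if sep:
        warnings.warn("perfect separation: returning the regularized "
                      "selection only")
        return l1
    fwd = _forward_stepwise(X, y, names, p_enter)
    bwd = _backward_stepwise(X, y, names, p_remove)
    return l1 & fwd & bwd


def compare_marginals(ens_surv: ParameterEnsemble,
                      ens_nonsurv: ParameterEnsemble,
                      param: str) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on one parameter's marginals."""
    a = ens_surv.draws[param].to_numpy(float)
    b = ens_nonsurv.draws[param].to_numpy(float)
    if len(a) < 10 or len(b) < 10:
        raise ValueError("need at least 10 draws per group")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def marginal_report(ens_surv: ParameterEnsemble,
                    ens_nonsurv: ParameterEnsemble,
                    params: list[str] | None = None) -> pd.DataFrame:
    """Per-parameter location/spread summary with KS p-values, mirroring
    the ensemble-comparison figures (mean, quartiles, 2.5-97.5%)."""
    params = params or [c for c in ens_surv.param_names
                        if c in ens_nonsurv.param_names]
    rows = []
    for p in params:
        row: dict[str, float | str] = {"parameter": p}
        for tag, ens in (("surv", ens_surv), ("nonsurv", ens_nonsurv)):
            v = ens.draws[p].to_numpy(float)
            row[f"mean_{tag}"] = v.mean()
            row[f"q25_{tag}"], row[f"q75_{tag}"] = np.percentile(v, [25, 75])
            row[f"q2.5_{tag}"], row[f"q97.5_{tag}"] = \
                np.percentile(v, [2.5, 97.5])
        if np.ptp(ens_surv.draws[p]) > 0 or np.ptp(ens_nonsurv.draws[p]) > 0:
            _, row["ks_p"] = compare_marginals(ens_surv, ens_nonsurv, p)
        else:
            row["ks_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def phenotype_peaks(ens: ParameterEnsemble,
                    horizon: float = 144.0,
                    grid_h: float = 0.5) -> pd.DataFrame:
    """Per-draw maxima of each neutrophil phenotype over the horizon."""
    times = np.arange(0.0, horizon + 1e-9, grid_h)
    rows = np.empty((len(ens), len(PHENOTYPES)))
    for i in range(len(ens)):
        p, y0 = ens.params_at(i)
        traj = simulate(p, y0, horizon=horizon, times=times)
        rows[i] = [traj.state_series(ph).max() for ph in PHENOTYPES]
    return pd.DataFrame(rows, columns=list(PHENOTYPES))


def compare_phenotype_peaks(peaks_surv: pd.DataFrame,
                            peaks_nonsurv: pd.DataFrame) -> pd.DataFrame:
    """Two-sample t-tests on per-trajectory phenotype maxima.

    Accepts the frames produced by :func:`phenotype_peaks` (or any frames
    with one column per phenotype).  Returns t statistic and p per
    phenotype (survivor minus non-survivor orientation).
    """
    rows = []
    for ph in peaks_surv.columns:
        a = peaks_surv[ph].to_numpy(float)
        b = peaks_nonsurv[ph].to_numpy(float)
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b)
        rows.append({"phenotype": ph, "t": float(t), "p": float(p),
                     "mean_surv": a.mean(), "mean_nonsurv": b.mean()})
    return pd.DataFrame(rows)
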