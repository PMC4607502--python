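"""Bayesian ensemble calibration by parallel tempering.

A ladder of Metropolis chains at increasing temperatures exchanges states
so the cold chain can escape local optima of the weighted sum-of-squares
fitness.  Proposals are Gaussian in log-parameter space under log-uniform
priors; per-chain step sizes and the temperature ladder are servo-adapted
toward a 23% acceptance rate and a 15-30% swap-rate band, then frozen,
and only post-freeze cold-chain samples enter the reported ensemble.
Convergence is judged by the Gelman-Rubin potential scale reduction
factor (PSRF < 1.1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import (FITTED_GROUP, FITTED_SHARED, ModelParams, ModelState,
                     ParamTables, complete_params, load_param_tables)
from .simulate import SimulationError, apply_detection_limit, simulate
from .synth import ObservationSet, ParameterEnsemble

__all__ = [
    "PTConfig",
    "ChainSet",
    "log_fitness",
    "sample_pt",
    "run_pt",
    "psrf",
    "two_round_fit",
]


@dataclass
class PTConfig:
    """Sampler control knobs.

    The production protocol saves every 25th step and adapts step sizes and
    temperatures every 6,250 and 2,500 proposals; desk-scale runs shrink
    ``n_adapt``/``n_save``/``save_every`` but keep the same servo logic.
    """

    n_chains: int = 6
    save_every: int = 25
    swap_every: int = 25
    step_adapt_every: int = 6250
    temp_adapt_every: int = 2500
    target_accept: float = 0.23
    swap_band: tuple[float, float] = (0.15, 0.30)
    n_adapt: int = 12500        # proposals before the servos freeze
    n_save: int = 2000          # cold-chain samples collected after freeze
    max_temp: float = 1e3
    init_step: float = 0.1      # initial step SD, in units of prior width
    init_draws: int = 1000      # prior draws for the max-energy screen
    init_quantile: float = 0.01
    prior_decades: float = 3.0  # half-width of default log10-uniform priors
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("save_every", "swap_every", "step_adapt_every",
                     "temp_adapt_every", "n_adapt", "n_save", "n_chains"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        lo, hi = self.swap_band
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("swap band must satisfy 0 < lo < hi < 1")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError("target acceptance must be in (0, 1)")


@dataclass
class ChainSet:
    """Post-freeze sampler output (cold chain plus ladder diagnostics)."""

    samples: np.ndarray            # (n_save, d), sampler coordinates
    log_fitness: np.ndarray        # (n_save,)
    temperatures: np.ndarray       # ladder after adaptation, T[0] == 1
    accept_rate: np.ndarray        # per-chain, post-freeze
    swap_rate: np.ndarray          # per adjacent pair, post-freeze
    step_sizes: np.ndarray         # (n_chains, d) frozen proposal SDs
    param_names: list[str] = field(default_factory=list)
    n_proposals: int = 0

    def to_frame(self) -> pd.DataFrame:
        names = self.param_names or [f"x{i}" for i in
                                     range(self.samples.shape[1])]
        return pd.DataFrame(self.samples, columns=names)


def log_fitness(params: ModelParams,
                data: ObservationSet | list[ObservationSet],
                init: ModelState | list[ModelState] | None = None,
                weights: float | dict[str, float] = 1.0,
                rtol: float = 1e-6,
                atol: float | np.ndarray | None = None) -> float:
    """Weighted sum-of-squares log fitness of ``params`` against data.

    Returns ``-sum_{i,j,k} w * (y - yhat)^2 / (2 sigma^2)`` over time points
    *i*, observables *j* and datasets *k*; simulated pathogen is censored at
    the 4.4 CFU detection limit before residuals are formed.  A failed
    integration scores ``-inf``.
    """
    datasets = data if isinstance(data, list) else [data]
    if init is None:
        tabs = load_param_tables()
        inits = [tabs.state_for(d.group) for d in datasets]
    else:
        inits = init if isinstance(init, list) else [init] * len(datasets)
    total = 0.0
    for obs_set, y0 in zip(datasets, inits):
        times = obs_set.times()
        try:
            traj = simulate(params, y0, horizon=float(times.max()),
                            times=times, rtol=rtol, atol=atol)
        except (SimulationError, ValueError):
            return -math.inf
        tindex = {t: i for i, t in enumerate(traj.times)}
        for obs in obs_set.data["observable"].unique():
            sub = obs_set.series(obs)
            sd = sub["sd"].to_numpy(float)
            if np.any(sd <= 0):
                raise ValueError(f"non-positive SD for observable {obs}")
            sim = np.array([traj.observables[obs][tindex[t]]
                            for t in sub["time_h"]])
            if obs == "pathogen":
                sim = apply_detection_limit(sim, obs_set.detection_limit)
            w = weights.get(obs, 1.0) if isinstance(weights, dict) else weights
            r = (sub["mean"].to_numpy(float) - sim) / sd
            total += w * float(r @ r) / 2.0
    if not np.isfinite(total):
        return -math.inf
    return -total


class _FitnessEvaluator:
    """Precompiled fast path for ``log_fitness`` over fixed datasets.

    Caches the completed parameter vector, the free-parameter indices and
    the per-observable data arrays so one evaluation is a single LSODA call
    plus array arithmetic.  Agrees with :func:`log_fitness` to rounding
    (asserted in the test suite).
    """

    def __init__(self, base: ModelParams, init: ModelState,
                 datasets: list[ObservationSet], free: list[str],
                 weights: float | dict[str, float] = 1.0,
                 rtol: float = 1e-6):
        from scipy.integrate import odeint

        from .model import _rhs
        from .params import PARAM_INDEX
        from .simulate import DEFAULT_ATOL
        self._odeint = odeint
        self._rhs = _rhs
        self.rtol = rtol
        self.atol = DEFAULT_ATOL
        self.theta = complete_params(base, init).to_array()
        self.free_idx = np.array([PARAM_INDEX[n] for n in free])
        self.y0 = init.to_array()
        self.blocks = []
        for obs_set in datasets:
            times = obs_set.times()
            ts = np.concatenate([[0.0], times]) if times[0] != 0.0 else times
            tpos = {t: i for i, t in enumerate(ts)}
            per_obs = []
            for obs in obs_set.data["observable"].unique():
                sub = obs_set.series(obs)
                sd = sub["sd"].to_numpy(float)
                if np.any(sd <= 0):
                    raise ValueError(f"non-positive SD for observable {obs}")
                w = weights.get(obs, 1.0) if isinstance(weights, dict) \
                    else weights
                from .simulate import OBSERVABLE_STATES
                from .params import STATE_INDEX
                col = STATE_INDEX[OBSERVABLE_STATES[obs]]
                rows = np.array([tpos[t] for t in sub["time_h"]])
                per_obs.append((col, rows, sub["mean"].to_numpy(float),
                                sd, w, obs == "pathogen",
                                obs_set.detection_limit))
            self.blocks.append((ts, per_obs))

    def __call__(self, x_log10: np.ndarray) -> float:
        theta = self.theta.copy()
        theta[self.free_idx] = 10.0 ** x_log10
        total = 0.0
        for ts, per_obs in self.blocks:
            sol, info = self._odeint(
                self._rhs, self.y0, ts, args=(theta, 0.0),
                rtol=self.rtol, atol=self.atol, mxstep=100000,
                full_output=True)
            if info["message"] != "Integration successful." or \
                    not np.all(np.isfinite(sol)):
                return -math.inf
            for col, rows, mean, sd, w, censor, limit in per_obs:
                sim = np.maximum(sol[rows, col], 0.0)
                if censor:
                    sim = np.where(sim < limit, 0.0, sim)
                r = (mean - sim) / sd
                total += w * float(r @ r) / 2.0
        if not np.isfinite(total):
            return -math.inf
        return -total


def sample_pt(logf, bounds: np.ndarray, cfg: PTConfig,
              param_names: list[str] | None = None) -> ChainSet:
    """Run the parallel-tempering sampler on an arbitrary log-fitness.

    ``logf`` maps a point inside ``bounds`` (shape ``(d, 2)``) to a scalar;
    the prior is uniform on the box.  Chains start from prior draws passing
    a maximum-energy screen (fitness above the ``init_quantile`` of prior
    draws).  Returns post-freeze cold-chain samples and ladder diagnostics.
    """
    bounds = np.asarray(bounds, dtype=float)
    d = bounds.shape[0]
    width = bounds[:, 1] - bounds[:, 0]
    if np.any(width <= 0):
        raise ValueError("each bound must satisfy lo < hi")
    rng = np.random.default_rng(cfg.seed)
    K = cfg.n_chains

    # geometric initial ladder up to max_temp
    temps = np.geomspace(1.0, cfg.max_temp, K) if K > 1 else np.array([1.0])

    # maximum-energy initialization screen
    screen = bounds[:, 0] + width * rng.random((cfg.init_draws, d))
    screen_f = np.array([logf(x) for x in screen])
    finite = screen_f[np.isfinite(screen_f)]
    if finite.size == 0:
        raise RuntimeError("all prior draws have -inf fitness")
    threshold = np.quantile(finite, cfg.init_quantile)
    x = np.empty((K, d))
    fx = np.empty(K)
    for c in range(K):
        for _ in range(10000):
            cand = bounds[:, 0] + width * rng.random(d)
            f = logf(cand)
            if np.isfinite(f) and f >= threshold:
                x[c], fx[c] = cand, f
                break
        else:
            raise RuntimeError("could not initialize chain above the "
                               "maximum-energy threshold")

    step = np.tile(cfg.init_step * width, (K, 1))
    # hotter chains start with proportionally larger steps
    step *= np.sqrt(temps)[:, None]

    acc_cnt = np.zeros(K, int)
    prop_cnt = np.zeros(K, int)
    swap_acc = np.zeros(max(K - 1, 1), int)
    swap_try = np.zeros(max(K - 1, 1), int)
    post_acc = np.zeros(K, int)
    post_prop = np.zeros(K, int)
    post_swap_acc = np.zeros(max(K - 1, 1), int)
    post_swap_try = np.zeros(max(K - 1, 1), int)

    saved: list[np.ndarray] = []
    saved_f: list[float] = []
    total_steps = cfg.n_adapt + cfg.n_save * cfg.save_every
    adapt_round = 0

    for t in range(1, total_steps + 1):
        adapting = t <= cfg.n_adapt
        for c in range(K):
            prop = x[c] + step[c] * rng.standard_normal(d)
            prop_cnt[c] += 1
            if not adapting:
                post_prop[c] += 1
            if np.any(prop < bounds[:, 0]) or np.any(prop > bounds[:, 1]):
                continue
            f = logf(prop)
            if not np.isfinite(f):
                continue
            if f >= fx[c] or rng.random() < math.exp((f - fx[c]) / temps[c]):
                x[c], fx[c] = prop, f
                acc_cnt[c] += 1
                if not adapting:
                    post_acc[c] += 1

        if K > 1 and t % cfg.swap_every == 0:
            for c in range(K - 1, 0, -1):   # hottest pair first
                swap_try[c - 1] += 1
                if not adapting:
                    post_swap_try[c - 1] += 1
                delta = (fx[c] - fx[c - 1]) * (1.0 / temps[c - 1]
                                               - 1.0 / temps[c])
                if delta >= 0 or rng.random() < math.exp(delta):
                    x[[c - 1, c]] = x[[c, c - 1]]
                    fx[[c - 1, c]] = fx[[c, c - 1]]
                    swap_acc[c - 1] += 1
                    if not adapting:
                        post_swap_acc[c - 1] += 1

        if adapting and t % cfg.step_adapt_every == 0:
            adapt_round += 1
            gain = 2.0 / math.sqrt(adapt_round)
            rates = acc_cnt / np.maximum(prop_cnt, 1)
            step *= np.exp(gain * (rates - cfg.target_accept))[:, None]
            acc_cnt[:] = 0
            prop_cnt[:] = 0
            if np.all(rates == 0) and adapt_round >= 4:
                raise RuntimeError("no proposals accepted during adaptation")

        if adapting and K > 1 and t % cfg.temp_adapt_every == 0:
            rates = swap_acc / np.maximum(swap_try, 1)
            gaps = np.diff(np.log(temps))
            lo, hi = cfg.swap_band
            for c in range(K - 1):
                if rates[c] < lo:
                    gaps[c] *= 0.8
                elif rates[c] > hi:
                    gaps[c] *= 1.25
            # ladder stays within [1, max_temp]; on a too-easy target the
            # swap servo would otherwise inflate the gaps without bound
            log_t = np.concatenate(
                [[0.0], np.cumsum(np.clip(gaps, 1e-4, None))])
            temps = np.exp(np.minimum(log_t, math.log(cfg.max_temp)))
            swap_acc[:] = 0
            swap_try[:] = 0

        if not adapting and (t - cfg.n_adapt) % cfg.save_every == 0:
            saved.append(x[0].copy())
            saved_f.append(fx[0])
            if len(saved) >= cfg.n_save:
                break

    return ChainSet(
        samples=np.array(saved),
        log_fitness=np.array(saved_f),
        temperatures=temps,
        accept_rate=post_acc / np.maximum(post_prop, 1),
        swap_rate=post_swap_acc / np.maximum(post_swap_try, 1),
        step_sizes=step,
        param_names=param_names or [],
        n_proposals=int(prop_cnt.sum() + post_prop.sum()),
    )


def psrf(segments: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Gelman-Rubin potential scale reduction factor per parameter.

    ``segments`` is a list of equal-length post-burn-in sample blocks (or a
    3-D array ``(m, n, d)``).  Degenerate parameters with zero
    within-segment variance report 1.0.
    """
    arr = np.asarray(segments, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    m, n, d = arr.shape
    if m < 2 or n < 10:
        raise ValueError("need >= 2 segments of length >= 10")
    seg_mean = arr.mean(axis=1)                    # (m, d)
    seg_var = arr.var(axis=1, ddof=1)              # (m, d)
    W = seg_var.mean(axis=0)
    B = n * seg_mean.var(axis=0, ddof=1)
    out = np.ones(d)
    ok = W > 0
    var_hat = (n - 1) / n * W[ok] + B[ok] / n
    out[ok] = np.sqrt(var_hat / W[ok])
    return out


def _default_bounds(center: dict[str, float], free: list[str],
                    decades: float) -> np.ndarray:
    b = np.empty((len(free), 2))
    for i, name in enumerate(free):
        c = math.log10(center[name])
        b[i] = (c - decades, c + decades)
    return b


def run_pt(cfg: PTConfig,
           data: ObservationSet | list[ObservationSet],
           free: list[str],
           fixed: dict[str, float] | None = None,
           tables: ParamTables | None = None,
           weights: float | dict[str, float] = 1.0,
           bounds: dict[str, tuple[float, float]] | None = None) -> ChainSet:
    """Calibrate ``free`` parameters of the model to one group's data.

    Sampling happens in log10-parameter space with log-uniform priors
    spanning ``cfg.prior_decades`` either side of the published means
    (overridable via ``bounds``, in natural units).  All other parameters
    stay at the published means for the dataset's group, except entries of
    ``fixed``.
    """
    datasets = data if isinstance(data, list) else [data]
    group = datasets[0].group
    tabs = tables or load_param_tables()
    base = tabs.params_for(group)
    if fixed:
        base = base.replace(**fixed)
    init = tabs.state_for(group)
    center, _ = tabs.mean_sd_for(group)
    if fixed:
        center.update(fixed)
    for name in free:
        if name not in center:
            raise ValueError(f"unknown free parameter {name}")
    if bounds:
        b = np.array([[math.log10(bounds[n][0]), math.log10(bounds[n][1])]
                      if n in bounds else
                      [math.log10(center[n]) - cfg.prior_decades,
                       math.log10(center[n]) + cfg.prior_decades]
                      for n in free])
    else:
        b = _default_bounds(center, list(free), cfg.prior_decades)

    closure_deps = {"k_r1", "k_r2", "K_D_IL8", "k_creat"}
    if closure_deps.isdisjoint(free):
        logf = _FitnessEvaluator(base, init, datasets, list(free),
                                 weights=weights)
    else:
        def logf(x: np.ndarray) -> float:
            p = base.replace(**{n: 10.0 ** xi for n, xi in zip(free, x)})
            try:
                p = complete_params(p, init)
            except ValueError:
                return -math.inf
            return log_fitness(p, datasets, init=[init] * len(datasets),
                               weights=weights)

    return sample_pt(logf, b, cfg, param_names=list(free))


def chainset_to_ensemble(cs: ChainSet, group: str,
                         tables: ParamTables | None = None,
                         seed: int | None = None) -> ParameterEnsemble:
    """Cold-chain samples (log10 space) -> labeled natural-space ensemble."""
    tabs = tables or load_param_tables()
    mean, _ = tabs.mean_sd_for(group)
    df = pd.DataFrame(10.0 ** cs.samples, columns=cs.param_names)
    for name in list(FITTED_SHARED) + list(FITTED_GROUP):
        if name not in df.columns:
            df[name] = mean[name]
    df["k_NG"] = mean["k_NG"]
    df["k_creat"] = mean["k_creat"]
    df["group"] = group
    return ParameterEnsemble(df, provenance="posterior", seed=seed,
                             tables=tabs)


def two_round_fit(data_surv: ObservationSet | list[ObservationSet],
                  data_nonsurv: ObservationSet | list[ObservationSet],
                  key_params: list[str],
                  cfg: PTConfig,
                  free: list[str] | None = None,
                  tables: ParamTables | None = None,
                  run_round1: bool = True
                  ) -> tuple[ParameterEnsemble, ParameterEnsemble]:
    """Two-round shared/split calibration protocol.

    Round 1 fits each group independently (used to screen for key
    parameters; skipped when ``run_round1`` is False).  Round 2 fits both
    datasets jointly: shared parameters take a single value across groups
    while each key parameter takes one value per group; the two
    group-fixed constants (neutrophil source and creatinine clearance)
    keep their published per-group values.  Returns the two round-2
    ensembles.
    """
    import warnings

    free = list(free) if free is not None else \
        list(FITTED_SHARED) + list(FITTED_GROUP)
    key = [k for k in key_params]
    if not set(key).issubset(free):
        raise ValueError("key_params must be a subset of the free set")
    if not key:
        warnings.warn("empty key set: round 2 degenerates to a joint fit")
    shared = [n for n in free if n not in key]
    tabs = tables or load_param_tables()

    round1_medians: dict[str, dict[str, float]] = {}
    if run_round1:
        cs_s = run_pt(cfg, data_surv, free, tables=tabs)
        cfg2 = PTConfig(**{**cfg.__dict__, "seed": cfg.seed + 1})
        cs_n = run_pt(cfg2, data_nonsurv, free, tables=tabs)
        for g, cs_g in (("survivor", cs_s), ("nonsurvivor", cs_n)):
            med = np.median(10.0 ** cs_g.samples, axis=0)
            round1_medians[g] = dict(zip(cs_g.param_names, med))

    ds = data_surv if isinstance(data_surv, list) else [data_surv]
    dn = data_nonsurv if isinstance(data_nonsurv, list) else [data_nonsurv]
    base_s = tabs.params_for("survivor")
    base_n = tabs.params_for("nonsurvivor")
    init_s = tabs.state_for("survivor")
    init_n = tabs.state_for("nonsurvivor")
    center_s, _ = tabs.mean_sd_for("survivor")
    center_n, _ = tabs.mean_sd_for("nonsurvivor")
    # round-1 posteriors, when run, recenter the round-2 priors
    if round1_medians:
        center_s.update(round1_medians["survivor"])
        center_n.update(round1_medians["nonsurvivor"])

    # joint layout: [shared | key (survivor) | key (non-survivor)]
    names = shared + [f"{k}__surv" for k in key] + [f"{k}__nons" for k in key]
    geo_center = {n: math.sqrt(center_s[n] * center_n[n]) for n in shared}
    b = np.vstack([
        _default_bounds(geo_center, shared, cfg.prior_decades)
        if shared else np.empty((0, 2)),
        _default_bounds(center_s, key, cfg.prior_decades)
        if key else np.empty((0, 2)),
        _default_bounds(center_n, key, cfg.prior_decades)
        if key else np.empty((0, 2)),
    ])

    ns, nk = len(shared), len(key)
    ev_s = _FitnessEvaluator(base_s, init_s, ds, shared + key)
    ev_n = _FitnessEvaluator(base_n, init_n, dn, shared + key)

    def logf(x: np.ndarray) -> float:
        x_s = np.concatenate([x[:ns], x[ns:ns + nk]])
        x_n = np.concatenate([x[:ns], x[ns + nk:]])
        f_s = ev_s(x_s)
        if not np.isfinite(f_s):
            return -math.inf
        return f_s + ev_n(x_n)

    cs = sample_pt(logf, b, cfg, param_names=names)

    nat = 10.0 ** cs.samples
    out = []
    for g, keytag, mean in (("survivor", "__surv", center_s),
                            ("nonsurvivor", "__nons", center_n)):
        df = pd.DataFrame(nat[:, :ns], columns=shared)
        for i, k in enumerate(key):
            col = ns + (0 if keytag == "__surv" else nk) + i
            df[k] = nat[:, col]
        for name in list(FITTED_SHARED) + list(FITTED_GROUP):
            if name not in df.columns:
                df[name] = mean[name]
        df["k_NG"] = mean["k_NG"]
        df["k_creat"] = mean["k_creat"]
        df["group"] = g
        out.append(ParameterEnsemble(df, provenance="posterior",
                                     seed=cfg.seed, tables=tabs))
    return out[0], out[1]
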