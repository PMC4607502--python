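"""Model/Results front end for ensemble calibration.

:class:`SepsisEnsembleModel` wraps the mechanistic neutrophil-phenotype
model together with one or both outcome groups' observation sets;
``fit()`` runs the parallel-tempering calibration and returns a
:class:`CalibrationResults` carrying the posterior ensemble(s), chain
diagnostics and a printable summary, with simulation, ensemble comparison
and the treatment trial reachable from the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import (ChainSet, PTConfig, chainset_to_ensemble, psrf,
                        run_pt, two_round_fit)
from .params import ParamTables, TreatmentSpec, complete_params, \
    load_param_tables
from .simulate import Trajectory, simulate
from .synth import ObservationSet, ParameterEnsemble

__all__ = ["SepsisEnsembleModel", "CalibrationResults"]


class SepsisEnsembleModel:
    """Mechanistic sepsis model bound to group-level observation data.

    Parameters
    ----------
    data : one :class:`ObservationSet` or a dict ``{group: ObservationSet}``
        with groups ``survivor`` / ``nonsurvivor``.
    free : parameter names to estimate (default: every fitted rate).
    key_params : parameters allowed to differ between groups in a joint
        (two-group) fit; ignored for single-group data.
    tables : published parameter tables (defaults to the bundled ones).
    """

    def __init__(self, data, free=None, key_params=None,
                 tables: ParamTables | None = None):
        if isinstance(data, ObservationSet):
            data = {data.group: data}
        self.data = dict(data)
        self.tables = tables or load_param_tables()
        from .params import FITTED_GROUP, FITTED_SHARED
        self.free = list(free) if free is not None else \
            list(FITTED_SHARED) + list(FITTED_GROUP)
        self.key_params = list(key_params or [])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "SepsisEnsembleModel":
        """Build from a long-format frame with columns
        group, observable, time_h, mean, sd, n."""
        data = {g: ObservationSet(g, sub.drop(columns="group")
                                  .reset_index(drop=True))
                for g, sub in df.groupby("group")}
        return cls(data, **kw)

    def simulate(self, group: str = "survivor",
                 horizon: float = 144.0,
                 trt: TreatmentSpec | None = None, **kw) -> Trajectory:
        """Trajectory at the published mean parameters for ``group``."""
        base = self.tables.params_for(group)
        init = self.tables.state_for(group)
        params = complete_params(base, init, trt=trt)
        return simulate(params, init, horizon=horizon, trt=trt, **kw)

    def fit(self, config: PTConfig | None = None) -> "CalibrationResults":
        """Calibrate by parallel tempering.

        Single-group data runs one fit; two-group data runs the joint
        shared/split protocol using ``key_params`` (both groups' datasets
        fitted simultaneously, shared parameters common, key parameters
        split per group).
        """
        cfg = config or PTConfig()
        if not self.data:
            raise ValueError("no observation data attached to the model")
        groups = sorted(self.data)
        if len(groups) == 1:
            g = groups[0]
            cs = run_pt(cfg, self.data[g], self.free, tables=self.tables)
            ens = {g: chainset_to_ensemble(cs, g, self.tables, cfg.seed)}
            chains = {g: cs}
        else:
            ens_s, ens_n = two_round_fit(
                self.data["survivor"], self.data["nonsurvivor"],
                self.key_params, cfg, free=self.free, tables=self.tables,
                run_round1=False)
            ens = {"survivor": ens_s, "nonsurvivor": ens_n}
            chains = {}
        return CalibrationResults(self, cfg, ens, chains)


@dataclass
class CalibrationResults:
    """Posterior ensembles plus sampler diagnostics."""

    model: SepsisEnsembleModel
    config: PTConfig
    ensembles: dict[str, ParameterEnsemble]
    chains: dict[str, ChainSet] = field(default_factory=dict)

    def psrf(self, group: str | None = None, n_segments: int = 4
             ) -> pd.Series:
        """Gelman-Rubin PSRF per free parameter from the cold chain."""
        g = group or sorted(self.chains)[0]
        cs = self.chains[g]
        n = (len(cs.samples) // n_segments) * n_segments
        segs = cs.samples[:n].reshape(n_segments, n // n_segments, -1)
        return pd.Series(psrf(segs), index=cs.param_names)

    def posterior_interval(self, group: str, param: str,
                           level: float = 0.95) -> tuple[float, float]:
        v = self.ensembles[group].draws[param].to_numpy(float)
        a = 100 * (1 - level) / 2
        lo, hi = np.percentile(v, [a, 100 - a])
        return float(lo), float(hi)

    def simulate_posterior(self, group: str, n: int = 100,
                           horizon: float = 144.0, seed: int | None = None,
                           times=None) -> list[Trajectory]:
        """Trajectories for ``n`` random posterior draws."""
        ens = self.ensembles[group]
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(ens), size=n)
        out = []
        for i in idx:
            p, y0 = ens.params_at(int(i))
            out.append(simulate(p, y0, horizon=horizon, times=times))
        return out

    def plot_marginals(self, group: str, params: list[str] | None = None,
                       bins: int = 40):
        """Histogram grid of posterior marginals (log10 scale)."""
        import matplotlib.pyplot as plt
        ens = self.ensembles[group]
        params = params or [c for c in ens.param_names
                            if ens.draws[c].nunique() > 1]
        fig, axes = plt.subplots(1, len(params),
                                 figsize=(3 * len(params), 2.5))
        for ax, p in zip(np.atleast_1d(axes), params):
            ax.hist(np.log10(ens.draws[p]), bins=bins)
            ax.set_xlabel(f"log10 {p}")
        return axes

    def summary(self) -> str:
        lines = ["Neutrophil-phenotype sepsis model: ensemble calibration",
                 "=" * 56]
        for g, ens in sorted(self.ensembles.items()):
            lines.append(f"\nGroup: {g}   draws: {len(ens)}   "
                         f"provenance: {ens.provenance}")
            sub = ens.draws[[c for c in ens.param_names]]
            varying = [c for c in sub.columns if sub[c].nunique() > 1]
            tab = sub[varying].describe(percentiles=[.025, .25, .5, .75, .975])
            lines.append(tab.T[["mean", "2.5%", "50%", "97.5%"]]
                         .to_string(float_format=lambda v: f"{v:.4g}"))
            if g in self.chains:
                cs = self.chains[g]
                lines.append(f"cold-chain acceptance: "
                             f"{cs.accept_rate[0]:.3f}   "
                             f"swap rates: "
                             + " ".join(f"{r:.2f}" for r in cs.swap_rate))
                r = self.psrf(g)
                lines.append("PSRF: " + "  ".join(
                    f"{k}={v:.3f}" for k, v in r.items()))
        return "\n".join(lines)
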