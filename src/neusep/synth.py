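"""Synthetic baboon-bacteremia datasets and surrogate parameter ensembles.

The original calibration data are per-group mean +/- SD time series of five
blood observables (pathogen CFU, IL-8, white cell count, elastase/alpha1-PI
complex, creatinine) from 16 animals given an E. coli infusion: 11 died and
5 survived, and the acute arm was sampled over the first hours and then at
11, 23, 35, 47, 72 hours and 6 days.  :func:`generate_dataset` emulates that
structure from a known ground-truth parameter set, which makes calibration,
sensitivity analysis and the treatment trial testable end to end.

:func:`sample_surrogate_ensemble` builds stand-in posterior ensembles by
moment-matched lognormal sampling of the published per-parameter mean/SD.
These surrogates reproduce the published marginals but carry no posterior
covariance (only marginals are published), a fidelity limit documented in
the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .params import (FITTED_GROUP, FITTED_SHARED, GROUP_FIXED, ModelParams,
                     ModelState, ParamTables, complete_params,
                     load_param_tables)
from .simulate import (DETECTION_LIMIT_CFU, OBSERVABLE_STATES,
                       apply_detection_limit, simulate)

__all__ = [
    "DEFAULT_DESIGN_TIMES",
    "OBSERVABLES",
    "ObservationSet",
    "ParameterEnsemble",
    "generate_dataset",
    "sample_surrogate_ensemble",
    "load_observations",
]

#: Acute-arm sampling schedule, hours post-infusion.
DEFAULT_DESIGN_TIMES = np.array([1.0, 2.0, 4.0, 11.0, 23.0, 35.0, 47.0, 72.0, 144.0])

OBSERVABLES = tuple(OBSERVABLE_STATES)

#: Default per-animal coefficient of variation of measurement noise.
DEFAULT_CV = 0.20


@dataclass
class ObservationSet:
    """Group-level time series: one row per (observable, time)."""

    group: str
    data: pd.DataFrame       # columns: observable, time_h, mean, sd, n
    detection_limit: float = DETECTION_LIMIT_CFU

    def __post_init__(self) -> None:
        need = {"observable", "time_h", "mean", "sd", "n"}
        if not need.issubset(self.data.columns):
            raise ValueError(f"observation table needs columns {sorted(need)}")
        if (self.data["sd"] < 0).any():
            raise ValueError("negative SD in observation table")
        t = self.data["time_h"]
        if (t < 0).any() or (t > 672).any():
            raise ValueError("sampling times must lie in [0, 672] hours")

    def series(self, observable: str) -> pd.DataFrame:
        sub = self.data[self.data["observable"] == observable]
        return sub.sort_values("time_h").reset_index(drop=True)

    def times(self) -> np.ndarray:
        return np.unique(self.data["time_h"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "group", self.group)
        out.to_csv(path, index=False)


def load_observations(path: str | Path) -> list[ObservationSet]:
    """Read one or more groups from the CSV schema written by ``to_csv``."""
    df = pd.read_csv(path)
    return [ObservationSet(g, sub.drop(columns="group").reset_index(drop=True))
            for g, sub in df.groupby("group")]


@dataclass
class ParameterEnsemble:
    """Labeled parameter draws (one row per draw).

    ``draws`` holds one column per model parameter plus a ``group`` column;
    ``provenance`` records whether the rows were sampled from published
    marginals (``sampled-surrogate``) or produced by calibration
    (``posterior``).
    """

    draws: pd.DataFrame
    provenance: str = "sampled-surrogate"
    seed: int | None = None
    tables: ParamTables | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if "group" not in self.draws.columns:
            raise ValueError("ensemble draws need a 'group' column")
        num = self.draws.drop(columns="group")
        if (num.to_numpy(dtype=float) < 0).any():
            raise ValueError("ensemble contains negative rates")

    def __len__(self) -> int:
        return len(self.draws)

    @property
    def param_names(self) -> list[str]:
        return [c for c in self.draws.columns if c != "group"]

    def subset(self, group: str) -> "ParameterEnsemble":
        sub = self.draws[self.draws["group"] == group].reset_index(drop=True)
        return ParameterEnsemble(sub, self.provenance, self.seed, self.tables)

    def params_at(self, i: int) -> tuple[ModelParams, ModelState]:
        """Complete :class:`ModelParams` and initial state for row ``i``."""
        tabs = self.tables or load_param_tables()
        row = self.draws.iloc[i]
        base = tabs.params_for(row["group"])
        vals = {k: float(row[k]) for k in self.param_names}
        init = tabs.state_for(row["group"])
        return complete_params(base.replace(**vals), init), init

    def to_csv(self, path: str | Path) -> None:
        self.draws.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path,
                 provenance: str = "posterior") -> "ParameterEnsemble":
        return cls(pd.read_csv(path), provenance=provenance)


def import_study_xls(path: str | Path) -> list[ObservationSet]:
    """Importer stub for the original animal-study spreadsheet.

    The source workbook (one sheet per animal, 16 animals, five observables
    sampled at the acute-arm schedule) has no published layout
    specification, so no parser is provided.  Convert the workbook to the
    long CSV schema ``group, observable, time_h, mean, sd, n`` — observable
    in {pathogen, il8, wbc, elastase, creatinine}, times in hours
    post-infusion — and use :func:`load_observations` instead.
    """
    raise NotImplementedError(
        "spreadsheet layout unspecified; convert to the CSV schema "
        "(group, observable, time_h, mean, sd, n) and call "
        "load_observations()")


def _noise_sd(traj_vals: np.ndarray, cv: float) -> np.ndarray:
    """Per-time-point measurement SD: proportional to the signal with a
    floor of ``cv`` times 5% of the series peak, so that zero-valued
    observations (censored pathogen, pre-induction IL-8) keep a finite SD."""
    floor = cv * 0.05 * max(traj_vals.max(), 1e-12)
    return np.maximum(cv * np.abs(traj_vals), floor)


def generate_dataset(truth: ModelParams,
                     init: ModelState,
                     group: str = "survivor",
                     design: np.ndarray | None = None,
                     cv: float | dict[str, float] = DEFAULT_CV,
                     n: int = 8,
                     seed: int | None = None,
                     horizon: float = 144.0) -> ObservationSet:
    """Simulate ``truth`` and emit a noisy group-level dataset.

    For each observable, ``n`` virtual animals are drawn i.i.d. Gaussian
    around the noiseless trajectory at the design times (truncated at zero),
    pathogen counts are censored at the 4.4 CFU detection limit per animal,
    and the group mean and sample SD are reported.  ``cv = 0`` returns the
    noiseless trajectory with the floor SD retained for likelihood use.
    """
    design = DEFAULT_DESIGN_TIMES if design is None else np.asarray(design, float)
    if design.max() > horizon:
        raise ValueError("design time beyond simulation horizon")
    if isinstance(cv, dict):
        cvs = {o: float(cv.get(o, DEFAULT_CV)) for o in OBSERVABLES}
    else:
        cvs = {o: float(cv) for o in OBSERVABLES}
    if any(v < 0 for v in cvs.values()):
        raise ValueError("noise CV must be >= 0")

    traj = simulate(truth, init, horizon=horizon, times=design)
    sel = np.isin(traj.times, design)
    rng = np.random.default_rng(seed)
    rows = []
    for obs in OBSERVABLES:
        mu = traj.observables[obs][sel]
        # in the noise-free limit the reported SD keeps a 1% CV so the
        # dataset remains usable as a likelihood target
        sd = _noise_sd(mu, cvs[obs] if cvs[obs] > 0 else 0.01)
        if cvs[obs] > 0:
            samples = rng.normal(mu, sd, size=(n, len(mu)))
            samples = np.clip(samples, 0.0, None)
            if obs == "pathogen":
                samples = apply_detection_limit(samples)
            mean, ssd = samples.mean(axis=0), samples.std(axis=0, ddof=1)
            ssd = np.maximum(ssd, sd * 0.1)  # guard exact-zero sample SD
        else:
            mean = apply_detection_limit(mu) if obs == "pathogen" else mu
            ssd = sd
        for t, m, s in zip(design, mean, ssd):
            rows.append((obs, t, m, s, n))
    df = pd.DataFrame(rows, columns=["observable", "time_h", "mean", "sd", "n"])
    return ObservationSet(group, df)


def _lognormal_moments(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given mean and SD."""
    var = sd * sd
    sigma2 = np.log1p(var / (mean * mean))
    mu = np.log(mean) - 0.5 * sigma2
    return mu, np.sqrt(sigma2)


def sample_surrogate_ensemble(group: str,
                              n: int,
                              seed: int | None = None,
                              tables: ParamTables | None = None) -> ParameterEnsemble:
    """Moment-matched lognormal draws of the published per-parameter
    mean/SD for ``group``; parameters published with SD = 0 are fixed.

    Draws are independent across parameters: the published tables carry
    marginal moments only, so the surrogate cannot reproduce posterior
    covariance.
    """
    if n < 1:
        raise ValueError("need n >= 1 draws")
    tabs = tables or load_param_tables()
    mean, sd = tabs.mean_sd_for(group)
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for name in list(FITTED_SHARED) + list(FITTED_GROUP) + list(GROUP_FIXED):
        m, s = mean[name], sd[name]
        if s < 0:
            raise ValueError(f"negative SD for {name}")
        if s == 0:
            cols[name] = np.full(n, m)
        else:
            mu, sig = _lognormal_moments(m, s)
            cols[name] = rng.lognormal(mu, sig, size=n)
    df = pd.DataFrame(cols)
    df["group"] = group
    return ParameterEnsemble(df, provenance="sampled-surrogate", seed=seed,
                             tables=tabs)
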