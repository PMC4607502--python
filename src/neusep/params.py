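"""Parameter and state containers for the neutrophil-phenotype sepsis model.

The model tracks a bacterial pathogen, IL-8 and a generic proinflammatory
ligand (fMLP), CXCR-1/2 receptor occupancy states, four neutrophil
phenotypes, a systemic damage indicator, creatinine and an elastase
biomarker.  Rate constants come in two flavours: *shared* values common to
both outcome groups and *group* values that differ between animals that
survived the bacteremia and those that did not.

A handful of constants appear in the equations but carry no tabulated
value; :func:`complete_params` closes them from the tabulated ones (receptor
association from dissociation rate and affinity, creatinine production from
the healthy steady state) or from explicit configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path
import numpy as np
import yaml

__all__ = [
    "STATE_NAMES",
    "PARAM_NAMES",
    "FITTED_SHARED",
    "FITTED_GROUP",
    "GROUP_FIXED",
    "ModelState",
    "ModelParams",
    "TreatmentSpec",
    "ParamTables",
    "load_param_tables",
    "default_params",
    "default_state",
    "complete_params",
]

#: Order of the dynamic state vector handed to the integrator.
STATE_NAMES = (
    "P",        # pathogen, CFU
    "C_IL8",    # interleukin-8, nM
    "C_fMLP",   # generic proinflammatory ligand, nM
    "C_R1s",    # CXCR-1 surface-bound fraction
    "C_R1i",    # CXCR-1 internalized fraction
    "C_R1t",    # CXCR-1 trapped fraction (treatment)
    "C_R2s",    # CXCR-2 surface-bound fraction
    "C_R2i",    # CXCR-2 internalized fraction
    "C_R2t",    # CXCR-2 trapped fraction (treatment)
    "N_B",      # basal neutrophils, 1e3 cells/ul
    "F",        # mobilization filter (delay) state
    "N_M",      # migratory neutrophils
    "N_K",      # killer neutrophils
    "N_KM",     # dual killer/migratory neutrophils
    "C_elas",   # elastase/alpha1-PI complex, ng/ml
    "D",        # systemic damage, dimensionless in [0, 1]
    "C_creat",  # creatinine, nM
)

STATE_INDEX = {n: i for i, n in enumerate(STATE_NAMES)}


@dataclass
class ModelState:
    """One instant of the model state.  Units as in :data:`STATE_NAMES`."""

    P: float = 0.0
    C_IL8: float = 0.0
    C_fMLP: float = 0.0
    C_R1s: float = 0.0
    C_R1i: float = 0.0
    C_R1t: float = 0.0
    C_R2s: float = 0.0
    C_R2i: float = 0.0
    C_R2t: float = 0.0
    N_B: float = 0.0
    F: float = 0.0
    N_M: float = 0.0
    N_K: float = 0.0
    N_KM: float = 0.0
    C_elas: float = 0.0
    D: float = 0.0
    C_creat: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        return cls(**{n: float(y[i]) for i, n in enumerate(STATE_NAMES)})

    def validate(self) -> None:
        y = self.to_array()
        if np.any(y < 0):
            bad = [n for n, v in zip(STATE_NAMES, y) if v < 0]
            raise ValueError(f"negative state component(s): {bad}")
        if not 0.0 <= self.D <= 1.0:
            raise ValueError(f"damage D={self.D} outside [0, 1]")
        for r in ("R1", "R2"):
            tot = sum(getattr(self, f"C_{r}{s}") for s in ("s", "i", "t"))
            if tot > 1.0 + 1e-9:
                raise ValueError(f"{r} receptor fractions sum to {tot} > 1")


#: Order of the parameter vector handed to the compiled right-hand side.
PARAM_NAMES = (
    # shared, tabulated
    "k_PG", "k_P_NKM", "k_PL", "k_p", "k_pd",
    "k_NB", "k_NK", "k_NM", "k_NKM", "k_NM_NK_IL8",
    "k_IL8_P", "k_IL8_D", "k_IL8", "k_D_NK", "k_Drec",
    "k_filter_on", "k_r1", "k_r2", "K_D_IL8",
    "k_i1", "k_i1p", "k_i2", "k_i2p",
    "k_fMLP", "k_fMLPd", "k_fMLP_D", "k_fMLP_NB", "k_NE",
    # group-specific, tabulated
    "k_NG", "k_creat",
    "k_NB_G", "k_NB_Gd", "k_NK_IL8", "k_NM_IL8", "k_NK_NM_IL8",
    "k_IL8_Pd", "k_filter_off",
    # closures (derived, not tabulated)
    "k_f1", "k_f2", "k_IL8_Dd", "k_creat_P",
    # treatment rates (zero when untreated)
    "k_ft1", "k_ft1p", "k_ft2", "k_ft2p",
    # behaviour switch: multiply the fMLP-pathway flux by C_fMLP when 1
    "fmlp_mass_action",
)

PARAM_INDEX = {n: i for i, n in enumerate(PARAM_NAMES)}

#: Shared rate constants estimated from data (nonzero posterior spread).
FITTED_SHARED = (
    "k_P_NKM", "k_PL", "k_p", "k_NK", "k_NM", "k_NKM", "k_NM_NK_IL8",
    "k_IL8_P", "k_IL8_D", "k_IL8", "k_D_NK", "k_Drec", "k_filter_on",
    "k_fMLP", "k_fMLPd", "k_fMLP_D", "k_fMLP_NB", "k_NE",
)

#: Group-specific rate constants estimated from data.
FITTED_GROUP = (
    "k_NB_G", "k_NB_Gd", "k_NK_IL8", "k_NM_IL8", "k_NK_NM_IL8",
    "k_IL8_Pd", "k_filter_off",
)

#: Fixed constants that nevertheless take a different value per group.
GROUP_FIXED = ("k_NG", "k_creat")


@dataclass
class ModelParams:
    """Full rate-constant set.  Closure fields default to NaN until
    :func:`complete_params` fills them."""

    k_PG: float = np.nan
    k_P_NKM: float = np.nan
    k_PL: float = np.nan
    k_p: float = np.nan
    k_pd: float = np.nan
    k_NB: float = np.nan
    k_NK: float = np.nan
    k_NM: float = np.nan
    k_NKM: float = np.nan
    k_NM_NK_IL8: float = np.nan
    k_IL8_P: float = np.nan
    k_IL8_D: float = np.nan
    k_IL8: float = np.nan
    k_D_NK: float = np.nan
    k_Drec: float = np.nan
    k_filter_on: float = np.nan
    k_r1: float = np.nan
    k_r2: float = np.nan
    K_D_IL8: float = np.nan
    k_i1: float = np.nan
    k_i1p: float = np.nan
    k_i2: float = np.nan
    k_i2p: float = np.nan
    k_fMLP: float = np.nan
    k_fMLPd: float = np.nan
    k_fMLP_D: float = np.nan
    k_fMLP_NB: float = np.nan
    k_NE: float = np.nan
    k_NG: float = np.nan
    k_creat: float = np.nan
    k_NB_G: float = np.nan
    k_NB_Gd: float = np.nan
    k_NK_IL8: float = np.nan
    k_NM_IL8: float = np.nan
    k_NK_NM_IL8: float = np.nan
    k_IL8_Pd: float = np.nan
    k_filter_off: float = np.nan
    k_f1: float = np.nan
    k_f2: float = np.nan
    k_IL8_Dd: float = np.nan
    k_creat_P: float = np.nan
    k_ft1: float = 0.0
    k_ft1p: float = 0.0
    k_ft2: float = 0.0
    k_ft2p: float = 0.0
    fmlp_mass_action: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "ModelParams":
        return cls(**{n: float(theta[i]) for i, n in enumerate(PARAM_NAMES)})

    def replace(self, **kw: float) -> "ModelParams":
        return replace(self, **kw)

    def validate(self, require_closures: bool = True) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in ("k_ft1", "k_ft1p", "k_ft2", "k_ft2p",
                          "fmlp_mass_action"):
                if v < 0:
                    raise ValueError(f"{f.name} must be >= 0, got {v}")
                continue
            if np.isnan(v):
                if require_closures or f.name not in (
                        "k_f1", "k_f2", "k_IL8_Dd", "k_creat_P"):
                    raise ValueError(f"parameter {f.name} is unset")
                continue
            if v < 0:
                raise ValueError(f"rate {f.name} must be positive, got {v}")


@dataclass
class TreatmentSpec:
    """Extracorporeal receptor-trapping treatment window and strength.

    ``Kd_device`` is the dissociation constant of the trapping surface for
    free CXCR-1/2, carried on the same concentration scale as the IL-8
    receptor affinity (2.5e-3); smaller means stronger capture.  Trap and
    release rates may be given explicitly, otherwise they are derived from
    ``Kd_device`` by :func:`complete_params`.
    """

    t_on: float
    t_off: float
    Kd_device: float = np.nan
    k_ft1: float = np.nan
    k_ft2: float = np.nan
    k_ft1p: float = np.nan
    k_ft2p: float = np.nan

    def __post_init__(self) -> None:
        if self.t_on < 0 or self.t_off < self.t_on:
            raise ValueError(
                f"need 0 <= t_on <= t_off, got ({self.t_on}, {self.t_off})")
        if not np.isnan(self.Kd_device) and self.Kd_device <= 0:
            raise ValueError("Kd_device must be > 0")


@dataclass
class ParamTables:
    """Published per-group parameter statistics: mean and posterior SD per
    symbol, plus the shared initial conditions."""

    shared_mean: dict[str, float]
    shared_sd: dict[str, float]
    group_mean: dict[str, dict[str, float]]   # group -> symbol -> mean
    group_sd: dict[str, dict[str, float]]
    init: dict[str, dict[str, float]]         # group -> state symbol -> value

    def params_for(self, group: str) -> ModelParams:
        """Mean-parameter :class:`ModelParams` for ``group`` (closures unset)."""
        vals = dict(self.shared_mean)
        vals.update(self.group_mean[group])
        return ModelParams(**vals)

    def state_for(self, group: str) -> ModelState:
        return ModelState(**self.init[group])

    def mean_sd_for(self, group: str) -> tuple[dict[str, float], dict[str, float]]:
        mean = dict(self.shared_mean)
        mean.update(self.group_mean[group])
        sd = dict(self.shared_sd)
        sd.update(self.group_sd[group])
        return mean, sd


_DATA = Path(__file__).parent / "data" / "baboon_tables.yaml"


def load_param_tables(path: str | Path | None = None) -> ParamTables:
    """Load the bundled (or a user-supplied) parameter/initial-condition file."""
    with open(path or _DATA) as fh:
        raw = yaml.safe_load(fh)
    shared_mean = {k: float(v[0]) for k, v in raw["shared"].items()}
    shared_sd = {k: float(v[1]) for k, v in raw["shared"].items()}
    group_mean: dict[str, dict[str, float]] = {}
    group_sd: dict[str, dict[str, float]] = {}
    for g, tab in raw["group"].items():
        group_mean[g] = {k: float(v[0]) for k, v in tab.items()}
        group_sd[g] = {k: float(v[1]) for k, v in tab.items()}
    init = {g: {k: float(v) for k, v in tab.items()}
            for g, tab in raw["init"].items()}
    return ParamTables(shared_mean, shared_sd, group_mean, group_sd, init)


def default_params(group: str = "survivor",
                   complete: bool = True) -> ModelParams:
    """Mean published parameters for ``group``, closures filled by default."""
    tabs = load_param_tables()
    p = tabs.params_for(group)
    if complete:
        p = complete_params(p, tabs.state_for(group))
    return p


def default_state(group: str = "survivor") -> ModelState:
    return load_param_tables().state_for(group)


def complete_params(raw: ModelParams,
                    init: ModelState,
                    trt: TreatmentSpec | None = None,
                    k_IL8_Dd: float = 1.0,
                    fmlp_mass_action: bool = False) -> ModelParams:
    """Fill the closure constants the equations need but no table provides.

    * association rates from detailed balance, ``k_f = k_r / K_D``;
    * creatinine production pinned so that creatinine is stationary at its
      healthy baseline when damage is zero, ``k_creat_P = k_creat * C_creat(0)``;
    * the damage-driven IL-8 Hill constant ``k_IL8_Dd`` from configuration
      (dimensionless damage-squared scale, default 1.0);
    * device trap/untrap rates: release mirrors the receptor recycle rates
      (``k_ftX' = k_iX'``) and capture follows from the device dissociation
      constant, ``k_ftX = k_ftX' / Kd_device``, the same detailed-balance
      construction used for IL-8 binding.
    """
    for name in ("k_r1", "k_r2", "K_D_IL8", "k_creat"):
        if np.isnan(getattr(raw, name)):
            raise ValueError(f"tabulated parameter {name} is missing")
    out = raw.replace(
        k_f1=raw.k_r1 / raw.K_D_IL8,
        k_f2=raw.k_r2 / raw.K_D_IL8,
        k_creat_P=raw.k_creat * init.C_creat,
        k_IL8_Dd=k_IL8_Dd,
        fmlp_mass_action=float(fmlp_mass_action),
    )
    if trt is not None:
        k_ft1p = trt.k_ft1p if not np.isnan(trt.k_ft1p) else raw.k_i1p
        k_ft2p = trt.k_ft2p if not np.isnan(trt.k_ft2p) else raw.k_i2p
        if not np.isnan(trt.k_ft1):
            k_ft1, k_ft2 = trt.k_ft1, trt.k_ft2
        else:
            if np.isnan(trt.Kd_device):
                raise ValueError("TreatmentSpec needs Kd_device or explicit rates")
            k_ft1 = k_ft1p / trt.Kd_device
            k_ft2 = k_ft2p / trt.Kd_device
        out = out.replace(k_ft1=k_ft1, k_ft2=k_ft2,
                          k_ft1p=k_ft1p, k_ft2p=k_ft2p)
    out.validate()
    return out
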