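"""Trajectory integration, observables and damage metrics.

Integration uses LSODA (stiff/non-stiff switching): the receptor level
relaxes within minutes while the systemic level evolves over days, so the
system is stiff over most of the horizon.  Treatment on/off switches are
handled by restarting the integrator exactly at the discontinuities rather
than letting the step controller straddle them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import odeint, trapezoid

from .model import _rhs
from .params import (ModelParams, ModelState, STATE_INDEX, STATE_NAMES,
                     TreatmentSpec)

__all__ = [
    "Trajectory",
    "SimulationError",
    "simulate",
    "damage_metrics",
    "apply_detection_limit",
    "OBSERVABLE_STATES",
    "DETECTION_LIMIT_CFU",
]

#: Pathogen counts below this value are unresolvable experimentally.
DETECTION_LIMIT_CFU = 4.4

#: Observable name -> state column(s).  WBC maps to basal neutrophils by
#: default; pass ``wbc_total=True`` to ``simulate`` to sum all phenotypes.
OBSERVABLE_STATES = {
    "pathogen": "P",
    "il8": "C_IL8",
    "wbc": "N_B",
    "elastase": "C_elas",
    "creatinine": "C_creat",
}

_NONNEG_TOL = 1e-8

#: Per-state absolute tolerances.  State scales span ~18 orders of
#: magnitude (pathogen up to 6e6 CFU, fMLP equilibrium ~1e-11 nM), so a
#: scalar atol either drowns the small states in noise or wastes steps on
#: the large ones.
DEFAULT_ATOL = np.array([
    1e-8,    # P
    1e-14,   # C_IL8
    1e-16,   # C_fMLP
    1e-12, 1e-12, 1e-12,   # C_R1s, C_R1i, C_R1t
    1e-12, 1e-12, 1e-12,   # C_R2s, C_R2i, C_R2t
    1e-9,    # N_B
    1e-9,    # F
    1e-9, 1e-9, 1e-9,      # N_M, N_K, N_KM
    1e-9,    # C_elas
    1e-11,   # D
    1e-7,    # C_creat
])


class SimulationError(RuntimeError):
    """Integration failure, carrying the failing time and state."""

    def __init__(self, msg: str, t: float | None = None,
                 state: np.ndarray | None = None):
        super().__init__(msg)
        self.t = t
        self.state = state


@dataclass
class Trajectory:
    """Dense model solution plus the fitted observables."""

    times: np.ndarray                  # hours, strictly increasing, times[0]=0
    states: np.ndarray                 # (n_times, 17)
    observables: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def state_series(self, name: str) -> np.ndarray:
        return self.states[:, STATE_INDEX[name]]

    def final_state(self) -> ModelState:
        return ModelState.from_array(self.states[-1])

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_h", self.times)
        return df

    def plot(self, names: tuple[str, ...] = ("P", "C_IL8", "N_B", "N_K",
                                             "D", "C_creat"), ax=None):
        """Quick-look panel of selected state series (log scale where the
        dynamic range warrants it)."""
        import matplotlib.pyplot as plt
        if ax is None:
            fig, axes = plt.subplots(len(names), 1, sharex=True,
                                     figsize=(6, 1.8 * len(names)))
        else:
            axes = np.atleast_1d(ax)
        for a, name in zip(np.atleast_1d(axes), names):
            y = self.state_series(name)
            a.plot(self.times, y)
            if y.max() > 0 and y.max() / max(y[y > 0].min(), 1e-300) > 1e3:
                a.set_yscale("symlog", linthresh=max(y.max() * 1e-6, 1e-12))
            a.set_ylabel(name)
        np.atleast_1d(axes)[-1].set_xlabel("time (h)")
        return axes


def _default_grid(horizon: float, extra: np.ndarray | None) -> np.ndarray:
    grid = np.arange(0.0, horizon + 1e-9, 0.1)
    if grid[-1] < horizon:
        grid = np.append(grid, horizon)
    if extra is not None:
        grid = np.union1d(grid, np.asarray(extra, dtype=float))
    return grid


def _integrate_segment(y0: np.ndarray, ts: np.ndarray, theta: np.ndarray,
                       trap_on: float, rtol: float, atol: float) -> np.ndarray:
    if len(ts) == 1:
        return y0[None, :]
    out, info = odeint(_rhs, y0, ts, args=(theta, trap_on),
                       rtol=rtol, atol=atol, mxstep=100000,
                       full_output=True, tfirst=False)
    if info["message"] != "Integration successful.":
        i = max(int(np.searchsorted(ts, info.get("tcur", [ts[0]])[-1])) - 1, 0)
        raise SimulationError(
            f"LSODA failed: {info['message']}", t=float(ts[min(i, len(ts) - 1)]),
            state=out[min(i, len(out) - 1)])
    return out


def simulate(params: ModelParams,
             init: ModelState,
             horizon: float = 144.0,
             trt: TreatmentSpec | None = None,
             times: np.ndarray | None = None,
             rtol: float = 1e-7,
             atol: float | np.ndarray | None = None,
             wbc_total: bool = False,
             check_nonneg: bool = True) -> Trajectory:
    """Integrate the model over ``[0, horizon]`` hours.

    ``times`` overrides the default dense grid (0.1 h spacing).  When a
    treatment window is given the integration restarts at ``t_on`` and
    ``t_off`` so the Heaviside switch is event-exact; the window times are
    inserted into the output grid.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if atol is None:
        atol = DEFAULT_ATOL
    params.validate()
    theta = params.to_array()
    if times is None:
        ts = _default_grid(horizon, None)
    else:
        ts = np.asarray(times, dtype=float)
        if ts[0] != 0.0:
            ts = np.concatenate([[0.0], ts])
        if np.any(np.diff(ts) <= 0):
            raise ValueError("output times must be strictly increasing")
        if ts[-1] > horizon:
            raise ValueError("output times exceed the horizon")

    # segment boundaries where the trapping term switches
    cuts = [0.0]
    if trt is not None:
        for tc in (trt.t_on, trt.t_off):
            if 0.0 < tc < horizon:
                cuts.append(float(tc))
    cuts.append(float(ts[-1]))
    cuts = sorted(set(cuts))

    y0 = init.to_array()
    segments: list[np.ndarray] = []
    seg_times: list[np.ndarray] = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        trap_on = 0.0
        if trt is not None and trt.t_on <= a < trt.t_off:
            trap_on = 1.0
        inner = ts[(ts > a) & (ts < b)]
        seg_ts = np.concatenate([[a], inner, [b]])
        sol = _integrate_segment(y0, seg_ts, theta, trap_on, rtol, atol)
        y0 = sol[-1]
        keep = np.isin(seg_ts, ts)
        keep[-1] = False  # boundary points belong to the next segment
        segments.append(sol[keep])
        seg_times.append(seg_ts[keep])
    if ts[-1] in ts:  # final point
        segments.append(y0[None, :])
        seg_times.append(np.array([ts[-1]]))
    states = np.vstack(segments)
    out_times = np.concatenate(seg_times)
    order = np.argsort(out_times)
    out_times, states = out_times[order], states[order]
    # drop duplicates introduced by cut points that coincide with grid points
    uniq = np.concatenate([[True], np.diff(out_times) > 0])
    out_times, states = out_times[uniq], states[uniq]

    if check_nonneg:
        # floor check, relative to each state's excursion so that the
        # pathogen's 1e6 CFU scale and fMLP's 1e-11 nM scale are judged
        # by the same 1e-8 relative yardstick
        tol = _NONNEG_TOL * np.maximum(1.0, states.max(axis=0))
        worst = states.min(axis=0)
        bad = worst < -tol
        if np.any(bad):
            j = int(np.flatnonzero(bad)[0])
            i = int(np.argmin(states[:, j]))
            raise SimulationError(
                f"state {STATE_NAMES[j]} fell to {worst[j]:.3e} "
                f"at t={out_times[i]:.2f} h", t=float(out_times[i]),
                state=states[i])
        states = np.clip(states, 0.0, None)

    obs = {name: states[:, STATE_INDEX[col]].copy()
           for name, col in OBSERVABLE_STATES.items()}
    if wbc_total:
        obs["wbc"] = (states[:, STATE_INDEX["N_B"]]
                      + states[:, STATE_INDEX["N_M"]]
                      + states[:, STATE_INDEX["N_K"]]
                      + states[:, STATE_INDEX["N_KM"]])
    meta = {
        "rtol": rtol, "atol": atol, "horizon": horizon,
        "treatment": None if trt is None else
        (trt.t_on, trt.t_off, trt.Kd_device),
        "params_hash": hash(params.to_array().tobytes()),
    }
    return Trajectory(out_times, states, obs, meta)


def damage_metrics(traj: Trajectory,
                   horizon: float = 144.0) -> tuple[float, float]:
    """Cumulative and peak damage over ``[0, horizon]``.

    Returns ``(AUC_D, peak_D)`` with the area computed by the trapezoid
    rule on the stored grid.
    """
    if traj.times[-1] < horizon - 1e-9:
        raise ValueError(
            f"trajectory ends at {traj.times[-1]} h < horizon {horizon} h")
    mask = traj.times <= horizon + 1e-9
    t = traj.times[mask]
    d = traj.state_series("D")[mask]
    return float(trapezoid(d, t)), float(d.max())


def apply_detection_limit(series: np.ndarray,
                          limit: float = DETECTION_LIMIT_CFU) -> np.ndarray:
    """Censor pathogen values strictly below the assay detection limit to 0."""
    out = np.asarray(series, dtype=float).copy()
    out[out < limit] = 0.0
    return out
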