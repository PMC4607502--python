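"""Right-hand side of the neutrophil-phenotype sepsis model.

The systemic level couples a logistic-with-saturable-clearance pathogen, two
ligands (IL-8 and a generic proinflammatory peptide, fMLP), four neutrophil
phenotypes and a bounded damage variable; the receptor level tracks
non-dimensionalized CXCR-1/2 occupancy (surface-bound, internalized and,
under extracorporeal treatment, trapped), with the free fraction given by
conservation as ``1 - sum``.  Elastase/alpha1-PI is an exact slave of the
killer phenotype; creatinine relaxes to a damage-dependent level.

The heavy lifting happens in a numba-compiled kernel so that ensemble
calibration and the virtual trial can afford 1e5-1e6 integrations.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import ModelParams, ModelState, TreatmentSpec

__all__ = ["rhs_untreated", "rhs_treated", "rhs_array"]


@njit(cache=True)
def _rhs(y, t, th, trap_on):
    """Time-derivative of the 17-component state vector.

    ``th`` is the parameter vector in :data:`neusep.params.PARAM_NAMES`
    order; ``trap_on`` is 1.0 inside the treatment window, else 0.0.
    """
    # Fluxes are evaluated on the nonnegative part of the state: adaptive
    # steppers probe (and may transiently overshoot into) y < 0, where the
    # quadratic pathogen cap would otherwise turn a decaying mode into a
    # finite-time blowup.  Inside the physical domain this is the identity.
    (P, C_IL8, C_fMLP, C_R1s, C_R1i, C_R1t, C_R2s, C_R2i, C_R2t,
     N_B, F, N_M, N_K, N_KM, C_elas, D, C_creat) = (
        max(y[0], 0.0), max(y[1], 0.0), max(y[2], 0.0), max(y[3], 0.0),
        max(y[4], 0.0), max(y[5], 0.0), max(y[6], 0.0), max(y[7], 0.0),
        max(y[8], 0.0), max(y[9], 0.0), max(y[10], 0.0), max(y[11], 0.0),
        max(y[12], 0.0), max(y[13], 0.0), max(y[14], 0.0), max(y[15], 0.0),
        max(y[16], 0.0))

    k_PG, k_P_NKM, k_PL, k_p, k_pd = th[0], th[1], th[2], th[3], th[4]
    k_NB, k_NK, k_NM, k_NKM, k_NM_NK_IL8 = th[5], th[6], th[7], th[8], th[9]
    k_IL8_P, k_IL8_D, k_IL8, k_D_NK, k_Drec = th[10], th[11], th[12], th[13], th[14]
    k_filter_on, k_r1, k_r2 = th[15], th[16], th[17]
    k_i1, k_i1p, k_i2, k_i2p = th[19], th[20], th[21], th[22]
    k_fMLP, k_fMLPd, k_fMLP_D, k_fMLP_NB, k_NE = th[23], th[24], th[25], th[26], th[27]
    k_NG, k_creat = th[28], th[29]
    k_NB_G, k_NB_Gd, k_NK_IL8, k_NM_IL8, k_NK_NM_IL8 = th[30], th[31], th[32], th[33], th[34]
    k_IL8_Pd, k_filter_off = th[35], th[36]
    k_f1, k_f2, k_IL8_Dd, k_creat_P = th[37], th[38], th[39], th[40]
    k_ft1, k_ft1p, k_ft2, k_ft2p = th[41], th[42], th[43], th[44]
    fmlp_mass_action = th[45]

    dy = np.empty(17)

    # pathogen: linear growth, N_KM kill, saturable decay, quadratic cap
    dy[0] = k_PG * P - k_P_NKM * N_KM * P - k_p * P / (k_pd + P) - k_PL * P * P

    # IL-8: pathogen Hill source, damage^2 Hill source, first-order decay
    D2 = D * D
    dy[1] = (k_IL8_P * P / (k_IL8_Pd + P)
             + k_IL8_D * D2 / (k_IL8_Dd + D2)
             - k_IL8 * C_IL8)

    # generic proinflammatory ligand
    dy[2] = k_fMLP * P / (k_fMLPd + P) - k_fMLP_D * C_fMLP

    # CXCR-1: free fraction by conservation.  The device exchanges FREE
    # (unliganded) receptors with the trapped pool; since the free fraction
    # is the conservation remainder, both capture and release live in the
    # trapped-state equation and the surface-bound (IL-8 occupied) state
    # keeps its binding/internalization kinetics unchanged.
    free1 = 1.0 - C_R1s - C_R1i - C_R1t
    dy[3] = k_f1 * C_IL8 * free1 - (k_r1 + k_i1) * C_R1s
    dy[4] = k_i1 * C_R1s - k_i1p * C_R1i
    dy[5] = trap_on * k_ft1 * free1 - k_ft1p * C_R1t

    # CXCR-2
    free2 = 1.0 - C_R2s - C_R2i - C_R2t
    dy[6] = k_f2 * C_IL8 * free2 - (k_r2 + k_i2) * C_R2s
    dy[7] = k_i2 * C_R2s - k_i2p * C_R2i
    dy[8] = trap_on * k_ft2 * free2 - k_ft2p * C_R2t

    # fMLP-pathway exit flux from N_B (printed as first order in N_B; the
    # mass-action variant multiplies by ligand concentration)
    fmlp_flux = k_fMLP_NB * N_B
    if fmlp_mass_action > 0.5:
        fmlp_flux *= C_fMLP

    # basal neutrophils: filter-gated source, receptor-driven transitions
    source = k_NG * (1.0 + k_NB_G * F / (k_NB_Gd + F))
    dy[9] = (source - k_NK_IL8 * N_B * C_R1s - k_NM_IL8 * N_B * C_R2s
             - k_NB * N_B - fmlp_flux)

    # mobilization filter (first-order delay on pathogen)
    dy[10] = k_filter_on * P - k_filter_off * F

    # migratory neutrophils
    dy[11] = k_NM_IL8 * N_B * C_R2s - k_NM_NK_IL8 * N_M * C_R1s - k_NM * N_M

    # killer neutrophils, with elastase slaved to dN_K/dt
    dNK = k_NK_IL8 * N_B * C_R1s - k_NK_NM_IL8 * N_K * C_R2s - k_NK * N_K
    dy[12] = dNK
    dy[14] = k_NE * dNK

    # dual killer/migratory neutrophils
    dy[13] = (k_NK_NM_IL8 * N_K * C_R2s + k_NM_NK_IL8 * N_M * C_R1s
              - k_NKM * N_KM + fmlp_flux)

    # damage: production bounded by (1 - D), first-order recovery
    dy[15] = k_D_NK * N_K * (1.0 - D) - k_Drec * D

    # creatinine: constant production, damage-impaired clearance
    dy[16] = k_creat_P - k_creat * (1.0 - D) * C_creat

    return dy


def rhs_array(y: np.ndarray, t: float, theta: np.ndarray,
              trap_on: float = 0.0) -> np.ndarray:
    """Array-level entry point (used by the integrator)."""
    return _rhs(y, t, theta, trap_on)


def _check_state(state: ModelState) -> None:
    y = state.to_array()
    if np.any(y < 0):
        raise ValueError("state has negative components")


def rhs_untreated(state: ModelState, params: ModelParams) -> ModelState:
    """Derivative of the untreated model at ``state``.

    Trapped-receptor pools, if present, decay at the device release rate but
    receive no influx (the trapping term is gated off).
    """
    _check_state(state)
    params.validate()
    dy = _rhs(state.to_array(), 0.0, params.to_array(), 0.0)
    return ModelState.from_array(dy)


def rhs_treated(state: ModelState, params: ModelParams,
                trt: TreatmentSpec, t: float) -> ModelState:
    """Derivative of the treatment-extended model at time ``t``.

    Inside ``[t_on, t_off)`` free receptors are depleted into the trapped
    state at the device capture rate; outside the window only the release
    flux remains.  ``params`` must carry the device rates (see
    :func:`neusep.params.complete_params`).
    """
    _check_state(state)
    params.validate()
    trap_on = 1.0 if trt.t_on <= t < trt.t_off else 0.0
    dy = _rhs(state.to_array(), t, params.to_array(), trap_on)
    return ModelState.from_array(dy)
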