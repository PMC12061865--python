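"""Pure evaluation of the model equations.

Every function here is side-effect free and vectorized over numpy arrays:
transfer functions, regional current assembly, gating / serotonergic-current
/ serotonin derivatives, and the inflammation factors X1 (synthesis
suppression) and X2 (reuptake enhancement).  Stochastic integration lives in
:mod:`serocircuit.simulate`; these functions return deterministic drifts only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (
    InflammationCondition,
    NeuralRegionParams,
    SerotoninKineticsParams,
)

__all__ = [
    "SystemState",
    "transfer_rate",
    "inflammation_factors",
    "region_currents",
    "gating_derivatives",
    "serotonergic_current_derivative",
    "serotonin_derivative",
]

#: |d*g*(I - I_thr)| below which the transfer function switches to its
#: series expansion around the removable singularity at threshold.
_TRANSFER_SERIES_CUTOFF = 1e-6


@dataclass
class SystemState:
    """State of one region (or an array of regions/replicates) at a time point.

    ``S_E``/``S_I`` are NMDA/GABA synaptic gating fractions, ``M_5HT`` the
    dimensionless serotonergic current variable and ``conc_5HT`` the
    extracellular serotonin concentration in nM.
    """

    S_E: np.ndarray
    S_I: np.ndarray
    M_5HT: np.ndarray
    conc_5HT: np.ndarray
    time: float = 0.0

    def copy(self) -> "SystemState":
        return SystemState(self.S_E.copy(), self.S_I.copy(), self.M_5HT.copy(),
                           self.conc_5HT.copy(), self.time)


def transfer_rate(I, g, d, I_thr):
    """Population firing rate (Hz) from input current (nA).

    r = g(I - I_thr) / (1 - exp(-d g (I - I_thr))), the standard reduced
    mean-field input-output curve: soft-rectifying, strictly increasing,
    with the removable singularity at I = I_thr filled by the analytic
    limit 1/d (a short series keeps the branch strictly monotone).
    """
    I = np.asarray(I, dtype=float)
    if not (np.all(np.isfinite(I)) and np.all(np.isfinite(g))
            and np.all(np.isfinite(d)) and np.all(np.isfinite(I_thr))):
        raise ValueError("transfer_rate requires finite inputs")
    x = g * (I - I_thr)
    dx = d * x
    with np.errstate(over="ignore", invalid="ignore"):
        denom = -np.expm1(-dx)
        rate = np.where(np.abs(dx) < _TRANSFER_SERIES_CUTOFF,
                        1.0 / d + x / 2.0 + d * x * x / 12.0,
                        x / denom)
    # dx -> -inf drives x/denom to -0.0; rates are nonnegative by construction
    rate = np.abs(rate)
    return rate if rate.ndim else float(rate)


def inflammation_factors(cond: InflammationCondition,
                         kin: SerotoninKineticsParams) -> tuple[float, float]:
    """Multiplicative factors (X1, X2) on serotonin synthesis and reuptake.

    X1 = c1^m / (c1^m + theta * B * degree^m)   (synthesis, <= 1)
    X2 = 1 + c2 * theta * B * degree            (reuptake,  >= 1)

    theta is the Heaviside gate on cytokine excess: 0 for degree <= 1 (the
    control condition leaves kinetics untouched), 1 above.  The blocker
    B in (0, 1] attenuates the cytokine term; B = 1 is the untreated case.
    """
    degree, B = cond.degree, cond.B
    if degree < 0:
        raise ValueError("degree of inflammation must be >= 0")
    if B <= 0:
        raise ValueError("blocker factor B must be > 0")
    theta = 1.0 if degree > 1.0 else 0.0
    c1m = kin.c1 ** kin.m
    x1 = c1m / (c1m + theta * B * degree ** kin.m)
    x2 = 1.0 + kin.c2 * theta * B * degree
    return x1, x2


def region_currents(state: SystemState, self_params: NeuralRegionParams,
                    other_region_S_E):
    """Input currents (I_E, I_I) in nA for one region.

    I_E collects recurrent excitation, local inhibitory feedback, the
    serotonergic current (added in PFC, subtracted in SCC via the region's
    sign), the weighted external drive, and long-range NMDA input from the
    other region.  I_I omits the long-range term.
    """
    p = self_params
    sero = p.serotonergic_sign * p.R * state.M_5HT
    I_E = (p.w_plus * p.J_NMDA * state.S_E
           - p.J * state.S_I
           + p.W5HT_E * sero
           + p.W_E * p.Io
           + p.J_NMDA * p.C_in * np.asarray(other_region_S_E))
    I_I = (p.J_NMDA * state.S_E
           - state.S_I
           + p.W5HT_I * sero
           + p.W_I * p.Io)
    return I_E, I_I


def gating_derivatives(S_E, S_I, r_E, r_I, params: NeuralRegionParams):
    """Deterministic drift of the synaptic gating variables (per second).

    dS_E/dt = -S_E/tau_NMDA + (1 - S_E) * gamma * r_E
    dS_I/dt = -S_I/tau_GABA + r_I

    Noise is additive on top of these drifts and is the integrator's job.
    """
    dS_E = -np.asarray(S_E) / params.tau_NMDA + (1.0 - np.asarray(S_E)) * params.gamma * np.asarray(r_E)
    dS_I = -np.asarray(S_I) / params.tau_GABA + np.asarray(r_I)
    return dS_E, dS_I


def serotonergic_current_derivative(M, conc, kin: SerotoninKineticsParams):
    """Drift of the serotonergic current variable M (per second).

    tau_5HT dM/dt = -M + J_5HT / (1 + exp(-beta (conc + 1)))

    The sigmoid's argument carries a fixed 1 nM offset; at equilibrium
    M* lies in (0, J_5HT) and increases with serotonin concentration.
    """
    drive = kin.J_5HT / (1.0 + np.exp(-kin.beta * (np.asarray(conc) + 1.0)))
    return (-np.asarray(M) + drive) / kin.tau_5HT


def serotonin_derivative(r_E, conc, X1, X2, kin: SerotoninKineticsParams):
    """Drift of extracellular serotonin (nM/s).

    d[5HT]/dt = alpha C_BR r_E X1  -  Vmax [5HT]/(Km + [5HT]) X2

    Synthesis is linear in the excitatory population rate and suppressed by
    inflammation (X1 <= 1); reuptake saturates at Vmax and is enhanced by
    inflammation (X2 >= 1).
    """
    conc = np.asarray(conc, dtype=float)
    synthesis = kin.alpha * kin.C_BR * np.asarray(r_E) * X1
    reuptake = kin.Vmax * conc / (kin.Km + conc) * X2
    return synthesis - reuptake


def serotonin_fixed_point(r_E: float, X1: float, X2: float,
                          kin: SerotoninKineticsParams) -> float:
    """Closed-form root of the serotonin kinetics at a fixed excitatory rate.

    Setting synthesis = reuptake gives conc* = Km u / (1 - u) with
    u = alpha C_BR r_E X1 / (Vmax X2).  Requires u < 1 (synthesis below the
    saturating reuptake capacity); otherwise no finite steady state exists.
    """
    u = kin.alpha * kin.C_BR * r_E * X1 / (kin.Vmax * X2)
    if u >= 1.0:
        raise ValueError(
            f"synthesis exceeds maximal reuptake (u={u:.4f} >= 1); "
            "no finite serotonin steady state")
    return kin.Km * u / (1.0 - u)
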