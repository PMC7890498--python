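"""Three-compartment energy balance: perfusion laws, heat losses, ODE core.

The model tracks one average temperature for the tumour (T), the healthy
brain surrounding it (T_s) and the systemic blood (T_b).  Both tissues
exchange heat with blood under the Pennes assumption (venous blood leaves
at tissue temperature); conduction is neglected because perfusion dominates
heat transfer in the brain.  The blood compartment closes the balance:
it collects the tissue exchanges, the remaining whole-body metabolic heat,
and loses energy to the environment through skin convection and sweating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .parameters import InternalParameters, ParameterSet, to_internal

__all__ = [
    "ThermalState",
    "PerfusionState",
    "EquilibriumState",
    "CalibrationError",
    "TemperatureRangeError",
    "SANITY_RANGE",
    "perfusion",
    "sweat_loss",
    "skin_heat_transfer",
    "equilibrium_state",
    "ode_rhs",
]

logger = logging.getLogger(__name__)

#: Physiological sanity window [°C]; simulated temperatures leaving it
#: indicate a parameter blunder and abort the integration.
SANITY_RANGE = (20.0, 50.0)


class CalibrationError(ValueError):
    """Raised when the homeostatic calibration has no physical solution."""


class TemperatureRangeError(RuntimeError):
    """Raised when a simulated temperature leaves the sanity window."""

    def __init__(self, t: float, state: np.ndarray):
        self.t = t
        self.state = np.asarray(state, dtype=float)
        super().__init__(
            f"temperature outside {SANITY_RANGE} °C at t = {t:.1f} s: "
            f"(T, T_s, T_b) = {tuple(np.round(self.state, 3))}"
        )


@dataclass(frozen=True)
class ThermalState:
    """Compartment temperatures at one time point [°C]."""

    T: float    #: tumour
    T_s: float  #: surrounding healthy tissue
    T_b: float  #: systemic blood

    def as_array(self) -> np.ndarray:
        return np.array([self.T, self.T_s, self.T_b], dtype=float)


@dataclass(frozen=True)
class PerfusionState:
    """Tissue perfusion rates [kg s⁻¹ m⁻³]."""

    w: float    #: tumour
    w_s: float  #: surrounding healthy tissue


@dataclass(frozen=True)
class EquilibriumState:
    """Homeostatic temperatures and the calibrated skin coefficient.

    With no applied power the system settles at these values: the blood at
    T_beq, the healthy brain at T_seq, the tumour at T_eq (above T_seq for
    an impaired vasculature, since less flow removes the same metabolic
    heat).  h0 is the skin heat-transfer coefficient that makes the resting
    metabolic heat balance the loss to the environment.
    """

    T_beq: float  #: blood equilibrium temperature [°C]
    T_eq: float   #: tumour equilibrium temperature [°C]
    T_seq: float  #: healthy-brain equilibrium temperature [°C]
    h0: float     #: baseline skin heat-transfer coefficient [W m⁻² °C⁻¹]

    def as_state(self) -> ThermalState:
        return ThermalState(T=self.T_eq, T_s=self.T_seq, T_b=self.T_beq)


def equilibrium_state(params: ParameterSet) -> EquilibriumState:
    """Calibrate the no-power steady state of the model.

    In order: the blood temperature follows from the healthy-tissue balance,
    T_beq = T_seq − q_s/(w₀ c_b); the skin coefficient from the whole-body
    balance, h₀ = MET / [A (T_beq − T_E)]; and the tumour temperature from
    its own balance, T_eq = T_beq + q/(ζ w₀ c_b).
    """
    ip = to_internal(params)
    T_beq = params.T_seq - ip.q_s / ip.w0_cb
    if T_beq <= params.T_E:
        raise CalibrationError(
            f"equilibrium blood temperature {T_beq:.2f} °C does not exceed "
            f"the environment ({params.T_E} °C); h0 calibration impossible"
        )
    h0 = params.MET / (params.A * (T_beq - params.T_E))
    T_eq = T_beq + ip.q / (params.zeta * ip.w0_cb)
    return EquilibriumState(T_beq=T_beq, T_eq=T_eq, T_seq=params.T_seq, h0=h0)


def perfusion(
    T: float,
    T_s: float,
    eq: EquilibriumState,
    params: ParameterSet,
    fluct_factor: float = 1.0,
    ip: InternalParameters | None = None,
) -> PerfusionState:
    """Temperature-dependent perfusion of tumour and healthy tissue.

    Linear response around equilibrium, w = f·ζ·w₀·[1 + γ(T − T_eq)] and
    w_s = w₀·[1 + χ(T_s − T_seq)], clamped at zero (the linear law can go
    negative far below equilibrium, which is unphysical).
    """
    if ip is None:
        ip = to_internal(params)
    w = fluct_factor * params.zeta * ip.w0 * (1.0 + params.gamma * (T - eq.T_eq))
    w_s = ip.w0 * (1.0 + params.chi * (T_s - eq.T_seq))
    return PerfusionState(w=max(w, 0.0), w_s=max(w_s, 0.0))


def sweat_loss(T_b: float, eq: EquilibriumState, params: ParameterSet) -> float:
    """Evaporative heat loss [W], linear in blood warming above T_beq.

    Blood temperature acts as the surrogate for core temperature; skin
    temperature variation is neglected.  Clamped at zero below equilibrium
    (no negative sweating).
    """
    return max(params.h_e * params.A * (T_b - eq.T_beq), 0.0)


def skin_heat_transfer(
    T_b: float, eq: EquilibriumState, params: ParameterSet
) -> float:
    """Skin convection coefficient h [W m⁻² °C⁻¹] at blood temperature T_b.

    Quadratic enhancement h = h₀[1 + κΔT_b − νΔT_b²] mimicking the diversion
    of blood flow to the skin as the core warms.  The fit loses validity
    beyond its positive root (ΔT_b ≈ 2.3 °C with default κ, ν); the value
    is then clamped at zero with a logged warning.
    """
    d = T_b - eq.T_beq
    h = eq.h0 * (1.0 + params.kappa * d - params.nu * d * d)
    if h < 0.0:
        logger.warning(
            "skin heat-transfer quadratic negative at T_b - T_beq = %.3f °C; "
            "clamping to 0 (outside fit validity)", d,
        )
        return 0.0
    return h


def ode_rhs(
    t: float,
    state: np.ndarray,
    params: ParameterSet,
    eq: EquilibriumState,
    power: Callable[[float], tuple[float, float]],
    fluct: Callable[[float], float] | None = None,
    ip: InternalParameters | None = None,
) -> np.ndarray:
    """Time derivatives of (T, T_s, T_b) [°C s⁻¹].

    ``power(t)`` returns the instantaneous device power densities
    (P, P_s) [W kg⁻¹]; ``fluct(t)`` the multiplicative tumour blood-flow
    factor (``None`` means 1, the deterministic backbone).  Pass a
    precomputed ``ip`` in hot loops to avoid re-deriving internal units.
    """
    if ip is None:
        ip = to_internal(params)
    T, T_s, T_b = float(state[0]), float(state[1]), float(state[2])
    lo, hi = SANITY_RANGE
    if not (lo <= T <= hi and lo <= T_s <= hi and lo <= T_b <= hi):
        raise TemperatureRangeError(t, np.asarray(state))

    factor = 1.0 if fluct is None else float(fluct(t))
    perf = perfusion(T, T_s, eq, params, factor, ip=ip)
    P_t, Ps_t = power(t)
    p = P_t * params.rho
    p_s = Ps_t * params.rho_s

    w_cb = perf.w * ip.c_b_mass
    ws_cb = perf.w_s * ip.c_b_mass

    dT = (w_cb * (T_b - T) + ip.q + p) / ip.rc
    dT_s = (ws_cb * (T_b - T_s) + ip.q_s + p_s) / ip.rc_s

    h = skin_heat_transfer(T_b, eq, params)
    Q_e = sweat_loss(T_b, eq, params)
    dT_b = (
        params.V * w_cb * (T - T_b)
        + params.V_s * ws_cb * (T_s - T_b)
        + params.MET
        - ip.q * params.V
        - ip.q_s * params.V_s
        - h * params.A * (T_b - params.T_E)
        - Q_e
    ) / ip.blood_heat_mass
    return np.array([dT, dT_s, dT_b])
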