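"""Local relative-error sensitivity of the model temperatures.

For each parameter p the relative percentage error of an output temperature
T under a relative input uncertainty r is

    δT = (1/T) · (∂T/∂p) · r·|p| · 100  [%],

with the partial derivative estimated by an adaptive central finite
difference.  The skin coefficient h₀ is a derived quantity and is
re-calibrated after every perturbation, so each δ reflects the full chain
through the homeostatic calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bioheat import equilibrium_state
from .parameters import ParameterSet
from .scenarios import CANONICAL_SCHEDULE, PowerSchedule, run_treatment

__all__ = ["SensitivityReport", "sensitivity_analysis", "DEFAULT_PARAMETERS"]

#: Parameters scanned by default: every physical constant of the model
#: (the vascular pair ζ, γ is usually scanned over its whole range instead,
#: but is accepted here too).
DEFAULT_PARAMETERS = (
    "rho", "rho_s", "c", "c_s", "c_b", "c_T", "m_T", "A", "V", "V_s",
    "MET", "Q", "Q_s", "P", "P_s", "h_e", "kappa", "nu", "T_seq", "T_E",
    "w0_clinical", "chi",
)


@dataclass(frozen=True)
class SensitivityReport:
    """Per-parameter (δT, δT_b, δT_s) triples and the output definition."""

    table: pd.DataFrame
    r: float
    output: str
    eval_time_s: float | None

    def to_text(self) -> str:
        return self.table.to_string(
            float_format=lambda v: f"{v: .3e}", index=False
        )


def _plateau_output(
    params: ParameterSet, schedule: PowerSchedule, t_eval: float
) -> np.ndarray:
    """(T, T_b, T_s) on the heated plateau at ``t_eval`` s, fluctuations off.

    The schedule's plateau powers are slaved to the parameter set so that
    perturbations of P and P_s propagate into the run.
    """
    import dataclasses

    schedule = dataclasses.replace(schedule, P=params.P, P_s=params.P_s)
    res = run_treatment(
        params, schedule, fluctuations_on=False, horizon=t_eval
    )
    return np.array([res.T[-1], res.T_b[-1], res.T_s[-1]])


def _equilibrium_output(params: ParameterSet) -> np.ndarray:
    """(T_eq, T_beq, T_seq): the closed-form homeostatic temperatures."""
    eq = equilibrium_state(params)
    return np.array([eq.T_eq, eq.T_beq, eq.T_seq])


def sensitivity_analysis(
    params: ParameterSet | None = None,
    r: float = 0.10,
    output: str = "plateau",
    parameter_list: tuple[str, ...] = DEFAULT_PARAMETERS,
    schedule: PowerSchedule = CANONICAL_SCHEDULE,
    eval_time_min: float = 55.0,
    fd_rtol: float = 0.01,
    max_halvings: int = 6,
) -> SensitivityReport:
    """Relative-error sensitivities of the three output temperatures.

    Parameters
    ----------
    r
        Common relative input uncertainty (default 10%).
    output
        ``"plateau"`` — temperatures at ``eval_time_min`` of the canonical
        heated schedule (fluctuations off); ``"equilibrium"`` — the
        closed-form homeostatic temperatures.
    fd_rtol, max_halvings
        The central-difference step starts at r·|p| and is halved until two
        successive derivative estimates agree within ``fd_rtol`` relative
        (or the halving budget is exhausted); non-finite estimates are
        flagged as NaN rather than raised.
    """
    if params is None:
        params = ParameterSet()
    if r <= 0:
        raise ValueError("relative perturbation r must be positive")
    t_eval = eval_time_min * 60.0
    if output == "plateau":
        def f(p: ParameterSet) -> np.ndarray:
            return _plateau_output(p, schedule, t_eval)
        output_desc = (
            f"heated plateau at t = {eval_time_min:g} min, "
            f"P = {schedule.P:g} W kg^-1, fluctuations off"
        )
        eval_time: float | None = t_eval
    elif output == "equilibrium":
        f = _equilibrium_output
        output_desc = "homeostatic equilibrium (no applied power)"
        eval_time = None
    else:
        raise ValueError(f"unknown output spec {output!r}")

    base = f(params)
    rows = []
    for name in parameter_list:
        value = getattr(params, name)
        if value == 0.0:
            # r·|p| vanishes: the stated uncertainty is zero, hence δ = 0.
            rows.append({"parameter": name, "dT_pct": 0.0,
                         "dTb_pct": 0.0, "dTs_pct": 0.0})
            continue
        step = r * abs(value)
        deriv = None
        for _ in range(max_halvings + 1):
            try:
                hi = f(params.replace(**{name: value + step}))
                lo = f(params.replace(**{name: value - step}))
            except Exception:
                hi = lo = None
            est = (hi - lo) / (2 * step) if hi is not None else None
            if est is not None and deriv is not None and np.all(np.isfinite(est)):
                denom = np.maximum(np.abs(est), 1e-300)
                if np.all(np.abs(est - deriv) <= fd_rtol * denom):
                    deriv = est
                    break
            deriv = est if est is not None else deriv
            step /= 2.0
        if deriv is None or not np.all(np.isfinite(deriv)):
            rows.append({"parameter": name, "dT_pct": np.nan,
                         "dTb_pct": np.nan, "dTs_pct": np.nan})
            continue
        delta = deriv / base * r * abs(value) * 100.0
        rows.append({"parameter": name, "dT_pct": float(delta[0]),
                     "dTb_pct": float(delta[1]), "dTs_pct": float(delta[2])})
    return SensitivityReport(
        table=pd.DataFrame(rows), r=r, output=output_desc,
        eval_time_s=eval_time,
    )
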