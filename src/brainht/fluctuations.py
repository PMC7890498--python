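"""Stochastic multiplicative forcing of the tumour blood flow.

Tumour microvasculature does not deliver a steady flow: the model applies a
multiplicative factor to the tumour perfusion consisting of a harmonic
component with a 30 min period plus zero-centred uniform random jumps
refreshed every 90 s and linearly interpolated in between.  Both amplitudes
grow as the impairment parameter ζ decreases, reflecting the noisier supply
of more disrupted vasculatures.  Healthy-tissue perfusion is not forced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FluctuationTrace",
    "generate_fluctuation_trace",
    "evaluate_fluctuation",
    "default_random_amplitude",
]

DEFAULT_REFRESH_S = 90.0
DEFAULT_PERIOD_S = 1800.0


def default_random_amplitude(zeta: float) -> float:
    """Amplitude of the uniform random component as a function of ζ.

    Decreasing in ζ: an intact vasculature (ζ = 1) keeps a small residual
    jitter of 0.03 while a heavily impaired one (ζ → 0) fluctuates by up to
    ±0.15 of its baseline flow.
    """
    return 0.03 + 0.12 * (1.0 - min(zeta, 1.0))


@dataclass(frozen=True)
class FluctuationTrace:
    """Piecewise-linear stochastic blood-flow factor.

    ``knot_times`` are equally spaced by the refresh interval and cover the
    whole requested horizon; ``knot_values`` are the uniform draws of the
    random component at the knots.  Evaluation adds the harmonic term
    ``harmonic_amp * sin(2π t / period + phase)`` on top of the linear
    interpolation of the knots, around a mean factor of 1.
    """

    knot_times: np.ndarray = field(repr=False)
    knot_values: np.ndarray = field(repr=False)
    harmonic_amp: float
    random_amp: float
    period: float
    phase: float
    zeta: float
    seed: int | None

    @property
    def duration(self) -> float:
        return float(self.knot_times[-1])

    def __call__(self, t: float | np.ndarray) -> float | np.ndarray:
        return evaluate_fluctuation(self, t)


def generate_fluctuation_trace(
    duration: float,
    zeta: float,
    seed: int | None = None,
    *,
    random_amp: float | None = None,
    harmonic_amp: float | None = None,
    refresh: float = DEFAULT_REFRESH_S,
    period: float = DEFAULT_PERIOD_S,
    phase: float = 0.0,
) -> FluctuationTrace:
    """Draw a reproducible fluctuation trace covering ``[0, duration]``.

    One independent uniform draw on [−a_r, +a_r] is consumed per knot, in
    time order, from ``numpy.random.default_rng(seed)``; the seed therefore
    fully determines the trace.  ``random_amp``/``harmonic_amp`` override
    the ζ-dependent defaults (harmonic defaults to half the random
    amplitude).
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if refresh <= 0:
        raise ValueError(f"refresh interval must be positive, got {refresh}")
    a_r = default_random_amplitude(zeta) if random_amp is None else random_amp
    a_h = a_r / 2.0 if harmonic_amp is None else harmonic_amp
    if a_r + a_h >= 1.0:
        raise ValueError("combined fluctuation amplitude must stay below 1")

    n_knots = int(np.ceil(duration / refresh)) + 1
    knot_times = np.arange(n_knots) * refresh
    rng = np.random.default_rng(seed)
    knot_values = rng.uniform(-a_r, a_r, size=n_knots)
    return FluctuationTrace(
        knot_times=knot_times,
        knot_values=knot_values,
        harmonic_amp=a_h,
        random_amp=a_r,
        period=period,
        phase=phase,
        zeta=zeta,
        seed=seed,
    )


def evaluate_fluctuation(
    trace: FluctuationTrace, t: float | np.ndarray
) -> float | np.ndarray:
    """Evaluate the multiplicative factor at time(s) ``t`` [s].

    Exact piecewise-linear interpolation of the random knots plus the
    harmonic term.  Raises for times outside the trace coverage.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > trace.duration):
        raise ValueError(
            f"time outside trace coverage [0, {trace.duration:g}] s"
        )
    random_part = np.interp(t_arr, trace.knot_times, trace.knot_values)
    harmonic = trace.harmonic_amp * np.sin(
        2.0 * np.pi * t_arr / trace.period + trace.phase
    )
    out = 1.0 + harmonic + random_part
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out
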