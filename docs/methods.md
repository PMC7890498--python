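# Methods

## Model

`brainht` simulates regional hyperthermia of a brain tumour with a lumped
three-compartment energy balance. Each compartment carries one average
temperature: the tumour `T`, the surrounding healthy brain `T_s`, and the
systemic blood `T_b` (all °C). Tissues exchange heat with blood under the
Pennes assumption — venous blood leaves at the local tissue temperature, so
the net exchange is `w·c_b·(T_b − T)` per unit tissue volume, with `w` the
perfusion (kg s⁻¹ m⁻³) and `c_b` the blood heat capacity. Conduction between
compartments and directly to the environment is neglected: in the brain,
perfusion dominates heat transfer and conduction matters only within a few
millimetres of a boundary. The governing system is

    ρc   dT/dt   = w  c_b (T_b − T)   + q   + p(t)
    ρ_sc_s dT_s/dt = w_s c_b (T_b − T_s) + q_s + p_s(t)
    (m_T − ρV − ρ_sV_s) c_T dT_b/dt =
          V w c_b (T − T_b) + V_s w_s c_b (T_s − T_b)
        + MET − qV − q_sV_s − h(T_b) A (T_b − T_E) − Q_e(T_b)

where `q, q_s` are metabolic heat densities, `p(t), p_s(t)` the applied
power densities, and the blood compartment closes the whole-body balance:
it collects the tissue exchanges and the remaining resting metabolic heat
`MET`, and loses energy through skin convection (`h·A·(T_b − T_E)`) and
sweating (`Q_e = h_e·A·(T_b − T_beq)`, clamped at zero below equilibrium).
The convection coefficient itself responds to core warming,
`h = h₀[1 + κΔT_b − νΔT_b²]` with `ΔT_b = T_b − T_beq`; the quadratic is
clamped at zero beyond its positive root (≈ 2.3 °C with the default κ, ν),
which no nominal scenario approaches (blood warms < 0.1 °C at 40 W kg⁻¹).

Perfusion responds linearly to local temperature:

    w   = f(t) · ζ · w₀ · [1 + γ (T − T_eq)]
    w_s =          w₀ · [1 + χ (T_s − T_seq)]

`ζ` is the tumour flow-impairment factor (ratio of tumour to healthy
baseline perfusion), `γ ≤ χ` its blunted thermal response, and `f(t)` a
stochastic factor (below) applied to tumour flow only. Both laws are
clamped at zero; the linear form can go negative only far outside the
simulated regime.

## Units

Parameters are stored as clinically reported (perfusion in ml min⁻¹ per
100 ml of tissue, powers in W kg⁻¹, capacities in MJ °C⁻¹ m⁻³) and converted
once into a single SI volumetric convention (`parameters.to_internal`):
`w₀ [kg s⁻¹ m⁻³] = w₀_clinical/6000 × ρ_blood`, `q = Q·ρ`, `c_b_mass =
c_b_vol/ρ_blood`. A blood density of 1050 kg m⁻³ (equal to tissue) is used
for these conversions; since the heat-exchange coefficient `w·c_b` is what
enters the equations, the two conventions give identical products and the
density choice cancels to first order (the local sensitivity of the output
temperatures to density is < 10⁻²%/%).

## Equilibrium and calibration

With no applied power the system has a closed-form steady state, computed
in order: `T_beq = T_seq − q_s/(w₀c_b)` (healthy-tissue balance inverted
around the known brain temperature of 36.9 °C), `h₀ = MET/[A(T_beq − T_E)]`
(skin coefficient calibrated so the resting metabolic heat exactly balances
the environmental loss), and `T_eq = T_beq + q/(ζw₀c_b)`. With defaults the
brain runs 0.369 °C above the incoming blood and `h₀ ≈ 3.06 W m⁻² °C⁻¹`.
Every simulation starts from this fixed point, and `h₀` is re-derived
whenever parameters change (including inside the sensitivity analysis),
since it is a calibrated rather than a measured quantity.

## Blood-flow fluctuations

Tumour perfusion is multiplied by
`f(t) = 1 + a_h sin(2πt/1800 s) + r(t)`, where `r(t)` linearly interpolates
independent uniform draws on `[−a_r, a_r]` refreshed every 90 s. The
amplitudes grow with impairment: `a_r(ζ) = 0.03 + 0.12·(1 − min(ζ, 1))` and
`a_h = a_r/2` by default, both overridable. These amplitudes are a
calibration choice of this package (modest ripples for a functional
vasculature, visibly larger ones at ζ ≈ 0.4); one uniform draw is consumed
per knot in time order, so a seed fully determines a trace. Healthy-tissue
perfusion carries no fluctuation factor.

## Vascular-network reading of ζ

`vasculature` builds tree-like networks with N arterial levels (2^k vessels
at level k) bifurcating down to capillaries of radius 5 μm and length
75 μm, mirrored by N merging venous levels. Backbone geometry follows
Murray-type cube-root branching (`r_k = 2^{1/3} r_{k+1}`, same for lengths;
the exponent is configurable). Each vessel's radius and length receive
independent mean-one log-normal perturbations. Under laminar flow each
vessel has Hagen–Poiseuille resistance `Z = 8μl/(πr⁴)`; with equal flow
splitting at every junction the network's total resistance collapses to a
per-level weighted sum, and an explicit path-enumeration oracle (flows
propagated by conservation, pressure drops accumulated per root-to-root
path) verifies that formula to 10⁻¹⁰ on small networks.

ζ is estimated as the ratio `Z_tot(normal)/Z_tot(tumour)` of paired draws
from the two populations at equal driving pressure (viscosity cancels when
equal across populations; default μ = 3×10⁻³ Pa s). Default coefficients of
variation are 0.05 (normal) and 0.25 (tumour), chosen so the relative
spread of total resistance lands at ≈ 3.5% and ≈ 21% for N = 6 — the
regimes the model is meant to contrast; because resistance is convex in the
radius, the wider tumour dispersion also *raises* its mean resistance
(Jensen), so the ζ distribution centres near 0.55 with essentially all mass
below 1. The underlying perturbation distributions are not identifiable
from summary histograms, so these defaults are a soft calibration, not a
reproduction of any specific dataset.

## Numerics

The system is mildly stiff: tissue time constants `ρc/(wc_b)` are ~2 min
while the blood compartment relaxes over ~20 min. `run_treatment`
integrates with SciPy's BDF method (rtol 10⁻⁶, atol 10⁻⁸ °C), splitting the
time span at the power-schedule breakpoints so the solver never steps
across a kink in the forcing; with fluctuations on, the maximum step is
capped at 45 s (half the knot spacing) to resolve the piecewise-linear
factor. Output is sampled every 10 s. Halving the tolerances changes the
maximum tumour temperature by < 10⁻³ °C. Temperatures outside 20–50 °C
abort the run: that window catches parameter blunders, not a physical
limit.

The return time after power-off is the elapsed time until the tumour
temperature first enters *and remains* within a threshold (default 0.1 °C)
of its pre-treatment equilibrium through the end of the horizon (default
120 min: 60 min treatment + 60 min observation). In the stochastic
perfusion sweep the threshold is widened per cell to the baseline
fluctuation band `(T_eq − T_beq)(a_r + a_h)` when that exceeds 0.1 °C,
because a poorly perfused tumour wobbles by more than 0.1 °C around its
equilibrium even untreated; nominal scenarios are unaffected by this rule.

## Sensitivity analysis

`sensitivity_analysis` computes `δT = (1/T)(∂T/∂p) r|p| × 100` per
parameter with a common relative uncertainty r = 10%, using central finite
differences with an adaptive step (start `r|p|`, halve until two successive
estimates agree within 1%). The default output is the heated plateau at
t = 55 min of the canonical 40 W kg⁻¹ schedule with fluctuations off — the
quasi-steady state the treatment actually probes; an equilibrium output is
also available and admits closed-form checks (e.g. ∂T_beq/∂T_seq = 1).
The qualitative structure is robust to the output definition (signs of the
power, flow, metabolic and reference-temperature entries; dominance of
T_seq at ≈ 10%), but digit-level values are not, so only structure is
asserted in the tests.

## Problem sizes and defaults

Canonical schedule: power starts at 5 min, ramps linearly to the plateau at
15 min, off at 60 min; plateau 40 W kg⁻¹ applied equally to tumour and
brain (no focusing), with 25 and 50 W kg⁻¹ as standard alternatives.
Ensembles default to 20 runs over stated (ζ, γ) ranges; the perfusion sweep
to w₀ ∈ {10 … 49.2} ml min⁻¹/100 ml × ζ ∈ {0.3, 0.5, 0.85, 1.2} with 14
trials per cell; the network Monte Carlo to 500 paired draws at N = 6.
Tests use reduced grids and sample counts of the same constructions.

## Limitations

No spatial resolution (hot-spots from locally collapsed microvasculature
are averaged away); no vessel damage or vasoconstriction at high thermal
dose, and no delayed (inertial) blood-flow response after heating — the
perfusion–temperature coupling is instantaneous and linear; blood
temperature stands in for core temperature in both heat-loss laws; the
fluctuation model is phenomenological, not a vasomotion model. The
synthetic vascular trees assume symmetric bifurcation with equal flow
splitting and Newtonian blood; they ground ζ's order of magnitude, not any
patient's vasculature.
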