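"""Model constants, unit conversions and parameter validation.

The model works with two unit conventions at once: clinical parameters are
kept exactly as they are usually reported (perfusion in ml min⁻¹ per 100 ml
of tissue, metabolic heat in W kg⁻¹, heat capacities in MJ °C⁻¹ m⁻³), while
all energy-balance arithmetic is done in a single SI volumetric convention
(W m⁻³, J °C⁻¹ m⁻³, kg s⁻¹ m⁻³, seconds, °C).  :class:`ParameterSet` holds
the clinical form; :func:`to_internal` produces the SI form used by the ODE
right-hand side.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "ParameterSet",
    "InternalParameters",
    "ConfigurationError",
    "ValidationError",
    "load_parameters",
    "to_internal",
    "validate_parameters",
    "BLOOD_DENSITY",
]

#: Mass density used to convert clinical (volume-fraction) perfusion and
#: per-mass heat capacities into the SI volumetric convention [kg m⁻³].
#: Taken equal to the tissue density; the model outputs are insensitive to
#: this choice (see docs/methods.md).
BLOOD_DENSITY = 1050.0


class ConfigurationError(ValueError):
    """Raised for unknown or unparseable configuration entries."""


class ValidationError(ValueError):
    """Raised when a parameter set violates a physical invariant."""


@dataclass(frozen=True)
class ParameterSet:
    """Physical and physiological constants of the three-compartment model.

    Defaults describe a 80 cm³ glioma in a 1.28 l brain of a resting 70 kg
    adult in a 22 °C room, heated by a non-focused capacitive device.
    Units are the clinical ones in which these quantities are reported.
    """

    rho: float = 1050.0      #: tumour tissue density [kg m⁻³]
    rho_s: float = 1050.0    #: surrounding (brain) tissue density [kg m⁻³]
    c: float = 3.86          #: tumour heat capacity [MJ °C⁻¹ m⁻³]
    c_s: float = 3.86        #: surrounding-tissue heat capacity [MJ °C⁻¹ m⁻³]
    c_b: float = 3.82        #: blood heat capacity [MJ °C⁻¹ m⁻³]
    c_T: float = 4.12        #: whole-body average heat capacity [MJ °C⁻¹ m⁻³]
    m_T: float = 70.0        #: total body mass [kg]
    A: float = 1.91          #: body surface area [m²]
    V: float = 80e-6         #: tumour volume [m³]
    V_s: float = 1200e-6     #: surrounding-tissue (brain) volume [m³]
    MET: float = 85.0        #: whole-body resting metabolic heat [W]
    Q: float = 11.0          #: tumour metabolic heat production [W kg⁻¹]
    Q_s: float = 11.0        #: surrounding-tissue metabolic heat [W kg⁻¹]
    P: float = 40.0          #: effective device power density, tumour [W kg⁻¹]
    P_s: float = 40.0        #: effective device power density, brain [W kg⁻¹]
    h_e: float = 80.25       #: sweat-rate escalation parameter [W m⁻² °C⁻¹]
    kappa: float = 8.25      #: skin-convection linear adjustment [°C⁻¹]
    nu: float = 3.8          #: skin-convection quadratic adjustment [°C⁻²]
    T_seq: float = 36.9      #: healthy-brain homeostatic temperature [°C]
    T_E: float = 22.0        #: environment temperature [°C]
    w0_clinical: float = 49.2  #: baseline perfusion [ml min⁻¹ per 100 ml]
    chi: float = 0.1         #: healthy perfusion-temperature slope [°C⁻¹]
    gamma: float = 0.08      #: tumour perfusion-temperature slope [°C⁻¹]
    zeta: float = 0.85       #: tumour flow-impairment factor [-]

    def replace(self, **changes: float) -> "ParameterSet":
        """Return a copy with the given fields overridden."""
        return dataclasses.replace(self, **changes)

    def asdict(self) -> dict:
        return dataclasses.asdict(self)


_FIELD_NAMES = {f.name for f in dataclasses.fields(ParameterSet)}


@dataclass(frozen=True)
class InternalParameters:
    """SI volumetric form of :class:`ParameterSet` used by the ODE core.

    Every heat-exchange product here is in W m⁻³ °C⁻¹ so the per-mass and
    volumetric conventions of the published constants coincide exactly.
    """

    rc: float        #: tumour volumetric heat capacity ρc [J °C⁻¹ m⁻³]
    rc_s: float      #: surrounding volumetric heat capacity [J °C⁻¹ m⁻³]
    c_b_mass: float  #: blood heat capacity per mass [J kg⁻¹ °C⁻¹]
    c_T_mass: float  #: body-average heat capacity per mass [J kg⁻¹ °C⁻¹]
    w0: float        #: baseline perfusion [kg s⁻¹ m⁻³]
    q: float         #: tumour metabolic heat [W m⁻³]
    q_s: float       #: surrounding metabolic heat [W m⁻³]
    p: float         #: tumour plateau device power [W m⁻³]
    p_s: float       #: surrounding plateau device power [W m⁻³]
    blood_heat_mass: float  #: (m_T − ρV − ρ_sV_s)·c_T [J °C⁻¹]

    @property
    def w0_cb(self) -> float:
        """Baseline perfusion heat-exchange coefficient [W m⁻³ °C⁻¹]."""
        return self.w0 * self.c_b_mass


def to_internal(params: ParameterSet) -> InternalParameters:
    """Convert a clinical parameter set into the SI volumetric convention.

    Clinical perfusion w₀ [ml min⁻¹ per 100 ml] is a volume-fraction rate;
    dividing by 6000 gives s⁻¹ and multiplying by the blood density gives
    kg s⁻¹ m⁻³.  Per-mass metabolic and device powers [W kg⁻¹] become
    volumetric by multiplying with the tissue density.
    """
    rc = params.c * 1e6
    rc_s = params.c_s * 1e6
    c_b_mass = params.c_b * 1e6 / BLOOD_DENSITY
    c_T_mass = params.c_T * 1e6 / BLOOD_DENSITY
    w0 = params.w0_clinical / 6000.0 * BLOOD_DENSITY
    blood_mass = params.m_T - params.rho * params.V - params.rho_s * params.V_s
    return InternalParameters(
        rc=rc,
        rc_s=rc_s,
        c_b_mass=c_b_mass,
        c_T_mass=c_T_mass,
        w0=w0,
        q=params.Q * params.rho,
        q_s=params.Q_s * params.rho_s,
        p=params.P * params.rho,
        p_s=params.P_s * params.rho_s,
        blood_heat_mass=blood_mass * c_T_mass,
    )


def validate_parameters(params: ParameterSet) -> list[str]:
    """Check physical invariants; return a list of violation messages.

    An empty list means the parameter set is usable.  This never raises:
    callers that want an exception use :func:`load_parameters` or check the
    returned report themselves.
    """
    violations: list[str] = []
    positive = [
        "rho", "rho_s", "c", "c_s", "c_b", "c_T", "m_T", "A", "V", "V_s",
        "MET", "h_e", "w0_clinical",
    ]
    for name in positive:
        if getattr(params, name) <= 0:
            violations.append(f"{name} must be strictly positive")
    for name in ("Q", "Q_s", "P", "P_s", "gamma", "chi", "kappa", "nu"):
        if getattr(params, name) < 0:
            violations.append(f"{name} must be non-negative")
    if params.zeta <= 0:
        violations.append("zeta must be strictly positive")
    tissue_mass = params.rho * params.V + params.rho_s * params.V_s
    if params.m_T <= tissue_mass:
        violations.append(
            "blood thermal mass non-positive "
            f"(m_T = {params.m_T} kg <= rho*V + rho_s*V_s = {tissue_mass:.4g} kg)"
        )
    if params.T_E >= params.T_seq:
        violations.append(
            "environment hotter than brain equilibrium "
            f"(T_E = {params.T_E} >= T_seq = {params.T_seq})"
        )
    return violations


def load_parameters(
    config: Mapping[str, float] | str | Path | None = None,
) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from an optional config.

    Parameters
    ----------
    config
        Either a mapping of field names to numbers, a path to a flat YAML
        file with such a mapping, or ``None`` for the defaults.  Keys must
        be :class:`ParameterSet` field names; values must be numeric and in
        the clinical units documented on the fields.

    Raises
    ------
    ConfigurationError
        For unknown keys or non-numeric values.
    ValidationError
        If the resulting set violates a physical invariant.
    """
    if config is None:
        overrides: dict[str, float] = {}
    elif isinstance(config, (str, Path)):
        with open(config) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, Mapping):
            raise ConfigurationError(
                f"configuration file {config} must contain a flat mapping"
            )
        overrides = dict(loaded)
    else:
        overrides = dict(config)

    for key, value in overrides.items():
        if key not in _FIELD_NAMES:
            raise ConfigurationError(f"unknown parameter {key!r}")
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigurationError(
                f"parameter {key!r} must be numeric, got {value!r}"
            )

    params = ParameterSet(**{k: float(v) for k, v in overrides.items()})
    violations = validate_parameters(params)
    if violations:
        raise ValidationError("; ".join(violations))
    return params
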