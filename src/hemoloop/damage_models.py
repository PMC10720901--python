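"""Power-law blood-damage models and the energy-dissipation effective stress.

Blood damage (hemolysis, platelet activation) accumulated under mechanical
stress is modelled with the classical power law

    D = C * tau**alpha * t**beta

where ``tau`` is a scalar effective stress in Pa, ``t`` the exposure time in
seconds, and (C, alpha, beta) empirically fitted constants.  ``D`` is the
hemolysis index in percent (HI %) for the hemolysis constant sets and a
dimensionless platelet activation index (PAI) for the platelet set.

The effective stress used throughout this package is the energy-dissipation
stress

    tau = sqrt(eps * mu * rho)

built from the total specific dissipation rate ``eps`` (W/kg), the dynamic
viscosity ``mu`` (Pa*s) and the density ``rho`` (kg/m^3).  ``eps`` is the
caller-supplied sum of resolved (viscous) and modelled (turbulent)
dissipation; splitting the two is the flow-field layer's job.

For Eulerian transport the power law is linearised: DI = D**(1/beta) grows at
the constant rate

    sigma = C**(1/beta) * tau**(alpha/beta)

per second, the "source term".  ``(sigma * t)**beta`` recovers ``D`` exactly
for constant stress.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "PowerLawConstants",
    "FluidProperties",
    "BLOOD",
    "HO",
    "TZ",
    "DING",
    "CONSTANTS_REGISTRY",
    "get_constants",
    "is_registry_set",
    "constants_to_dict",
    "constants_from_dict",
    "effective_stress",
    "damage_index",
    "source_term",
]

_DAMAGE_KINDS = ("HI", "PAI")


@dataclass(frozen=True)
class PowerLawConstants:
    """One (C, alpha, beta) power-law constant set.

    Parameters
    ----------
    name:
        Label of the set (e.g. ``"HO"``).
    C:
        Model coefficient, dimensioned so that with stress in Pa and time in
        seconds the damage comes out in percent (HI) or as a dimensionless
        index (PAI).
    alpha:
        Stress exponent (> 0).
    beta:
        Time exponent (0 < beta <= 1).
    damage_kind:
        ``"HI"`` or ``"PAI"``.
    """

    name: str
    C: float
    alpha: float
    beta: float
    damage_kind: str

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not 0 < self.beta <= 1:
            raise ValueError(f"beta must lie in (0, 1], got {self.beta}")
        if self.damage_kind not in _DAMAGE_KINDS:
            raise ValueError(
                f"damage_kind must be one of {_DAMAGE_KINDS}, got {self.damage_kind!r}"
            )


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid properties; defaults are whole blood."""

    rho: float = 1055.0  # kg/m^3
    mu: float = 0.0035  # Pa*s

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise ValueError(f"rho must be positive, got {self.rho}")
        if not self.mu > 0:
            raise ValueError(f"mu must be positive, got {self.mu}")


BLOOD = FluidProperties()

# Published constant sets.  HO and TZ predict hemolysis (HI %); Ding predicts
# the platelet activation index.
HO = PowerLawConstants("HO", 1.800e-4, 1.9910, 0.7650, "HI")
TZ = PowerLawConstants("TZ", 1.228e-5, 1.9918, 0.6606, "HI")
DING = PowerLawConstants("Ding-PAI", 4.08e-5, 1.56, 0.8, "PAI")

#: Closed registry of the shipped constant sets, keyed by name.
CONSTANTS_REGISTRY: Mapping[str, PowerLawConstants] = {
    c.name: c for c in (HO, TZ, DING)
}


def get_constants(name: str) -> PowerLawConstants:
    """Look up a shipped constant set by name (case-sensitive)."""
    try:
        return CONSTANTS_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown constant set {name!r}; shipped sets: "
            f"{sorted(CONSTANTS_REGISTRY)}"
        ) from None


def is_registry_set(constants: PowerLawConstants) -> bool:
    """True if *constants* is one of the shipped sets (value-wise equality).

    User-defined sets are accepted everywhere but flagged as non-standard in
    reports.
    """
    return CONSTANTS_REGISTRY.get(constants.name) == constants


def constants_to_dict(constants: PowerLawConstants) -> dict:
    """Serialize a constant set to a plain key-value block."""
    return {
        "name": constants.name,
        "C": constants.C,
        "alpha": constants.alpha,
        "beta": constants.beta,
        "damage_kind": constants.damage_kind,
    }


def constants_from_dict(block: Mapping) -> PowerLawConstants:
    """Rebuild a constant set from :func:`constants_to_dict` output."""
    return PowerLawConstants(
        name=str(block["name"]),
        C=float(block["C"]),
        alpha=float(block["alpha"]),
        beta=float(block["beta"]),
        damage_kind=str(block["damage_kind"]),
    )


def effective_stress(eps_total, fluid: FluidProperties = BLOOD):
    """Energy-dissipation effective stress tau = sqrt(eps * mu * rho) in Pa.

    ``eps_total`` is the total specific dissipation rate in W/kg (viscous plus
    turbulence-model contributions, already summed by the caller).  Accepts a
    scalar or array; negative values are rejected.
    """
    eps = np.asarray(eps_total, dtype=float)
    if np.any(eps < 0):
        bad = np.min(eps)
        raise ValueError(f"dissipation rate must be non-negative, got {bad}")
    tau = np.sqrt(eps * fluid.mu * fluid.rho)
    return float(tau) if np.isscalar(eps_total) else tau


def damage_index(tau, t, constants: PowerLawConstants):
    """Power-law damage D = C * tau**alpha * t**beta.

    Returns HI in percent for HI-kind constants, a dimensionless index for
    PAI.  Monotone non-decreasing in both arguments.
    """
    tau_a = np.asarray(tau, dtype=float)
    t_a = np.asarray(t, dtype=float)
    if np.any(tau_a < 0):
        raise ValueError(f"stress must be non-negative, got {np.min(tau_a)}")
    if np.any(t_a < 0):
        raise ValueError(f"exposure time must be non-negative, got {np.min(t_a)}")
    d = constants.C * tau_a**constants.alpha * t_a**constants.beta
    return float(d) if (np.isscalar(tau) and np.isscalar(t)) else d


def source_term(tau_eff, constants: PowerLawConstants):
    """Linearised damage production rate sigma = C**(1/beta) * tau**(alpha/beta).

    Consistent with :func:`damage_index`: for constant stress,
    ``(source_term(tau) * t)**beta == damage_index(tau, t)``.
    """
    tau_a = np.asarray(tau_eff, dtype=float)
    if np.any(tau_a < 0):
        raise ValueError(f"stress must be non-negative, got {np.min(tau_a)}")
    sigma = constants.C ** (1.0 / constants.beta) * tau_a ** (
        constants.alpha / constants.beta
    )
    return float(sigma) if np.isscalar(tau_eff) else sigma
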