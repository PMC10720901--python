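"""Stress-history composition of pump and valve damage, and comparison stats.

In a closed test loop the blood passes the pump and the resistance valve in
series, so the linearised damage indices add: the single-pass stress integral
of the pair is S_p + S_v and the joint damage is

    D_{p+v} = ((S_p + S_v) / Q)**beta.

The valve's marginal contribution is D_v = D_{p+v} - D_p (the exact split:
D_p + D_v = D_{p+v} by construction), and the valve-to-pump ratio

    R = D_v / D_p = (1 + S_v / S_p)**beta - 1

is independent of both Q and the model coefficient C.  For multi-pass loop
experiments both S values scale with the pass count, which leaves R
unchanged.

Case-to-case comparisons use the damage ratio eta = D_A / D_B (pump-only or
pump+valve) and the attenuation

    delta = (eta_{p+v} - 1) / (eta_p - 1) - 1

which measures how much the valve's added damage masks the true difference
between two pumps or operating points (reported as a percentage).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .damage_models import (
    PowerLawConstants,
    constants_to_dict,
    is_registry_set,
)
from .field_engine import StressIntegral, outlet_damage

__all__ = [
    "DeviceDamagePair",
    "ComparisonResult",
    "combined_damage",
    "split_damage",
    "valve_to_pump_ratio",
    "averaged_ratio",
    "eta",
    "attenuation_delta",
    "relative_error",
    "comparison_report",
    "write_report",
]


@dataclass(frozen=True)
class DeviceDamagePair:
    """Pump and valve stress integrals sharing one flow rate and model."""

    S_p: StressIntegral
    S_v: StressIntegral

    def __post_init__(self) -> None:
        if self.S_p.constants_name != self.S_v.constants_name:
            raise ValueError(
                f"pump and valve integrals use different constant sets: "
                f"{self.S_p.constants_name!r} vs {self.S_v.constants_name!r}"
            )
        if not math.isclose(self.S_p.Q, self.S_v.Q, rel_tol=1e-12):
            raise ValueError(
                f"pump and valve integrals use different flow rates: "
                f"{self.S_p.Q} vs {self.S_v.Q}"
            )

    @property
    def Q(self) -> float:
        return self.S_p.Q


@dataclass(frozen=True)
class ComparisonResult:
    """Valve-to-pump ratio and case-comparison statistics.

    ``delta`` is dimensionless (multiply by 100 for the percent figure
    quoted in reports).
    """

    R_by_model: Mapping[str, float]
    R_mean: float
    R_sd: float
    eta_p: float | None = None
    eta_pv: float | None = None
    delta: float | None = None


def _check_pair(pair: DeviceDamagePair, constants: PowerLawConstants) -> None:
    if pair.S_p.constants_name != constants.name:
        raise ValueError(
            f"pair was computed with constants {pair.S_p.constants_name!r}, "
            f"not {constants.name!r}"
        )


def combined_damage(pair: DeviceDamagePair, constants: PowerLawConstants) -> float:
    """Joint single-pass damage D_{p+v} = ((S_p + S_v) / Q)**beta."""
    _check_pair(pair, constants)
    return ((pair.S_p.S + pair.S_v.S) / pair.Q) ** constants.beta


def split_damage(
    pair: DeviceDamagePair, constants: PowerLawConstants
) -> tuple[float, float]:
    """Exact split (D_p, D_v) with D_p + D_v = D_{p+v}.

    D_p = (S_p/Q)**beta and D_v is the valve's marginal damage on top of the
    pump.  For beta < 1 the marginal damage is below the valve's stand-alone
    damage (concavity of the power law).  A pump with S_p = 0 is degenerate:
    the split reduces to D_p = 0, D_v = (S_v/Q)**beta, with a warning.
    """
    _check_pair(pair, constants)
    d_pv = combined_damage(pair, constants)
    if pair.S_p.S == 0 and pair.S_v.S > 0:
        warnings.warn(
            "pump stress integral is zero; attributing all damage to the valve",
            stacklevel=2,
        )
        return 0.0, d_pv
    d_p = outlet_damage(pair.S_p, constants)
    return d_p, d_pv - d_p


def valve_to_pump_ratio(S_p: float, S_v: float, beta: float) -> float:
    """R = D_v / D_p = (1 + S_v/S_p)**beta - 1.

    Independent of Q and of the model coefficient C; scale-invariant in
    (S_p, S_v), which also covers multi-pass experiments where both integrals
    scale with the pass count.
    """
    if not S_p > 0:
        raise ValueError(f"pump stress integral must be positive, got {S_p}")
    if S_v < 0:
        raise ValueError(f"valve stress integral must be non-negative, got {S_v}")
    if not 0 < beta <= 1:
        raise ValueError(f"beta must lie in (0, 1], got {beta}")
    return (1.0 + S_v / S_p) ** beta - 1.0


def averaged_ratio(R_by_model: Mapping[str, float]) -> tuple[float, float]:
    """Mean and sample SD of R across constant sets.

    Hemolysis ratios are averaged over the HO and TZ sets to reduce model
    uncertainty; with a single set (e.g. the lone PAI model) the SD is zero.
    """
    if not R_by_model:
        raise ValueError("need at least one ratio to average")
    values = list(R_by_model.values())
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        return mean, 0.0
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    return mean, sd


def eta(D_A: float, D_B: float) -> float:
    """Case-to-case damage ratio eta = D_A / D_B."""
    if not D_B > 0:
        raise ValueError(f"reference damage must be positive, got {D_B}")
    return D_A / D_B


def attenuation_delta(eta_p: float, eta_pv: float) -> float:
    """Attenuation delta = (eta_pv - 1) / (eta_p - 1) - 1 (dimensionless).

    Measures the relative change in the between-case damage difference when
    the valve's contribution is included; negative values mean the valve
    masks part of the true pump-to-pump difference.  Undefined when the
    pump-only damages are equal (eta_p = 1).
    """
    if eta_p == 1.0:
        raise ValueError(
            "attenuation is undefined when pump-only damages are equal (eta_p = 1)"
        )
    return (eta_pv - 1.0) / (eta_p - 1.0) - 1.0


def relative_error(predicted: float, reference: float) -> float:
    """|predicted - reference| / reference (dimensionless fraction)."""
    if reference == 0:
        raise ValueError("reference value must be nonzero")
    return abs(predicted - reference) / abs(reference)


def comparison_report(
    pairs_by_model: Mapping[str, DeviceDamagePair],
    constants_by_model: Mapping[str, PowerLawConstants],
    eta_p: float | None = None,
    eta_pv: float | None = None,
) -> dict:
    """Assemble a JSON-ready comparison document.

    ``pairs_by_model`` maps constant-set name to the (pump, valve) pair
    evaluated with that set.  R mean/SD is taken over the HI-kind sets only;
    PAI sets are reported individually.  If a pair of case ratios is supplied,
    the attenuation delta is included.
    """
    damages: dict[str, dict] = {}
    r_by_model: dict[str, float] = {}
    r_hi: dict[str, float] = {}
    for name, pair in pairs_by_model.items():
        constants = constants_by_model[name]
        _check_pair(pair, constants)
        d_p, d_v = split_damage(pair, constants)
        d_pv = combined_damage(pair, constants)
        r = valve_to_pump_ratio(pair.S_p.S, pair.S_v.S, constants.beta)
        r_by_model[name] = r
        if constants.damage_kind == "HI":
            r_hi[name] = r
        damages[name] = {
            "constants": constants_to_dict(constants),
            "registry_set": is_registry_set(constants),
            "S_p": pair.S_p.S,
            "S_v": pair.S_v.S,
            "Q_m3_per_s": pair.Q,
            "labels": {"pump": pair.S_p.label, "valve": pair.S_v.label},
            "D_p": d_p,
            "D_v": d_v,
            "D_p_plus_v": d_pv,
            "units": "percent" if constants.damage_kind == "HI" else "index",
            "R": r,
        }
    report: dict = {"per_model": damages, "R_by_model": r_by_model}
    if r_hi:
        mean, sd = averaged_ratio(r_hi)
        report["R_HI_mean"] = mean
        report["R_HI_sd"] = sd
    if eta_p is not None and eta_pv is not None:
        report["eta_p"] = eta_p
        report["eta_pv"] = eta_pv
        try:
            report["delta_percent"] = 100.0 * attenuation_delta(eta_p, eta_pv)
        except ValueError:
            report["delta_percent"] = None  # undefined when eta_p == 1
    return report


def write_report(report: dict, path) -> None:
    """Write a comparison document as indented JSON."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
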