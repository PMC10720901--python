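"""Quasi-1D loop hydraulics: pressure-drop surrogate, matching loops, fields.

The full test-loop workflow needs three things that in the original study
came from 3D CFD: the pressure drop of the clamped tubing at a given throat
opening, the pump head at a given speed, and a dissipation field to feed the
damage integrals.  This module supplies desk-scale surrogates for all three:

* :func:`tubing_pressure_drop` — a standard loss-coefficient model (sharp
  contraction + Borda-Carnot expansion + Darcy friction on the swept section
  areas).  Its contract is qualitative: positive, smooth, strictly
  decreasing in throat thickness d and increasing in flow rate; it is not a
  calibration of any measured head.
* :func:`size_throat_for_head` / :func:`match_pump_speed` — the two
  iterative matching workflows: bisection on a 1 um grid of d (resp. a 5 rpm
  grid of speed) until the relative head error is below 0.75%.
* :func:`distribute_dissipation` — an energy-consistent dissipation field:
  total dissipated power equals Q * dP exactly, concentrated in the throat
  and an exponentially decaying downstream jet, split between viscous and
  turbulent parts in the jet.

Unit conventions: flow rates in L/min and heads in mmHg at the interfaces
(1 mmHg = 133.322 Pa, 1 L/min = 1/60000 m^3/s); everything internal is SI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .damage_models import BLOOD, FluidProperties
from .field_engine import DiscreteFlowField
from .throat_geometry import (
    TUBE_INNER_DIAMETER_MM,
    ThroatSpec,
    TubingModelSpec,
    section_profile,
)

__all__ = [
    "MMHG_PA",
    "LPM_M3S",
    "OperatingPoint",
    "PumpSurrogate",
    "IterationLog",
    "BracketingError",
    "tubing_pressure_drop",
    "size_throat_for_head",
    "match_pump_speed",
    "distribute_dissipation",
]

MMHG_PA = 133.322  # Pa per mmHg
LPM_M3S = 1.0 / 60000.0  # m^3/s per L/min

_D_QUANTUM_MM = 1e-3  # 1 um sizing grid
_RPM_QUANTUM = 5.0  # 5 rpm matching grid
_HEAD_RTOL = 0.0075  # 0.75% relative head error


class BracketingError(RuntimeError):
    """Target head outside the range achievable by the search bracket."""


@dataclass(frozen=True)
class OperatingPoint:
    """One loop operating point: flow, pump speed, matched pressure head."""

    flow_rate: float  # L/min
    rotational_speed: float  # rpm
    pressure_head: float | None = None  # mmHg (None when not yet matched)
    case_id: str = ""

    def __post_init__(self) -> None:
        if not self.flow_rate > 0:
            raise ValueError(f"flow rate must be positive, got {self.flow_rate}")
        if self.pressure_head is not None and not self.pressure_head > 0:
            raise ValueError(
                f"pressure head must be positive, got {self.pressure_head}"
            )


@dataclass(frozen=True)
class PumpSurrogate:
    """Similarity-law pump model standing in for pump CFD.

    Reference (flow L/min, speed rpm, head mmHg) triples are collapsed to
    head coefficient psi = H / n^2 versus flow coefficient phi = Q / n and
    interpolated piecewise-linearly, so every reference point is reproduced
    exactly and head scales with speed squared at fixed flow coefficient.
    psi must be non-increasing in phi (a falling pump curve), which makes
    head strictly increasing in speed at fixed flow.
    """

    reference_points: Sequence[tuple[float, float, float]]
    head_speed_exponent: float = 2.0

    def __post_init__(self) -> None:
        pts = sorted(self.reference_points, key=lambda p: p[0] / p[1])
        if not pts:
            raise ValueError("need at least one reference point")
        for q, n, h in pts:
            if q <= 0 or n <= 0 or h <= 0:
                raise ValueError(f"invalid reference point {(q, n, h)}")
        phi = [q / n for q, n, _ in pts]
        psi = [h / n**self.head_speed_exponent for q, n, h in pts]
        if any(b > a for a, b in zip(psi, psi[1:])):
            raise ValueError(
                "head coefficient must be non-increasing in flow coefficient "
                "(falling pump curve)"
            )
        object.__setattr__(self, "_phi", tuple(phi))
        object.__setattr__(self, "_psi", tuple(psi))

    def head(self, flow_lpm: float, speed_rpm: float) -> float:
        """Predicted head (mmHg) at a flow (L/min) and speed (rpm)."""
        if flow_lpm <= 0 or speed_rpm <= 0:
            raise ValueError("flow and speed must be positive")
        phi = flow_lpm / speed_rpm
        psi = float(np.interp(phi, self._phi, self._psi))
        # np.interp clamps outside the data range; extrapolate the end slopes
        ph, ps = self._phi, self._psi
        if len(ph) > 1:
            if phi < ph[0]:
                slope = (ps[1] - ps[0]) / (ph[1] - ph[0])
                psi = ps[0] + slope * (phi - ph[0])
            elif phi > ph[-1]:
                slope = (ps[-1] - ps[-2]) / (ph[-1] - ph[-2])
                psi = ps[-1] + slope * (phi - ph[-1])
        head = psi * speed_rpm**self.head_speed_exponent
        if head <= 0:
            raise ValueError(
                f"surrogate head non-positive at Q={flow_lpm} L/min, "
                f"n={speed_rpm} rpm (outside the valid curve range)"
            )
        return head


@dataclass
class IterationLog:
    """Trial-by-trial record of a matching loop."""

    rows: list[dict] = field(default_factory=list)

    def add(self, trial: int, x: float, head: float, rel_err: float, x_name: str) -> None:
        self.rows.append(
            {"trial": trial, x_name: x, "dP_mmHg": head, "rel_err": rel_err}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _friction_factor(re: float) -> float:
    """Darcy friction factor: laminar 64/Re below 2300, else Blasius."""
    if re <= 0:
        return 0.0
    if re < 2300.0:
        return 64.0 / re
    return 0.316 * re**-0.25


def tubing_pressure_drop(
    model: TubingModelSpec,
    flow_lpm: float,
    fluid: FluidProperties = BLOOD,
    n_stations: int = 101,
) -> float:
    """Pressure drop (mmHg) of the tubing model at a flow rate (L/min).

    Loss budget: sharp-contraction loss K_c = 0.5 (1 - A_throat/A_tube) on
    the throat velocity head, Borda-Carnot expansion loss
    0.5 rho (V_throat - V_tube)^2, and Darcy friction integrated over the
    swept section profile with the local hydraulic diameter (laminar 64/Re
    or Blasius by regime).  Strictly decreasing in throat thickness d and
    increasing in flow rate.
    """
    if not flow_lpm > 0:
        raise ValueError(f"flow rate must be positive, got {flow_lpm}")
    if model.throat.d < _D_QUANTUM_MM:
        raise ValueError(
            f"throat thickness {model.throat.d} mm below 1 um: unphysical closure"
        )
    q = flow_lpm * LPM_M3S
    rho, mu = fluid.rho, fluid.mu

    def _area_m2(p) -> float:
        return p.area * 1e-6

    a_tube = math.pi * (model.inner_diameter * 1e-3) ** 2 / 4.0
    p_mid = section_profile(
        (model.z_throat_start + model.z_throat_end) / 2.0, model
    )
    a_throat = _area_m2(p_mid)
    v_tube = q / a_tube
    v_throat = q / a_throat

    k_c = 0.5 * (1.0 - a_throat / a_tube)
    dp_contraction = k_c * 0.5 * rho * v_throat**2
    dp_expansion = 0.5 * rho * (v_throat - v_tube) ** 2

    # distributed friction over the axial profile (trapezoid in z)
    zs = np.linspace(0.0, model.total_length, n_stations)
    grad = np.empty_like(zs)
    for i, z in enumerate(zs):
        p = section_profile(float(z), model)
        a = _area_m2(p)
        per = p.perimeter * 1e-3
        dh = 4.0 * a / per
        v = q / a
        re = rho * v * dh / mu
        f = _friction_factor(re)
        grad[i] = f / dh * 0.5 * rho * v**2  # Pa per m
    dp_friction = float(np.trapezoid(grad, zs * 1e-3))

    return (dp_contraction + dp_expansion + dp_friction) / MMHG_PA


def _dp_at_d(d_mm: float, flow_lpm: float, fluid: FluidProperties) -> float:
    model = TubingModelSpec(throat=ThroatSpec.from_thickness(d_mm))
    return tubing_pressure_drop(model, flow_lpm, fluid)


def size_throat_for_head(
    target_head: float,
    flow_lpm: float,
    fluid: FluidProperties = BLOOD,
) -> tuple[ThroatSpec, IterationLog]:
    """Size the throat thickness d to match a target head at a given flow.

    Bisection on the 1 um grid of d over (1 um, 9.525 mm); the pressure drop
    is strictly decreasing in d, so convergence is guaranteed whenever the
    target lies between the fully-open and nearly-closed heads.  The result
    is quantized to 1 um, the relative head error is at most 0.75%, and of
    the adjacent grid points meeting the tolerance the smaller d is
    returned.  Every trial is recorded in the iteration log.
    """
    if not target_head > 0:
        raise ValueError(f"target head must be positive, got {target_head}")
    log = IterationLog()
    lo_um, hi_um = 1, int(round(TUBE_INNER_DIAMETER_MM / _D_QUANTUM_MM))
    trial = 0

    def _probe(d_um: int) -> float:
        nonlocal trial
        trial += 1
        d_mm = d_um * _D_QUANTUM_MM
        dp = _dp_at_d(d_mm, flow_lpm, fluid)
        log.add(trial, d_mm, dp, abs(dp - target_head) / target_head, "d_mm")
        return dp

    dp_lo, dp_hi = _probe(lo_um), _probe(hi_um)
    if not dp_hi <= target_head <= dp_lo:
        raise BracketingError(
            f"target head {target_head:.4g} mmHg outside achievable range "
            f"[{dp_hi:.4g}, {dp_lo:.4g}] mmHg at {flow_lpm} L/min"
        )
    while hi_um - lo_um > 1:
        mid = (lo_um + hi_um) // 2
        if _probe(mid) >= target_head:
            lo_um = mid
        else:
            hi_um = mid
    # prefer the smaller d among adjacent grid points within tolerance
    candidates = []
    for d_um in (lo_um, hi_um):
        dp = _dp_at_d(d_um * _D_QUANTUM_MM, flow_lpm, fluid)
        candidates.append((d_um, abs(dp - target_head) / target_head))
    within = [c for c in candidates if c[1] <= _HEAD_RTOL]
    if within:
        d_um = min(c[0] for c in within)
    else:
        d_um, rel = min(candidates, key=lambda c: c[1])
        raise BracketingError(
            f"1 um grid cannot meet the 0.75% head tolerance near d = "
            f"{d_um * _D_QUANTUM_MM:.3f} mm (best relative error {rel:.3%})"
        )
    return ThroatSpec.from_thickness(d_um * _D_QUANTUM_MM), log


def match_pump_speed(
    target_head: float,
    flow_lpm: float,
    surrogate: PumpSurrogate,
    speed_bracket_rpm: tuple[float, float] = (500.0, 20000.0),
) -> tuple[float, IterationLog]:
    """Tune pump speed (5 rpm grid) until the head matches to 0.75%.

    The surrogate's head is strictly increasing in speed at fixed flow, so
    bisection on the 5 rpm grid has a unique solution.
    """
    if not target_head > 0:
        raise ValueError(f"target head must be positive, got {target_head}")
    log = IterationLog()
    lo = int(math.ceil(speed_bracket_rpm[0] / _RPM_QUANTUM))
    hi = int(math.floor(speed_bracket_rpm[1] / _RPM_QUANTUM))
    trial = 0

    def _probe(n_grid: int) -> float:
        nonlocal trial
        trial += 1
        rpm = n_grid * _RPM_QUANTUM
        try:
            h = surrogate.head(flow_lpm, rpm)
        except ValueError:
            h = 0.0  # below the valid curve: treat as no head
        log.add(trial, rpm, h, abs(h - target_head) / target_head, "speed_rpm")
        return h

    h_lo, h_hi = _probe(lo), _probe(hi)
    if not h_lo <= target_head <= h_hi:
        raise BracketingError(
            f"target head {target_head:.4g} mmHg outside achievable range "
            f"[{h_lo:.4g}, {h_hi:.4g}] mmHg for speeds "
            f"{lo * _RPM_QUANTUM:.0f}-{hi * _RPM_QUANTUM:.0f} rpm"
        )
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _probe(mid) <= target_head:
            lo = mid
        else:
            hi = mid
    best = None
    for n_grid in (lo, hi):
        h = _probe(n_grid)
        rel = abs(h - target_head) / target_head
        if rel <= _HEAD_RTOL and (best is None or n_grid < best[0]):
            best = (n_grid, rel)
    if best is None:
        raise BracketingError(
            "5 rpm grid cannot meet the 0.75% head tolerance for target "
            f"{target_head:.4g} mmHg"
        )
    return best[0] * _RPM_QUANTUM, log


def distribute_dissipation(
    model: TubingModelSpec,
    flow_lpm: float,
    dp_mmhg: float,
    n_cells: int = 200,
    fluid: FluidProperties = BLOOD,
    jet_turb_fraction: float = 0.8,
    jet_decay_length_mm: float = 5.0,
    jet_length_mm: float = 20.0,
    label: str = "",
) -> DiscreteFlowField:
    """Build an energy-consistent dissipation field for the tubing model.

    Axial slices of the model become cells (volume = local area x dz); the
    dissipation density is uniform-low in the straight sections, high in the
    throat, and decays exponentially over a downstream jet region, then the
    whole profile is rescaled so that

        sum over cells of rho * (eps_vis + eps_turb) * V  =  Q * dP

    holds exactly (in SI).  In the jet and throat, ``jet_turb_fraction`` of
    the dissipation is booked as turbulent; the laminar straights are fully
    viscous.
    """
    if n_cells < 3:
        raise ValueError(f"need at least 3 cells, got {n_cells}")
    if dp_mmhg < 0:
        raise ValueError(f"pressure drop must be non-negative, got {dp_mmhg}")
    q = flow_lpm * LPM_M3S
    p_total = q * dp_mmhg * MMHG_PA  # W

    edges = np.linspace(0.0, model.total_length, n_cells + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    dz_m = np.diff(edges) * 1e-3
    areas_m2 = np.array(
        [section_profile(float(z), model).area * 1e-6 for z in centers]
    )
    volumes = areas_m2 * dz_m

    z0, z1 = model.z_throat_start, model.z_throat_end
    jet_end = min(z1 + jet_length_mm, model.total_length)
    weights = np.full(n_cells, 1e-3)  # faint background in the straights
    turbulent = np.zeros(n_cells, dtype=bool)
    in_throat = (centers >= z0) & (centers <= z1)
    weights[in_throat] = 1.0
    turbulent[in_throat] = True
    in_jet = (centers > z1) & (centers <= jet_end)
    weights[in_jet] = np.exp(-(centers[in_jet] - z1) / jet_decay_length_mm)
    turbulent[in_jet] = True

    if p_total == 0.0:
        eps = np.zeros(n_cells)
    else:
        scale = p_total / float(np.sum(fluid.rho * weights * volumes))
        eps = scale * weights

    eps_vis = np.where(turbulent, (1.0 - jet_turb_fraction) * eps, eps)
    eps_turb = np.where(turbulent, jet_turb_fraction * eps, 0.0)
    return DiscreteFlowField(
        volumes=volumes,
        eps_vis=eps_vis,
        eps_turb=eps_turb,
        Q=q,
        fluid=fluid,
        label=label or f"tubing d={model.throat.d:.3f}mm {flow_lpm}L/min",
    )
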