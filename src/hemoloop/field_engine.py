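"""Discretized flow fields and the Eulerian stress-volume integral.

A :class:`DiscreteFlowField` is the stand-in for a CFD export: per-cell
volumes and specific dissipation rates (resolved viscous ``eps_vis`` plus
turbulence-model ``eps_turb``), together with the bulk flow rate Q and fluid
properties.  No velocity field or connectivity is needed: under the
steady-state linearised transport of the damage index DI, integrating the
source term over the device volume and balancing the outlet flux gives

    Q * DI_outlet = integral_V sigma dV = S

so the single-pass outlet damage is D = (S / Q)**beta.  S carries the model
coefficient C**(1/beta) inside it (it is the integral of the source term),
so no further constant appears in D.

A Lagrangian oracle (:func:`lagrangian_damage`) integrates the same source
term along a stress history tau(t) and serves as an independent check: for
plug flow through a uniform field the two routes agree exactly.

Field I/O supports two dialects: a flat CSV (columns volume,eps_vis,eps_turb
with a commented header block for Q, rho, mu, label) and a minimal VTU
unstructured-grid file (ascii XML, one vertex cell per flow cell, cell-data
arrays ``volume``, ``eps_vis``, ``eps_turb``, field-data Q/rho/mu).  Both
writers are bit-stable: identical fields produce identical bytes.
"""

from __future__ import annotations

import io
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .damage_models import (
    BLOOD,
    FluidProperties,
    PowerLawConstants,
    effective_stress,
    source_term,
)

__all__ = [
    "DiscreteFlowField",
    "StressIntegral",
    "StreamlineHistory",
    "cell_effective_stress",
    "stress_volume_integral",
    "outlet_damage",
    "lagrangian_damage",
    "write_field_csv",
    "read_field_csv",
    "write_field_vtu",
    "read_field_vtu",
]


@dataclass(frozen=True)
class DiscreteFlowField:
    """Cell-wise dissipation field with bulk flow rate, in SI units.

    Parameters
    ----------
    volumes:
        Cell volumes, m^3, all positive.
    eps_vis, eps_turb:
        Resolved (viscous) and turbulence-model specific dissipation rates,
        W/kg, non-negative, one value per cell.
    Q:
        Bulk volumetric flow rate through the device, m^3/s, positive.
    fluid:
        Fluid properties (defaults to blood).
    label:
        Device / operating-point tag carried through to reports.
    """

    volumes: np.ndarray
    eps_vis: np.ndarray
    eps_turb: np.ndarray
    Q: float
    fluid: FluidProperties = BLOOD
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("volumes", "eps_vis", "eps_turb"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float)
            )
        v, ev, et_ = self.volumes, self.eps_vis, self.eps_turb
        if v.ndim != 1 or v.size == 0:
            raise ValueError("field must contain at least one cell")
        if ev.shape != v.shape or et_.shape != v.shape:
            raise ValueError(
                f"shape mismatch: volumes {v.shape}, eps_vis {ev.shape}, "
                f"eps_turb {et_.shape}"
            )
        if np.any(v <= 0):
            i = int(np.argmin(v))
            raise ValueError(f"cell {i} has non-positive volume {v[i]}")
        for name, arr in (("eps_vis", ev), ("eps_turb", et_)):
            if np.any(arr < 0):
                i = int(np.argmin(arr))
                raise ValueError(f"cell {i} has negative {name} {arr[i]}")
        if not self.Q > 0:
            raise ValueError(f"flow rate must be positive, got {self.Q}")

    @property
    def n_cells(self) -> int:
        return int(self.volumes.size)

    @property
    def total_volume(self) -> float:
        return float(self.volumes.sum())

    @property
    def eps_total(self) -> np.ndarray:
        """Total specific dissipation rate per cell, W/kg."""
        return self.eps_vis + self.eps_turb

    @property
    def total_power(self) -> float:
        """Total dissipated power, W: sum of rho * eps * V over cells."""
        return float(np.sum(self.fluid.rho * self.eps_total * self.volumes))


@dataclass(frozen=True)
class StressIntegral:
    """Volume integral S of the damage source term for one device.

    Units are DI-units * m^3 / s; the outlet damage is (S / Q)**beta.
    """

    S: float
    constants_name: str
    Q: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.S < 0:
            raise ValueError(f"S must be non-negative, got {self.S}")
        if not self.Q > 0:
            raise ValueError(f"flow rate must be positive, got {self.Q}")


@dataclass(frozen=True)
class StreamlineHistory:
    """Ordered (time, stress) samples along one pathline.

    Times are strictly increasing and start at zero; stresses in Pa.
    """

    times: np.ndarray
    taus: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "taus", np.asarray(self.taus, dtype=float))
        t, tau = self.times, self.taus
        if t.shape != tau.shape or t.ndim != 1:
            raise ValueError("times and taus must be 1-D arrays of equal length")
        if t.size and t[0] != 0.0:
            raise ValueError(f"history must start at t=0, got t[0]={t[0]}")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("history times must be strictly increasing")
        if np.any(tau < 0):
            raise ValueError("stresses must be non-negative")


def cell_effective_stress(fld: DiscreteFlowField) -> np.ndarray:
    """Per-cell effective stress tau = sqrt((eps_vis + eps_turb) * mu * rho), Pa."""
    try:
        return effective_stress(fld.eps_total, fld.fluid)
    except ValueError as exc:  # pragma: no cover - guarded by field validation
        raise ValueError(f"field {fld.label!r}: {exc}") from exc


def stress_volume_integral(
    fld: DiscreteFlowField, constants: PowerLawConstants
) -> StressIntegral:
    """S = sum over cells of source_term(tau_cell) * V_cell.

    Exactly invariant under dissipation-preserving cell subdivision: splitting
    a cell into equal halves with the same dissipation rates leaves S
    unchanged.
    """
    tau = cell_effective_stress(fld)
    s = float(np.sum(source_term(tau, constants) * fld.volumes))
    return StressIntegral(S=s, constants_name=constants.name, Q=fld.Q, label=fld.label)


def outlet_damage(si: StressIntegral, constants: PowerLawConstants) -> float:
    """Single-pass outlet damage D = (S / Q)**beta."""
    if si.constants_name != constants.name:
        raise ValueError(
            f"stress integral was computed with constants "
            f"{si.constants_name!r}, not {constants.name!r}"
        )
    return (si.S / si.Q) ** constants.beta


def lagrangian_damage(
    history: StreamlineHistory, constants: PowerLawConstants
) -> float:
    """Damage accumulated along a pathline: D = (integral sigma(tau(t)) dt)**beta.

    The damage-index rate is integrated with the trapezoidal rule over the
    sampled stress history; histories are assumed smooth between samples.
    """
    if history.times.size < 2:
        raise ValueError("streamline history needs at least 2 samples")
    sigma = source_term(history.taus, constants)
    di = float(np.trapezoid(sigma, history.times))
    return di**constants.beta


# ---------------------------------------------------------------------------
# Field I/O
# ---------------------------------------------------------------------------

_FMT = "%.17g"  # round-trips float64 exactly and bit-stably


def _fmt(x: float) -> str:
    return _FMT % x


def write_field_csv(fld: DiscreteFlowField, path) -> None:
    """Write the flat CSV dialect: commented header block + cell table."""
    buf = io.StringIO()
    buf.write(f"# Q = {_fmt(fld.Q)}\n")
    buf.write(f"# rho = {_fmt(fld.fluid.rho)}\n")
    buf.write(f"# mu = {_fmt(fld.fluid.mu)}\n")
    buf.write(f"# label = {fld.label}\n")
    buf.write("volume,eps_vis,eps_turb\n")
    for v, ev, et_ in zip(fld.volumes, fld.eps_vis, fld.eps_turb):
        buf.write(f"{_fmt(v)},{_fmt(ev)},{_fmt(et_)}\n")
    Path(path).write_text(buf.getvalue())


def read_field_csv(path) -> DiscreteFlowField:
    """Read the flat CSV dialect written by :func:`write_field_csv`.

    A missing ``eps_turb`` column is treated as zero (with the caller expected
    to log a warning at the interface layer); Q, rho and mu come from the
    commented header block.
    """
    path = Path(path)
    header: dict[str, str] = {}
    lines = path.read_text().splitlines()
    n_header = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_header += 1
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, value = body.partition("=")
            header[key.strip()] = value.strip()
    try:
        q = float(header["Q"])
    except KeyError:
        raise ValueError(f"{path}: missing 'Q' in header block") from None
    rho = float(header.get("rho", BLOOD.rho))
    mu = float(header.get("mu", BLOOD.mu))
    label = header.get("label", "")
    table = pd.read_csv(
        io.StringIO("\n".join(lines[n_header:])), float_precision="round_trip"
    )
    if "volume" not in table.columns or "eps_vis" not in table.columns:
        raise ValueError(f"{path}: need at least columns volume,eps_vis")
    eps_turb = (
        table["eps_turb"].to_numpy()
        if "eps_turb" in table.columns
        else np.zeros(len(table))
    )
    return DiscreteFlowField(
        volumes=table["volume"].to_numpy(),
        eps_vis=table["eps_vis"].to_numpy(),
        eps_turb=eps_turb,
        Q=q,
        fluid=FluidProperties(rho=rho, mu=mu),
        label=label,
    )


def _data_array(name: str, values: Sequence[float], components: int = 1) -> ET.Element:
    el = ET.Element(
        "DataArray",
        type="Float64",
        Name=name,
        NumberOfComponents=str(components),
        format="ascii",
    )
    el.text = " ".join(_fmt(v) for v in values)
    return el


def write_field_vtu(fld: DiscreteFlowField, path) -> None:
    """Write the unstructured-grid dialect: ascii VTU with one vertex cell
    per flow cell (cell data ``volume``, ``eps_vis``, ``eps_turb``; field
    data ``Q``, ``rho``, ``mu``).  Cells carry no geometry beyond a point
    index because the Eulerian evaluation needs only volumes and dissipation.
    """
    n = fld.n_cells
    root = ET.Element(
        "VTKFile", type="UnstructuredGrid", version="0.1", byte_order="LittleEndian"
    )
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(grid, "Piece", NumberOfPoints=str(n), NumberOfCells=str(n))

    fdata = ET.SubElement(root, "FieldData")
    for name, value in (("Q", fld.Q), ("rho", fld.fluid.rho), ("mu", fld.fluid.mu)):
        fdata.append(_data_array(name, [value]))
    label_el = ET.SubElement(
        fdata, "DataArray", type="String", Name="label", format="ascii"
    )
    label_el.text = fld.label

    points = ET.SubElement(piece, "Points")
    coords = np.zeros(3 * n)
    coords[::3] = np.arange(n, dtype=float)  # placeholder 1-D layout
    points.append(_data_array("Points", coords, components=3))

    cells = ET.SubElement(piece, "Cells")
    conn = ET.SubElement(
        cells, "DataArray", type="Int64", Name="connectivity", format="ascii"
    )
    conn.text = " ".join(str(i) for i in range(n))
    offs = ET.SubElement(
        cells, "DataArray", type="Int64", Name="offsets", format="ascii"
    )
    offs.text = " ".join(str(i + 1) for i in range(n))
    types = ET.SubElement(
        cells, "DataArray", type="UInt8", Name="types", format="ascii"
    )
    types.text = " ".join("1" for _ in range(n))  # VTK_VERTEX

    cdata = ET.SubElement(piece, "CellData")
    cdata.append(_data_array("volume", fld.volumes))
    cdata.append(_data_array("eps_vis", fld.eps_vis))
    cdata.append(_data_array("eps_turb", fld.eps_turb))

    ET.indent(root)
    Path(path).write_bytes(ET.tostring(root, xml_declaration=True))


def read_field_vtu(path) -> DiscreteFlowField:
    """Read the VTU dialect written by :func:`write_field_vtu`."""
    path = Path(path)
    root = ET.parse(path).getroot()

    def _floats(el: ET.Element) -> np.ndarray:
        return np.array((el.text or "").split(), dtype=float)

    scalars: dict[str, float] = {}
    label = ""
    fdata = root.find("FieldData")
    if fdata is not None:
        for el in fdata.findall("DataArray"):
            if el.get("Name") == "label":
                label = (el.text or "").strip()
            else:
                scalars[el.get("Name", "")] = float(_floats(el)[0])
    if "Q" not in scalars:
        raise ValueError(f"{path}: missing field-data array 'Q'")

    cdata = root.find("UnstructuredGrid/Piece/CellData")
    if cdata is None:
        raise ValueError(f"{path}: no CellData section")
    arrays = {el.get("Name"): _floats(el) for el in cdata.findall("DataArray")}
    for required in ("volume", "eps_vis"):
        if required not in arrays:
            raise ValueError(f"{path}: missing cell-data array {required!r}")
    eps_turb = arrays.get("eps_turb")
    if eps_turb is None:
        eps_turb = np.zeros_like(arrays["volume"])
    return DiscreteFlowField(
        volumes=arrays["volume"],
        eps_vis=arrays["eps_vis"],
        eps_turb=eps_turb,
        Q=scalars["Q"],
        fluid=FluidProperties(
            rho=scalars.get("rho", BLOOD.rho), mu=scalars.get("mu", BLOOD.mu)
        ),
        label=label,
    )
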