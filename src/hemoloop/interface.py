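"""Command-line interface and report assembly for the loop workflow.

Thin wrappers over the library tying the stages together the way an
in-vitro test campaign runs them:

* ``hemoloop damage``       — S and outlet damage for a field (file or
                              uniform synthetic spec), per constant set;
* ``hemoloop loop-compare`` — pump A vs pump B with a shared valve field:
                              split damages, valve-to-pump ratio R
                              (mean +/- SD over the hemolysis sets), case
                              ratios eta and attenuation delta;
* ``hemoloop throat-size``  — size the clamp opening for a target head and
                              export the geometry + iteration log;
* ``hemoloop geometry``     — STL + profile table for a given opening;
* ``hemoloop synth``        — write synthetic fields in both dialects;
* ``hemoloop fixtures``     — the eight shipped operating points as CSV.

Every run directory receives a ``manifest.json`` naming the outputs and the
constant sets used (with their values, so reports are auditable).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import click
import yaml

from . import composition, field_engine, reduced_flow, synthetic_data, throat_geometry
from .damage_models import (
    CONSTANTS_REGISTRY,
    PowerLawConstants,
    constants_from_dict,
    constants_to_dict,
    get_constants,
    is_registry_set,
)

__all__ = ["RunConfig", "load_config", "read_field", "main"]

log = logging.getLogger("hemoloop")

_DEFAULT_SETS = ("HO", "TZ", "Ding-PAI")


@dataclass
class RunConfig:
    """Configuration for a CLI run (flat YAML/JSON file)."""

    constants: list[PowerLawConstants] = dc_field(
        default_factory=lambda: [get_constants(n) for n in _DEFAULT_SETS]
    )
    out_dir: Path = Path("hemoloop_run")
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.constants:
            raise ValueError("need at least one constants set")
        self.out_dir = Path(self.out_dir)


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML (or JSON) file.

    The ``constants`` entry may mix registry names and inline
    {name, C, alpha, beta, damage_kind} blocks; inline sets are flagged as
    non-registry in reports.
    """
    block = yaml.safe_load(Path(path).read_text()) or {}
    constants = []
    for entry in block.get("constants", list(_DEFAULT_SETS)):
        if isinstance(entry, str):
            constants.append(get_constants(entry))
        else:
            constants.append(constants_from_dict(entry))
    return RunConfig(
        constants=constants,
        out_dir=Path(block.get("out_dir", "hemoloop_run")),
        seed=int(block.get("seed", 0)),
    )


def read_field(path) -> field_engine.DiscreteFlowField:
    """Read a field file in either dialect, dispatching on the suffix."""
    path = Path(path)
    if path.suffix == ".vtu":
        fld = field_engine.read_field_vtu(path)
    else:
        header = path.read_text().split("\n", 8)
        if not any(line.startswith("volume") and "eps_turb" in line for line in header):
            log.warning("%s: no eps_turb column; treating it as zero", path)
        fld = field_engine.read_field_csv(path)
    return fld


def _resolve_constants(names: tuple[str, ...]) -> list[PowerLawConstants]:
    return [get_constants(n) for n in (names or _DEFAULT_SETS)]


def _damage_block(
    fld: field_engine.DiscreteFlowField, constants: list[PowerLawConstants]
) -> dict:
    out = {}
    for c in constants:
        si = field_engine.stress_volume_integral(fld, c)
        out[c.name] = {
            "constants": constants_to_dict(c),
            "registry_set": is_registry_set(c),
            "S": si.S,
            "D": field_engine.outlet_damage(si, c),
            "units": "percent" if c.damage_kind == "HI" else "index",
        }
    return out


def _write_outputs(out_dir: Path, files: dict[str, object]) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"outputs": []}
    for name, payload in files.items():
        target = out_dir / name
        if isinstance(payload, (bytes, bytearray)):
            target.write_bytes(bytes(payload))
        elif isinstance(payload, str):
            target.write_text(payload)
        else:  # JSON-serializable
            target.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        manifest["outputs"].append(name)
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Log every iteration at INFO.")
def main(verbose: bool) -> None:
    """Blood-damage accounting for in-vitro blood-pump test loops."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )


@main.command()
@click.option("--field", "field_path", type=click.Path(exists=True), default=None,
              help="Field file (.csv or .vtu).")
@click.option("--tau", type=float, default=None,
              help="Uniform synthetic spec: effective stress, Pa.")
@click.option("--volume", type=float, default=2e-5, show_default=True,
              help="Uniform spec volume, m^3.")
@click.option("--flow", type=float, default=5.0, show_default=True,
              help="Uniform spec flow rate, L/min.")
@click.option("--constants", "names", multiple=True,
              type=click.Choice(sorted(CONSTANTS_REGISTRY)))
@click.option("--out", "out_dir", type=click.Path(), default="hemoloop_run",
              show_default=True)
def damage(field_path, tau, volume, flow, names, out_dir) -> None:
    """Stress-volume integral S and outlet damage D for one field."""
    if (field_path is None) == (tau is None):
        raise click.UsageError("give exactly one of --field or --tau")
    if field_path is not None:
        try:
            fld = read_field(field_path)
        except (ValueError, KeyError) as exc:
            raise click.ClickException(f"malformed field file: {exc}") from exc
    else:
        fld, _ = synthetic_data.generate_uniform_field(
            tau, volume, flow * reduced_flow.LPM_M3S
        )
    constants = _resolve_constants(names)
    report = {
        "field": {
            "label": fld.label,
            "n_cells": fld.n_cells,
            "total_volume_m3": fld.total_volume,
            "total_power_w": fld.total_power,
            "Q_m3_per_s": fld.Q,
        },
        "per_model": _damage_block(fld, constants),
    }
    _write_outputs(Path(out_dir), {"damage_report.json": report})
    click.echo(json.dumps(report["per_model"], indent=2, sort_keys=True))


@main.command("loop-compare")
@click.option("--pump-a", type=click.Path(exists=True), required=True)
@click.option("--pump-b", type=click.Path(exists=True), required=True)
@click.option("--valve", type=click.Path(exists=True), required=True)
@click.option("--constants", "names", multiple=True,
              type=click.Choice(sorted(CONSTANTS_REGISTRY)))
@click.option("--out", "out_dir", type=click.Path(), default="hemoloop_run",
              show_default=True)
def loop_compare(pump_a, pump_b, valve, names, out_dir) -> None:
    """Compare two pumps tested on the same loop (shared valve field)."""
    fa, fb, fv = read_field(pump_a), read_field(pump_b), read_field(valve)
    if not (abs(fa.Q - fb.Q) <= 1e-12 * fa.Q and abs(fa.Q - fv.Q) <= 1e-12 * fa.Q):
        raise click.ClickException(
            f"flow rates differ across fields: {fa.Q}, {fb.Q}, {fv.Q}"
        )
    constants = _resolve_constants(names)
    report: dict = {"per_model": {}, "labels": {"pump_a": fa.label,
                                                "pump_b": fb.label,
                                                "valve": fv.label}}
    r_hi_a, r_hi_b = {}, {}
    for c in constants:
        s_a = field_engine.stress_volume_integral(fa, c)
        s_b = field_engine.stress_volume_integral(fb, c)
        s_v = field_engine.stress_volume_integral(fv, c)
        pair_a = composition.DeviceDamagePair(S_p=s_a, S_v=s_v)
        pair_b = composition.DeviceDamagePair(S_p=s_b, S_v=s_v)
        d_pa, d_va = composition.split_damage(pair_a, c)
        d_pb, d_vb = composition.split_damage(pair_b, c)
        eta_p = composition.eta(d_pa, d_pb)
        eta_pv = composition.eta(
            composition.combined_damage(pair_a, c),
            composition.combined_damage(pair_b, c),
        )
        entry = {
            "constants": constants_to_dict(c),
            "registry_set": is_registry_set(c),
            "S": {"pump_a": s_a.S, "pump_b": s_b.S, "valve": s_v.S},
            "D_p": {"pump_a": d_pa, "pump_b": d_pb},
            "D_v": {"pump_a": d_va, "pump_b": d_vb},
            "D_p_plus_v": {
                "pump_a": composition.combined_damage(pair_a, c),
                "pump_b": composition.combined_damage(pair_b, c),
            },
            "R": {
                "pump_a": composition.valve_to_pump_ratio(s_a.S, s_v.S, c.beta),
                "pump_b": composition.valve_to_pump_ratio(s_b.S, s_v.S, c.beta),
            },
            "eta_p": eta_p,
            "eta_pv": eta_pv,
            "units": "percent" if c.damage_kind == "HI" else "index",
        }
        if eta_p == 1.0:
            entry["delta_percent"] = None  # undefined: pumps identical
        else:
            entry["delta_percent"] = 100.0 * composition.attenuation_delta(
                eta_p, eta_pv
            )
        report["per_model"][c.name] = entry
        if c.damage_kind == "HI":
            r_hi_a[c.name] = entry["R"]["pump_a"]
            r_hi_b[c.name] = entry["R"]["pump_b"]
    if r_hi_a:
        for key, rs in (("pump_a", r_hi_a), ("pump_b", r_hi_b)):
            mean, sd = composition.averaged_ratio(rs)
            report[f"R_HI_{key}"] = {"mean": mean, "sd": sd}
    _write_outputs(Path(out_dir), {"loop_compare.json": report})
    click.echo(json.dumps(report["per_model"], indent=2, sort_keys=True))


@main.command("throat-size")
@click.option("--head", type=float, required=True, help="Target head, mmHg.")
@click.option("--flow", type=float, required=True, help="Flow rate, L/min.")
@click.option("--out", "out_dir", type=click.Path(), default="hemoloop_run",
              show_default=True)
def throat_size(head, flow, out_dir) -> None:
    """Size the clamp opening to a target pressure head."""
    try:
        spec, it_log = reduced_flow.size_throat_for_head(head, flow)
    except reduced_flow.BracketingError as exc:
        raise click.ClickException(str(exc)) from exc
    for row in it_log.rows:
        log.info(
            "trial %d: d=%.3f mm -> %.2f mmHg (rel err %.4f)",
            row["trial"], row["d_mm"], row["dP_mmHg"], row["rel_err"],
        )
    model = throat_geometry.TubingModelSpec(throat=spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mesh = throat_geometry.export_geometry(
        model, out / "throat.stl", out / "profile.csv"
    )
    it_log.to_csv(out / "iterations.csv")
    final = it_log.rows[-1]
    report = {
        "throat": spec.to_config(),
        "target_head_mmHg": head,
        "flow_lpm": flow,
        "achieved_head_mmHg": reduced_flow.tubing_pressure_drop(model, flow),
        "n_trials": len(it_log.rows),
        "mesh_watertight": bool(mesh.is_watertight),
    }
    report["final_rel_err"] = abs(report["achieved_head_mmHg"] - head) / head
    _write_outputs(out, {"throat_size.json": report})
    click.echo(
        f"d = {spec.d:.3f} mm, L = {spec.L:.2f} mm, achieved "
        f"{report['achieved_head_mmHg']:.2f} mmHg "
        f"(rel err {report['final_rel_err']:.4%})"
    )


@main.command()
@click.option("--d", "d_mm", type=float, required=True,
              help="Throat thickness, mm.")
@click.option("--out", "out_dir", type=click.Path(), default="hemoloop_run",
              show_default=True)
def geometry(d_mm, out_dir) -> None:
    """Export STL + profile table for a given throat opening."""
    spec = throat_geometry.ThroatSpec.from_thickness(d_mm)
    model = throat_geometry.TubingModelSpec(throat=spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    throat_geometry.export_geometry(model, out / "throat.stl", out / "profile.csv")
    _write_outputs(out, {"geometry.json": model.to_config()})
    click.echo(f"d = {spec.d:.3f} mm, L = {spec.L:.2f} mm, "
               f"total length {model.total_length} mm")


@main.command()
@click.option("--kind", type=click.Choice(["uniform", "poiseuille", "pump-like"]),
              required=True)
@click.option("--tau", type=float, default=50.0, show_default=True)
@click.option("--volume", type=float, default=2e-5, show_default=True)
@click.option("--flow", type=float, default=5.0, show_default=True,
              help="L/min")
@click.option("--n-cells", type=int, default=1000, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", "out_dir", type=click.Path(), default="hemoloop_run",
              show_default=True)
def synth(kind, tau, volume, flow, n_cells, seed, out_dir) -> None:
    """Generate a synthetic field and write it in both dialects."""
    q = flow * reduced_flow.LPM_M3S
    if kind == "uniform":
        fld, _ = synthetic_data.generate_uniform_field(tau, volume, q, n_cells)
    elif kind == "poiseuille":
        fld, _ = synthetic_data.generate_poiseuille_field(
            radius=0.0047625, length=0.2265, Q=min(q, 1.0 * reduced_flow.LPM_M3S),
            n_radial=max(8, n_cells),
        )
    else:
        fld = synthetic_data.generate_pump_like_field(
            seed=seed, n_cells=n_cells, volume=volume, Q=q
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    field_engine.write_field_csv(fld, out / f"{kind}.csv")
    field_engine.write_field_vtu(fld, out / f"{kind}.vtu")
    _write_outputs(out, {
        "synth.json": {
            "kind": kind, "label": fld.label, "n_cells": fld.n_cells,
            "total_power_w": fld.total_power, "Q_m3_per_s": fld.Q,
        }
    })
    click.echo(f"wrote {kind}.csv and {kind}.vtu ({fld.n_cells} cells)")


@main.command()
@click.option("--out", "out_path", type=click.Path(), default="fixtures.csv",
              show_default=True)
def fixtures(out_path) -> None:
    """Write the eight shipped operating points as CSV."""
    synthetic_data.table1_frame().to_csv(out_path, index=False)
    click.echo(f"wrote {out_path}")
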