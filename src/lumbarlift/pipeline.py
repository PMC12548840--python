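"""End-to-end orchestration: simulate -> kinematics -> dynamics -> FE -> stats.

Each stage reads only the delimited-text/JSON artifacts of its upstream
stages from the output directory, so stages can be run separately (in
order) or all at once with identical results.  Every run writes a manifest
recording the configuration hash, package version and artifacts produced.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import __version__
from .config import PipelineConfig, load_literature
from .dynamics import (
    first_peak_torque,
    lumbar_torque_series,
    segment_phases,
)
from .errors import DependencyError
from .femodel import (
    assign_materials,
    build_geometry,
    build_load_case,
    mesh_geometry,
)
from .fesolver import assemble_system, peak_stress_by_part, solve_static
from .io import (
    read_grf,
    read_markers,
    read_torque,
    write_angles,
    write_grf,
    write_json,
    write_markers,
    write_phases,
    write_torque,
    write_vtk,
)
from .kinematics import flexion_series, range_of_motion
from .stressstats import (
    partition_disc,
    region_stats,
    region_table,
    risk_assessment,
    sensitivity_analysis,
    validation_report,
)
from .synthgen import generate_trial

STAGES = ("simulate", "kinematics", "dynamics", "fem", "stats", "risk", "validate", "sensitivity")

_STAGE_NEEDS = {
    "kinematics": "markers_{a}.tsv",
    "dynamics": "markers_{a}.tsv",
    "fem": "torque_{a}.tsv",
    "stats": "torque_{a}.tsv",
    "risk": "stress_{a}.json",
}


class _Trial:
    """Duck-typed trial reconstructed from on-disk artifacts."""

    def __init__(self, markers, grf, trunk):
        self.markers = markers
        self.grf = grf
        self.trunk = trunk


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    stages=None,
    actions=None,
) -> dict:
    """Execute the requested stages in order; returns the summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGES if s in (stages or STAGES)]
    actions = list(actions or config.actions)

    for stage in stages:
        needs = _STAGE_NEEDS.get(stage)
        if needs and stages.index(stage) == 0:
            for a in actions:
                if not (out / needs.format(a=a)).exists():
                    raise DependencyError(
                        f"stage {stage!r} needs {needs.format(a=a)}; run its upstream stage first"
                    )

    summary = _load_json(out / "summary.json") or {"actions": {}}
    for a in actions:
        summary["actions"].setdefault(a, {})

    if "simulate" in stages:
        for idx, a in enumerate(sorted(actions)):
            from dataclasses import replace

            template = replace(config.actions[a], seed=config.seed + idx)
            trial = generate_trial(
                template, trunk=config.trunk, marker_hz=config.marker_hz, force_hz=config.force_hz
            )
            write_markers(trial.markers, out / f"markers_{a}.tsv")
            write_grf(trial.grf, out / f"grf_{a}.tsv")
            summary["actions"][a]["n_frames"] = int(trial.n_frames)

    if "kinematics" in stages:
        for a in actions:
            markers = read_markers(out / f"markers_{a}.tsv")
            angles = flexion_series(markers, spec=config.kin_filter())
            write_angles(angles, out / f"angles_{a}.tsv")
            summary["actions"][a]["flexion_rom_deg"] = round(range_of_motion(angles), 3)

    if "dynamics" in stages:
        for a in actions:
            trial = _Trial(
                read_markers(out / f"markers_{a}.tsv"),
                read_grf(out / f"grf_{a}.tsv"),
                config.trunk,
            )
            torque = lumbar_torque_series(
                trial, config.trunk, config.kin_filter(), config.force_filter()
            )
            write_torque(torque, out / f"torque_{a}.tsv")
            seg = segment_phases(torque)
            write_phases(seg, torque, out / f"phases_{a}.json")
            p1, p2 = seg.peak_frames
            summary["actions"][a].update(
                first_peak_torque_Nm=round(float(torque.torque_Nm[p1]), 2),
                second_peak_torque_Nm=round(float(torque.torque_Nm[p2]), 2),
                n_phases=len(seg.PHASES),
                phase_bounds={k: list(v) for k, v in seg.intervals.items()},
            )

    mesh = None
    if {"fem", "stats", "sensitivity"} & set(stages):
        mesh = assign_materials(
            mesh_geometry(build_geometry(config.geometry)), config.materials
        )

    if "fem" in stages or "stats" in stages:
        if "fem" in stages:
            write_json(mesh.census(), out / "mesh_census.json")
        system = assemble_system(mesh)
        for a in actions:
            torque = read_torque(out / f"torque_{a}.tsv")
            case = build_load_case(mesh, a, torque, vertical_load_N=config.vertical_load_N)
            _, field, report = solve_static(system, case)
            if "fem" in stages:
                write_json(
                    {
                        "action": a,
                        "sagittal_moment_Nm": case.sagittal_moment_Nm,
                        "vertical_load_N": case.vertical_load_N,
                        "dof": report.dof,
                        "residual": report.residual_norm,
                        "part_peak_MPa": report.part_peak_MPa,
                    },
                    out / f"stress_{a}.json",
                )
                write_vtk(
                    mesh,
                    out / f"stress_{a}.vtk",
                    cell_data={"von_mises_MPa": field.von_mises},
                )
                summary["actions"][a]["part_peak_MPa"] = {
                    k: round(v, 3) for k, v in sorted(report.part_peak_MPa.items())
                }
            if "stats" in stages:
                grid = partition_disc(field, "L4-L5")
                stats = region_stats(grid, field, thresholds=config.thresholds)
                region_table(stats).to_csv(out / f"regions_L4-L5_{a}.csv")
                summary["actions"][a]["region_E_mean_MPa"] = round(stats["E"].mean_MPa, 4)
                summary["actions"][a]["region_table"] = {
                    lab: {
                        "mean_MPa": round(s.mean_MPa, 4),
                        "qd": round(s.quantitative_difference, 3),
                        "class": s.significance,
                    }
                    for lab, s in stats.items()
                }

    if "risk" in stages:
        for a in actions:
            peaks_all = _load_json(out / f"stress_{a}.json")["part_peak_MPa"]
            monitored = {
                "L5_cortical": peaks_all["L5_cortical"],
                "L5_cancellous": peaks_all["L5_cancellous"],
                "L4-L5_disc": max(
                    v for k, v in peaks_all.items()
                    if k.startswith("L4-L5") and ("annulus" in k or "nucleus" in k)
                ),
            }
            report = risk_assessment(monitored, config.thresholds)
            write_json(report, out / f"risk_{a}.json")
            summary["actions"][a]["risk"] = report

    if "validate" in stages:
        literature, reference_sim = load_literature()
        table = validation_report(reference_sim, literature)
        table.to_csv(out / "validation.csv")
        summary["validation"] = {
            k: {
                "relative_error_pct": float(table.loc[k, "relative_error_pct"]),
                "within_sd": bool(table.loc[k, "within_sd"]),
            }
            for k in table.index
        }

    if "sensitivity" in stages:
        torque_file = out / "torque_DL.tsv"
        moment = (
            first_peak_torque(read_torque(torque_file))
            if torque_file.exists()
            else config.actions["DL"].first_peak_torque_Nm
        )
        case = build_load_case(mesh, "DL", moment, vertical_load_N=config.vertical_load_N)
        results = sensitivity_analysis(mesh, case)
        payload = [
            {
                "parameter": r.parameter,
                "amplitude_pct": r.amplitude_pct,
                "change_rate_pct": [round(c, 3) for c in r.change_rate_pct],
                "level": r.level,
            }
            for r in results
        ]
        write_json(payload, out / "sensitivity.json")
        summary["sensitivity"] = payload

    manifest = {
        "config_hash": config.hash(),
        "version": __version__,
        "stages": stages,
        "actions": actions,
        "artifacts": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    write_json(manifest, out / "manifest.json")
    write_json(summary, out / "summary.json")
    return summary


def _load_json(path: Path):
    if Path(path).exists():
        return json.loads(Path(path).read_text())
    return None
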