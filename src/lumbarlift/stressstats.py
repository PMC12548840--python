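"""Regional disc statistics, injury thresholds, validation and sensitivity.

The transverse plane of a disc is tiled into a 3x3 grid of regions
labelled A..I (row-major, anterior row first, E central).  Each region's
element von Mises stresses are summarised by mean, SD and CV, and
contrasted against the central region E through a standardised mean
difference ("quantitative difference")

    QD(r) = |mean_r - mean_E| / sqrt((sd_r^2 + sd_E^2) / 2)

classified against the thresholds beta = 0.8 (significant) and
gamma = 1.27 (very significant).  Peak stresses are screened against
damage thresholds: 1000 MPa cortical bone, 3.0 MPa trabecular bone,
40 MPa intervertebral disc.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ParameterError, QueryError
from .femodel import LumbarMesh, LoadCase, assign_materials
from .fesolver import StressField, assemble_system, peak_stress_by_part, solve_static

REGION_LABELS = ("A", "B", "C", "D", "E", "F", "G", "H", "I")


@dataclass(frozen=True)
class ThresholdConfig:
    """Significance boundaries and damage thresholds."""

    beta: float = 0.8
    gamma: float = 1.27
    cortical_damage_MPa: float = 1000.0
    trabecular_fatigue_MPa: float = 3.0
    disc_tolerance_MPa: float = 40.0

    def __post_init__(self) -> None:
        if not 0 < self.beta < self.gamma:
            raise ParameterError("need 0 < beta < gamma")
        if min(self.cortical_damage_MPa, self.trabecular_fatigue_MPa, self.disc_tolerance_MPa) <= 0:
            raise ParameterError("damage thresholds must be positive")


@dataclass(frozen=True)
class RegionalGrid:
    """Nine disjoint element-index sets tiling a disc's transverse plane."""

    disc: str
    regions: dict  # label -> np.ndarray of element indices

    def __post_init__(self) -> None:
        seen = np.concatenate([self.regions[l] for l in REGION_LABELS])
        if len(np.unique(seen)) != len(seen):
            raise ParameterError("regions overlap")


@dataclass(frozen=True)
class RegionStats:
    """Summary of one region's element von Mises stresses."""

    label: str
    n_elements: int
    mean_MPa: float
    sd_MPa: float
    cv: float  # SD/mean; NaN when the mean is zero
    quantitative_difference: float
    significance: str  # not significant | significant | very significant


def partition_disc(field: StressField, disc: str) -> RegionalGrid:
    """3x3 tiling of a disc's elements by terciles of the two transverse axes.

    Rows (A,B,C / D,E,F / G,H,I) follow the sagittal coordinate with the
    anterior third as the top row; columns follow the coronal coordinate
    left to right.  Region E is central and contains the nucleus centroid.
    """
    mesh = field.mesh
    idx = np.concatenate(
        [
            mesh.elements_of_part(p)
            for p in mesh.part_names
            if p.startswith(f"{disc}_") and mesh.part_class[p] in
            ("nucleus", "annulus_inner", "annulus_middle", "annulus_outer")
        ]
        or [np.array([], dtype=int)]
    )
    if len(idx) == 0:
        raise QueryError(f"disc {disc!r} has no elements")
    cx = field.centroids[idx, 0]  # sagittal, anterior positive
    cy = field.centroids[idx, 1]  # coronal, left positive
    row = _tercile_bins(-cx)  # row 0 = anterior
    col = _tercile_bins(-cy)  # col 0 = viewer's left (+y)
    regions = {}
    for r in range(3):
        for c in range(3):
            lab = REGION_LABELS[3 * r + c]
            regions[lab] = idx[(row == r) & (col == c)]
    return RegionalGrid(disc=disc, regions=regions)


def _tercile_bins(v: np.ndarray) -> np.ndarray:
    q1, q2 = np.quantile(v, [1 / 3, 2 / 3])
    return np.digitize(v, [q1, q2], right=True)


def region_stats(
    grid: RegionalGrid,
    field: StressField,
    reference: str = "E",
    thresholds: ThresholdConfig | None = None,
) -> dict:
    """Per-region stats with the standardised contrast against ``reference``."""
    thresholds = thresholds or ThresholdConfig()
    vm = field.von_mises
    ref_vals = vm[grid.regions[reference]]
    ref_mean, ref_sd = float(ref_vals.mean()), float(ref_vals.std(ddof=1))
    out = {}
    for lab in REGION_LABELS:
        vals = vm[grid.regions[lab]]
        if len(vals) == 0:
            raise QueryError(f"region {lab} is empty")
        mean, sd = float(vals.mean()), float(vals.std(ddof=1))
        qd = quantitative_difference(mean, sd, ref_mean, ref_sd)
        out[lab] = RegionStats(
            label=lab,
            n_elements=int(len(vals)),
            mean_MPa=mean,
            sd_MPa=sd,
            cv=sd / mean if mean != 0 else float("nan"),
            quantitative_difference=qd,
            significance=classify_difference(qd, thresholds),
        )
    return out


def quantitative_difference(mean_r: float, sd_r: float, mean_ref: float, sd_ref: float) -> float:
    """Pooled-SD standardised mean difference; 0 when the means are equal."""
    if mean_r == mean_ref:
        return 0.0
    pooled = np.sqrt((sd_r**2 + sd_ref**2) / 2.0)
    return float(abs(mean_r - mean_ref) / pooled) if pooled > 0 else float("inf")


def classify_difference(qd: float, thresholds: ThresholdConfig | None = None) -> str:
    t = thresholds or ThresholdConfig()
    if qd >= t.gamma:
        return "very significant"
    if qd > t.beta:
        return "significant"
    return "not significant"


def region_table(stats: dict) -> pd.DataFrame:
    """Tabular report mirroring the regional-statistics layout."""
    rows = [
        {
            "region": s.label,
            "n_elements": s.n_elements,
            "mean_MPa": s.mean_MPa,
            "sd_MPa": s.sd_MPa,
            "cv": s.cv,
            "quantitative_difference": s.quantitative_difference,
            "significance": s.significance,
        }
        for s in stats.values()
    ]
    return pd.DataFrame(rows).set_index("region")


# ---------------------------------------------------------------------------
# risk assessment


_KIND_THRESHOLD = {
    "cortical": "cortical_damage_MPa",
    "trabecular": "trabecular_fatigue_MPa",
    "cancellous": "trabecular_fatigue_MPa",
    "disc": "disc_tolerance_MPa",
    "annulus": "disc_tolerance_MPa",
    "nucleus": "disc_tolerance_MPa",
}


def risk_assessment(peaks: dict, thresholds: ThresholdConfig | None = None) -> dict:
    """Exceedance of each monitored peak over its damage threshold.

    ``peaks`` maps part keys (containing 'cortical', 'cancellous'/
    'trabecular' or 'disc'/'annulus'/'nucleus') to peak von Mises MPa.
    Exceedance is (peak - threshold)/threshold * 100; the flag is strict.
    """
    thresholds = thresholds or ThresholdConfig()
    report = {}
    for key, peak in peaks.items():
        if peak < 0:
            raise ParameterError(f"negative peak stress for {key!r}")
        kind = next((k for k in _KIND_THRESHOLD if k in key.lower()), None)
        if kind is None:
            raise QueryError(f"cannot map part key {key!r} to a damage threshold")
        thr = getattr(thresholds, _KIND_THRESHOLD[kind])
        exce = (peak - thr) / thr * 100.0
        report[key] = {
            "peak_MPa": float(peak),
            "threshold_MPa": float(thr),
            "exceedance_pct": float(exce),
            "exceeded": bool(peak > thr),
        }
    return report


# ---------------------------------------------------------------------------
# literature validation


def validation_report(simulated: dict, literature: dict) -> pd.DataFrame:
    """Relative error of simulated values against literature mean +/- SD.

    ``literature`` maps the same keys to (mean, sd).  Relative error is
    |sim - mean|/mean * 100, reported to one decimal; ``within_sd`` flags
    values inside the literature dispersion band.
    """
    if set(simulated) != set(literature):
        raise ParameterError("simulated and literature key sets differ")
    rows = []
    for key in simulated:
        mean, sd = literature[key]
        if mean == 0:
            raise ParameterError(f"zero literature mean for {key!r}")
        sim = float(simulated[key])
        rows.append(
            {
                "indicator": key,
                "simulated": sim,
                "literature_mean": mean,
                "literature_sd": sd,
                "relative_error_pct": round(abs(sim - mean) / mean * 100.0, 1),
                "within_sd": bool(mean - sd <= sim <= mean + sd),
            }
        )
    return pd.DataFrame(rows).set_index("indicator")


# ---------------------------------------------------------------------------
# parameter sensitivity


@dataclass(frozen=True)
class SensitivityCase:
    """One perturbation study: a parameter and its fluctuation amplitude."""

    parameter: str  # cortical_modulus | nucleus_modulus | vertical_load | moment
    amplitude_pct: float
    change_rate_pct: tuple = ()
    level: str = ""

    def __post_init__(self) -> None:
        if self.amplitude_pct <= 0:
            raise ParameterError("fluctuation amplitude must be positive")


DEFAULT_SENSITIVITY_CASES = (
    SensitivityCase("cortical_modulus", 10.0),
    SensitivityCase("nucleus_modulus", 20.0),
    SensitivityCase("vertical_load", 5.0),
    SensitivityCase("moment", 5.0),
)

_LEVEL_BANDS = ((5.0, "high"), (3.0, "medium"), (0.0, "low"))

_PARAM_MATERIAL = {"cortical_modulus": "Cortical bone", "nucleus_modulus": "Nucleus pulposus"}


def sensitivity_level(max_abs_change_pct: float) -> str:
    for bound, name in _LEVEL_BANDS:
        if max_abs_change_pct >= bound:
            return name
    return "low"


def sensitivity_analysis(
    mesh: LumbarMesh,
    loadcase: LoadCase,
    cases=DEFAULT_SENSITIVITY_CASES,
    monitor: str = "L5_cortical",
) -> list:
    """Re-solve at both ends of each fluctuation and report change rates.

    The response is the relative change of the monitored part's peak von
    Mises stress; levels follow the bands >=5% high, 3-5% medium, <3% low.
    """
    table = list(mesh.materials.values())
    base_system = assemble_system(assign_materials(mesh, table))
    base_peak = peak_stress_by_part(_solve(base_system, loadcase), monitor)
    results = []
    for case in cases:
        rates = []
        for sign in (-1.0, 1.0):
            f = 1.0 + sign * case.amplitude_pct / 100.0
            system, pert_case = base_system, loadcase
            if case.parameter in _PARAM_MATERIAL:
                row = _PARAM_MATERIAL[case.parameter]
                pert_table = [
                    replace(m, elastic_modulus_MPa=m.elastic_modulus_MPa * f)
                    if m.name == row
                    else m
                    for m in table
                ]
                if any(m.elastic_modulus_MPa <= 0 for m in pert_table):
                    raise ParameterError("perturbation produced a non-positive modulus")
                system = assemble_system(assign_materials(mesh, pert_table))
            elif case.parameter == "vertical_load":
                pert_case = replace(loadcase, vertical_load_N=loadcase.vertical_load_N * f)
            elif case.parameter == "moment":
                pert_case = replace(loadcase, sagittal_moment_Nm=loadcase.sagittal_moment_Nm * f)
            else:
                raise ParameterError(f"unknown sensitivity parameter {case.parameter!r}")
            peak = peak_stress_by_part(_solve(system, pert_case), monitor)
            rates.append((peak - base_peak) / base_peak * 100.0)
        level = sensitivity_level(max(abs(r) for r in rates))
        results.append(replace(case, change_rate_pct=tuple(rates), level=level))
    # restore the unperturbed binding on the shared mesh
    assign_materials(mesh, table)
    return results


def _solve(system, loadcase: LoadCase) -> StressField:
    _, field, _ = solve_static(system, loadcase)
    return field
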