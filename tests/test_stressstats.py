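"""Regional grids, quantitative differences, risk, validation, sensitivity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lumbarlift.errors import ParameterError, QueryError
from lumbarlift.femodel import (
    LumbarMesh,
    MaterialSpec,
    build_load_case,
    composite_column_mesh,
)
from lumbarlift.fesolver import StressField, assemble_system, peak_stress_by_part, solve_static
from lumbarlift.stressstats import (
    REGION_LABELS,
    SensitivityCase,
    ThresholdConfig,
    classify_difference,
    partition_disc,
    quantitative_difference,
    region_stats,
    risk_assessment,
    sensitivity_analysis,
    sensitivity_level,
    validation_report,
)


def _synthetic_disc_field(n_per_region=4, values=None):
    """A fake one-part disc whose element centroids sit on a 3x3 grid."""
    n = 9 * n_per_region
    cx, cy = [], []
    for r, x in enumerate((10.0, 0.0, -10.0)):  # anterior -> posterior rows
        for c, y in enumerate((10.0, 0.0, -10.0)):  # left -> right columns
            for k in range(n_per_region):
                cx.append(x + 0.1 * k)
                cy.append(y + 0.1 * k)
    centroids = np.column_stack([cx, cy, np.zeros(n)])
    mesh = LumbarMesh(
        nodes=np.zeros((4, 3)),
        tets=np.zeros((n, 4), dtype=int),
        tet_part=np.zeros(n, dtype=int),
        part_names=["L4-L5_nucleus"],
        part_class={"L4-L5_nucleus": "nucleus"},
        lines=np.zeros((0, 2), dtype=int),
        line_part=np.zeros(0, dtype=int),
        ligament_area_mm2=1.0,
    )
    vm = np.asarray(values) if values is not None else np.ones(n)
    stress = np.zeros((n, 6))
    stress[:, 0] = vm
    return StressField(stress=stress, von_mises=vm, centroids=centroids, mesh=mesh)


class TestPartitionDisc:
    def test_uniform_grid_balanced_regions(self):
        field = _synthetic_disc_field(n_per_region=5)
        grid = partition_disc(field, "L4-L5")
        for lab in REGION_LABELS:
            assert len(grid.regions[lab]) == 5

    def test_regions_disjoint_and_complete(self, coarse_fields):
        field = coarse_fields["TBDL"]
        grid = partition_disc(field, "L4-L5")
        allidx = np.concatenate([grid.regions[l] for l in REGION_LABELS])
        assert len(np.unique(allidx)) == len(allidx)
        mesh = field.mesh
        disc_elems = np.concatenate(
            [
                mesh.elements_of_part(p)
                for p in mesh.part_names
                if p.startswith("L4-L5_") and "endplate" not in p
            ]
        )
        assert set(allidx) == set(disc_elems)
        for lab in REGION_LABELS:
            assert len(grid.regions[lab]) > 0

    def test_nucleus_centroid_in_central_region(self, coarse_fields):
        field = coarse_fields["TBDL"]
        grid = partition_disc(field, "L4-L5")
        mesh = field.mesh
        nucleus = mesh.elements_of_part("L4-L5_nucleus")
        nucleus_centroid = field.centroids[nucleus].mean(axis=0)
        # element nearest the nucleus centroid must be binned into E
        d = np.linalg.norm(field.centroids[nucleus] - nucleus_centroid, axis=1)
        assert nucleus[np.argmin(d)] in grid.regions["E"]

    def test_missing_disc_raises(self, coarse_fields):
        with pytest.raises(QueryError):
            partition_disc(coarse_fields["DL"], "L7-L8")


class TestRegionStats:
    def test_reference_region_has_zero_difference(self):
        field = _synthetic_disc_field(values=np.arange(36, dtype=float))
        grid = partition_disc(field, "L4-L5")
        stats = region_stats(grid, field)
        assert stats["E"].quantitative_difference == 0.0
        assert stats["E"].significance == "not significant"

    def test_identical_regions_zero_difference(self):
        field = _synthetic_disc_field(values=np.tile([1.0, 2.0, 3.0, 4.0], 9))
        grid = partition_disc(field, "L4-L5")
        stats = region_stats(grid, field)
        assert all(s.quantitative_difference == 0.0 for s in stats.values())

    def test_cv_is_sd_over_mean(self):
        field = _synthetic_disc_field(values=np.tile([1.0, 3.0, 1.0, 3.0], 9))
        grid = partition_disc(field, "L4-L5")
        s = region_stats(grid, field)["A"]
        assert s.cv == pytest.approx(s.sd_MPa / s.mean_MPa)

    def test_central_region_softest_on_solved_disc(self, coarse_fields):
        # the nucleus-dominated centre carries less stress than the annulus
        # periphery in every action
        for field in coarse_fields.values():
            grid = partition_disc(field, "L4-L5")
            stats = region_stats(grid, field)
            for lab in REGION_LABELS:
                if lab != "E":
                    assert stats["E"].mean_MPa < stats[lab].mean_MPa


class TestQuantitativeDifference:
    def test_symmetry(self):
        assert quantitative_difference(1.0, 0.3, 2.0, 0.4) == pytest.approx(
            quantitative_difference(2.0, 0.4, 1.0, 0.3)
        )

    def test_zero_iff_means_equal(self):
        assert quantitative_difference(1.5, 0.2, 1.5, 0.9) == 0.0
        assert quantitative_difference(1.5, 0.2, 1.6, 0.2) > 0.0

    def test_classification_bands(self):
        t = ThresholdConfig()
        assert classify_difference(0.5, t) == "not significant"
        assert classify_difference(0.8, t) == "not significant"  # boundary: <= beta
        assert classify_difference(1.22, t) == "significant"
        assert classify_difference(1.27, t) == "very significant"
        assert classify_difference(3.5, t) == "very significant"

    @given(qd1=st.floats(0, 5), qd2=st.floats(0, 5))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_classification_monotone(self, qd1, qd2):
        order = ["not significant", "significant", "very significant"]
        if qd1 <= qd2:
            assert order.index(classify_difference(qd1)) <= order.index(
                classify_difference(qd2)
            )

    def test_invalid_thresholds(self):
        with pytest.raises(ParameterError):
            ThresholdConfig(beta=1.5, gamma=1.27)


class TestRiskAssessment:
    def test_disc_exceedance_fourteen_percent(self):
        out = risk_assessment({"L4-L5_disc": 45.6})
        assert out["L4-L5_disc"]["exceedance_pct"] == pytest.approx(14.0)
        assert out["L4-L5_disc"]["exceeded"]

    def test_cortical_just_below_threshold(self):
        out = risk_assessment({"L5_cortical": 997.0})
        assert out["L5_cortical"]["exceedance_pct"] == pytest.approx(-0.3)
        assert not out["L5_cortical"]["exceeded"]

    def test_peak_equal_to_threshold_not_exceeded(self):
        out = risk_assessment({"L5_cancellous": 3.0})
        assert out["L5_cancellous"]["exceedance_pct"] == 0.0
        assert not out["L5_cancellous"]["exceeded"]

    def test_zero_stress_is_minus_hundred_percent(self):
        assert risk_assessment({"L5_cortical": 0.0})["L5_cortical"][
            "exceedance_pct"
        ] == pytest.approx(-100.0)

    def test_exceedance_strictly_increasing(self):
        lo = risk_assessment({"L4-L5_disc": 30.0})["L4-L5_disc"]["exceedance_pct"]
        hi = risk_assessment({"L4-L5_disc": 50.0})["L4-L5_disc"]["exceedance_pct"]
        assert lo < hi

    def test_unknown_part_key_raises(self):
        with pytest.raises(QueryError):
            risk_assessment({"mystery_part": 10.0})

    def test_negative_peak_raises(self):
        with pytest.raises(ParameterError):
            risk_assessment({"L5_cortical": -1.0})


class TestValidationReport:
    LIT = {
        "L5_cortical_peak_MPa": (820.0, 30.0),
        "L4_L5_disc_peak_MPa": (37.5, 2.0),
        "L5_trabecular_peak_MPa": (2.5, 0.3),
        "compression_stiffness_N_mm": (1230.0, 50.0),
    }
    SIM = {
        "L5_cortical_peak_MPa": 815.0,
        "L4_L5_disc_peak_MPa": 36.9,
        "L5_trabecular_peak_MPa": 2.6,
        "compression_stiffness_N_mm": 1250.0,
    }

    def test_reference_relative_errors(self):
        table = validation_report(self.SIM, self.LIT)
        assert table.loc["L5_cortical_peak_MPa", "relative_error_pct"] == 0.6
        assert table.loc["L4_L5_disc_peak_MPa", "relative_error_pct"] == 1.6
        assert table.loc["L5_trabecular_peak_MPa", "relative_error_pct"] == 4.0
        assert table.loc["compression_stiffness_N_mm", "relative_error_pct"] == 1.6
        assert table["within_sd"].all()

    def test_exact_agreement_is_zero(self):
        table = validation_report({"a": 10.0}, {"a": (10.0, 1.0)})
        assert table.loc["a", "relative_error_pct"] == 0.0

    def test_zero_literature_mean_raises(self):
        with pytest.raises(ParameterError):
            validation_report({"a": 1.0}, {"a": (0.0, 1.0)})

    def test_key_mismatch_raises(self):
        with pytest.raises(ParameterError):
            validation_report({"a": 1.0}, {"b": (1.0, 0.1)})


class TestSensitivity:
    def test_level_bands(self):
        assert sensitivity_level(8.2) == "high"
        assert sensitivity_level(4.7) == "medium"
        assert sensitivity_level(2.3) == "low"

    def test_pure_vertical_load_change_is_exact_linearity(self, tiny_mesh):
        case = build_load_case(tiny_mesh, "DL", 0.0)  # zero moment
        results = sensitivity_analysis(
            tiny_mesh, case, cases=(SensitivityCase("vertical_load", 5.0),)
        )
        lo, hi = results[0].change_rate_pct
        assert lo == pytest.approx(-5.0, abs=1e-6)
        assert hi == pytest.approx(5.0, abs=1e-6)

    def test_modulus_change_bounded_by_perturbation_on_composite(self):
        # parallel composite under fixed load: stress change from a +10%
        # core-modulus change follows the closed-form share and is < +10%
        mesh = composite_column_mesh(platen=True)
        mesh.part_class = {
            "core": "Cortical bone",
            "shell": "Cancellous bone",
            "platen": "Platen",
        }
        table = [
            MaterialSpec("Cortical bone", 400.0, 0.0),
            MaterialSpec("Cancellous bone", 100.0, 0.0),
            MaterialSpec("Platen", 1e6, 0.0),
        ]
        from lumbarlift.femodel import assign_materials

        assign_materials(mesh, table)
        case = build_load_case(mesh, "DL", 0.0, vertical_load_N=1000.0)
        results = sensitivity_analysis(
            mesh, case, cases=(SensitivityCase("cortical_modulus", 10.0),), monitor="core"
        )
        lo, hi = results[0].change_rate_pct
        A = {p: mesh.part_volume(p) / 20.0 for p in ("core", "shell")}
        EA = 400.0 * A["core"] + 100.0 * A["shell"]

        # sigma_core(E') = F E' / (E' A1 + E2 A2); change vs base share
        def change(f):
            e = f * 400.0
            return (e / (e * A["core"] + 100.0 * A["shell"])) / (
                400.0 / EA
            ) * 100.0 - 100.0

        assert hi == pytest.approx(change(1.1), abs=0.15)
        assert lo == pytest.approx(change(0.9), abs=0.15)
        assert 0 < hi < 10.0
        assert -10.0 < lo < 0

    def test_nucleus_less_sensitive_than_cortical(self, tiny_mesh):
        case = build_load_case(tiny_mesh, "DL", 749.0)
        results = sensitivity_analysis(
            tiny_mesh,
            case,
            cases=(
                SensitivityCase("cortical_modulus", 10.0),
                SensitivityCase("nucleus_modulus", 20.0),
            ),
        )
        by_name = {r.parameter: max(abs(c) for c in r.change_rate_pct) for r in results}
        assert by_name["nucleus_modulus"] < by_name["cortical_modulus"]

    def test_invalid_parameter_raises(self, tiny_mesh):
        case = build_load_case(tiny_mesh, "DL", 100.0)
        with pytest.raises(ParameterError):
            sensitivity_analysis(
                tiny_mesh, case, cases=(SensitivityCase("shoe_size", 5.0),)
            )
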