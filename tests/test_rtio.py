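"""DICOM-RT round trips, rasterization, plan formats, case bundles."""

import numpy as np
import pydicom
import pytest

from cyberbeam.beams import Beam, Plan
from cyberbeam.grid import StructureRole, StructureSet, VolumeGrid
from cyberbeam.rtio import (
    CaseBundle,
    export_dicom,
    harmonize_bundle,
    load_case_bundle,
    rasterize_polygon,
    read_ckplan,
    read_ct_series,
    read_dose,
    read_plan,
    read_structures,
    save_case_bundle,
    write_ckplan,
    write_ct_series,
    write_dose,
    write_plan,
    write_structures,
)


def _hu_grid(shape=(12, 10, 16), spacing=(1.0, 1.0, 2.0)):
    rng = np.random.default_rng(0)
    vals = np.round(rng.uniform(-1000, 700, shape)).astype(np.float32)
    origin = (-100.0, -100.0, -50.0)
    return VolumeGrid(vals, origin, spacing)


class TestCTSeries:
    def test_round_trip_identity(self, tmp_path):
        grid = _hu_grid()
        write_ct_series(grid, tmp_path)
        back = read_ct_series(tmp_path)
        assert back.same_geometry(grid)
        assert np.array_equal(back.values, grid.values)
        assert np.allclose(back.indices_to_world(np.zeros(3)), (-100, -100, -50))

    def test_missing_slice_is_hard_error(self, tmp_path):
        grid = _hu_grid()
        write_ct_series(grid, tmp_path)
        (tmp_path / "ct_0007.dcm").unlink()
        with pytest.raises(ValueError, match="spacing|gap"):
            read_ct_series(tmp_path)

    def test_duplicate_slice_is_hard_error(self, tmp_path):
        grid = _hu_grid()
        write_ct_series(grid, tmp_path)
        import shutil

        shutil.copy(tmp_path / "ct_0003.dcm", tmp_path / "ct_0003b.dcm")
        with pytest.raises(ValueError, match="duplicate"):
            read_ct_series(tmp_path)

    def test_mixed_series_is_hard_error(self, tmp_path):
        grid = _hu_grid(shape=(8, 8, 4))
        write_ct_series(grid, tmp_path)
        other = VolumeGrid(grid.values, np.array(grid.origin) + [0, 0, 100],
                           grid.spacing, grid.axes)
        write_ct_series(other, tmp_path / "other")
        for f in (tmp_path / "other").iterdir():
            f.rename(tmp_path / f"x_{f.name}")
        (tmp_path / "other").rmdir()
        with pytest.raises(ValueError, match="mixed"):
            read_ct_series(tmp_path)


class TestRasterization:
    def test_square_contour_voxel_count(self):
        # 10 mm square on a 1 mm grid, corners between voxel centers
        poly = np.array([[-0.5, -0.5], [9.5, -0.5], [9.5, 9.5], [-0.5, 9.5]])
        mask = rasterize_polygon(poly, (20, 20))
        assert mask.sum() == 100

    def test_circle_area_convergence(self, tmp_path):
        # rasterized circle area approaches pi r^2; error shrinks with spacing
        r = 20.0
        errors = []
        for spacing in (2.0, 1.0, 0.5):
            n = int(120 / spacing)
            grid = VolumeGrid(np.zeros((n, n, 1)), origin=(-60, -60, 0),
                              spacing=(spacing, spacing, 1.0))
            theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
            world = np.column_stack([r * np.cos(theta), r * np.sin(theta), np.zeros_like(theta)])
            poly_idx = grid.world_to_indices(world)[:, :2]
            mask = rasterize_polygon(poly_idx, (n, n))
            area = mask.sum() * spacing**2
            errors.append(abs(area - np.pi * r**2) / (np.pi * r**2))
        assert errors[1] < 0.02
        assert errors[0] > errors[1] > errors[2]

    def test_structure_round_trip(self, tmp_path):
        grid = VolumeGrid(np.zeros((40, 40, 12), dtype=np.float32),
                          origin=(-39, -39, -11), spacing=(2, 2, 2))
        centers = grid.voxel_centers()
        sphere = np.linalg.norm(centers, axis=-1) <= 16.0
        ss = StructureSet(grid=grid)
        ss.add("PTV", sphere, StructureRole.TARGET_PTV)
        write_structures(ss, tmp_path / "rs.dcm")
        back = read_structures(tmp_path / "rs.dcm", grid)
        assert "PTV" in back
        assert back.roles["PTV"] == StructureRole.TARGET_PTV
        a, b = sphere, back.masks["PTV"]
        dice = 2 * (a & b).sum() / (a.sum() + b.sum())
        assert dice >= 0.97

    def test_empty_rtstruct(self, tmp_path):
        grid = _hu_grid(shape=(8, 8, 4))
        ss = StructureSet(grid=grid)
        write_structures(ss, tmp_path / "rs.dcm")
        back = read_structures(tmp_path / "rs.dcm", grid)
        assert len(back.masks) == 0

    def test_roi_without_contours_warns_empty(self, tmp_path):
        grid = _hu_grid(shape=(8, 8, 4))
        ss = StructureSet(grid=grid)
        ss.add("NoContours", np.zeros(grid.shape, bool), StructureRole.OAR)
        write_structures(ss, tmp_path / "rs.dcm")
        with pytest.warns(UserWarning, match="NoContours"):
            back = read_structures(tmp_path / "rs.dcm", grid)
        assert not back.masks["NoContours"].any()


class TestDose:
    def test_uniform_round_trip(self, tmp_path):
        dose = VolumeGrid(np.full((10, 10, 8), 10.0), (0, 0, 0), (2, 2, 2))
        write_dose(dose, tmp_path / "d.dcm")
        back = read_dose(tmp_path / "d.dcm")
        assert back.same_geometry(dose)
        assert np.abs(back.values - 10.0).max() < 0.001

    def test_zero_volume_exact(self, tmp_path):
        dose = VolumeGrid(np.zeros((6, 6, 6)), (0, 0, 0), (1, 1, 1))
        write_dose(dose, tmp_path / "d.dcm")
        assert np.array_equal(read_dose(tmp_path / "d.dcm").values, dose.values)

    def test_random_volume_relative_error(self, tmp_path):
        rng = np.random.default_rng(1)
        dose = VolumeGrid(rng.uniform(0, 60, (12, 10, 8)), (0, 0, 0), (2, 2, 2))
        write_dose(dose, tmp_path / "d.dcm")
        back = read_dose(tmp_path / "d.dcm")
        assert np.abs(back.values - dose.values).max() / 60.0 < 1e-4

    def test_negative_dose_rejected(self, tmp_path):
        dose = VolumeGrid(np.full((4, 4, 4), -1.0), (0, 0, 0), (1, 1, 1))
        with pytest.raises(ValueError, match="negative"):
            write_dose(dose, tmp_path / "d.dcm")


def _plan(n=3):
    rng = np.random.default_rng(2)
    beams = []
    for i in range(n):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        beams.append(Beam(source=800 * d, aim=rng.uniform(-10, 10, 3),
                          cone=float(rng.choice([20, 30, 40])),
                          mu=float(rng.integers(0, 400))))
    beams[0].mu = 100.0
    return Plan(beams, prescription_dose=24.0, fractions=3)


class TestPlans:
    def test_ckplan_round_trip(self, tmp_path):
        plan = _plan()
        write_ckplan(plan, tmp_path / "p.ckplan")
        back = read_ckplan(tmp_path / "p.ckplan")
        assert back.n_beams == plan.n_beams
        assert back.prescription_dose == plan.prescription_dose
        assert back.fractions == plan.fractions
        for a, b in zip(plan.beams, back.beams):
            assert np.allclose(a.source, b.source, atol=1e-3)
            assert np.allclose(a.aim, b.aim, atol=1e-3)
            assert (a.cone, a.mu) == (b.cone, b.mu)

    def test_rtplan_round_trip(self, tmp_path):
        plan = _plan()
        write_plan(plan, tmp_path / "p.dcm")
        back = read_plan(tmp_path / "p.dcm")
        assert back.n_beams == plan.n_beams
        assert back.prescription_dose == plan.prescription_dose
        for a, b in zip(plan.beams, back.beams):
            assert np.allclose(a.source, b.source, atol=1e-4)
            assert np.allclose(a.aim, b.aim, atol=1e-4)
            assert (a.cone, a.mu, a.l_source) == (b.cone, b.mu, b.l_source)

    def test_zero_mu_beams_retained_but_flagged(self, tmp_path):
        beams = [Beam(source=(0, 0, 800), aim=(0, 0, 0), cone=20, mu=m)
                 for m in (100, 0, 50)]
        plan = Plan(beams, prescription_dose=24)
        write_ckplan(plan, tmp_path / "p.ckplan")
        back = read_ckplan(tmp_path / "p.ckplan")
        assert back.n_beams == 3
        assert len(back.deliverable_beams) == 2

    def test_missing_cone_is_hard_error(self, tmp_path):
        plan = _plan()
        write_plan(plan, tmp_path / "p.dcm")
        ds = pydicom.dcmread(tmp_path / "p.dcm")
        del ds.BeamSequence[1].ApplicatorSequence
        ds.save_as(tmp_path / "broken.dcm", enforce_file_format=True)
        with pytest.raises(ValueError, match="beam index 1.*cone"):
            read_plan(tmp_path / "broken.dcm")

    def test_typical_cyberknife_scale(self, tmp_path):
        plan = _plan(120)
        write_ckplan(plan, tmp_path / "p.ckplan")
        assert read_ckplan(tmp_path / "p.ckplan").n_beams == 120


class TestCaseBundle:
    def test_bundle_round_trip(self, phantom_case, tmp_path):
        bundle = phantom_case["bundle"]
        save_case_bundle(bundle, tmp_path / "case", beam_matrix=phantom_case["beam"])
        back, beam = load_case_bundle(tmp_path / "case")
        assert back.ct.same_geometry(bundle.ct)
        assert np.array_equal(back.ct.values, bundle.ct.values)
        assert np.allclose(back.dose.values, bundle.dose.values)
        assert np.allclose(beam.values, phantom_case["beam"].values)
        assert set(back.structures.masks) == set(bundle.structures.masks)
        assert back.plan.n_beams == bundle.plan.n_beams

    def test_dose_must_be_coregistered_and_nonnegative(self, phantom_case):
        bundle = phantom_case["bundle"]
        bad = VolumeGrid(np.zeros((4, 4, 4)), (0, 0, 0), (1, 1, 1))
        with pytest.raises(ValueError):
            CaseBundle(ct=bundle.ct, structures=bundle.structures, dose=bad)
        with pytest.raises(ValueError, match="nonnegative"):
            CaseBundle(ct=bundle.ct, structures=bundle.structures,
                       dose=bundle.ct.with_values(np.full(bundle.ct.shape, -1.0)))

    def test_dicom_export_is_readable(self, phantom_case, tmp_path):
        bundle = phantom_case["bundle"]
        export_dicom(bundle, tmp_path / "dicom")
        ct = read_ct_series(tmp_path / "dicom" / "ct")
        assert ct.same_geometry(bundle.ct)
        ss = read_structures(tmp_path / "dicom" / "rtstruct.dcm", ct)
        assert "PTV" in ss
        dose = read_dose(tmp_path / "dicom" / "rtdose.dcm")
        assert np.allclose(dose.values, bundle.dose.values, atol=1e-3)
        plan = read_plan(tmp_path / "dicom" / "rtplan.dcm")
        assert plan.n_beams == bundle.plan.n_beams

    def test_frame_of_reference_mismatch(self, tmp_path):
        grid = _hu_grid(shape=(8, 8, 4))
        ss = StructureSet(grid=grid)
        write_structures(ss, tmp_path / "rs.dcm")
        grid.frame_of_reference = "1.2.3.4"
        with pytest.raises(ValueError, match="frame"):
            read_structures(tmp_path / "rs.dcm", grid)


class TestHarmonize:
    def test_resamples_everything_to_ct(self):
        ct = _hu_grid(shape=(16, 16, 8), spacing=(2, 2, 2))
        coarse = VolumeGrid(np.zeros((8, 8, 4)), ct.origin, (4, 4, 4), ct.axes)
        mask = np.zeros(coarse.shape, bool)
        mask[2:6, 2:6, 1:3] = True
        ss = StructureSet(grid=coarse)
        ss.add("PTV", mask, StructureRole.TARGET_PTV)
        dose = coarse.with_values(np.full(coarse.shape, 5.0))
        bundle = harmonize_bundle(ct, ss, dose=dose)
        assert bundle.structures.grid.same_geometry(ct)
        assert bundle.dose.same_geometry(ct)
        assert bundle.structures.masks["PTV"].any()

    def test_inplane_padding(self):
        ct = _hu_grid(shape=(16, 16, 8), spacing=(2, 2, 2))
        ss = StructureSet(grid=ct)
        ss.add("PTV", np.ones(ct.shape, bool), StructureRole.TARGET_PTV)
        bundle = harmonize_bundle(ct, ss, inplane=24)
        assert bundle.ct.shape == (24, 24, 8)
        # original volume sits centered; padding is background HU
        assert bundle.ct.values[0, 0, 0] == -1000.0
        assert bundle.structures.masks["PTV"].sum() == 16 * 16 * 8
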