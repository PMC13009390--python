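"""Synthetic generator: determinism, geometry, truth fidelity, cohorts."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from gplkit.mesh_io import MISSING
from gplkit.method_a import run_method_a
from gplkit.synthetic_data import (
    DEFECT_CLASSES,
    MandibleParams,
    SyntheticCaseParams,
    generate_case,
    generate_cohort,
    generate_mandible,
    measure_case,
)
from gplkit.transforms import RTMComponents, decompose


class TestGenerateMandible:
    def test_deterministic_and_watertight(self):
        m1 = generate_mandible()
        m2 = generate_mandible()
        assert np.array_equal(m1.vertices, m2.vertices)
        assert np.array_equal(m1.faces, m2.faces)
        tm = m1.to_trimesh()
        assert tm.is_watertight
        assert 500 < len(m1.vertices) < 5000

    def test_width_doubling_doubles_transverse_distance(self):
        """The A-A'-analog (condyle-to-condyle) distance scales with width."""
        from gplkit.synthetic_data import _build_arch, _true_landmarks

        def aa_dist(width):
            params = MandibleParams(width=width, asymmetry=0.0)
            verts, faces, u, v = _build_arch(params)
            lm = _true_landmarks(verts, u, v, "m")
            return float(np.linalg.norm(lm.get("A") - lm.get("A'")))

        ratio = aa_dist(200.0) / aa_dist(100.0)
        assert ratio == pytest.approx(2.0, rel=0.02)

    def test_symmetric_params_give_mirror_symmetry(self):
        mesh = generate_mandible(MandibleParams(asymmetry=0.0))
        mirrored = mesh.vertices * np.array([-1.0, 1.0, 1.0])
        d, _ = cKDTree(mesh.vertices).query(mirrored)
        assert d.max() < 1e-9

    def test_degenerate_params_rejected(self):
        with pytest.raises(ValueError):
            generate_mandible(MandibleParams(width=-1.0))
        with pytest.raises(ValueError):
            generate_mandible(MandibleParams(n_u=4))


class TestGenerateCase:
    def test_bitwise_reproducibility(self):
        p = SyntheticCaseParams(seed=9, true_components=RTMComponents(1, 1, -1, 0.5, -0.5, 0.5))
        c1, c2 = generate_case(p), generate_case(p)
        assert np.array_equal(
            c1.gpl_case.postop_prosthesis.vertices, c2.gpl_case.postop_prosthesis.vertices
        )
        assert np.array_equal(
            c1.gpl_case.postop_mandible.vertices, c2.gpl_case.postop_mandible.vertices
        )
        for op in c1.seeds:
            for occ in (1, 2):
                assert np.array_equal(
                    c1.seeds[op][occ].source_points, c2.seeds[op][occ].source_points
                )
                for s1, s2 in zip(c1.vsp_sessions[op][occ], c2.vsp_sessions[op][occ]):
                    for label in s1.points:
                        assert np.array_equal(s1.points[label], s2.points[label])

    def test_truth_fidelity_of_applied_displacement(self):
        """Stored components equal the decomposition of the transform that
        was actually applied to the prosthesis (in the GPL frame)."""
        from gplkit.gpl import establish_gpl_rs
        from gplkit.transforms import compose, invert

        truth = RTMComponents(0.9, -1.2, 0.4, 0.3, -0.6, 0.2)
        case = generate_case(
            SyntheticCaseParams(seed=10, true_components=truth, segmentation_noise_sd=0.0)
        )
        rtm1 = establish_gpl_rs(case.gpl_case.reference_mandible)
        in_rs = compose(rtm1, compose(case.world_displacement, invert(rtm1)))
        back = decompose(in_rs)
        assert np.abs(back.as_array() - truth.as_array()).max() < 1e-9
        # and the postoperative prosthesis really is the displaced design
        expected = case.world_displacement
        designed = case.gpl_case.designed_prosthesis
        from gplkit.transforms import apply_transform

        assert np.allclose(
            case.gpl_case.postop_prosthesis.vertices,
            apply_transform(expected, designed).vertices,
        )

    def test_defect_spanning_landmark_marks_it_missing(self):
        # a resection reaching the coronoid/angle region makes the landmarks
        # inside the span unpickable even when the anatomy flag allows C/E
        p = SyntheticCaseParams(seed=11, defect_span=(0.06, 0.30), can_pick_ce=True)
        case = generate_case(p)
        assert "E" in case.unpickable
        assert "F" in case.unpickable
        assert "E'" not in case.unpickable
        assert "F'" not in case.unpickable

    def test_zero_truth_zero_noise_recovers_exactly(self):
        from gplkit.gpl import run_gpl

        case = generate_case(SyntheticCaseParams(seed=12, segmentation_noise_sd=0.0))
        result = run_gpl(case.gpl_case)
        assert np.abs(result.components.as_array()).max() < 1e-6


class TestCohort:
    def test_cohort_determinism_and_shape(self):
        cases1, rec1 = generate_cohort(3, seed=42, methods=("a",))
        cases2, rec2 = generate_cohort(3, seed=42, methods=("a",))
        assert len(cases1) == 3
        assert [c.params.seed for c in cases1] == [c.params.seed for c in cases2]
        assert [(r.patient_id, r.metric, r.value) for r in rec1] == [
            (r.patient_id, r.metric, r.value) for r in rec2
        ]

    def test_measurement_table_design(self):
        """3 operators x 2 occasions x n patients rows for each metric."""
        _, records = generate_cohort(3, seed=1, methods=("a",))
        by_metric = {}
        for r in records:
            by_metric.setdefault(r.metric, []).append(r)
        for metric, rows in by_metric.items():
            assert len(rows) == 3 * 3 * 2
        dd = [r.value for r in by_metric["D-D' accuracy"]]
        assert all(v is MISSING for v in dd)

    def test_zero_operator_noise_gives_zero_interoperator_spread(self):
        from gplkit.synthetic_data import OperatorProfile

        profiles = {o: OperatorProfile((0, 0, 0), 0.0, 0.0) for o in ("O1", "O2", "O3")}
        template = SyntheticCaseParams(operator_profiles=profiles)
        _, records = generate_cohort(2, params_template=template, seed=2, methods=("a",))
        values = {}
        for r in records:
            if r.value is not MISSING:
                values.setdefault((r.patient_id, r.metric, r.occasion), set()).add(r.value)
        for key, vals in values.items():
            assert len(vals) == 1, f"operator spread at {key}"

    def test_known_operator_bias_recovered_by_lmem(self):
        """+0.3 mm picking bias for O3 appears in the O1-vs-O3 contrast."""
        from gplkit.stats import LMEMSpec, fit_lmem, pairwise_contrasts
        from gplkit.synthetic_data import OperatorProfile

        profiles = {
            "O1": OperatorProfile((0.0, 0.0, 0.0), 0.05, 0.1, 0.0),
            "O2": OperatorProfile((0.0, 0.0, 0.0), 0.05, 0.1, 0.0),
            "O3": OperatorProfile((0.0, 0.0, 0.0), 0.05, 0.1, 0.3),
        }
        template = SyntheticCaseParams(operator_profiles=profiles)
        _, records = generate_cohort(8, params_template=template, seed=3, methods=("a",))
        fitted = fit_lmem(records, LMEMSpec("B-B' accuracy"))
        inter = pairwise_contrasts(fitted)["inter_operator"]
        o1_vs_o3 = [e for e in inter if e["contrast"] == "O1 vs. O3"]
        assert o1_vs_o3
        # O3 reads every postoperative B-B' distance 0.3 mm wider, so the
        # O1 - O3 accuracy contrast should recover about -0.3 mm
        for entry in o1_vs_o3:
            assert entry["estimate"] == pytest.approx(-0.3, abs=0.1)


class TestMeasureCase:
    def test_gpl_rows_identical_across_operators(self):
        case = generate_case(
            SyntheticCaseParams(seed=13, true_components=RTMComponents(1, 0.5, -0.7, 0.3, 0.2, -0.4))
        )
        records = measure_case(case, methods=("gpl",))
        by_metric = {}
        for r in records:
            by_metric.setdefault(r.metric, set()).add(r.value)
        assert len(by_metric) == 6
        for metric, vals in by_metric.items():
            assert len(vals) == 1
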