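"""Base-pair-step parameters, groove widths and the B/A/LirA classifier."""

import math

import numpy as np
import pytest

from triplexkit import builder as bd
from triplexkit import conformation as cf
from triplexkit import helical as hx
from triplexkit import oligo as og
from triplexkit.structure import StructureAssembler


def _reverse_duplex(structure):
    """Relabel a duplex read 3'→5': the pyrimidine strand becomes strand I."""
    w_res = structure.residues_of("W")
    c_res = structure.residues_of("C")
    asm = StructureAssembler()
    for r in c_res:
        atoms = {n: structure.coords[row] for n, row in r.atom_rows.items()}
        asm.add_residue("W", r.index, r.base, r.chemistry, r.protonated, atoms)
    for r in w_res:
        atoms = {n: structure.coords[row] for n, row in r.atom_rows.items()}
        asm.add_residue("C", r.index, r.base, r.chemistry, r.protonated, atoms)
    return asm.build()


class TestBaseFrames:
    def test_frame_equivariance_under_rigid_motion(self, b_duplex, random_rigid_motion):
        R, t = random_rigid_motion
        moved = b_duplex.transformed(R, t)
        f = hx.base_reference_frame(b_duplex, "W", 7)
        g = hx.base_reference_frame(moved, "W", 7)
        assert np.allclose(g.origin, R @ f.origin + t, atol=1e-9)
        assert np.allclose(g.rotation, R @ f.rotation, atol=1e-9)

    def test_wc_paired_bases_have_antialigned_normals(self, b_duplex):
        fw = hx.base_reference_frame(b_duplex, "W", 7)
        fc = hx.base_reference_frame(b_duplex, "C", 19 + 1 - 7)
        assert float(np.dot(fw.z, fc.z)) < 0

    def test_frame_is_right_handed_orthonormal(self, b_duplex):
        f = hx.base_reference_frame(b_duplex, "W", 3)
        assert np.allclose(f.rotation @ f.rotation.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(f.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_missing_ring_atoms_raise(self, b_duplex):
        import copy

        s = bd.build_duplex(og.duplex_from_notations("gag", "ctc"))
        res = s.residue("W", 2)
        for name in list(res.atom_rows):
            if name not in ("P", "C1'", "O4'"):
                del res.atom_rows[name]
        with pytest.raises(cf.AnalysisError):
            hx.base_reference_frame(s, "W", 2)


class TestStepParameters:
    def test_constructed_pure_twist_step(self, b_duplex):
        # two identical pairs related by a 36 deg rotation at 3.38 A rise
        s = bd.build_duplex(og.duplex_from_notations("gg", "cc"))
        step = hx.step_parameters(s).iloc[0]
        assert step["twist"] == pytest.approx(36.0, abs=1e-6)
        assert step["rise"] == pytest.approx(3.38, abs=1e-6)
        for name in ("roll", "tilt", "shift", "slide"):
            assert step[name] == pytest.approx(0.0, abs=1e-3)

    @pytest.mark.parametrize("twist", [30.0, 32.7, 36.0])
    def test_builder_round_trip_twist(self, ds19, twist):
        spec = bd.HelixParamsSpec(form="X", twist_per_step=twist, rise_per_step=3.3)
        s = bd.build_duplex(ds19, spec)
        mean = hx.mean_step_parameters(hx.step_parameters(s))
        assert mean["twist"] == pytest.approx(twist, abs=0.1)
        assert mean["rise"] == pytest.approx(3.3, abs=0.01)

    def test_b_form_round_trip_with_x_displacement(self, b_duplex):
        mean = hx.mean_step_parameters(hx.step_parameters(b_duplex))
        assert mean["twist"] == pytest.approx(36.0, abs=0.1)
        assert mean["rise"] == pytest.approx(3.38, abs=0.01)
        assert mean["x_displacement"] == pytest.approx(0.0, abs=0.05)

    def test_a_form_has_negative_x_displacement(self, ds19):
        s = bd.build_duplex(ds19, bd.HelixParamsSpec.a_form())
        mean = hx.mean_step_parameters(hx.step_parameters(s))
        assert mean["twist"] == pytest.approx(32.7, abs=0.1)
        assert mean["x_displacement"] < -3.0

    def test_x_displacement_recovers_spec_value(self, ds19):
        spec = bd.HelixParamsSpec(
            form="X", twist_per_step=30.0, rise_per_step=3.2, x_displacement=-4.3
        )
        s = bd.build_duplex(ds19, spec)
        mean = hx.mean_step_parameters(hx.step_parameters(s))
        assert mean["x_displacement"] == pytest.approx(-4.3, abs=0.05)

    def test_reversal_symmetry_twist_and_rise(self, b_duplex):
        fwd = hx.step_parameters(b_duplex)
        rev = hx.step_parameters(_reverse_duplex(b_duplex))
        assert np.allclose(
            fwd["twist"].to_numpy(), rev["twist"].to_numpy()[::-1], atol=1e-6
        )
        assert np.allclose(
            fwd["rise"].to_numpy(), rev["rise"].to_numpy()[::-1], atol=1e-6
        )

    def test_agrees_with_projected_c1_c1_vector_oracle(self):
        # brute-force twist: angle between successive cross-strand C1'-C1'
        # vectors projected on the plane normal to the mid-frame z axis
        duplex = og.duplex_from_notations("gagaag", og.wc_complement("gagaag"))
        s = bd.build_duplex(duplex)
        steps = hx.step_parameters(s)
        frames = hx.pair_frames(s)
        n = 6
        for i in range(n - 1):
            v1 = s.xyz("W", i + 1, "C1'") - s.xyz("C", n - i, "C1'")
            v2 = s.xyz("W", i + 2, "C1'") - s.xyz("C", n - i - 1, "C1'")
            zm = frames[i].z + frames[i + 1].z
            zm = zm / np.linalg.norm(zm)
            p1 = v1 - np.dot(v1, zm) * zm
            p2 = v2 - np.dot(v2, zm) * zm
            brute = math.degrees(
                math.atan2(float(np.dot(np.cross(p1, p2), zm)), float(np.dot(p1, p2)))
            )
            assert steps.iloc[i]["twist"] == pytest.approx(brute, abs=0.5)


class TestGrooves:
    def test_minor_narrower_than_major_in_b_form(self, b_duplex):
        gw = hx.groove_widths(b_duplex)
        interior = gw.loc[5:15]
        assert not interior.empty
        assert (interior["minor"] < interior["major"]).all()

    def test_widths_invariant_under_rigid_motion(self, b_duplex, random_rigid_motion):
        R, t = random_rigid_motion
        a = hx.groove_widths(b_duplex)
        b = hx.groove_widths(b_duplex.transformed(R, t))
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_two_bp_duplex_yields_empty_result(self):
        s = bd.build_duplex(og.duplex_from_notations("gg", "cc"))
        assert hx.groove_widths(s).empty


class TestClassifier:
    @staticmethod
    def _means(x, slide, twist, incl, roll):
        return {
            "x_displacement": x,
            "slide": slide,
            "twist": twist,
            "inclination": incl,
            "roll": roll,
        }

    def test_b_form_mean_tuple(self):
        call = hx.classify_helix(self._means(-0.8, 0.0, 36.0, 2.0, 1.0))
        assert call.label == "B"

    def test_lira_mean_tuple(self):
        call = hx.classify_helix(self._means(-4.3, -1.6, 30.0, 2.0, 1.0))
        assert call.label == "LirA"

    def test_a_form_tuple(self):
        call = hx.classify_helix(self._means(-4.5, -1.5, 31.0, 20.0, 10.0))
        assert call.label == "A"

    def test_gap_between_a_and_lira_is_intermediate(self):
        call = hx.classify_helix(self._means(-4.0, -1.5, 31.0, 10.0, 5.0))
        assert call.label == "intermediate"

    def test_unclassifiable_geometry_is_intermediate(self):
        call = hx.classify_helix(self._means(-2.0, -0.5, 33.0, 5.0, 5.0))
        assert call.label == "intermediate"

    def test_too_few_interior_steps_rejected(self):
        with pytest.raises(cf.AnalysisError):
            hx.classify_helix(self._means(-0.8, 0, 36, 0, 0), n_steps=3)

    def test_evidence_reports_the_inputs(self):
        means = self._means(-0.8, 0.0, 36.0, 2.0, 1.0)
        call = hx.classify_helix(means)
        assert call.evidence == means
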