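"""Fiber-model construction, sugar puckering and PDB round trips."""

import numpy as np
import pytest

from triplexkit import builder as bd
from triplexkit import conformation as cf
from triplexkit import oligo as og
from triplexkit import pairing as pg
from triplexkit.structure import PDBFormatError, Trajectory, read_pdb, write_pdb


class TestSugarPucker:
    @pytest.mark.parametrize("P, tau", [(18.0, 40.0), (162.0, 35.0)])
    def test_set_then_measure_round_trip(self, b_duplex, P, tau):
        out = bd.set_sugar_pucker(b_duplex, "W", 5, P, tau)
        P_m, tau_m = cf.pseudorotation(out, "W", 5)
        assert P_m == pytest.approx(P, abs=1e-4)
        assert tau_m == pytest.approx(tau, abs=1e-4)

    def test_repucker_preserves_chi_and_base(self, b_duplex):
        chi_before = cf.glycosidic_chi(b_duplex, "W", 5)
        n9_before = b_duplex.xyz("W", 5, "N9").copy()
        out = bd.set_sugar_pucker(b_duplex, "W", 5, 18.0, 40.0)
        assert cf.glycosidic_chi(out, "W", 5) == pytest.approx(chi_before, abs=1e-6)
        assert np.allclose(out.xyz("W", 5, "N9"), n9_before)

    def test_lna_rejects_south_targets(self, ds19_hetero):
        s = bd.build_duplex(ds19_hetero)
        lna_idx = next(
            r.index for r in s.residues_of("C") if r.chemistry == "LNA"
        )
        with pytest.raises(bd.BuildError, match="locked nucleotide"):
            bd.set_sugar_pucker(s, "C", lna_idx, 180.0, 38.0)
        # north targets are fine on LNA
        bd.set_sugar_pucker(s, "C", lna_idx, 20.0, 48.0)

    def test_built_sugars_are_d_configured(self, b_duplex):
        # D-deoxyribose reference sign frozen from an embedded
        # stereo-correct thymidine model: det([C3'-C1', C2'-C1', O4'-C1']) > 0
        for res in b_duplex.residues:
            c1 = b_duplex.xyz(res.chain, res.index, "C1'")
            vol = np.linalg.det(
                np.array(
                    [
                        b_duplex.xyz(res.chain, res.index, "C3'") - c1,
                        b_duplex.xyz(res.chain, res.index, "C2'") - c1,
                        b_duplex.xyz(res.chain, res.index, "O4'") - c1,
                    ]
                )
            )
            assert vol > 0.5


class TestDuplexBuild:
    def test_ds19_has_38_residues_in_two_chains(self, b_duplex):
        assert len(b_duplex.residues) == 38
        assert b_duplex.chains == ["W", "C"]
        assert len(b_duplex.residues_of("W")) == 19

    def test_single_bp_duplex_builds_but_has_no_steps(self):
        from triplexkit.helical import step_parameters

        s = bd.build_duplex(og.duplex_from_notations("g", "c"))
        assert len(s.residues) == 2
        with pytest.raises(cf.AnalysisError):
            step_parameters(s)

    def test_wc_nitrogens_within_pairing_cutoff(self, b_duplex):
        for pair in pg.pair_registry(b_duplex):
            assert pg.pair_distance(b_duplex, pair) < pg.DEFAULT_CUTOFF

    def test_hetero_duplex_lna_residues_built_north(self, ds19_hetero):
        s = bd.build_duplex(ds19_hetero)
        for res in s.residues_of("C"):
            P, _ = cf.pseudorotation(s, "C", res.index)
            label = cf.classify_pucker(P)
            assert label == ("north" if res.chemistry == "LNA" else "south")

    def test_dna_pucker_follows_form(self, ds19):
        s = bd.build_duplex(ds19, bd.HelixParamsSpec.a_form())
        P, tau = cf.pseudorotation(s, "W", 7)
        assert P == pytest.approx(18.0, abs=1e-4)
        assert tau == pytest.approx(40.0, abs=1e-4)

    def test_bad_spec_rejected(self):
        with pytest.raises(bd.BuildError):
            bd.HelixParamsSpec(twist_per_step=75.0)
        with pytest.raises(bd.BuildError):
            bd.HelixParamsSpec(rise_per_step=-1.0)


class TestTriplexBuild:
    def test_three_chains_with_expected_lengths(self, triplex):
        assert triplex.chains == ["W", "C", "T"]
        assert [len(triplex.residues_of(c)) for c in "WCT"] == [19, 19, 15]

    def test_all_hg_distances_below_cutoff(self, triplex):
        hg = [p for p in pg.pair_registry(triplex) if p.kind == "HG"]
        assert len(hg) == 15
        for pair in hg:
            assert pg.pair_distance(triplex, pair) < pg.DEFAULT_CUTOFF

    def test_tfo_cytosines_are_protonated(self, triplex):
        cytosines = [r for r in triplex.residues_of("T") if r.base == "C"]
        assert cytosines and all(r.protonated for r in cytosines)

    def test_fxn_triplex_has_only_ta_and_cg_triads(self):
        duplex = og.get_duplex("FXN_DS19")
        tfo = og.get_oligo("ON4-3′LNA⦁reduced")
        s = bd.build_triplex(duplex, tfo)
        triads = {p.triad for p in pg.pair_registry(s) if p.kind == "HG"}
        assert triads == {"T*A", "C+*G"}

    def test_tfo_parallel_to_purine_strand(self, triplex):
        # 5' TFO end sits at the 5' purine end of the site: residue T1
        # pairs the site start, T15 the site end
        site = triplex.meta["tfo_site_start"]
        hg = [p for p in pg.pair_registry(triplex) if p.kind == "HG"]
        assert hg[0].donor == ("W", site)
        assert hg[-1].donor == ("W", site + 14)

    def test_duplex_without_purine_tract_is_rejected(self):
        duplex = og.duplex_from_notations("gtgtgtgt", og.wc_complement("gtgtgtgt"))
        with pytest.raises(bd.BuildError, match="binding site"):
            bd.build_triplex(duplex, og.get_oligo("ON1"))

    def test_mismatched_tfo_is_rejected(self, ds19):
        with pytest.raises(bd.BuildError):
            bd.build_triplex(ds19, og.parse_mixmer("ggaaa"))


class TestPdbIO:
    def test_structure_round_trip_preserves_atom_table(self, triplex, tmp_path):
        path = tmp_path / "triplex.pdb"
        write_pdb(triplex, path)
        back = read_pdb(path)
        assert back.atom_names == triplex.atom_names
        assert np.abs(back.coords - triplex.coords).max() < 1e-3
        assert [r.chain for r in back.residues] == [r.chain for r in triplex.residues]
        assert [r.chemistry for r in back.residues] == [
            r.chemistry for r in triplex.residues
        ]
        assert back.residue("T", 1).protonated == triplex.residue("T", 1).protonated

    def test_trajectory_round_trip_has_model_blocks(self, b_duplex, tmp_path):
        coords = np.stack([b_duplex.coords + i * 0.01 for i in range(5)])
        traj = Trajectory(b_duplex, coords, frame_interval=40.0)
        path = tmp_path / "traj.pdb"
        write_pdb(traj, path)
        text = path.read_text()
        model_lines = [l for l in text.splitlines() if l.startswith("MODEL")]
        assert len(model_lines) == 5
        back = read_pdb(path)
        assert isinstance(back, Trajectory)
        assert back.n_frames == 5
        assert back.frame_interval == 40.0
        assert np.abs(back.coords - coords).max() < 1e-3

    def test_truncated_file_errors_not_silent(self, b_duplex, tmp_path):
        path = tmp_path / "full.pdb"
        coords = np.stack([b_duplex.coords, b_duplex.coords])
        write_pdb(Trajectory(b_duplex, coords), path)
        lines = path.read_text().splitlines()
        truncated = tmp_path / "broken.pdb"
        truncated.write_text("\n".join(lines[: len(lines) // 2]))
        with pytest.raises(PDBFormatError):
            read_pdb(truncated)

    def test_malformed_atom_line_reports_line_number(self, b_duplex, tmp_path):
        path = tmp_path / "m.pdb"
        write_pdb(b_duplex, path)
        lines = path.read_text().splitlines()
        atom_idx = next(i for i, l in enumerate(lines) if l.startswith("ATOM"))
        lines[atom_idx] = lines[atom_idx][:30] + "  badcoord" + lines[atom_idx][40:]
        path.write_text("\n".join(lines))
        with pytest.raises(PDBFormatError, match=f"line {atom_idx + 1}"):
            read_pdb(path)


class TestInvariances:
    def test_rigid_motion_changes_no_analysis_output(
        self, b_duplex, random_rigid_motion
    ):
        from triplexkit.helical import mean_step_parameters, step_parameters

        R, t = random_rigid_motion
        moved = b_duplex.transformed(R, t)
        ref = mean_step_parameters(step_parameters(b_duplex))
        got = mean_step_parameters(step_parameters(moved))
        assert float((ref - got).abs().max()) < 1e-6
        chi_ref = cf.glycosidic_chi(b_duplex, "W", 7)
        assert cf.glycosidic_chi(moved, "W", 7) == pytest.approx(chi_ref, abs=1e-9)
        P_ref, _ = cf.pseudorotation(b_duplex, "W", 7)
        assert cf.pseudorotation(moved, "W", 7)[0] == pytest.approx(P_ref, abs=1e-9)
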