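"""Mixmer notation parsing, complements, binding sites and ratios."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from triplexkit import oligo as og


class TestParsing:
    def test_catalog_oligo_lengths_match_printed_table(self, catalog):
        for name, rec in catalog.items():
            if rec["kind"] != "oligo":
                continue
            parsed = og.parse_mixmer(rec["notation"], name=name)
            assert len(parsed) == rec["length_nt"], name

    def test_catalog_duplex_lengths_and_complementarity(self, catalog):
        for name, rec in catalog.items():
            if rec["kind"] != "duplex":
                continue
            duplex = og.get_duplex(name)  # constructor validates WC pairing
            assert len(duplex) == rec["length_nt"]

    def test_parse_serialize_parse_is_identity(self, catalog):
        for name, rec in catalog.items():
            if rec["kind"] != "oligo":
                continue
            first = og.parse_mixmer(rec["notation"], name=name)
            second = og.parse_mixmer(og.to_notation(first), name=name)
            assert second.sequence == first.sequence
            assert second.chemistries == first.chemistries
            assert (second.label5, second.label3) == (first.label5, first.label3)
            assert second.segments == first.segments

    @pytest.mark.parametrize(
        "name, expected",
        [("ON2", 8), ("ON2-5′DNA", 7), ("ON1", 0), ("WC29", 12)],
    )
    def test_lna_counts(self, name, expected):
        assert og.count_lna(og.get_oligo(name)) == expected

    def test_on2_lna_positions_alternate_from_5prime(self):
        on2 = og.get_oligo("ON2")
        lna_positions = [
            m.position for m in on2.monomers if m.chemistry == og.LNA
        ]
        assert lna_positions == [1, 3, 5, 7, 9, 11, 13, 15]

    def test_bislna_arms_linker_and_label(self):
        bis = og.get_oligo("bisLNA49")
        assert len(bis) == 49
        assert bis.label5 == "Cy3"
        spans = [(e - s + 1) for s, e in bis.segments]
        assert spans == [15, 5, 29]
        # the linker is ordinary DNA, not a separate chemistry
        linker = bis.monomers[15:20]
        assert all(m.chemistry == og.DNA for m in linker)

    def test_tina_is_base_free_and_positioned_between_nucleotides(self):
        on = og.get_oligo("ON2-5′-penultimate-TINA")
        assert len(on) == 15
        assert og.count_tina(on) == 1
        kinds = [m.chemistry for m in on.monomers]
        assert kinds[1] == og.TINA  # between nucleotides 1 and 2
        assert on.monomers[0].position == 1 and on.monomers[2].position == 2
        assert on.monomers[1].base is None

    def test_bare_p_rejected_in_strict_mode(self):
        og.parse_mixmer("CcP", strict_tina=False)
        with pytest.raises(og.NotationError, match="bare 'P'"):
            og.parse_mixmer("CcP", strict_tina=True)

    def test_three_prime_to_five_prime_strings_are_reversed(self):
        o = og.parse_mixmer("3′-cC**cCt**Ag-5′")
        assert o.sequence == "GATCCCC"
        # LNA uppercase survives reversal at the right positions
        assert o.chemistries == ("DNA", "LNA", "DNA", "LNA", "DNA", "LNA", "DNA")

    def test_label_on_reversed_strand_lands_on_five_prime_end(self):
        pyr = og.get_duplex("c-MYC_DS29Hetero").pyrimidine_strand
        assert pyr.label5 == "Cy5"
        assert pyr.label3 is None

    @pytest.mark.parametrize(
        "bad, match",
        [
            ("acgx", "unknown character"),
            ("acgU", "unknown character"),
            ("5'-acg-5'", "conflicting direction"),
            ("ac**gt", "unbalanced"),
            ("", "empty"),
        ],
    )
    def test_parse_errors(self, bad, match):
        with pytest.raises(og.NotationError, match=match):
            og.parse_mixmer(bad)

    def test_parse_error_reports_position(self):
        with pytest.raises(og.NotationError, match="position 3"):
            og.parse_mixmer("acXgt")


class TestComplements:
    def test_wc_complement_of_printed_duplex_strand(self):
        assert og.wc_complement("ggggaaaagaaaaaagatc") == "gatcttttttcttttcccc"

    def test_wc_complement_single_base(self):
        assert og.wc_complement("a") == "t"

    @given(st.text(alphabet="acgtACGT", min_size=1, max_size=60))
    def test_wc_complement_is_an_involution(self, seq):
        assert og.wc_complement(og.wc_complement(seq)) == seq

    def test_wc_complement_rejects_non_acgt(self):
        with pytest.raises(og.NotationError, match="position 2"):
            og.wc_complement("anc")

    @pytest.mark.parametrize(
        "purines, pyrimidines",
        [
            ("ggaaaagaaaaaaga", "ccttttcttttttct"),  # c-MYC site -> ON1
            ("gaagaagaagaagaa", "cttcttcttcttctt"),  # FXN site -> ON4 letters
            ("g", "c"),
        ],
    )
    def test_hoogsteen_parallel_complement(self, purines, pyrimidines):
        hg = og.hoogsteen_parallel_complement(purines)
        assert hg.sequence == pyrimidines
        assert len(hg.sequence) == len(purines)
        # only T and C; every C is protonated, every T is not
        for base, prot in zip(hg.sequence, hg.protonated):
            assert base in "ct"
            assert prot == (base == "c")

    def test_hoogsteen_complement_rejects_pyrimidines(self):
        with pytest.raises(og.NotationError, match="position 3"):
            og.hoogsteen_parallel_complement("ggtga")


class TestBindingSites:
    def test_c_myc_ds45_site_for_on2(self):
        duplex = og.get_duplex("c-MYC_DS45")
        assert og.find_tfo_binding_site(duplex, og.get_oligo("ON2")) == (16, 30)

    def test_c_myc_ds19_site_for_on1(self, ds19):
        assert og.find_tfo_binding_site(ds19, og.get_oligo("ON1")) == (3, 17)

    def test_sites_match_the_printed_bold_spans(self, catalog):
        for name, rec in catalog.items():
            if rec["kind"] == "duplex":
                duplex = og.get_duplex(name)
                assert duplex.binding_site is not None

    def test_purine_tfo_is_rejected(self, ds19):
        with pytest.raises(og.NotationError, match="purine"):
            og.find_tfo_binding_site(ds19, og.parse_mixmer("aaaaa"))

    def test_absent_site_returns_none(self, ds19):
        assert og.find_tfo_binding_site(ds19, og.parse_mixmer("cccccccc")) is None

    def test_ambiguous_site_lists_all_intervals(self):
        duplex = og.duplex_from_notations("ggaaggaa", og.wc_complement("ggaaggaa"))
        with pytest.raises(og.AmbiguousSiteError, match=r"\(1, 4\).*\(5, 8\)"):
            og.find_tfo_binding_site(duplex, og.parse_mixmer("cctt"))

    def test_hetero_flag(self, ds19, ds19_hetero):
        assert not ds19.is_hetero
        assert ds19_hetero.is_hetero

    def test_non_complementary_duplex_names_first_mismatch(self):
        with pytest.raises(og.NotationError, match="position 2"):
            og.duplex_from_notations("ga", "gc")


class TestRatios:
    def test_printed_concentration_ladder(self):
        target = 5e-9  # 5 nM dsDNA
        ladder_um = [0.06, 0.09, 0.125, 0.25, 0.5, 1.0, 2.0]
        ratios = [og.hybridization_ratio(target, c * 1e-6) for c in ladder_um]
        assert ratios == [12, 18, 25, 50, 100, 200, 400]

    def test_equal_concentrations_give_one(self):
        assert og.hybridization_ratio(3.3e-7, 3.3e-7) == 1

    def test_non_integer_ratio_returned_exactly(self):
        assert og.hybridization_ratio(3.0, 10.0) == pytest.approx(10.0 / 3.0)

    @pytest.mark.parametrize("bad", [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)])
    def test_nonpositive_concentration_rejected(self, bad):
        with pytest.raises(ValueError):
            og.hybridization_ratio(*bad)


class TestFasta:
    def test_roundtrip_with_chemistry_sidecar(self, tmp_path):
        oligos = [og.get_oligo("ON2"), og.get_oligo("ON1")]
        fasta = tmp_path / "seqs.fasta"
        sidecar = tmp_path / "seqs.chem.tsv"
        og.write_fasta(oligos, fasta, sidecar=sidecar)
        back = og.read_fasta(fasta, sidecar=sidecar)
        assert [o.sequence for o in back] == [o.sequence for o in oligos]
        assert [o.chemistries for o in back] == [o.chemistries for o in oligos]

    def test_fasta_alone_loses_chemistry(self, tmp_path):
        fasta = tmp_path / "seqs.fasta"
        og.write_fasta([og.get_oligo("ON2")], fasta)
        (back,) = og.read_fasta(fasta)
        assert set(back.chemistries) == {og.DNA}
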