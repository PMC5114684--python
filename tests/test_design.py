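import itertools

import numpy as np
import pytest

import mirsponge as ms
from mirsponge.design import construct_annotations

SENSE = "GTCCCAGGGATTCCTTTTAAACTGGACAATTAGGGATTCCTTTTAAACTGGACGG"
ANTI = "GACCCGTCCAGTTTAAAAGGAATCCCTAATTGTCCAGTTTAAAAGGAATCCCTGG"
MIR145_MBS = "AGGGATTCCTTTTAAACTGGAC"


class TestPerfectMbs:
    def test_mir145(self, mir145):
        spec = ms.perfect_mbs(mir145)
        assert str(spec.mbs_dna) == "AGGGATTCCTGGGAAAACTGGAC"
        assert spec.mode is ms.MBSMode.PERFECT

    def test_short_example(self):
        rec = ms.MiRNARecord("x-miR-1", ms.rna("AAAAAAAAAAAAAAAA"))
        assert str(ms.perfect_mbs(rec).mbs_dna) == "T" * 16

    def test_length_preserved_on_random_mirnas(self):
        for rec in ms.generate_synthetic_mirna_set(100, (15, 35), 0.5, seed=3):
            assert len(ms.perfect_mbs(rec).mbs_dna) == len(rec)


class TestSelectBulgeFill:
    def test_calibrated_mir145_fill(self):
        assert str(ms.select_bulge_fill("UCCC")) == "TTT"

    def test_all_windows_non_pairing_and_length_three(self):
        for window in itertools.product("ACGU", repeat=4):
            window = "".join(window)
            fill = str(ms.select_bulge_fill(window))
            assert len(fill) == 3
            # candidate position k (5'->3' sense) faces window base 4-k (antiparallel)
            opposite = window[::-1]
            for base, wbase in zip(fill, opposite):
                rna_base = base.replace("T", "U")
                assert not ms.pair_allowed(rna_base, wbase, wobble=True)

    def test_window_must_be_four_nt(self):
        with pytest.raises(ms.ValidationError):
            ms.select_bulge_fill("UCC")


class TestBulgedMbs:
    def test_mir145_printed_mbs(self, mir145):
        spec = ms.bulged_mbs(mir145, (10, 13))
        assert str(spec.mbs_dna) == MIR145_MBS
        assert len(spec.mbs_dna) == len(mir145) - 1

    def test_positions_outside_window_match_perfect(self, mir145):
        perfect = str(ms.perfect_mbs(mir145).mbs_dna)
        n = len(mir145)
        for start in range(2, n - 4):
            window = (start, start + 3)
            bulged = str(ms.bulged_mbs(mir145, window).mbs_dna)
            # antisense indices opposite the window: n-end .. n-start (0-based)
            assert bulged[: n - window[1]] == perfect[: n - window[1]]
            assert bulged[n - window[1] + 3:] == perfect[n - window[0] + 1:]

    def test_window_2_5_on_22mer(self):
        rec = ms.generate_synthetic_mirna_set(1, (22, 22), 0.5, seed=11)[0]
        spec = ms.bulged_mbs(rec, (2, 5))
        assert len(spec.mbs_dna) == 21
        perfect = str(ms.perfect_mbs(rec).mbs_dna)
        assert str(spec.mbs_dna)[:17] == perfect[:17]
        assert str(spec.mbs_dna)[-1] == perfect[-1]

    def test_window_touching_ends_rejected(self, mir145):
        with pytest.raises(ms.ValidationError, match="internal"):
            ms.bulged_mbs(mir145, (1, 4))
        with pytest.raises(ms.ValidationError, match="internal"):
            ms.bulged_mbs(mir145, (20, 23))


class TestBuildConstruct:
    def test_printed_oligos(self, mir145):
        construct = ms.build_construct(
            ms.bulged_mbs(mir145, (10, 13)), repeats=2, spacer="AATT",
            preset="pcdh-cumate",
        )
        assert str(construct.sense_oligo) == SENSE
        assert str(construct.antisense_oligo) == ANTI

    def test_degenerate_assembly(self, mir145):
        spec = ms.perfect_mbs(mir145)
        construct = ms.build_construct(spec, repeats=1, spacer="")
        assert str(construct.sense_oligo) == str(spec.mbs_dna)

    def test_round_robin_interleaving(self, mir145):
        other = ms.MiRNARecord("x-miR-2", ms.rna("GGGAUUCCUGGGAAAACUGG"))
        a = ms.perfect_mbs(mir145)
        b = ms.perfect_mbs(other)
        construct = ms.build_construct([a, b], repeats=2, spacer="AATT")
        parts = construct.core.split("AATT")
        assert parts == [str(a.mbs_dna), str(b.mbs_dna),
                         str(a.mbs_dna), str(b.mbs_dna)]

    def test_core_length_formula(self, mir145):
        rng = np.random.default_rng(5)
        spec = ms.bulged_mbs(mir145)
        for k in (1, 2, 3, 6):
            spacer = "".join("ACGT"[i] for i in rng.integers(0, 4, 4))
            construct = ms.build_construct(spec, repeats=k, spacer=spacer)
            assert len(construct.core) == k * len(spec.mbs_dna) + (k - 1) * 4

    def test_transcript_contains_k_antisense_copies(self, mir145):
        spec = ms.perfect_mbs(mir145)
        antisense_rna = str(spec.mbs_dna.as_rna())
        for k in (1, 3):
            construct = ms.build_construct(spec, repeats=k)
            assert str(construct.transcript).count(antisense_rna) == k

    def test_byte_identical_determinism(self, mir145):
        one = ms.build_construct(ms.bulged_mbs(mir145), repeats=2, preset="pcdh-cumate")
        two = ms.build_construct(ms.bulged_mbs(mir145), repeats=2, preset="pcdh-cumate")
        assert str(one.sense_oligo) == str(two.sense_oligo)
        assert str(one.antisense_oligo) == str(two.antisense_oligo)

    def test_empty_mbs_list_rejected(self):
        with pytest.raises(ms.ValidationError):
            ms.build_construct([], repeats=1)

    def test_long_spacer_warns(self, mir145):
        with pytest.warns(UserWarning, match="spacer"):
            ms.build_construct(ms.perfect_mbs(mir145), spacer="ACGTACGTAC")


class TestEmitOligos:
    def test_paper_construct_emission(self, mir145):
        construct = ms.build_construct(
            ms.bulged_mbs(mir145), repeats=2, spacer="AATT", preset="pcdh-cumate"
        )
        text = ms.emit_oligos(construct)
        assert SENSE in text and ANTI in text
        assert "phos5'" in text

    def test_annotation_intervals(self, mir145):
        construct = ms.build_construct(
            ms.bulged_mbs(mir145), repeats=2, spacer="AATT", preset="pcdh-cumate"
        )
        rows = {feat.split("[")[0]: (start, end)
                for feat, start, end, _ in construct_annotations(construct)}
        assert rows["MBS_1"] == (5, 27)
        assert rows["MBS_2"] == (31, 53)
        assert rows["spacer_1"] == (27, 31)

    def test_fasta_round_trip(self, tmp_path, mir145):
        from Bio import SeqIO
        construct = ms.build_construct(ms.bulged_mbs(mir145), repeats=2,
                                       preset="pcdh-cumate")
        path = tmp_path / "oligos.fa"
        ms.design.write_oligos_fasta(construct, path)
        entries = {e.id: str(e.seq) for e in SeqIO.parse(str(path), "fasta")}
        assert entries["sense_oligo"] == str(construct.sense_oligo)
        assert entries["antisense_oligo"] == str(construct.antisense_oligo)
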