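"""Precursor annotation, six-frame translation, and database scanning."""

import pytest
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ginsentides import data, precursor, synth
from ginsentides.precursor import (
    NoMatureDomainError,
    NonCTerminalMatureError,
    annotate_precursor,
    scan_fasta,
    six_frame_orfs,
)

SIGNAL = "MALLLVVILLAFFAVSSA"  # 18 residues, hydrophobic core, small P1
PRO = "EAKDVQSTNAPSEMAEKGLARS"


@pytest.fixture
def tp1_precursor(tp1):
    return SIGNAL + PRO + tp1


# Independent codon-table oracle (standard code), for translation checks.
_BASES = "TCAG"
_AA_TABLE = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    a + b + c: _AA_TABLE[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def oracle_translate(nt: str) -> str:
    return "".join(
        CODON_TABLE[nt[i : i + 3]] for i in range(0, len(nt) - len(nt) % 3, 3)
    )


class TestAnnotation:
    def test_known_signal_length_recovers_all_boundaries(self, tp1, tp1_precursor):
        model = annotate_precursor(tp1_precursor, signal_length=len(SIGNAL))
        assert model.signal == SIGNAL
        assert model.pro == PRO
        assert model.mature == tp1

    def test_heuristic_still_finds_the_mature_domain(self, tp1, tp1_precursor):
        model = annotate_precursor(tp1_precursor)
        assert model.mature == tp1
        assert model.boundary_methods["mature"] == "heuristic"
        assert 15 <= model.signal_end <= 30

    def test_mature_only_input_has_empty_signal_and_pro(self, tp1):
        model = annotate_precursor(tp1)
        assert model.signal == "" and model.pro == ""
        assert model.mature == tp1

    def test_cargo_style_architecture_is_flagged_distinctly(self, tp1_precursor):
        cargo = tp1_precursor + "GG" + "KDEVAAKNDSTQE" * 2
        with pytest.raises(NonCTerminalMatureError, match="not C-terminal"):
            annotate_precursor(cargo)

    def test_too_few_cysteines_rejected(self):
        with pytest.raises(NoMatureDomainError):
            annotate_precursor(SIGNAL + PRO)

    def test_motif_free_cysteine_rich_sequence_has_no_mature_domain(self):
        scrambled = SIGNAL + PRO + "CCCCCCCC" + "GAVLK" * 4
        with pytest.raises((NoMatureDomainError, NonCTerminalMatureError)):
            annotate_precursor(scrambled)


class TestSixFrameTranslation:
    def test_agrees_with_independent_codon_table(self, rng):
        for _ in range(100):
            n = int(rng.integers(60, 300))
            nt = "".join(rng.choice(list("ACGT"), size=n))
            rc = str(Seq(nt).reverse_complement())
            for frame in range(3):
                fwd = oracle_translate(nt[frame:])
                orfs = six_frame_orfs(nt, min_orf=5, partial=True)
                for orf in orfs:
                    if orf.strand == "+" and orf.frame == frame:
                        assert orf.protein in fwd.replace("*", " ").split()
                    elif orf.strand == "-" and orf.frame == frame:
                        rev = oracle_translate(rc[frame:])
                        assert orf.protein in rev.replace("*", " ").split()

    def test_orf_coordinates_round_trip(self, rng):
        from ginsentides.synth import _reverse_translate

        protein = "MGAVLKWSTD" * 4
        nt = _reverse_translate(rng, protein)
        full = "CCCTCC" + nt + "GGAGGA"
        orfs = [o for o in six_frame_orfs(full, min_orf=30) if o.strand == "+"]
        assert any(
            o.protein == protein
            and full[o.start : o.end] == nt[:-3]
            for o in orfs
        )

    def test_reverse_strand_orf_detected(self, rng):
        from ginsentides.synth import _reverse_translate

        protein = "MWSTDKGAVL" * 4
        nt = _reverse_translate(rng, protein)
        full = "CCTCC" + str(Seq(nt).reverse_complement()) + "GGAGG"
        orfs = [o for o in six_frame_orfs(full, min_orf=30) if o.strand == "-"]
        assert any(o.protein == protein for o in orfs)

    def test_min_orf_filters_short_frames(self):
        nt = "ATG" + "GCT" * 10 + "TAA"
        assert six_frame_orfs(nt, min_orf=30) == []
        assert any(o.protein.startswith("MA") for o in six_frame_orfs(nt, min_orf=5))


class TestScanning:
    def test_embedded_precursors_are_the_only_hits(self):
        cfg = synth.GeneratorConfig(seed=42, n_decoys=60, n_embedded=3)
        records, truth = synth.gen_database(cfg)
        hits = scan_fasta(records)
        assert sorted(h.record_id for h in hits) == sorted(truth.record)
        for hit in hits:
            row = truth[truth.record == hit.record_id].iloc[0]
            assert hit.precursor.mature == row.mature

    def test_reverse_strand_nucleotide_embedding(self):
        for seed in range(8):
            cfg = synth.GeneratorConfig(seed=seed, n_decoys=10, n_embedded=2, decoy_nt=True)
            records, truth = synth.gen_database(cfg)
            hits = scan_fasta(records, input_type="nt")
            got = sorted((h.record_id, h.strand, h.orf_start, h.orf_end) for h in hits)
            want = sorted(
                (r.record, r.strand, r.orf_start, r.orf_end) for r in truth.itertuples()
            )
            assert got == want
            if any(h.strand == "-" for h in hits):
                break
        assert any(h.strand == "-" for h in hits)

    def test_empty_fasta_gives_no_hits(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        assert scan_fasta(str(p)) == []

    def test_fasta_path_input(self, tmp_path, tp1):
        p = tmp_path / "db.fasta"
        p.write_text(f">prec\n{SIGNAL + PRO + tp1}\n>junk\nMGAVLKGAVLKGAVLK\n")
        hits = scan_fasta(str(p))
        assert [h.record_id for h in hits] == ["prec"]

    def test_mixed_alphabet_record_skipped_with_warning(self, tmp_path):
        p = tmp_path / "db.fasta"
        p.write_text(">protein_in_nt_scan\nMEEPLQARFFF\n")
        with pytest.warns(UserWarning, match="skipped"):
            hits = scan_fasta(str(p), input_type="nt")
        assert hits == []
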