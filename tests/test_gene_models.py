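"""Coordinate transforms and codon-effect annotation."""

import numpy as np
import pytest
from Bio.Seq import Seq

from mitoedit import (
    CoordinateError,
    GeneModel,
    Intron,
    NotEditableError,
    annotate_genome_site,
    classify_effect,
    codon_index,
    genome_to_transcript,
    sense_transcript_sequence,
    transcript_to_genome,
)
from mitoedit.datasets import MATR_ANCHOR_SUM, load_matr_editing_sites

# sub-threshold co-edits implied by the published edited codons
# (third-position partners of the two multi-edit codons)
KNOWN_CO_EDITS = {237, 1719}


class TestCoordinateTransforms:
    def test_published_anchor_pairs(self, matr_model):
        """Every published matR site satisfies genome + transcript = 340,037
        and both transforms reproduce the printed pairing."""
        sites = load_matr_editing_sites()
        assert len(sites) == 17
        for _, row in sites.iterrows():
            gpos, tpos = int(row["genome_pos"]), int(row["tpos"])
            assert gpos + tpos == MATR_ANCHOR_SUM
            loc = genome_to_transcript(gpos, matr_model)
            assert loc.region == "exonic" and loc.tpos == tpos
            assert transcript_to_genome(tpos, matr_model) == gpos

    def test_first_base_identity(self):
        gene = GeneModel("g", "c", "+", ((101, 200),))
        assert genome_to_transcript(101, gene).tpos == 1
        assert transcript_to_genome(1, gene) == 101

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_identity_random_models(self, seed):
        """transcript -> genome -> transcript is the identity on every
        transcript position, for multi-exon models on both strands."""
        rng = np.random.default_rng(seed)
        n_exons = rng.integers(1, 6)
        strand = "+" if rng.random() < 0.5 else "-"
        cursor = int(rng.integers(1, 1000))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(5, 200))
            exons.append((cursor, cursor + length - 1))
            cursor += length + int(rng.integers(10, 100))
        if strand == "-":
            exons = exons[::-1]
        gene = GeneModel("g", "c", strand, tuple(exons))
        for tpos in range(1, gene.transcript_length + 1):
            assert genome_to_transcript(transcript_to_genome(tpos, gene), gene).tpos == tpos

    def test_intron_position_returns_label_not_tpos(self):
        gene = GeneModel(
            "g", "c", "+", ((1, 10), (21, 30)), (Intron(11, 20, "g intron 1"),)
        )
        loc = genome_to_transcript(15, gene)
        assert loc.region == "intronic"
        assert loc.tpos is None
        assert loc.intron_label == "g intron 1"
        assert genome_to_transcript(50, gene).region == "outside"

    def test_tpos_out_of_range_errors(self, matr_model):
        with pytest.raises(CoordinateError):
            transcript_to_genome(0, matr_model)
        with pytest.raises(CoordinateError):
            transcript_to_genome(matr_model.transcript_length + 1, matr_model)

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("g", "c", "+", ((10, 5),))  # start > end
        with pytest.raises(ValueError):
            GeneModel("g", "c", "+", ((1, 10), (5, 20)))  # overlap
        with pytest.raises(ValueError):
            GeneModel("g", "c", "-", ((1, 10), (21, 30)))  # wrong order for minus
        with pytest.raises(ValueError):
            GeneModel("g", "c", "+", ((1, 10),), cds_start_tpos=9)  # CDS < 1 codon


class TestCodonIndex:
    @pytest.mark.parametrize(
        "tpos,cds_start,expected",
        [(32, 1, (11, 2)), (1851, 1, (617, 3)), (1, 1, (1, 1)), (1841, 1, (614, 2))],
    )
    def test_examples(self, tpos, cds_start, expected):
        assert codon_index(tpos, cds_start) == expected

    def test_before_cds_is_noncoding(self):
        assert codon_index(3, 5) is None

    def test_formula_matches_exhaustive_tiling(self):
        """aa/codon positions agree with walking codons one base at a time."""
        aa, cpos = 1, 1
        for tpos in range(1, 3001):
            assert codon_index(tpos, 1) == (aa, cpos)
            cpos += 1
            if cpos == 4:
                aa, cpos = aa + 1, 1

    def test_published_aa_positions(self):
        for _, row in load_matr_editing_sites().iterrows():
            assert codon_index(int(row["tpos"]), 1)[0] == int(row["aa_pos"])


class TestClassifyEffect:
    def test_published_codon_changes(self, matr_model, matr_transcript):
        """All 17 published codon and amino-acid changes are reproduced
        from the planted transcript, including the two multi-edit codons
        (TCC→TTT, CGC→TGT) via the co-edited-site mechanism."""
        sites = load_matr_editing_sites()
        co_edits = set(sites["tpos"]) | KNOWN_CO_EDITS
        for _, row in sites.iterrows():
            ann = classify_effect(int(row["tpos"]), matr_model, matr_transcript, co_edits)
            assert ann.ref_codon == row["ref_codon"], row["genome_pos"]
            assert ann.edited_codon == row["edited_codon"], row["genome_pos"]
            change = str(row["aa_change"])
            if change.startswith("No"):
                assert ann.category == "synonymous"
                assert ann.ref_aa == ann.edited_aa == change[4]
            else:
                assert ann.category == "nonsynonymous"
                assert ann.ref_aa == change[0]
                if len(change) > 2:  # one published row omits the new residue
                    assert ann.edited_aa == change[2]

    def test_incomplete_published_row_translates_to_leucine(self, matr_model, matr_transcript):
        """The site whose published amino-acid change is truncated (CCC→CTC)
        is P→L by translation."""
        ann = classify_effect(1061, matr_model, matr_transcript)
        assert (ann.ref_aa, ann.edited_aa) == ("P", "L")

    def test_synonymy_matches_bruteforce_translation(self):
        """Over all 64 codons and every C position within them, the category
        equals a direct comparison of translated reference vs edited codon."""
        bases = "ACGT"
        for codon in ("".join(c) for c in __import__("itertools").product(bases, repeat=3)):
            gene = GeneModel("g", "c", "+", ((1, 3),))
            for i, base in enumerate(codon):
                if base != "C":
                    continue
                ann = classify_effect(i + 1, gene, codon)
                edited = codon[:i] + "T" + codon[i + 1 :]
                expect = (
                    "synonymous"
                    if str(Seq(codon).translate()) == str(Seq(edited).translate())
                    else "nonsynonymous"
                )
                assert ann.category == expect, codon
                assert ann.edited_codon == edited

    def test_non_cytidine_is_an_error(self, matr_model, matr_transcript):
        with pytest.raises(NotEditableError):
            classify_effect(34, matr_model, matr_transcript)  # G of codon 12

    def test_intronic_site_annotated_with_label(self):
        gene = GeneModel("g", "c", "+", ((1, 9), (20, 31)), (Intron(10, 19, "g intron 1"),))
        seq = "ATGCCCAAA" + "CCCGGGTTTAAA"
        ann = annotate_genome_site(12, gene, seq)
        assert ann.category == "intronic"
        assert ann.intron_label == "g intron 1"


class TestSenseStrand:
    def test_minus_strand_edit_is_plus_strand_g_to_a(self):
        """A C-to-U edit on a minus-strand gene sits on a plus-strand G;
        the sense transcript exposes it as C."""
        genome = "TTGGGCATTT"  # plus strand; gene on minus at 3..6 ("GGGC")
        gene = GeneModel("g", "c", "-", ((3, 6),))
        tseq = sense_transcript_sequence(genome, gene)
        assert tseq == "GCCC"
        loc = genome_to_transcript(4, gene)  # plus-strand G
        assert tseq[loc.tpos - 1] == "C"

    def test_multi_exon_minus_strand_splicing(self):
        genome = "AAAGGCCTTTTACGTAAA"
        gene = GeneModel("g", "c", "-", ((12, 15), (4, 8)), (Intron(9, 11, "i1"),))
        assert sense_transcript_sequence(genome, gene) == "ACGTAGGCC"
        # round trip across the intron
        for tpos in range(1, gene.transcript_length + 1):
            g = transcript_to_genome(tpos, gene)
            assert genome_to_transcript(g, gene).tpos == tpos
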