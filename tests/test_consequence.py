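import numpy as np
import pytest

from autozygmap.consequence import (
    apply_variant_translate,
    cds_codon_of,
    genomic_to_cds,
    truncation_stats,
)
from autozygmap.core import Variant
from autozygmap.synthetic import (
    build_gene_fixture,
    causal_deletion,
    mirror_gene_model,
    mirror_variant,
    random_gene_model,
)
from _oracles import edit_and_translate


class TestCdsCodonOf:
    @pytest.mark.parametrize(
        "cds_pos, expected",
        [(1350, (450, 3)), (1, (1, 1)), (4, (2, 1)), (3, (1, 3)), (1351, (451, 1))],
    )
    def test_codon_and_base(self, cds_pos, expected):
        assert cds_codon_of(cds_pos) == expected

    def test_out_of_bounds_errors(self):
        with pytest.raises(ValueError):
            cds_codon_of(0)
        with pytest.raises(ValueError):
            cds_codon_of(100, cds_length=99)


class TestGenomicToCds:
    def test_first_cds_base_maps_to_one(self, gene_fixture):
        model, _ = gene_fixture
        assert genomic_to_cds(model, model.cds_start).cds_pos == 1

    def test_intron_position_is_non_coding(self, gene_fixture):
        model, _ = gene_fixture
        proj = genomic_to_cds(model, model.exons[1].end + 3)
        assert not proj.is_coding
        assert str(proj) == "non-coding: intronic"

    def test_untranslated_first_exon_is_utr(self, gene_fixture):
        model, _ = gene_fixture
        assert genomic_to_cds(model, model.exons[0].start).kind == "utr5"

    def test_round_trip_with_inverse_projection(self, gene_fixture, rng):
        model, _ = gene_fixture
        for cds_pos in rng.integers(1, model.cds_length + 1, size=100):
            g = model.cds_to_genomic(int(cds_pos))
            assert genomic_to_cds(model, g).cds_pos == cds_pos

    def test_round_trip_on_minus_strand(self, gene_fixture, rng):
        model = mirror_gene_model(gene_fixture[0])
        for cds_pos in rng.integers(1, model.cds_length + 1, size=50):
            g = model.cds_to_genomic(int(cds_pos))
            assert genomic_to_cds(model, g).cds_pos == cds_pos


class TestApplyVariantTranslate:
    def test_planted_deletion_reproduces_known_consequence(self, gene_fixture):
        model, _ = gene_fixture
        csq = apply_variant_translate(model, causal_deletion(model, 1350))
        assert csq.frameshift
        assert csq.first_altered == 451
        assert csq.termination_index == 476
        assert csq.mutant_len == 475
        assert csq.residues_lost == 401
        assert csq.percent_lost == 46
        assert csq.protein_notation == "p.A451fs26"

    def test_both_deletion_spellings_normalise_identically(self, gene_fixture):
        """GG>G and an anchored 1 bp del describe the same edit."""
        model, _ = gene_fixture
        g = model.cds_to_genomic(1350)
        a = apply_variant_translate(model, Variant(model.chrom, g, "GG", "G"))
        anchor = model.sequence(g - 1, g - 1)
        b = apply_variant_translate(model, Variant(model.chrom, g - 1, anchor + "G", anchor))
        assert a == b

    def test_in_frame_deletion_is_not_a_frameshift(self, gene_fixture):
        model, _ = gene_fixture
        # delete codon 100 (CDS 298-300) with an anchor base
        g = model.cds_to_genomic(298)
        ref = model.sequence(g - 1, g + 2)
        v = Variant(model.chrom, g - 1, ref, ref[0])
        csq = apply_variant_translate(model, v)
        assert not csq.frameshift
        assert csq.mutant_len == csq.ref_len - 1

    def test_boundary_fixture_one_residue_protein(self):
        model, _ = build_gene_fixture(fs_codon=1, shifted_stop_codon=2)
        csq = apply_variant_translate(model, causal_deletion_at(model, 3))
        assert csq.mutant_len == 1
        assert csq.termination_index == 2

    def test_start_codon_removal_reported_as_start_lost(self, gene_fixture):
        model, _ = gene_fixture
        g = model.cds_to_genomic(1)  # the A of ATG
        v = Variant(model.chrom, g, model.sequence(g, g), "C")
        csq = apply_variant_translate(model, v)
        assert csq.kind == "start-lost"
        assert csq.termination_index is None

    def test_strand_mirroring_gives_identical_consequence(self, gene_fixture):
        model, _ = gene_fixture
        variant = causal_deletion(model, 1350)
        mirrored_model = mirror_gene_model(model)
        mirrored_variant = mirror_variant(model, variant)
        assert apply_variant_translate(mirrored_model, mirrored_variant) == \
            apply_variant_translate(model, variant)

    def test_matches_edit_and_translate_oracle(self, rng):
        """Random 1 bp CDS deletions on random small genes vs direct genome editing."""
        checked = 0
        while checked < 50:
            model = random_gene_model(rng)
            cds_pos = int(rng.integers(4, model.cds_length - 3))
            g = model.cds_to_genomic(cds_pos)
            # keep the deleted base strictly inside its CDS exon piece
            if not any(iv.start < g < iv.end for iv in model.cds_intervals()):
                continue
            anchor_pos = g - 1
            ref = model.sequence(anchor_pos, g)
            v = Variant(model.chrom, anchor_pos, ref, ref[0])
            csq = apply_variant_translate(model, v)
            mut_len, stop_found, first_altered = edit_and_translate(
                model, g if model.strand == "+" else g
            )
            assert csq.mutant_len == mut_len
            assert (csq.termination_index is not None) == stop_found
            assert csq.first_altered == first_altered
            checked += 1

    def test_reference_mismatch_errors(self, gene_fixture):
        model, _ = gene_fixture
        g = model.cds_to_genomic(1350)
        base = model.sequence(g, g)
        wrong = "A" if base != "A" else "C"
        with pytest.raises(ValueError, match="mismatch"):
            apply_variant_translate(model, Variant(model.chrom, g, wrong * 2, wrong))


def causal_deletion_at(model, cds_pos):
    """1 bp deletion at the given CDS coordinate, anchored on the previous base."""
    g = model.cds_to_genomic(cds_pos)
    if g > model.locus_start:
        ref = model.sequence(g - 1, g)
        return Variant(model.chrom, g - 1, ref, ref[0])
    return Variant(model.chrom, g, model.sequence(g, g), "")


class TestTruncationStats:
    @pytest.mark.parametrize(
        "ref_len, mut_len, expected",
        [(876, 475, (401, 46)), (876, 876, (0, 0)), (100, 50, (50, 50))],
    )
    def test_values(self, ref_len, mut_len, expected):
        assert truncation_stats(ref_len, mut_len) == expected

    def test_elongation_rejected(self):
        with pytest.raises(ValueError):
            truncation_stats(100, 101)


class TestGeneFixtureConstruction:
    def test_default_reference_protein_length(self, gene_fixture):
        model, _ = gene_fixture
        assert len(model.translate_reference()) == 876

    def test_nineteen_exons_translation_starts_in_exon_two(self, gene_fixture):
        model, _ = gene_fixture
        assert len(model.exons) == 19
        assert model.cds_start > model.exons[0].end
        assert model.exons[1].start <= model.cds_start <= model.exons[1].end

    def test_planted_deletion_sits_in_eleventh_exon(self, gene_fixture):
        model, _ = gene_fixture
        g = model.cds_to_genomic(1350)
        exon_index = next(
            i for i, e in enumerate(model.exons, start=1) if e.start <= g <= e.end
        )
        assert exon_index == 11

    def test_fixture_verified_by_independent_translation(self):
        """Mutant first stop lands exactly at the requested shifted-frame codon."""
        from Bio.Seq import Seq

        model, _ = build_gene_fixture(n_codons=200, fs_codon=50, shifted_stop_codon=90)
        cds = model.cds_sequence()
        assert "*" not in str(Seq(cds).translate())[:-1]
        mutant = cds[: 3 * 50 - 1] + cds[3 * 50 :]
        prot = str(Seq(mutant[: len(mutant) - len(mutant) % 3]).translate())
        assert prot.find("*") + 1 == 90

    def test_infeasible_geometry_raises(self):
        with pytest.raises(ValueError):
            build_gene_fixture(n_codons=100, fs_codon=50, shifted_stop_codon=100)
        with pytest.raises(ValueError):
            build_gene_fixture(n_codons=100, fs_codon=60, shifted_stop_codon=40)
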