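"""Gene architecture: splice phases, transcript assembly, GFF3 I/O and the
local-synteny check."""

import numpy as np
import pytest

from oracle_utils import cumsum_mod3_phases

from pseudocasp.gene_models import (
    Exon,
    GeneModel,
    GeneModelError,
    build_transcript,
    check_flanking_synteny,
    compute_splice_phases,
    extract_cds,
    parse_gff3_gene,
    phases_to_table,
    write_gff3,
)
from pseudocasp.sequence_core import NucSequence
from pseudocasp.synthetic_data import flip_locus, random_gene_model


def _simple_model(coding_lengths, utr_first=True):
    """Adjacent exons with the given coding lengths on a synthetic sequence
    (introns of 10 nt between exons)."""
    exons = []
    pos = 1
    idx = 1
    if utr_first:
        exons.append(Exon(idx, pos, pos + 49))
        pos += 60
        idx += 1
    for ln in coding_lengths:
        exons.append(Exon(idx, pos, pos + ln - 1, pos, pos + ln - 1))
        pos += ln + 10
        idx += 1
    model = GeneModel("g", "s", "+", tuple(exons), 2 if utr_first else 1)
    rng = np.random.default_rng(0)
    seq = NucSequence("s", "".join(rng.choice(list("ACGT"), size=pos + 50)))
    return model, seq


class TestSplicePhases:
    def test_casp16_like_phase_pattern(self, default_locus):
        """Exon 2 ends in phase 0 and exon 4 begins in phase 1 — the
        asymmetry that dooms the exon-3 skip."""
        _, model, _ = default_locus
        phases = {p.junction: p for p in compute_splice_phases(model)}
        assert phases[(2, 3)].end_phase_upstream == 0
        assert phases[(3, 4)].start_phase_downstream == 1

    def test_all_multiples_of_three_give_phase_zero(self):
        model, _ = _simple_model([30, 60, 9, 12])
        assert all(p.end_phase_upstream == 0 for p in compute_splice_phases(model))

    def test_against_cumulative_sum_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            lens = [int(rng.integers(4, 200)) for _ in range(int(rng.integers(2, 9)))]
            model, _ = _simple_model(lens)
            got = [p.end_phase_upstream for p in compute_splice_phases(model)]
            assert got == cumsum_mod3_phases(lens)

    def test_no_coding_segments_rejected(self):
        exons = (Exon(1, 1, 50), Exon(2, 61, 100))
        model = GeneModel("g", "s", "+", exons, 1)
        with pytest.raises(GeneModelError):
            compute_splice_phases(model)

    def test_phase_table_reports_both_conventions(self):
        model, _ = _simple_model([10, 11, 12])
        t = phases_to_table(compute_splice_phases(model))
        assert list(t.columns) == [
            "junction", "end_phase_upstream", "start_phase_downstream",
            "gff3_phase_downstream",
        ]
        assert (t.gff3_phase_downstream == (3 - t.start_phase_downstream) % 3).all()


class TestBuildTranscript:
    def test_all_exons_concatenate(self):
        model, seq = _simple_model([30, 45])
        t, cmap = build_transcript(model, seq)
        assert len(t) == sum(e.length for e in model.exons)
        assert len(cmap) == len(t)

    def test_skipping_drops_exon_and_map_interval(self):
        model, seq = _simple_model([30, 45, 21])
        full, _ = build_transcript(model, seq)
        skipped, cmap = build_transcript(model, seq, {1, 2, 4})
        assert len(full) - len(skipped) == model.exon(3).length
        inside = set(range(model.exon(3).genomic_start, model.exon(3).genomic_end + 1))
        assert not inside & set(int(x) for x in cmap)

    def test_map_matches_naive_concatenation(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            seq, model = random_gene_model(rng)
            n = len(model.exons)
            keep = sorted(rng.choice(np.arange(1, n + 1),
                                     size=int(rng.integers(1, n + 1)),
                                     replace=False).tolist())
            t, cmap = build_transcript(model, seq, keep)
            # naive per-exon oracle
            parts, positions = [], []
            for e in model.exons:
                if e.index not in keep:
                    continue
                seg = seq.residues[e.genomic_start - 1 : e.genomic_end]
                pos = list(range(e.genomic_start, e.genomic_end + 1))
                if model.strand == "-":
                    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
                    seg = "".join(comp[c] for c in reversed(seg))
                    pos = pos[::-1]
                parts.append(seg)
                positions.extend(pos)
            assert t.residues == "".join(parts)
            assert [int(x) for x in cmap] == positions

    def test_empty_inclusion_rejected(self):
        model, seq = _simple_model([30])
        with pytest.raises(GeneModelError):
            build_transcript(model, seq, set())

    def test_strand_symmetry(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            seq, model = random_gene_model(rng)
            t1, _ = build_transcript(model, seq)
            t2, _ = build_transcript(*reversed(flip_locus(seq, model)))
            assert t1.residues == t2.residues


class TestGff3:
    def test_single_exon_gene(self, tmp_path):
        f = tmp_path / "one.gff3"
        f.write_text(
            "##gff-version 3\n"
            "chr1\tx\tgene\t100\t190\t.\t+\t.\tID=g1\n"
            "chr1\tx\tmRNA\t100\t190\t.\t+\t.\tID=g1.t1;Parent=g1\n"
            "chr1\tx\texon\t100\t190\t.\t+\t.\tID=e1;Parent=g1.t1\n"
            "chr1\tx\tCDS\t100\t190\t.\t+\t0\tID=c1;Parent=g1.t1\n"
        )
        m = parse_gff3_gene(f, "g1")
        assert len(m.exons) == 1
        e = m.exons[0]
        assert (e.coding_start, e.coding_end) == (e.genomic_start, e.genomic_end)

    def test_write_parse_roundtrip(self, tmp_path, default_locus):
        _, model, _ = default_locus
        f = tmp_path / "rt.gff3"
        write_gff3(model, f)
        assert parse_gff3_gene(f, model.gene_id) == model

    def test_synthetic_11_exon_fixture(self, tmp_path, default_locus):
        _, model, _ = default_locus
        f = tmp_path / "c16.gff3"
        write_gff3(model, f)
        m = parse_gff3_gene(f, "CASP16LIKE")
        assert len(m.exons) == 11
        assert m.exons[0].coding_start is None  # exon 1 fully untranslated
        assert m.start_codon_exon == 2

    def test_phase_mismatch_warns(self, tmp_path):
        f = tmp_path / "bad_phase.gff3"
        f.write_text(
            "##gff-version 3\n"
            "chr1\tx\tgene\t1\t200\t.\t+\t.\tID=g1\n"
            "chr1\tx\texon\t1\t90\t.\t+\t.\tID=e1;Parent=g1\n"
            "chr1\tx\texon\t101\t200\t.\t+\t.\tID=e2;Parent=g1\n"
            "chr1\tx\tCDS\t1\t90\t.\t+\t0\tID=c1;Parent=g1\n"
            "chr1\tx\tCDS\t101\t200\t.\t+\t2\tID=c2;Parent=g1\n"  # should be 0
        )
        with pytest.warns(UserWarning, match="disagrees"):
            parse_gff3_gene(f, "g1")

    def test_cds_outside_exon_rejected(self, tmp_path):
        f = tmp_path / "stray.gff3"
        f.write_text(
            "##gff-version 3\n"
            "chr1\tx\tgene\t1\t200\t.\t+\t.\tID=g1\n"
            "chr1\tx\texon\t1\t90\t.\t+\t.\tID=e1;Parent=g1\n"
            "chr1\tx\tCDS\t120\t180\t.\t+\t0\tID=c1;Parent=g1\n"
        )
        with pytest.raises(GeneModelError, match="outside"):
            parse_gff3_gene(f, "g1")

    def test_minus_strand_transcription_order(self, tmp_path, default_locus):
        seq, model, _ = default_locus
        fseq, fmodel = flip_locus(seq, model)
        f = tmp_path / "minus.gff3"
        write_gff3(fmodel, f)
        m = parse_gff3_gene(f, fmodel.gene_id)
        assert m.strand == "-"
        assert m.exons[0].genomic_start > m.exons[-1].genomic_start
        t1, _ = build_transcript(model, seq)
        t2, _ = build_transcript(m, fseq)
        assert t1.residues == t2.residues


class TestFlankingSynteny:
    def test_neighbor_on_5prime_side(self):
        locus = [("ZNF213", 100), ("CASP16", 500)]
        assert check_flanking_synteny(locus, "CASP16", "ZNF213", "5prime")

    def test_lone_gene_has_no_neighbor(self):
        with pytest.raises(GeneModelError, match="no neighbor"):
            check_flanking_synteny([("CASP16", 500)], "CASP16", "ZNF213", "5prime")

    def test_neighbor_placed_3prime_fails_5prime_check(self):
        locus = [("CASP16", 100), ("ZNF213", 900), ("OTHER", 1500)]
        assert not check_flanking_synteny(locus, "CASP16", "ZNF213", "5prime")
        assert check_flanking_synteny(locus, "CASP16", "ZNF213", "3prime")

    def test_minus_strand_target_flips_sides(self):
        locus = [("ZNF213", 100), ("CASP16", 500)]
        assert check_flanking_synteny(locus, "CASP16", "ZNF213", "3prime",
                                      target_strand="-")

    def test_absent_target_rejected(self):
        with pytest.raises(GeneModelError, match="not in locus"):
            check_flanking_synteny([("A", 1)], "B", "A", "5prime")
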