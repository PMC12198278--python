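"""Intra-protein duplication detection, exon attribution and phase
signatures."""

import numpy as np
import pytest

from pseudocasp.domain_duplication import (
    exon_correspondence,
    map_exon_homology,
    phase_signature,
    phase_signature_compare,
    self_compare,
    split_by_exon,
)
from pseudocasp.gene_models import Exon, GeneModel
from pseudocasp.sequence_core import PepSequence, translate_cds
from pseudocasp.synthetic_data import random_gene_model
from pseudocasp.gene_models import extract_cds


def _coding_model(coding_lengths, with_stop=True):
    exons = []
    pos = 1
    for i, ln in enumerate(coding_lengths, start=1):
        exons.append(Exon(i, pos, pos + ln - 1, pos, pos + ln - 1))
        pos += ln + 10
    return GeneModel("g", "s", "+", tuple(exons), 1)


class TestSplitByExon:
    def test_single_exon_is_whole_protein(self):
        model = _coding_model([33])  # 10 codons + stop
        prot = PepSequence("p", "MAAAAAAAAA")
        (seg,) = split_by_exon(prot, model)
        assert seg.peptide.residues == prot.residues
        assert seg.ref_residue_span == (1, 10)

    def test_two_exons_nine_plus_nine(self):
        model = _coding_model([9, 12])  # 9+9 coding nt plus stop
        prot = PepSequence("p", "MAARRR")
        segs = split_by_exon(prot, model)
        assert [s.peptide.residues for s in segs] == ["MAA", "RRR"]
        assert [s.ref_residue_span for s in segs] == [(1, 3), (4, 6)]

    def test_junction_codon_goes_to_majority_exon(self):
        # exon 1 contributes 10 nt: codon 4 gets 1 nt from exon 1, 2 from
        # exon 2, so residue 4 belongs to exon 2
        model = _coding_model([10, 11])
        prot = PepSequence("p", "MAAAAAA")
        segs = split_by_exon(prot, model)
        assert segs[0].ref_residue_span == (1, 3)
        assert segs[1].ref_residue_span == (4, 7)

    def test_reconstruction_oracle_on_random_models(self):
        rng = np.random.default_rng(61)
        for _ in range(25):
            seq, model = random_gene_model(rng)
            cds, _, _ = extract_cds(model, seq)
            prot = translate_cds(cds, 0).peptide
            segs = split_by_exon(prot, model)
            assert "".join(s.peptide.residues for s in segs) == prot.residues
            spans = [s.ref_residue_span for s in segs]
            assert spans[0][0] == 1 and spans[-1][1] == len(prot)
            assert all(a[1] + 1 == b[0] for a, b in zip(spans, spans[1:]))

    def test_length_mismatch_rejected(self):
        model = _coding_model([33])
        with pytest.raises(Exception, match="inconsistent"):
            split_by_exon(PepSequence("p", "MA"), model)


class TestSelfCompare:
    def test_exact_tandem_repeat(self):
        prot = PepSequence("p", "MKVLTEWCDFGHIRNPQSAYMKVLTEWCDFGHIRNPQSAY")
        (hit,) = self_compare(prot, min_len=15, n_permutations=50, seed=1,
                              max_hits=1)
        assert hit.query_span == (1, 20) and hit.subject_span == (21, 40)
        assert hit.identity_pct == 100.0

    def test_too_short_protein_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="too short"):
            assert self_compare(PepSequence("p", "MKVLTEW"), min_len=20,
                                n_permutations=10, seed=0) == []

    def test_deterministic_under_seed(self, default_locus):
        _, _, manifest = default_locus
        h1 = self_compare(manifest.derived_protein, n_permutations=60, seed=9)
        h2 = self_compare(manifest.derived_protein, n_permutations=60, seed=9)
        assert [(h.query_span, h.subject_span, h.empirical_p) for h in h1] == \
            [(h.query_span, h.subject_span, h.empirical_p) for h in h2]
        for h in h1:
            assert h.query_span[1] < h.subject_span[0]  # non-overlap

    def test_null_proteins_rarely_significant(self):
        """Composition-matched random proteins: empirical p <= 0.05 at about
        the nominal 5% rate (conservative estimator), so the no-hit fraction
        stays within sampling noise of 95%."""
        rng = np.random.default_rng(71)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        n_trials, n_sig = 100, 0
        for t in range(n_trials):
            res = "".join(rng.choice(aas, size=120))
            hits = self_compare(PepSequence("null", res), min_len=5,
                                n_permutations=99, seed=1000 + t, max_hits=1)
            if hits and hits[0].empirical_p <= 0.05:
                n_sig += 1
        # binomial(100, 0.05): 3 sigma above the mean is ~11.5
        assert n_sig <= 12

    def test_divergent_duplicate_recovered(self, default_locus):
        _, model, manifest = default_locus
        hits = self_compare(manifest.derived_protein, n_permutations=100, seed=5)
        assert hits and hits[0].empirical_p <= 0.05
        qs, ss = hits[0].query_span, hits[0].subject_span
        # the duplication plan: prodomain (1-196) copies catalytic (197-416)
        assert qs[0] <= 10 and qs[1] >= 180
        assert ss[0] <= 210 and ss[1] >= 400


class TestExonHomology:
    def test_synthetic_correspondence_matches_duplication_plan(self, default_locus):
        _, model, manifest = default_locus
        hits = self_compare(manifest.derived_protein, n_permutations=50, seed=5)
        hits, table = map_exon_homology(hits, model, manifest.derived_protein)
        corr = exon_correspondence(table)
        # prodomain exons 2-3 map into large-subunit exons 6-7; 4-5 into
        # small-subunit exons 10-11
        assert set(corr[2]) <= {6, 7} and corr[2]
        assert set(corr[3]) <= {6, 7} and corr[3]
        assert set(corr[4]) <= {10, 11} and corr[4]
        assert set(corr[5]) <= {10, 11} and corr[5]
        assert set(hits[0].query_exons) <= {2, 3, 4, 5}
        assert set(hits[0].subject_exons) <= {6, 7, 10, 11}
        # linker exons 8-9 are bridged by a gap, never attributed
        assert 8 not in hits[0].subject_exons and 9 not in hits[0].subject_exons

    def test_duplication_across_two_exons(self):
        # one exact duplication split across two exons maps {1} -> {2}
        half = "MKVLTEWCDFGHIRNPQSAY"
        model = _coding_model([60, 63])
        prot = PepSequence("p", half + half)
        hits = self_compare(prot, min_len=15, n_permutations=50, seed=2,
                            max_hits=1)
        hits, table = map_exon_homology(hits, model, prot)
        assert hits[0].query_exons == (1,) and hits[0].subject_exons == (2,)


class TestPhaseSignatures:
    def test_identical_models_agree_fully(self, default_locus):
        _, model, _ = default_locus
        t = phase_signature_compare([model, model])
        assert t.loc[0, "lcs_length"] == t.loc[0, "n_junctions_a"]
        assert t.loc[0, "agreement_a"] == 1.0

    def test_ancestral_vs_derived_lcs_contains_ancestral_signature(self, default_locus):
        """The 8-exon ancestral gene's coding-junction phases survive the
        duplication: its full signature is a subsequence of the derived
        11-exon gene's signature."""
        _, model, manifest = default_locus
        anc = manifest.ancestral_model
        t = phase_signature_compare([anc, model])
        assert t.loc[0, "lcs_length"] == len(phase_signature(anc).phases)

    def test_duplicated_block_phases_appear_twice(self, default_locus):
        _, model, manifest = default_locus
        sig = phase_signature(model).phases
        # prodomain-internal junction phases (exons 2-5) reappear among the
        # catalytic-region junction phases (exons 6-11)
        pro = sig[:3]       # junctions (2,3), (3,4), (4,5)
        cat = sig[4:]       # junctions (6,7) onward
        it = iter(cat)
        assert all(p in it for p in pro)  # subsequence test

    def test_model_without_junctions_skipped(self):
        single = _coding_model([33])
        other = _coding_model([30, 33])
        with pytest.warns(UserWarning, match="no coding junctions"):
            t = phase_signature_compare([single, other, other])
        assert len(t) == 1
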