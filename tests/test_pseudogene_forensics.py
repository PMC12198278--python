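"""Frameshift propagation, PTC location, exon-skip rescue, rescue ORFs,
dyad checks and classification."""

import numpy as np
import pytest

from pseudocasp.gene_models import extract_cds
from pseudocasp.pairwise_align import IndelEvent
from pseudocasp.pseudogene_forensics import (
    DyadReport,
    ForensicsError,
    check_catalytic_dyad,
    classify_gene_status,
    evaluate_exon_skip,
    find_rescue_orf,
    locate_ptc,
    run_forensics,
    skip_translation_restores,
)
from pseudocasp.sequence_core import PepSequence, translate_cds
from pseudocasp.synthetic_data import (
    Lesion,
    flip_locus,
    apply_lesions,
    generate_caspase16_like_locus,
    inject_lesions,
    random_gene_model,
)


def _exon_cds_offset(model, exon):
    return sum(e.coding_length for e in model.exons if e.index < exon)


def _random_single_lesion(rng, model):
    """A frame-shifting indel in a random internal coding exon, at least
    11 nt away from both coding edges."""
    candidates = [
        e for e in model.coding_exons
        if e.index not in (1, len(model.exons))
        and e.index != model.start_codon_exon
        and e.coding_length > 30
    ]
    if not candidates:
        return None
    e = candidates[int(rng.integers(0, len(candidates)))]
    length = int(rng.integers(1, 3))  # 1 or 2 nt: always frame-shifting
    kind = "deletion" if rng.integers(0, 2) == 0 else "insertion"
    pos = int(rng.integers(11, e.coding_length - 10 - length))
    lesion = Lesion(kind, exon=e.index, position=pos, length=length,
                    replacement="G" * length if kind == "insertion" else "")
    off = _exon_cds_offset(model, e.index)
    ref_pos = off + pos - 1 if kind == "deletion" else off + pos
    event = IndelEvent(kind, ref_pos=ref_pos, length=length)
    return lesion, event


class TestLocatePtc:
    def test_canonical_deletion_six_triplets_and_105_residues(self, casp16p_scenario):
        s = casp16p_scenario
        events = [IndelEvent("deletion", ref_pos=298, length=1)]
        report = locate_ptc(s["model"], s["seq"], events)
        assert report.codons_downstream_to_stop == 6
        assert report.truncated_length == 105
        assert "*" not in report.truncated_peptide.residues

    def test_matches_translate_and_scan_oracle(self):
        rng = np.random.default_rng(41)
        checked = 0
        for _ in range(40):
            seq, model = random_gene_model(rng, minus_strand=False)
            drawn = _random_single_lesion(rng, model)
            if drawn is None:
                continue
            lesion, event = drawn
            lseq, lmodel = apply_lesions(seq, model, [lesion])
            if rng.integers(0, 2):
                lseq, lmodel = flip_locus(lseq, lmodel)
            cds, _, _ = extract_cds(lmodel, lseq)
            out = translate_cds(cds, 0)
            if not out.stop_found:
                continue
            report = locate_ptc(lmodel, lseq, [event])
            # independent oracle: translate-and-scan from the start codon
            assert report.truncated_length == len(out.peptide)
            q_d = event.ref_pos if event.kind == "deletion" else event.ref_pos
            disrupted = (q_d + 2) // 3
            assert report.codons_downstream_to_stop == \
                out.stop_codon_index + 1 - disrupted
            checked += 1
        assert checked >= 20

    def test_no_lesion_raises(self, default_locus):
        seq, model, _ = default_locus
        with pytest.raises(ForensicsError, match="no lesion"):
            locate_ptc(model, seq, [])

    def test_stop_substitution_without_indel(self, default_locus):
        seq, model, manifest = default_locus
        lseq, lmodel, lman = inject_lesions(seq, model, manifest,
                                            "stop-substitution")
        report = locate_ptc(lmodel, lseq, [])
        assert report.causal_event is None
        assert report.truncated_length == lman.expected["truncated_length"]


class TestEvaluateExonSkip:
    def test_exon3_skip_removes_lesion_but_not_frame(self, casp16p_scenario):
        s = casp16p_scenario
        events = [IndelEvent("deletion", ref_pos=298, length=1)]
        v = evaluate_exon_skip(s["model"], 3, events, s["seq"])
        assert v.removes_lesion and not v.frame_restored
        assert v.explanation.end_phase_upstream == 0
        assert v.explanation.start_phase_downstream == 1

    def test_mod3_exon_with_only_lesion_restores(self):
        # an exon whose pre-lesion coding length is a multiple of 3 and that
        # contains the only frameshift: skipping it restores the frame
        rng = np.random.default_rng(43)
        found = 0
        while found < 5:
            seq, model = random_gene_model(rng, minus_strand=False)
            mod3 = [
                e for e in model.coding_exons
                if e.index not in (1, len(model.exons))
                and e.index != model.start_codon_exon
                and e.coding_length % 3 == 0 and e.coding_length > 30
            ]
            if not mod3:
                continue
            e = mod3[0]
            pos = int(rng.integers(11, e.coding_length - 12))
            lesion = Lesion("deletion", exon=e.index, position=pos, length=1)
            event = IndelEvent("deletion",
                               ref_pos=_exon_cds_offset(model, e.index) + pos - 1,
                               length=1)
            lseq, lmodel = apply_lesions(seq, model, [lesion])
            v = evaluate_exon_skip(lmodel, e.index, [event])
            assert v.removes_lesion and v.frame_restored
            found += 1

    def test_skipping_start_codon_exon_rejected(self, default_locus):
        seq, model, _ = default_locus
        with pytest.raises(ForensicsError, match="start-codon"):
            evaluate_exon_skip(model, 2, [])

    def test_frame_law_against_translation_oracle(self):
        """Randomized models with one frame-shifting lesion: the phase-based
        verdict must equal direct translation of the skip isoform, and a
        skip rescues iff the lesion's exon has pre-lesion coding length
        divisible by 3."""
        rng = np.random.default_rng(47)
        agree = total = 0
        for _ in range(120):
            seq, model = random_gene_model(rng, minus_strand=False)
            drawn = _random_single_lesion(rng, model)
            if drawn is None:
                continue
            lesion, event = drawn
            lseq, lmodel = apply_lesions(seq, model, [lesion])
            if rng.integers(0, 2):
                lseq, lmodel = flip_locus(lseq, lmodel)
            n = len(lmodel.exons)
            for e in lmodel.coding_exons:
                if e.index in (1, n) or e.index == lmodel.start_codon_exon:
                    continue
                v = evaluate_exon_skip(lmodel, e.index, [event])
                pre_lesion_len = model.exon(e.index).coding_length
                # the skip law: rescue iff the lesion's exon is skipped and
                # its pre-lesion coding length is a multiple of 3
                assert v.frame_restored == (
                    (e.index == lesion.exon) and pre_lesion_len % 3 == 0
                )
                oracle = skip_translation_restores(lmodel, lseq, (e.index,))
                # nucleotides missing from the ortholog frame if this exon
                # is skipped: the exon itself plus the lesion's net change
                removed = pre_lesion_len + (
                    lesion.length if lesion.kind == "deletion" else -lesion.length
                )
                if e.index != lesion.exon and removed % 3 == 0:
                    # removing this exon arithmetically cancels the lesion's
                    # shift: the product is garbled between the junction and
                    # the lesion but the downstream frame is restored, so the
                    # translation oracle may read through to the terminal
                    # stop.  frame_restored is False by definition (the
                    # lesion remains); the oracle is not constrained here.
                    assert not v.frame_restored
                else:
                    assert v.frame_restored == oracle, (
                        f"exon {e.index}, lesion in {lesion.exon}"
                    )
                    agree += 1
                total += 1
        assert total >= 200 and agree >= 0.6 * total

    def test_compensating_indels_restore_downstream_frame(self, default_locus):
        seq, model, manifest = default_locus
        lseq, lmodel, lman = inject_lesions(seq, model, manifest,
                                            "compensated-double-indel")
        assert lman.expected["net_frame_shift"] == 0
        assert lman.expected_status == "intact"
        cds, _, _ = extract_cds(lmodel, lseq)
        out = translate_cds(cds, 0)
        assert out.stop_found and 3 * (out.stop_codon_index + 1) == len(cds)


class TestRescueOrf:
    def test_canonical_rescue_in_exon7(self, casp16p_scenario):
        s = casp16p_scenario
        orf = find_rescue_orf(s["model"], s["seq"], s["ortholog_protein"])
        assert orf is not None
        assert orf.start_codon_exon == 7
        assert orf.ref_start_residue == s["manifest"].expected["rescue"]["ref_start_residue"]
        assert orf.ref_end_residue == len(s["ortholog_protein"])
        assert orf.orf_peptide.residues.startswith("M")

    def test_intact_gene_rescue_is_annotated_cds(self, casp16p_scenario):
        s = casp16p_scenario
        orf = find_rescue_orf(s["intact_model"], s["intact_seq"],
                              s["ortholog_protein"])
        assert orf.start_codon_exon == s["intact_model"].start_codon_exon
        assert orf.ref_start_residue == 1
        assert orf.ref_end_residue == len(s["ortholog_protein"])

    def test_recovered_exon_matches_manifest_across_seeds(self):
        for seed in (11, 12, 13):
            seq, model, manifest = generate_caspase16_like_locus(seed)
            lseq, lmodel, lman = inject_lesions(seq, model, manifest,
                                                "human-casp16p")
            orf = find_rescue_orf(lmodel, lseq, manifest.derived_protein)
            truth = lman.expected["rescue"]
            assert orf.start_codon_exon == truth["exon"]
            assert orf.ref_start_residue == truth["ref_start_residue"]
            assert len(orf.orf_peptide) == truth["orf_length"]


class TestCatalyticDyad:
    def test_protein_against_itself(self, default_locus):
        _, _, manifest = default_locus
        his, cys = manifest.dyad
        rep = check_catalytic_dyad(manifest.derived_protein,
                                   manifest.derived_protein, his, cys)
        assert rep.intact and (rep.his_pos, rep.cys_pos) == (his, cys)

    def test_cys_to_ser_substitution_detected(self, default_locus):
        _, _, manifest = default_locus
        his, cys = manifest.dyad
        res = list(manifest.derived_protein.residues)
        res[cys - 1] = "S"
        mutant = PepSequence("mut", "".join(res))
        rep = check_catalytic_dyad(mutant, manifest.derived_protein, his, cys)
        assert rep.his_pos == his and rep.cys_pos is None and not rep.intact

    def test_dyad_survives_divergence_when_protected(self):
        """Orthologs at ~5% residue divergence with the dyad untouched by
        construction keep an intact dyad report."""
        rng = np.random.default_rng(51)
        seq, model, manifest = generate_caspase16_like_locus(8)
        his, cys = manifest.dyad
        base = manifest.derived_protein.residues
        n_ok = 0
        for trial in range(30):
            res = list(base)
            k = max(1, int(0.05 * len(res)))
            sites = rng.choice(len(res), size=k, replace=False)
            for s in sites:
                if abs(s - (his - 1)) <= 2 or abs(s - (cys - 1)) <= 2:
                    continue  # dyad context preserved by construction
                res[s] = "ACDEFGIKLMNPQRSTVWY"[int(rng.integers(0, 19))]
            rep = check_catalytic_dyad(PepSequence("o", "".join(res)),
                                       manifest.derived_protein, his, cys)
            n_ok += rep.intact
        assert n_ok == 30

    def test_reference_positions_validated(self, default_locus):
        _, _, manifest = default_locus
        with pytest.raises(ForensicsError):
            check_catalytic_dyad(manifest.derived_protein,
                                 manifest.derived_protein, 0, 10)


class TestClassification:
    def test_scenario_grid_matches_manifest(self):
        """Every named lesion scenario classifies as its manifest truth."""
        for scen in ("human-casp16p", "in-frame-deletion", "dyad-knockout",
                     "stop-substitution", "compensated-double-indel"):
            seq, model, manifest = generate_caspase16_like_locus(2)
            ortho_cds, _, _ = extract_cds(model, seq)
            lseq, lmodel, lman = inject_lesions(seq, model, manifest, scen)
            rep = run_forensics(lmodel, lseq, ortho_cds, manifest.derived_protein,
                                *manifest.dyad,
                                tuple(manifest.expected["domain_window"]))
            assert rep.status.verdict == lman.expected_status, scen

    def test_unmodified_gene_is_intact(self, casp16p_scenario):
        s = casp16p_scenario
        rep = run_forensics(s["intact_model"], s["intact_seq"],
                            s["ortholog_cds"], s["ortholog_protein"],
                            227, 286, (197, 416))
        assert rep.status.verdict == "intact"
        assert not rep.events

    def test_adding_dyad_loss_never_unmakes_pseudogene(self, casp16p_scenario):
        """Classification monotonicity: a pseudogene verdict cannot revert
        to intact when another lesion (dyad loss) is added."""
        s = casp16p_scenario
        ptc = locate_ptc(s["model"], s["seq"],
                         [IndelEvent("deletion", ref_pos=298, length=1)])
        skips = [evaluate_exon_skip(s["model"], k,
                                    [IndelEvent("deletion", ref_pos=298, length=1)])
                 for k in range(3, 11)]
        rescue = find_rescue_orf(s["model"], s["seq"], s["ortholog_protein"])
        for dyad in (DyadReport(227, 286), DyadReport(227, None),
                     DyadReport(None, None)):
            status = classify_gene_status(ptc, skips, rescue, dyad, (197, 416))
            assert status.verdict == "pseudogene"

    def test_contradictory_truncation_rejected(self, default_locus):
        _, _, manifest = default_locus
        ptc_like = locate_ptc.__wrapped__ if hasattr(locate_ptc, "__wrapped__") else None
        from pseudocasp.pseudogene_forensics import PtcReport

        long_pep = PepSequence("x", "M" * 500)
        ptc = PtcReport(None, 0, long_pep, 500)
        with pytest.raises(ForensicsError, match="contradictory"):
            classify_gene_status(ptc, [], None, DyadReport(1, 2), (197, 416),
                                 reference_length=416)
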