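"""Operon extraction and comP allele classification against generator truth."""

import numpy as np
import pytest

from quorumcomp.genomes import (MutationSpec, make_reference_operon,
                                mutate_comP, revcomp)
from quorumcomp.operon import (assign_pherotype, classify_comP,
                               detect_polyT_hotspot, extract_comQXPA,
                               predicted_variant_length)
from quorumcomp.references import boundary_from_alignment


def classify(genome, refs):
    return classify_comP(extract_comQXPA(genome, refs), refs)


class TestExtract:
    def test_minus_strand_operon_is_reverse_complemented(self, refs):
        g = make_reference_operon("3610", seed=21, strand="-")
        rec = extract_comQXPA(g, refs)
        lo, hi = g.truth["operon_span"]
        assert rec.operon_seq == revcomp(g.contigs["chr1"][lo:hi])
        assert rec.strand == "-"
        # same operon sequence as the forward-strand genome
        fwd = extract_comQXPA(make_reference_operon("3610", seed=21), refs)
        assert rec.operon_seq == fwd.operon_seq

    def test_missing_comQ_is_flagged_not_fatal(self, refs, reference_genome):
        g = reference_genome.copy()
        g.features = [f for f in g.features if f.gene != "comQ"]
        rec = extract_comQXPA(g, refs)
        assert "comQ missing" in rec.completeness
        assert rec.genes["comP"] is not None

    def test_fragmented_operon_still_classifies_comP(self, refs, reference_genome):
        g = reference_genome.copy()
        # move comA onto its own contig
        coma = g.find_gene("comA")
        seq = g.feature_seq(coma)
        g.contigs["chr2"] = "A" * 50 + seq + "C" * 50
        g.features = [f for f in g.features if f.gene != "comA"]
        from quorumcomp.genomes import Feature
        g.features.append(Feature("chr2", 50, 50 + len(seq), "+", "comA"))
        rec = extract_comQXPA(g, refs)
        assert "fragmented" in rec.completeness
        assert classify_comP(rec, refs).status == "intact"

    def test_similarity_fallback_survives_name_drift(self, refs, reference_genome):
        from dataclasses import replace
        g = reference_genome.copy()
        g.features = [replace(f, gene=f"orf{i:03d}")
                      for i, f in enumerate(g.features)]
        rec = extract_comQXPA(g, refs)
        assert rec.genes["comP"] is not None
        assert classify_comP(rec, refs).status == "intact"

    def test_comP_missing_gives_undetermined(self, refs, reference_genome):
        g = reference_genome.copy()
        g.features = [f for f in g.features if f.gene != "comP"]
        g.contigs["chr1"] = "ACGT" * 200  # no similarity rescue possible
        call = classify_comP(extract_comQXPA(g, refs), refs)
        assert call.status == "undetermined"
        assert "missing" in call.reason


class TestClassify:
    def test_reference_is_intact(self, refs, reference_genome):
        call = classify(reference_genome, refs)
        assert call.status == "intact" and not call.classes
        assert call.predicted_length_aa == refs.comP_length_aa
        assert call.identity == pytest.approx(100.0)

    @pytest.mark.parametrize("spec,expected", [
        (MutationSpec("nonsense", 200, 1), {"nonsense"}),
        (MutationSpec("frameshift_indel", 350, 1), {"frameshift"}),
        (MutationSpec("frameshift_indel", 350, 2, deletion=True), {"frameshift"}),
        (MutationSpec("inframe_3prime_deletion", 633, 17),
         {"inframe_3prime_deletion"}),
        (MutationSpec("insertion_element", 400, 4), {"insertion_element"}),
        (MutationSpec("polyT_slip", size=1), {"frameshift"}),
    ])
    def test_each_disruption_class_is_called(self, refs, reference_genome,
                                             spec, expected):
        gm = mutate_comP(reference_genome, spec)
        call = classify(gm, refs)
        assert call.status == "disrupted"
        assert call.classes == expected

    def test_delta_633_649_is_17_aa_shorter_than_reference(self, refs,
                                                           reference_genome):
        gm = mutate_comP(reference_genome,
                         MutationSpec("inframe_3prime_deletion", 633, 17))
        call = classify(gm, refs)
        assert refs.comP_length_aa - call.predicted_length_aa == 17

    def test_point_substitution_is_not_disruptive(self, refs, reference_genome):
        # an E510K-style missense change must not be called disrupted
        g = reference_genome.copy()
        f = g.find_gene("comP")
        cds = g.feature_seq(f)
        off = 509 * 3
        new = "AAA" if cds[off:off + 3] != "AAA" else "GAA"
        g.contigs["chr1"] = (g.contigs["chr1"][:f.start + off] + new
                             + g.contigs["chr1"][f.start + off + 3:])
        call = classify(g, refs)
        assert call.status == "intact"

    def test_5prime_inframe_deletion_is_not_disruptive(self, refs,
                                                       reference_genome):
        # in-frame deletion upstream of the conserved-region boundary
        gm = mutate_comP(reference_genome,
                         MutationSpec("inframe_3prime_deletion", 100, 5))
        call = classify(gm, refs)
        assert "inframe_3prime_deletion" not in call.classes

    def test_strand_invariance_of_calls(self, refs):
        for spec in [MutationSpec("nonsense", 250, 1),
                     MutationSpec("frameshift_indel", 500, 1)]:
            calls = []
            for strand in "+-":
                g = make_reference_operon("3610", seed=33, strand=strand)
                calls.append(classify(mutate_comP(g, spec), refs))
            assert calls[0].classes == calls[1].classes
            assert calls[0].predicted_length_aa == calls[1].predicted_length_aa


class TestVariantLength:
    def test_reference_returns_reference_length(self, refs):
        vl = predicted_variant_length(refs.comP_cds, refs)
        assert vl.length_aa == refs.comP_length_aa and not vl.runs_off

    def test_stop_at_codon_k_gives_k_minus_1(self, refs, reference_genome):
        gm = mutate_comP(reference_genome, MutationSpec("nonsense", 412, 1))
        rec = extract_comQXPA(gm, refs)
        assert predicted_variant_length(rec.gene_seqs["comP"], refs).length_aa == 411

    def test_polyT_variant_matches_independent_translation_oracle(
            self, refs, reference_genome):
        gm = mutate_comP(reference_genome, MutationSpec("polyT_slip", size=1))
        rec = extract_comQXPA(gm, refs)
        seq = rec.comP_context
        # independent oracle: direct codon scan of the edited sequence
        stops = {"TAA", "TAG", "TGA"}
        oracle = next(i // 3 for i in range(0, len(seq) - 2, 3)
                      if seq[i:i + 3] in stops)
        assert predicted_variant_length(seq, refs).length_aa == oracle

    def test_missing_stop_flags_runs_off(self, refs):
        seq = "ATG" + "GCA" * 50
        vl = predicted_variant_length(seq, refs)
        assert vl.runs_off and vl.length_aa == 51


class TestHotspot:
    def test_reference_has_run_8_no_indel(self, refs):
        h = detect_polyT_hotspot(refs.comP_cds, refs)
        assert (h.present, h.run_length, h.indel_in_run) == (True, 8, False)

    @pytest.mark.parametrize("size,deletion,run", [(1, False, 9), (1, True, 7),
                                                   (2, False, 10)])
    def test_slip_variants_report_indel_in_run(self, refs, reference_genome,
                                               size, deletion, run):
        gm = mutate_comP(reference_genome,
                         MutationSpec("polyT_slip", size=size, deletion=deletion))
        rec = extract_comQXPA(gm, refs)
        h = detect_polyT_hotspot(rec.gene_seqs["comP"], refs)
        assert h.present and h.indel_in_run and h.run_length == run

    def test_other_pherotype_has_no_hotspot(self, refs):
        g = make_reference_operon("RO-E-2", seed=8)
        rec = extract_comQXPA(g, refs)
        assert not detect_polyT_hotspot(rec.gene_seqs["comP"], refs).present

    def test_position_stable_under_flank_change(self, refs, reference_genome):
        # 2 kb of different flanking sequence must not move the call
        g = reference_genome.copy()
        rng = np.random.default_rng(99)
        pad = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        from dataclasses import replace
        g.contigs["chr1"] = pad + g.contigs["chr1"]
        g.features = [replace(f, start=f.start + 2000, end=f.end + 2000)
                      for f in g.features]
        rec = extract_comQXPA(g, refs)
        h = detect_polyT_hotspot(rec.gene_seqs["comP"], refs)
        assert (h.present, h.run_length) == (True, 8)


class TestPherotype:
    def test_reference_comQ_assigns_itself_at_100(self, refs):
        for label, prot in refs.comQ_pherotypes.items():
            call = assign_pherotype(prot, refs)
            assert call.label == label
            assert call.identity == pytest.approx(100.0)

    def test_near_reference_variant_assigns_with_margin(self, refs):
        # ~95% identical to the 3610 reference: assigned to 3610
        prot = refs.comQ_pherotypes["3610"]
        rng = np.random.default_rng(3)
        idx = rng.choice(len(prot), size=len(prot) // 20, replace=False)
        mutated = "".join("W" if i in set(idx) else c
                          for i, c in enumerate(prot))
        call = assign_pherotype(mutated, refs)
        assert call.label == "3610" and call.identity >= 90.0

    def test_distant_comQ_is_unassigned(self, refs):
        rng = np.random.default_rng(5)
        prot = "".join("ACDEFGHIKLMNPQRSTVWY"[i]
                       for i in rng.integers(0, 20, 280))
        assert assign_pherotype(prot, refs).label == "unassigned"


class TestBoundaryHelper:
    def test_boundary_found_at_start_of_conserved_block(self):
        rng = np.random.default_rng(11)
        conserved = "".join("ACGT"[i] for i in rng.integers(0, 4, 600))
        rows = []
        for k in range(3):
            r2 = np.random.default_rng(20 + k)
            variable = "".join("ACGT"[i] for i in r2.integers(0, 4, 300))
            rows.append(variable + conserved)
        boundary = boundary_from_alignment(rows)
        assert abs(boundary - 101) <= 12  # 300 nt variable region = 100 codons
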