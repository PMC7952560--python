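"""Demultiplexing, per-well distributions, significance calling, codon effects."""

import numpy as np
import pytest

from deamtools.enrichment import (
    AssignedRead,
    BarcodeManifest,
    annotate_codon,
    call_significant,
    filter_reads,
    gapless_align,
    well_distributions,
)
from deamtools.simulate import simulate_amplicon_campaign


def read_tuple(seq, q=30):
    return (seq, [q] * len(seq))


GENE = "ATGGATAAGCTT"  # M D K L


class TestFilterReads:
    def test_exact_barcodes_assigned(self, tiny_manifest):
        seq = "AAAAAAAA" + GENE + "TTTTTTTT"
        assigned, stats = filter_reads([read_tuple(seq)], tiny_manifest)
        assert len(assigned) == 1
        assert assigned[0].well == "w1"
        assert assigned[0].sequence == GENE
        assert stats["assigned"] == 1

    def test_one_mismatch_tolerated_two_rejected(self, tiny_manifest):
        one_mm = "AAAAAAAT" + GENE + "TTTTTTTT"
        two_mm = "AAAAAATT" + GENE + "TTTTTTTT"
        assigned, stats = filter_reads(
            [read_tuple(one_mm), read_tuple(two_mm)], tiny_manifest
        )
        assert [a.well for a in assigned] == ["w1"]
        assert stats["unmatched_barcode"] == 1

    def test_ambiguous_tie_discarded(self):
        manifest = BarcodeManifest(
            wells={"a": ("AAAA", "TTTT"), "b": ("AAAT", "GGGG")}, max_mismatch=1
        )
        # front is distance 1 from both wells
        seq = "AAAG" + GENE + "TTTT"
        assigned, stats = filter_reads([read_tuple(seq)], manifest)
        assert assigned == []
        assert stats["ambiguous_barcode"] == 1

    def test_disagreeing_ends_discarded(self, tiny_manifest):
        seq = "AAAAAAAA" + GENE + "GGGGGGGG"  # front w1, back w2
        assigned, stats = filter_reads([read_tuple(seq)], tiny_manifest)
        assert assigned == []

    def test_low_mean_quality_dropped(self, tiny_manifest):
        seq = "AAAAAAAA" + GENE + "TTTTTTTT"
        assigned, stats = filter_reads(
            [read_tuple(seq, q=10)], tiny_manifest, min_quality=20
        )
        assert stats["low_quality"] == 1 and assigned == []

    def test_length_window_enforced(self, tiny_manifest):
        seq = "AAAAAAAA" + GENE + "TTTTTTTT"
        assigned, stats = filter_reads(
            [read_tuple(seq)], tiny_manifest, length_range=(100, 200)
        )
        assert stats["bad_length"] == 1 and assigned == []

    def test_generator_labels_recovered(self):
        records, manifest, gene, truth = simulate_amplicon_campaign(
            n_wells=6, reads_per_well=5, gene_length=60,
            driver=(10, "C", 0.5, 1.0), noise=(2, 1, 0.5), seed=42,
        )
        assigned, stats = filter_reads(records, manifest, min_quality=20)
        assert stats["assigned"] == len(records)
        # generator stores the true well in the record description
        for rec, ar in zip(records, assigned):
            assert rec.description == ar.well


class TestWellDistributions:
    def test_wild_type_well_matches_reference(self):
        reads = [AssignedRead("w1", GENE) for _ in range(10)]
        table = well_distributions(reads, GENE)
        freqs = table.frequencies("w1")
        base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        for i, b in enumerate(GENE):
            assert freqs[i, base_idx[b]] == 1.0

    def test_partial_mutation_frequency(self):
        mutant = GENE[:3] + "A" + GENE[4:]  # position 4 G>A
        reads = [AssignedRead("w1", mutant)] * 6 + [AssignedRead("w1", GENE)] * 4
        table = well_distributions(reads, GENE)
        assert table.frequencies("w1")[3, 0] == pytest.approx(0.6)

    def test_gap_only_column_removed_as_blank(self):
        gapped = GENE[:5] + "-" + GENE[6:]
        reads = [AssignedRead("w1", gapped)] * 3
        table = well_distributions(reads, GENE)
        assert table.blanks["w1"] == [6]
        assert table.frequencies("w1")[5].mask.all()

    def test_empty_well_flagged(self):
        reads = [AssignedRead("w1", GENE)]
        table = well_distributions(reads, GENE)
        table.counts["w2"] = np.zeros((len(GENE), 5), dtype=int)
        table.n_reads["w2"] = 0
        assert table.empty_wells == ["w2"]

    def test_gapless_aligner_places_fragment(self):
        frag = GENE[4:10]
        off, mm = gapless_align(frag, GENE)
        assert (off, mm) == (4, 0)


def make_table(reference, well_specs):
    """well_specs: {well: (n_reads, [(pos, alt, n_alt)])} with full coverage."""
    reads = []
    for well, (n_total, muts) in well_specs.items():
        seqs = [list(reference) for _ in range(n_total)]
        for pos, alt, n_alt in muts:
            for s in seqs[:n_alt]:
                s[pos - 1] = alt
        reads += [AssignedRead(well, "".join(s)) for s in seqs]
    return well_distributions(reads, reference)


class TestCallSignificant:
    REF = "ATGGATCAACTT"

    def test_four_wells_low_global_called(self):
        # ~2% global frequency but present in 4 wells -> called via well criterion
        specs = {f"w{i}": (5, [(4, "A", 1)]) for i in range(4)}  # 20% within well
        specs.update({f"x{i}": (5, []) for i in range(36)})
        table = make_table(self.REF, specs)
        calls = call_significant(table, f_global=0.10, n_wells=4, presence_floor=0.10)
        assert [(c.position, c.alt) for c in calls] == [(4, "A")]
        assert calls[0].global_frequency < 0.10
        assert calls[0].n_wells == 4

    def test_three_wells_low_global_not_called(self):
        specs = {f"w{i}": (5, [(4, "A", 1)]) for i in range(3)}
        specs.update({f"x{i}": (5, []) for i in range(37)})
        table = make_table(self.REF, specs)
        assert call_significant(table, f_global=0.10, n_wells=4) == []

    def test_high_global_single_well_called(self):
        specs = {"w0": (4, [(4, "A", 3)]), "x0": (4, []), "x1": (4, []), "x2": (4, [])}
        table = make_table(self.REF, specs)
        calls = call_significant(table, f_global=0.10, n_wells=4)
        assert [(c.position, c.alt) for c in calls] == [(4, "A")]
        assert calls[0].n_wells == 1

    def test_monotone_in_thresholds(self):
        specs = {f"w{i}": (5, [(4, "A", 2)]) for i in range(5)}
        specs.update({f"x{i}": (5, []) for i in range(5)})
        table = make_table(self.REF, specs)
        base = call_significant(table, f_global=0.10, n_wells=4)
        stricter = call_significant(table, f_global=0.5, n_wells=8)
        assert {(c.position, c.alt) for c in stricter} <= {
            (c.position, c.alt) for c in base
        }

    def test_global_frequency_boundary_exact(self):
        # exactly 10% pooled -> called; 9.9% -> not
        specs_at = {"w0": (50, [(4, "A", 10)]), "x0": (50, [])}
        table = make_table(self.REF, specs_at)
        calls = call_significant(table, f_global=0.10, n_wells=99)
        assert len(calls) == 1
        specs_below = {"w0": (500, [(4, "A", 99)]), "x0": (500, [])}
        table = make_table(self.REF, specs_below)
        assert call_significant(table, f_global=0.10, n_wells=99) == []

    def test_annotation_attached(self):
        specs = {"w0": (10, [(4, "A", 9)]), "x0": (10, [])}
        table = make_table(self.REF, specs)
        calls = call_significant(table, cds=self.REF)
        assert calls[0].codon == 2
        assert calls[0].aa_change == "D2N"
        assert calls[0].effect == "missense"


class TestAnnotateCodon:
    def test_gat_to_aat_is_d_to_n(self):
        # GAT codon, G>A at codon position 1 -> AAT: D->N
        cds = "ATG" + "GAT" + "TAA"
        codon, label, effect = annotate_codon(4, "A", cds)
        assert (codon, label, effect) == (2, "D2N", "missense")

    def test_caa_to_taa_is_stop(self):
        cds = "ATG" + "CAA" + "GGG"
        codon, label, effect = annotate_codon(4, "T", cds)
        assert (codon, label, effect) == (2, "Q2*", "nonsense")

    def test_silent_change(self):
        cds = "ATG" + "CTA" + "GGG"  # CTA(L) -> CTG(L)
        codon, label, effect = annotate_codon(6, "G", cds)
        assert effect == "silent"
        assert label == "L2L"

    def test_noncoding_outside_frame(self):
        codon, label, effect = annotate_codon(1, "G", "ATGCTA", frame_offset=2)
        assert effect == "noncoding"

    def test_round_trip_against_biopython(self):
        from Bio.Seq import Seq

        cds = "ATGGATCAACTTGGA"
        codon, label, effect = annotate_codon(7, "T", cds)
        mutated = cds[:6] + "T" + cds[7:]
        assert str(Seq(mutated).translate())[codon - 1] == label[-1]


class TestCampaignEndToEnd:
    def test_driver_sweep_called_exactly(self):
        records, manifest, gene, truth = simulate_amplicon_campaign(
            n_wells=40, reads_per_well=20, gene_length=120,
            driver=(31, "A", 0.85, 0.9), noise=(6, 2, 0.05), seed=77,
        )
        assigned, _ = filter_reads(records, manifest, min_quality=20)
        table = well_distributions(assigned, gene)
        calls = call_significant(table, f_global=0.10, n_wells=4, cds=gene)
        d = truth["driver"]
        assert [(c.position, c.alt) for c in calls] == [(d["position"], d["alt"])]
        assert calls[0].n_wells == len(d["wells"])
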