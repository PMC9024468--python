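"""Scanner correctness: oracle equivalence, strand handling, IO round-trips."""

import numpy as np
import pytest

from _oracles import naive_scan, placements_of

from stwintron import (
    PlantSpec,
    ScanReport,
    StwintronCandidate,
    make_stwintron,
    preset_model,
    random_background,
    read_candidates,
    reverse_complement,
    scan_genome,
    scan_sequence,
    write_candidates,
)
from stwintron.models import SpliceElementSpec, StwintronSearchModel


def _wide_model(name="wide"):
    """A custom superset of Model A (internal donor-BP widened to 25-110)."""
    a = preset_model("A")
    return StwintronSearchModel(
        "D12",
        SpliceElementSpec(
            donors=a.internal.donors,
            donor_bp_spacer=(25, 110),
            bp_acceptor_spacer=(4, 20),
        ),
        a.external,
        name=name,
    )


class TestScanSequence:
    def test_planted_stwintron_found_at_exact_coordinates(self, model_a, planted_a):
        flank5 = random_background(150, seed=31)
        flank3 = random_background(150, seed=32)
        seq = flank5 + planted_a.sequence + flank3
        hits = scan_sequence(seq, model_a, mode="exhaustive")
        spans = {(h.start, h.end) for h in hits}
        assert (150, 150 + len(planted_a.sequence)) in spans
        truth = tuple(150 + s for _, s, _ in planted_a.motif_spans)
        assert truth in placements_of(hits)

    def test_no_g_means_no_candidates(self, model_a):
        assert scan_sequence("C" * 1000, model_a) == []

    def test_candidate_sequence_starts_ggt_ends_ag(self, model_a, planted_a):
        hits = scan_sequence(planted_a.sequence, model_a, mode="exhaustive")
        for h in hits:
            assert h.sequence.startswith("GGT")
            assert h.sequence.endswith("AG")
            assert len(h.sequence) >= model_a.min_length

    def test_internal_span_removal_reconstitutes_external_donor(self, model_a, planted_a):
        (hit,) = scan_sequence(planted_a.sequence, model_a, mode="exhaustive")
        i0, i1 = hit.internal_intron_span
        external = hit.sequence[:i0] + hit.sequence[i1:]
        assert external[:6] in model_a.external.donors

    def test_spacer_90_invisible_to_model_a_visible_to_b(self, model_a, model_b):
        spec = PlantSpec.random("B", seed=41)
        spec = PlantSpec(
            model=spec.model,
            internal_donor=spec.internal_donor,
            external_donor=spec.external_donor,
            internal_bp=spec.internal_bp,
            external_bp=spec.external_bp,
            internal_acceptor=spec.internal_acceptor,
            external_acceptor=spec.external_acceptor,
            spacers=(90, spec.spacers[1], spec.spacers[2], spec.spacers[3]),
        )
        stw = make_stwintron(spec, seed=42, clean_against=(model_a,))
        assert scan_sequence(stw.sequence, model_a, mode="exhaustive") == []
        hits = scan_sequence(stw.sequence, model_b, mode="exhaustive")
        assert [(h.start, h.end) for h in hits] == [(0, len(stw.sequence))]

    def test_cctaac_external_bp_invisible_to_a_visible_to_d(self, model_a, model_d):
        spec = PlantSpec.random("D", seed=43)
        spec = PlantSpec(
            model=spec.model,
            internal_donor=spec.internal_donor,
            external_donor=spec.external_donor,
            internal_bp=spec.internal_bp,
            external_bp="CCTAAC",
            internal_acceptor=spec.internal_acceptor,
            external_acceptor=spec.external_acceptor,
            spacers=spec.spacers,
        )
        stw = make_stwintron(spec, seed=44, clean_against=(model_a,))
        assert scan_sequence(stw.sequence, model_a, mode="exhaustive") == []
        hits = scan_sequence(stw.sequence, model_d, mode="exhaustive")
        assert [(h.start, h.end) for h in hits] == [(0, len(stw.sequence))]

    def test_n_anywhere_in_span_suppresses_candidate(self, model_a, planted_a):
        seq = planted_a.sequence
        # place an N inside a spacer run
        bp_start = dict((n, (s, e)) for n, s, e in planted_a.motif_spans)["internal_bp"][0]
        mutated = seq[: bp_start - 2] + "N" + seq[bp_start - 1 :]
        assert scan_sequence(mutated, model_a, mode="exhaustive") == []
        assert scan_sequence(mutated, model_a, mode="greedy") == []

    def test_invalid_characters_reported_with_positions(self, model_a):
        with pytest.raises(ValueError, match="positions 2"):
            scan_sequence("ACXGT", model_a)

    def test_unknown_mode_rejected(self, model_a):
        with pytest.raises(ValueError, match="mode"):
            scan_sequence("ACGT", model_a, mode="eager")


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_exhaustive_equals_brute_force_on_random_sequences(self, model_a, seed):
        rng = np.random.default_rng(5000 + seed)
        length = int(rng.integers(1000, 2001))
        seq = random_background(length, gc=0.45, seed=rng)
        hits = scan_sequence(seq, model_a, mode="exhaustive")
        assert placements_of(hits) == naive_scan(seq, model_a)

    def test_exhaustive_equals_brute_force_on_planted(self, model_a, planted_a):
        seq = (
            random_background(200, seed=51)
            + planted_a.sequence
            + random_background(200, seed=52)
        )
        hits = scan_sequence(seq, model_a, mode="exhaustive")
        oracle = naive_scan(seq, model_a)
        assert placements_of(hits) == oracle
        assert oracle  # the planted stwintron is in there

    @pytest.mark.parametrize("seed", range(4))
    def test_greedy_is_subset_of_exhaustive(self, model_a, planted_a, seed):
        seq = (
            random_background(300, seed=60 + seed)
            + planted_a.sequence
            + random_background(300, seed=70 + seed)
        )
        greedy = placements_of(scan_sequence(seq, model_a, mode="greedy"))
        exhaustive = placements_of(scan_sequence(seq, model_a, mode="exhaustive"))
        assert greedy <= exhaustive


class TestScanGenome:
    def _two_contig_source(self, planted_a):
        c1 = random_background(800, seed=81)
        stw_rc = reverse_complement(planted_a.sequence)
        c2 = random_background(300, seed=82) + stw_rc + random_background(300, seed=83)
        return {"ctg1": c1, "ctg2": c2}

    def test_minus_strand_plant_reported_on_plus_coordinates(self, model_a, planted_a):
        contigs = self._two_contig_source(planted_a)
        report = scan_genome(contigs, [model_a], strands="both", mode="exhaustive")
        minus = [c for c in report.candidates if c.strand == "-"]
        assert len(minus) >= 1
        spans = {(c.contig_id, c.start, c.end) for c in minus}
        assert ("ctg2", 300, 300 + len(planted_a.sequence)) in spans
        hit = next(c for c in minus if c.start == 300)
        assert hit.sequence == planted_a.sequence  # reading orientation

    def test_plus_only_scan_misses_minus_plant(self, model_a, planted_a):
        contigs = self._two_contig_source(planted_a)
        report = scan_genome(contigs, [model_a], strands="+", mode="exhaustive")
        assert all(c.start != 300 or c.contig_id != "ctg2" for c in report.candidates)

    def test_strand_mirror_invariance(self, model_a, planted_a):
        seq = random_background(250, seed=84) + planted_a.sequence + random_background(250, seed=85)
        fwd = scan_genome({"c": seq}, [model_a], strands="both", mode="exhaustive")
        rev = scan_genome(
            {"c": reverse_complement(seq)}, [model_a], strands="both", mode="exhaustive"
        )
        n = len(seq)
        mirrored = {
            (n - c.end, n - c.start, {"+": "-", "-": "+"}[c.strand])
            for c in rev.candidates
        }
        assert {(c.start, c.end, c.strand) for c in fwd.candidates} == mirrored

    def test_multi_model_dedup_keeps_all_labels(self, model_a, planted_a):
        seq = random_background(100, seed=86) + planted_a.sequence + random_background(100, seed=87)
        report = scan_genome(
            {"c": seq}, [model_a, _wide_model()], strands="+", mode="exhaustive"
        )
        planted_span = (100, 100 + len(planted_a.sequence))
        hit = next(c for c in report.candidates if (c.start, c.end) == planted_span)
        assert set(hit.model_names) == {"A", "wide"}
        assert report.per_model["A"] >= 1 and report.per_model["wide"] >= 1

    def test_duplicate_contig_ids_rejected(self, model_a):
        pairs = [("c", "ACGT" * 30), ("c", "TTTT" * 30)]
        with pytest.raises(ValueError, match="duplicate contig"):
            scan_genome(pairs, [model_a])

    def test_empty_source_rejected(self, model_a, tmp_path):
        empty = tmp_path / "empty.fa"
        empty.write_text("")
        with pytest.raises(ValueError, match="FASTA"):
            scan_genome(empty, [model_a])

    def test_fasta_file_input(self, model_a, planted_a, tmp_path):
        fa = tmp_path / "g.fa"
        seq = random_background(100, seed=88) + planted_a.sequence + random_background(100, seed=89)
        fa.write_text(">ctg\n" + seq + "\n")
        report = scan_genome(fa, [model_a], strands="both", mode="exhaustive")
        assert any((c.start, c.end) == (100, 100 + len(planted_a.sequence))
                   for c in report.candidates)


class TestWriters:
    def _report(self, planted_a):
        cand = StwintronCandidate(
            contig_id="ctg",
            strand="+",
            start=100,
            end=100 + len(planted_a.sequence),
            motif_spans=planted_a.motif_spans,
            sequence=planted_a.sequence,
            model_names=("A",),
        )
        return ScanReport(candidates=[cand], mode="greedy")

    def test_gff3_coordinates_one_based_inclusive(self, planted_a, tmp_path):
        path = write_candidates(self._report(planted_a), tmp_path / "o.gff3", "gff3")
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        parent = lines[0].split("\t")
        assert (parent[2], parent[3], parent[4]) == (
            "stwintron", "101", str(100 + len(planted_a.sequence))
        )
        assert sum(1 for l in lines if l.split("\t")[2] == "motif") == 5

    def test_tsv_round_trip(self, planted_a, tmp_path):
        report = self._report(planted_a)
        path = write_candidates(report, tmp_path / "o.tsv", "tsv")
        back = read_candidates(path, "tsv")
        assert back.candidates == report.candidates

    def test_gff3_round_trip(self, planted_a, tmp_path):
        report = self._report(planted_a)
        path = write_candidates(report, tmp_path / "o.gff3", "gff3")
        back = read_candidates(path, "gff3")
        assert back.candidates == report.candidates

    def test_empty_report_writes_header_only(self, tmp_path):
        path = write_candidates(ScanReport(), tmp_path / "e.tsv", "tsv")
        assert path.read_text().splitlines() == ["\t".join(
            ["contig", "strand", "start", "end", "model_names", "stw_type",
             "motif_spans", "sequence"]
        )]

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            write_candidates(ScanReport(), tmp_path / "x", "vcf")
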