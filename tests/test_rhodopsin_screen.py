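"""Topology prediction, helix-7 motif location and rhodopsin classification."""

import pytest

import heliocontext as hc
from heliocontext.rhodopsin_screen import TMSegment, TopologyModel


def topology(spans, side="in", pid="p"):
    return TopologyModel(
        protein_id=pid,
        segments=[TMSegment(index=i + 1, start=a, end=b) for i, (a, b) in enumerate(spans)],
        n_terminus_side=side,
    )


class TestFallbackTopology:
    def test_planted_poly_leu_helices_recovered_within_two_residues(self):
        # 7 poly-Leu helices of 23 aa between Asn loops: the cleanest case
        seq = "N" * 24 + ("L" * 23 + "N" * 16) * 6 + "L" * 23 + "N" * 12
        starts = [25 + i * 39 for i in range(7)]
        pred = hc.predict_topology_fallback(seq)
        assert pred.n_tm == 7
        for seg, start in zip(pred.segments, starts):
            assert abs(seg.start - start) <= 2
            assert abs(seg.end - (start + 22)) <= 2

    def test_poly_gly_has_no_segments(self):
        pred = hc.predict_topology_fallback("G" * 150)
        assert pred.n_tm == 0
        assert pred.n_terminus_side == "unknown"

    @pytest.mark.parametrize("n_helices", [5, 6, 7, 8])
    def test_planted_helix_count_recovered(self, n_helices):
        seq, planted, _ = hc.generate_protein(n_helices, None, seed=3)
        pred = hc.predict_topology_fallback(seq)
        assert pred.n_tm == n_helices
        for a, b in zip(planted.segments, pred.segments):
            assert abs(a.start - b.start) <= 3 and abs(a.end - b.end) <= 3

    def test_positive_inside_rule_recovers_planted_side(self):
        for side in ("in", "out"):
            seq, _, _ = hc.generate_protein(7, None, seed=9, n_terminus_side=side)
            assert hc.predict_topology_fallback(seq).n_terminus_side == side

    def test_nonstandard_residues_tolerated(self):
        seq, _, _ = hc.generate_protein(7, None, seed=4)
        noisy = "X" + seq[1:]
        assert hc.predict_topology_fallback(noisy).n_tm == 7

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="100"):
            hc.predict_topology_fallback("L" * 99)


class TestLocateMotif:
    def seq_with(self, pos_residues, length=240):
        chars = ["A"] * length
        for pos, aa in pos_residues:
            chars[pos - 1] = aa
        return "".join(chars)

    def topo7(self):
        return topology([(s, s + 20) for s in range(10, 230, 32)][:6] + [(200, 222)])

    def test_sxxxk_found_at_first_matching_position(self):
        # TM7 spans 200-222 with S204..K208
        topo = topology([(i * 25 + 5, i * 25 + 24) for i in range(6)] + [(200, 222)])
        seq = self.seq_with([(204, "S"), (208, "K")])
        assert hc.locate_helix7_motif(seq, topo, "SxxxK") == 204

    def test_absent_anchor_residue_gives_none(self):
        topo = topology([(i * 25 + 5, i * 25 + 24) for i in range(6)] + [(200, 222)])
        seq = self.seq_with([(204, "S"), (208, "K")])
        assert hc.locate_helix7_motif(seq, topo, "DxxxK") is None

    def test_window_extends_three_residues_past_helix_boundary(self):
        topo = topology([(i * 25 + 5, i * 25 + 24) for i in range(6)] + [(200, 222)])
        # S two residues before TM7 start, K inside the helix
        seq = self.seq_with([(198, "S"), (202, "K")])
        assert hc.locate_helix7_motif(seq, topo, "SxxxK") == 198
        # four residues before the helix is outside the window
        seq = self.seq_with([(196, "S"), (200, "K")])
        assert hc.locate_helix7_motif(seq, topo, "SxxxK") is None

    def test_fewer_than_seven_segments_is_an_error(self):
        topo = topology([(10, 30), (40, 60)])
        with pytest.raises(ValueError, match="fewer than 7"):
            hc.locate_helix7_motif("A" * 100, topo, "SxxxK")

    def test_malformed_pattern_rejected(self):
        topo = topology([(i * 25 + 5, i * 25 + 24) for i in range(6)] + [(200, 222)])
        with pytest.raises(ValueError):
            hc.locate_helix7_motif("A" * 240, topo, "SxK")


class TestClassify:
    def test_planted_heliorhodopsin_called_with_motif_position(self, config):
        seq, _, pos = hc.generate_protein(7, ("SxxxK", 7), seed=21)
        call = hc.classify_rhodopsin("p", seq, None, config)
        assert call.verdict == "heliorhodopsin"
        assert call.motif_pos == pos
        assert call.reasons == []

    def test_planted_type1_called(self, config):
        seq, _, pos = hc.generate_protein(7, ("DxxxK", 7), seed=22)
        call = hc.classify_rhodopsin("p", seq, None, config)
        assert call.verdict == "type1"
        assert call.motif_pos == pos

    def test_six_tm_rejected_for_tm_count_even_with_motif(self, config):
        seq, topo, _ = hc.generate_protein(6, ("SxxxK", 6), seed=23)
        call = hc.classify_rhodopsin("p", seq, None, config)
        assert call.verdict == "rejected"
        assert "tm_count" in call.reasons

    def test_seven_tm_without_motif_rejected_no_motif(self, config):
        seq, _, _ = hc.generate_protein(7, None, seed=24)
        call = hc.classify_rhodopsin("p", seq, None, config)
        assert call.verdict == "rejected"
        assert call.reasons == ["no_motif"]

    def test_out_facing_n_terminus_warns_but_keeps_verdict(self, config):
        seq, _, pos = hc.generate_protein(7, ("SxxxK", 7), seed=25, n_terminus_side="out")
        call = hc.classify_rhodopsin("p", seq, None, config)
        assert call.verdict == "heliorhodopsin"
        assert "orientation_conflict" in call.reasons

    def test_both_motifs_prefers_heliorhodopsin_with_ambiguity_note(self, config):
        # supplied topology; S..K early in TM7, D..K later
        topo = topology([(i * 25 + 5, i * 25 + 24) for i in range(6)] + [(200, 222)])
        chars = ["A"] * 240
        for pos, aa in [(202, "S"), (206, "K"), (210, "D"), (214, "K")]:
            chars[pos - 1] = aa
        call = hc.classify_rhodopsin("p", "".join(chars), topo, config)
        assert call.verdict == "heliorhodopsin"
        assert call.motif_pos == 202
        assert "ambiguous_motif" in call.reasons

    def test_empty_sequence_is_hard_error(self, config):
        with pytest.raises(ValueError, match="empty"):
            hc.classify_rhodopsin("p", "", None, config)

    def test_every_protein_gets_exactly_one_verdict(self, config, cohort):
        genomes, _ = cohort
        for genome in genomes[:4]:
            calls = hc.screen_proteins(genome.proteins, config)
            assert len(calls) == len(genome.proteins)
            assert all(c.verdict in ("heliorhodopsin", "type1", "rejected") for c in calls)

    def test_classification_invariant_to_input_order(self, config, cohort):
        genomes, _ = cohort
        proteins = genomes[0].proteins
        reordered = dict(reversed(list(proteins.items())))
        assert hc.screen_proteins(proteins, config) == hc.screen_proteins(reordered, config)


class TestTopologyTable:
    def test_round_trip(self, tmp_path):
        from heliocontext.rhodopsin_screen import write_topology_table

        topos = {"p1": topology([(10, 30), (40, 62)], side="out", pid="p1")}
        write_topology_table(topos, tmp_path / "topo.tsv")
        back = hc.read_topology_table(tmp_path / "topo.tsv")
        assert back == topos
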