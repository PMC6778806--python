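"""Screening rules, mosaic detection, and the internal local aligner."""

import numpy as np
import pytest

from haplopsc.config import ScreenParams
from haplopsc.hetstats import TranscriptHetStats
from haplopsc.pscscreen import (AlignmentHit, AlignParams, classify_copy_number,
                                detect_mosaics, flag_haploid_het, local_align,
                                read_blast_tab, screen_contaminants,
                                screen_organelle, self_align, write_blast_tab)
from conftest import mutate, random_seq


def hit(q="t1", s="s1", ident=90.0, length=400, qs=1, qe=400, ss=1, se=400,
        e=1e-30, bits=500.0, mism=None, gaps=0):
    mism = mism if mism is not None else int(round(length * (1 - ident / 100)))
    return AlignmentHit(q, s, ident, length, mism, gaps, qs, qe, ss, se, e, bits)


class TestHaploidHetFlag:
    def stat(self, contig, n_het, n_sites=500):
        n_obs = n_sites * 6
        return TranscriptHetStats(contig, "ME", n_sites, n_obs, n_het,
                                  n_het / n_obs, 0.0, 0.0, n_sites, 12)

    def test_zero_het_not_flagged(self):
        flags = flag_haploid_het([self.stat("a", 0)])
        assert flags["a"] is False

    def test_single_het_call_flags(self):
        flags = flag_haploid_het([self.stat("a", 1)])
        assert flags["a"] is True

    def test_below_min_callable_unassessed(self):
        flags = flag_haploid_het([self.stat("a", 1, n_sites=100)])
        assert "a" not in flags


class TestCopyNumber:
    def test_two_overlapping_high_identity_hits_multi(self):
        # 1000-bp transcript, two 90%-identity hits both spanning 200-600
        # after the 10-bp edge trim -> some position covered twice -> multi
        hits = [hit(qs=190, qe=610, ss=1, se=421),
                hit(s="s2", qs=190, qe=610, ss=1001, se=1421)]
        out = classify_copy_number(hits, {"t1": 1000})
        assert out["t1"] == "multi"

    def test_single_covering_hit(self):
        # one 95%-identity hit covering 100-700: 600-20 = 580 bp >= 500 -> single
        hits = [hit(ident=95.0, qs=100, qe=700, length=601)]
        assert classify_copy_number(hits, {"t1": 1000})["t1"] == "single"

    def test_short_hit_unassigned(self):
        hits = [hit(qs=1, qe=30, length=30)]
        assert classify_copy_number(hits, {"t1": 1000})["t1"] == "unassigned"

    def test_identity_at_85_is_not_multi(self):
        # the multi-copy rule is strictly > 85%
        hits = [hit(ident=85.0, qs=1, qe=600), hit(ident=85.0, s="s2", qs=1, qe=600)]
        out = classify_copy_number(hits, {"t1": 1000})
        assert out["t1"] == "single"  # coverage still counts for single-copy

    def test_edge_trim_separates_adjacent_hits(self):
        # overlap only within the trimmed 10-bp edges -> not multi
        hits = [hit(qs=1, qe=500, ss=1, se=500),
                hit(s="s2", qs=495, qe=1000, ss=1, se=506)]
        out = classify_copy_number(hits, {"t1": 1000})
        assert out["t1"] == "single"

    def test_tiny_alignment_ignored(self):
        # aln_len <= 2*edge_trim leaves an empty trimmed interval
        hits = [hit(qs=100, qe=115, length=16), hit(s="s2", qs=100, qe=115, length=16)]
        assert classify_copy_number(hits, {"t1": 1000})["t1"] == "unassigned"

    def test_no_hits_unassigned(self):
        assert classify_copy_number([], {"t1": 1000})["t1"] == "unassigned"


class TestMosaics:
    def test_full_length_self_match_not_mosaic(self):
        hits = [hit(q="a", s="a", ident=100.0, qs=1, qe=900, ss=1, se=900)]
        assert detect_mosaics(hits)["a"] is False

    def test_internal_duplication_is_mosaic(self):
        hits = [hit(q="a", s="a", ident=100.0, qs=1, qe=900, ss=1, se=900),
                hit(q="a", s="a", ident=98.0, qs=1, qe=300, ss=501, se=800)]
        assert detect_mosaics(hits)["a"] is True

    def test_invariant_to_interval_swap_and_order(self):
        a = hit(q="a", s="a", ident=98.0, qs=1, qe=300, ss=501, se=800)
        b = hit(q="a", s="a", ident=98.0, qs=501, qe=800, ss=1, se=300)
        full = hit(q="a", s="a", ident=100.0, qs=1, qe=900, ss=1, se=900)
        for hits in ([a, full], [full, a], [b, full], [full, b, a]):
            assert detect_mosaics(hits)["a"] is True

    def test_cross_contig_hits_ignored(self):
        hits = [hit(q="a", s="b", ident=98.0, qs=1, qe=300, ss=501, se=800)]
        assert "a" not in detect_mosaics(hits)


class TestOrganelleContaminantScreens:
    @pytest.mark.parametrize("e,ident,expect", [
        (1e-3, 85.0, True),
        (0.2, 95.0, False),   # e-value above 5e-2
        (1e-3, 79.0, False),  # identity below 80
        (5e-2, 80.0, True),   # both at boundary (<= and >=)
    ])
    def test_organelle_rule(self, e, ident, expect):
        flags = screen_organelle([hit(e=e, ident=ident)])
        assert flags["t1"] is expect

    def test_no_hits_false(self):
        assert screen_organelle([]) == {}

    @pytest.mark.parametrize("e,ident,expect", [
        (1e-6, 70.0, True),
        (1e-6, 60.0, False),
        (1e-4, 90.0, False),
        (1e-5, 65.0, True),  # boundary
    ])
    def test_contaminant_rule(self, e, ident, expect):
        flags = screen_contaminants([hit(e=e, ident=ident)])
        assert flags["t1"] is expect

    def test_screens_monotone_in_thresholds(self):
        # relaxing a threshold never unflags
        hits = [hit(e=1e-3, ident=82.0)]
        strict = screen_organelle(hits, ScreenParams(organelle_identity=85.0))
        relaxed = screen_organelle(hits, ScreenParams(organelle_identity=80.0))
        assert (not strict["t1"]) or relaxed["t1"]
        assert relaxed["t1"]


def sw_oracle(a: str, b: str):
    """Optimal Smith-Waterman local alignment via Bio.Align (oracle)."""
    from Bio import Align

    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = 1
    al.mismatch_score = -2
    al.open_gap_score = -5
    al.extend_gap_score = -2
    aln = al.align(a, b)[0]
    qs, qe = int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1])
    matches = sum((aln[0][i] == aln[1][i]) for i in range(aln.length))
    return qs, qe, matches, aln.length


class TestLocalAligner:
    def test_identical_sequences_full_length_hit(self):
        rng = np.random.default_rng(1)
        s = random_seq(rng, 500)
        hits = local_align(s, s)
        assert len(hits) == 1
        h = hits[0]
        assert (h.q_start, h.q_end, h.s_start, h.s_end) == (1, 500, 1, 500)
        assert h.pct_identity == 100.0
        assert h.mismatches == 0

    def test_single_substitution_identity(self):
        rng = np.random.default_rng(2)
        a = random_seq(rng, 200)
        b = mutate(a, [100], rng)
        hits = local_align(a, b)
        assert len(hits) == 1
        h = hits[0]
        assert h.aln_len == 200
        assert h.pct_identity == pytest.approx(99.5)
        # Smith-Waterman oracle agrees on span and matches
        qs, qe, matches, length = sw_oracle(a, b)
        assert (h.q_start - 1, h.q_end) == (qs, qe)
        assert h.aln_len - h.mismatches == matches

    @pytest.mark.parametrize("n_subs", [2, 5, 10])
    def test_scattered_substitutions_match_sw_oracle(self, n_subs):
        rng = np.random.default_rng(n_subs)
        a = random_seq(rng, 400)
        pos = rng.choice(np.arange(30, 370), size=n_subs, replace=False)
        b = mutate(a, pos, rng)
        (h,) = local_align(a, b)
        qs, qe, matches, length = sw_oracle(a, b)
        assert (h.q_start - 1, h.q_end) == (qs, qe)
        assert h.aln_len - h.mismatches == matches

    def test_unrelated_sequences_no_hit(self):
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            a, b = random_seq(rng, 300), random_seq(rng, 300)
            assert local_align(a, b) == []

    def test_duplicated_block_selfhits_feed_mosaic_detection(self):
        rng = np.random.default_rng(9)
        block = random_seq(rng, 300)
        filler = random_seq(rng, 200)
        seq = block + filler + mutate(block, [10, 50, 200], rng)
        hits = self_align({"st": seq})
        assert detect_mosaics(hits)["st"] is True
        # and a plain sequence is not mosaic
        plain = random_seq(rng, 800)
        assert detect_mosaics(self_align({"plain": plain}))["plain"] is False

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            local_align("", "ACGT" * 100)

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        a = random_seq(rng, 300)
        b = mutate(a, [50, 150], rng)
        assert local_align(a, b) == local_align(a, b)


class TestBlastTabIO:
    def test_roundtrip(self, tmp_path):
        hits = [hit(), hit(q="t2", ident=77.7, e=1e-10)]
        p = tmp_path / "hits.tsv"
        write_blast_tab(hits, p)
        back = read_blast_tab(p)
        assert len(back) == 2
        assert back[0].query_id == "t1"
        assert back[1].pct_identity == pytest.approx(77.7)
        assert back[1].evalue == pytest.approx(1e-10)
        assert (back[0].q_start, back[0].q_end) == (1, 400)


class TestTruthAgreement:
    def test_alignment_copy_class_agrees_with_provenance(self, paralog_truth):
        """Multi-copy flags from alignment hits vs truth provenance agree on
        >95% of transcripts at detectable divergence."""
        from haplopsc.simcore import build_reference, decode
        from haplopsc.pscscreen import align_many

        truth = paralog_truth  # 2% divergence, all genes in families
        contigs = build_reference(truth, "redundant")
        subjects = {g.gene_id: decode(g.ancestral) for g in truth.genes}
        params = AlignParams(min_identity=80.0)
        agree = 0
        total = 0
        for c in contigs[:40]:
            hits = align_many({c.contig_id: c.sequence}, subjects, params)
            out = classify_copy_number(hits, {c.contig_id: c.length})
            # every gene has a 2%-divergent partner -> truth says multi
            total += 1
            agree += out[c.contig_id] == "multi"
        assert agree / total > 0.95
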