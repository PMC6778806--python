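"""Truth-set simulation: SFS calibration, family design, reference building
and the mapping emulation."""

import itertools

import numpy as np
import pytest

from haplopsc import (SimConfig, build_reference, simulate_population,
                      simulate_site_evidence)
from haplopsc._seq import decode, encode, hamming


def pool_pairwise_diversity_oracle(pool: np.ndarray) -> float:
    """Average Hamming distance per bp over all haplotype pairs (brute force)."""
    n, L = pool.shape
    tot = sum(hamming(pool[i], pool[j])
              for i, j in itertools.combinations(range(n), 2))
    return tot / (n * (n - 1) / 2) / L


class TestSimulatePopulation:
    def test_theta_zero_is_monomorphic(self):
        cfg = SimConfig(n_genes=5, theta=0.0, seed=3)
        truth = simulate_population(cfg)
        for g in truth.genes:
            assert (g.pool == g.pool[0]).all()
            assert g.pairwise_diversity() == 0.0

    def test_pool_diversity_calibrated_to_theta(self):
        # mean all-pairs diversity over many genes recovers theta within MC error
        cfg = SimConfig(n_genes=400, gene_length=1500, seed=5)
        truth = simulate_population(cfg)
        div = np.mean([pool_pairwise_diversity_oracle(g.pool)
                       for g in truth.genes])
        assert div == pytest.approx(cfg.theta, rel=0.05)

    def test_fast_diversity_matches_bruteforce(self, small_truth):
        g = small_truth.genes[0]
        assert g.pairwise_diversity() == pytest.approx(
            pool_pairwise_diversity_oracle(g.pool), abs=1e-12)

    def test_paralog_fraction_counts(self):
        cfg = SimConfig(n_genes=100, paralog_fraction=0.2, seed=2)
        truth = simulate_population(cfg)
        in_family = [g for g in truth.genes if g.family_id is not None]
        assert len(in_family) == 20
        assert len(truth.families) == 10
        for fam in truth.families:
            a, b = fam.member_gene_ids
            assert a != b

    def test_realized_divergence_near_nominal(self):
        cfg = SimConfig(n_genes=40, paralog_fraction=1.0,
                        paralog_divergence=0.05, seed=9)
        truth = simulate_population(cfg)
        d, L = cfg.paralog_divergence, cfg.gene_length
        # substitution may hit the same base: realized <= nominal in expectation
        eff = d  # upper bound; allow 3 binomial SD below/above
        sd = np.sqrt(d * (1 - d) / L)
        for fam in truth.families:
            assert fam.realized_divergence == pytest.approx(eff, abs=3.5 * sd)

    def test_family_design_me_subset_of_em(self, small_truth):
        truth = small_truth
        rng = np.random.default_rng(0)
        for _ in range(200):
            gi = int(rng.integers(len(truth.genes)))
            pos = int(rng.integers(truth.genes[gi].length))
            m = int(rng.integers(len(truth.individuals)))
            gid = truth.genes[gi].gene_id
            me = truth.true_alleles(gid, pos, f"ME_{m}")
            em = truth.true_alleles(gid, pos, f"EM_{m}")
            veg = truth.true_alleles(gid, pos, f"VEG_{m}")
            assert len(me) == 1 and len(em) == 2 and len(veg) == 2
            assert me[0] in em
            assert me[0] in veg

    def test_seed_determinism(self):
        cfg = SimConfig(n_genes=8, seed=42, paralog_fraction=0.5)
        t1 = simulate_population(cfg)
        t2 = simulate_population(cfg)
        for g1, g2 in zip(t1.genes, t2.genes):
            assert (g1.pool == g2.pool).all()
        for i1, i2 in zip(t1.individuals, t2.individuals):
            assert (i1.maternal_pair_idx == i2.maternal_pair_idx).all()
            assert (i1.paternal_idx == i2.paternal_idx).all()
            assert i1.megagametophyte_index == i2.megagametophyte_index

    def test_excessive_theta_rejected(self):
        with pytest.raises(ValueError, match="theta"):
            SimConfig(theta=0.5).validate()

    def test_pool_smaller_than_family_rejected(self):
        with pytest.raises(ValueError, match="n_pool_haplotypes"):
            SimConfig(n_pool_haplotypes=10, n_mothers=6).validate()


class TestBuildReference:
    def test_close_alleles_cluster_into_one_contig(self):
        # two alleles at 0.5% divergence: identity 0.995 >= 0.95 -> one contig
        cfg = SimConfig(n_genes=30, theta=0.0042, seed=11, error_rate=0.0,
                        expression_logsd=0.0)
        truth = simulate_population(cfg)
        contigs = build_reference(truth, "clustered")
        assert len(contigs) == cfg.n_genes
        for c in contigs:
            assert len(c.provenance) >= 1
            assert not c.truth_collapsed

    def test_divergent_paralogs_stay_separate(self):
        # 10% divergence: identity 0.90 < 0.95 -> two contigs per family
        cfg = SimConfig(n_genes=10, paralog_fraction=1.0,
                        paralog_divergence=0.10, theta=0.0, seed=1)
        truth = simulate_population(cfg)
        contigs = build_reference(truth, "clustered")
        assert len(contigs) == 10
        assert not any(c.truth_collapsed for c in contigs)

    def test_similar_paralogs_collapse(self):
        # 2% divergence: identity 0.98 >= 0.95 -> collapsed, PSC-positive
        cfg = SimConfig(n_genes=10, paralog_fraction=1.0,
                        paralog_divergence=0.02, theta=0.0, seed=1)
        truth = simulate_population(cfg)
        contigs = build_reference(truth, "clustered")
        assert len(contigs) == 5
        for c in contigs:
            assert c.truth_collapsed
            assert len(c.source_genes) == 2

    def test_collapse_monotone_in_cluster_identity(self):
        cfg = SimConfig(n_genes=20, paralog_fraction=1.0,
                        paralog_divergence=0.03, theta=0.0, seed=4)
        truth = simulate_population(cfg)
        n_prev = None
        for ci in (0.90, 0.95, 0.98, 0.995):
            truth.config.cluster_identity = ci
            n = len(build_reference(truth, "clustered"))
            if n_prev is not None:
                assert n >= n_prev  # stricter identity -> less collapse
            n_prev = n

    def test_collapse_iff_identity_above_cutoff(self):
        cfg = SimConfig(n_genes=20, paralog_fraction=1.0,
                        paralog_divergence=0.05, theta=0.0, seed=8)
        truth = simulate_population(cfg)
        contigs = build_reference(truth, "clustered")
        collapsed_fams = {c.source_genes for c in contigs if c.truth_collapsed}
        for fam in truth.families:
            expect = 1.0 - fam.realized_divergence >= cfg.cluster_identity
            assert (tuple(sorted(fam.member_gene_ids)) in collapsed_fams) == expect

    def test_redundant_one_contig_per_distinct_allele(self, small_truth):
        contigs = build_reference(small_truth, "redundant")
        for c in contigs:
            assert c.strategy_label == "redundant"
            assert len(c.source_genes) == 1
        by_gene = {}
        for c in contigs:
            by_gene.setdefault(c.source_genes[0], []).append(c)
        for gid, cs in by_gene.items():
            gi = small_truth.gene_index(gid)
            distinct = {small_truth.genes[gi].pool[h].tobytes()
                        for h in small_truth.expressed_hap_indices(gi)}
            assert len(cs) == len(distinct)

    def test_supertranscript_single_contig_per_gene(self, small_truth):
        contigs = build_reference(small_truth, "supertranscript")
        assert len(contigs) == len(small_truth.genes)
        genes = [c.source_genes for c in contigs]
        assert all(len(g) == 1 for g in genes)

    def test_unknown_strategy_rejected(self, small_truth):
        with pytest.raises(ValueError, match="strategy"):
            build_reference(small_truth, "bogus")


class TestSiteEvidence:
    def test_error_free_counts_match_true_base(self):
        cfg = SimConfig(n_genes=4, theta=0.0, error_rate=0.0, seed=6,
                        expression_logsd=0.0)
        truth = simulate_population(cfg)
        contigs = build_reference(truth, "clustered")
        for ev, c in zip(simulate_site_evidence(truth, contigs, cfg), contigs):
            for s in range(len(ev.sample_ids)):
                covered = ev.counts[s].sum(axis=0) > 0
                called = ev.counts[s].argmax(axis=0)
                assert (called[covered] == c.seq[covered]).all()

    def test_divergent_haplotype_contributes_nothing(self):
        # 5% divergence exceeds the 2.5% mismatch cap in expectation; with
        # theta=0 every 150-bp window carries ~7.5 mismatches and windows
        # with <= 3 are rare; most of the contig gets zero depth from the
        # paralog haplotype while its own contig (absent here) is gone
        cfg = SimConfig(n_genes=2, paralog_fraction=1.0,
                        paralog_divergence=0.10, theta=0.0, error_rate=0.0,
                        seed=2, expression_logsd=0.0)
        truth = simulate_population(cfg)
        contigs = build_reference(truth, "clustered")
        assert len(contigs) == 2  # not collapsed at 10%
        # drop gene B's contig so its reads can only try gene A's contig
        keep = [c for c in contigs if c.source_genes == ("g00000",)]
        ev = next(simulate_site_evidence(truth, keep, cfg))
        a = truth.genes[0].pool[0]
        b = truth.genes[1].pool[0]
        # all observed bases equal gene A's haplotype: no paralog reads mapped
        for s in range(len(ev.sample_ids)):
            covered = ev.counts[s].sum(axis=0) > 0
            assert (ev.counts[s].argmax(axis=0)[covered] == a[covered]).all()
        div = (a != b).mean()
        assert div > 0.05

    def test_equidistant_placements_discarded(self):
        # two identical contigs -> every window ties -> zero depth everywhere
        cfg = SimConfig(n_genes=1, theta=0.0, error_rate=0.0, seed=3,
                        expression_logsd=0.0)
        truth = simulate_population(cfg)
        contigs = build_reference(truth, "clustered")
        dup = contigs[0]
        twin = type(dup)("twin", dup.seq.copy(), dup.strategy_label,
                         list(dup.provenance),
                         [type(p)(p.gene_id, p.gene_start, p.gene_end,
                                  p.contig_start, p.hap_idx)
                          for p in dup.placements])
        evs = list(simulate_site_evidence(truth, [dup, twin], cfg))
        assert all(ev.counts.sum() == 0 for ev in evs)

    def test_foreign_reference_rejected(self, small_truth):
        other = simulate_population(SimConfig(n_genes=40, seed=99))
        contigs = build_reference(other, "clustered")
        with pytest.raises(ValueError, match="truth"):
            next(simulate_site_evidence(small_truth, contigs, small_truth.config))

    def test_evidence_deterministic_under_seed(self):
        cfg = SimConfig(n_genes=3, seed=12, error_rate=0.01,
                        expression_logsd=0.0)
        truth = simulate_population(cfg)
        contigs = build_reference(truth, "clustered")
        e1 = [ev.counts.copy() for ev in simulate_site_evidence(truth, contigs, cfg)]
        e2 = [ev.counts.copy() for ev in simulate_site_evidence(truth, contigs, cfg)]
        assert all((a == b).all() for a, b in zip(e1, e2))

    def test_site_evidence_records(self, small_truth):
        cfg = small_truth.config
        contigs = build_reference(small_truth, "clustered")
        ev = next(simulate_site_evidence(small_truth, contigs, cfg))
        rec = next(ev.iter_sites())
        assert rec.depth == sum(rec.base_counts)
        assert 0 <= rec.pos < ev.length
        assert rec.group in ("ME", "EM", "VEG")


def test_encode_decode_roundtrip():
    s = "ACGTACGTTTGA"
    assert decode(encode(s)) == s
    with pytest.raises(ValueError):
        encode("ACGN")
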