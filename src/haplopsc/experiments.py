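"""Canned study-condition experiments.

Each function runs one calibration or validation experiment of the pipeline
under the study conditions (6 mothers, theta = 4.2e-3/bp, 150-bp reads,
unique-best mapping with mismatch fraction <= 0.025, depth/missing/quality
site filters) and returns plain dictionaries of measured quantities. They are
shared by the analysis drivers, the test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np

from . import calling, hetstats, simcore
from .config import CallerParams, FilterParams, SimConfig


def _aggregate(stats: list, group: str) -> dict:
    sel = [s for s in stats if s.group == group]
    n_obs = sum(s.n_obs for s in sel)
    n_het = sum(s.n_het for s in sel)
    n_sites = sum(s.n_sites for s in sel)
    pi_sum = sum(s.pi_sum for s in sel)
    return {
        "n_sites": n_sites, "n_obs": n_obs, "n_het": n_het,
        "ho": (n_het / n_obs) if n_obs else None,
        "he": (pi_sum / n_sites) if n_sites else None,
    }


def _run_groups(truth, contigs, caller=None, filters=None,
                groups=("ME", "EM", "VEG")) -> list:
    stats = []
    for ev in simcore.simulate_site_evidence(truth, contigs):
        calls = calling.call_genotypes_contig(ev, caller)
        for _, gsd in calling.filter_sites(calls, filters, groups=groups).items():
            stats.append(hetstats.transcript_stats(gsd))
    return stats


def haploid_null(seed: int, n_genes: int = 500) -> dict:
    """Error-free, collapse-free simulation: megagametophyte (haploid)
    observed heterozygosity should be exactly zero.

    500 genes x 1500 bp at theta = 4.2e-3, 6 mothers, no paralog families,
    no sequencing error; the clustered strategy merges alleles into one
    contig per gene, so reads are not split across allele contigs.
    """
    cfg = SimConfig(n_genes=n_genes, seed=seed, theta=0.0042,
                    paralog_fraction=0.0, error_rate=0.0)
    truth = simcore.simulate_population(cfg)
    contigs = simcore.build_reference(truth, "clustered")
    assert not any(c.truth_collapsed for c in contigs)
    stats = _run_groups(truth, contigs)
    out = {g: _aggregate(stats, g) for g in ("ME", "EM", "VEG")}
    out["me_ho_per_bp"] = out["ME"]["ho"]
    return out


def hwe_ratio(seed: int, n_sites: int = 100_000, n_diploids: int = 50,
              depth: int = 30) -> dict:
    """Large HWE simulation: aggregate H_o / pooled unbiased H_E -> 1.

    Biallelic sites with neutral-SFS allele frequencies; diploid genotypes
    drawn under Hardy-Weinberg equilibrium at uniform depth; the caller and
    the depth/missing/quality filters applied before both estimators.
    """
    stats = []
    for ev in simcore.simulate_hwe_site_evidence(n_sites, n_diploids, depth,
                                                 seed=seed):
        calls = calling.call_genotypes_contig(ev)
        gsd = calling.filter_sites_group(calls, "EM", FilterParams())
        stats.append(hetstats.transcript_stats(gsd))
    agg = _aggregate(stats, "EM")
    agg["ratio"] = agg["ho"] / agg["he"] if agg["he"] else None
    return agg


def theta_recovery(seed: int, n_genes: int = 500) -> dict:
    """Pooled diploid pi from the vegetative (maternal) group recovers the
    simulated theta: the 12 maternal haplotypes are unrelated draws from the
    population pool, so the unbiased per-site estimator is calibrated."""
    cfg = SimConfig(n_genes=n_genes, seed=seed, theta=0.0042, error_rate=0.0)
    truth = simcore.simulate_population(cfg)
    contigs = simcore.build_reference(truth, "clustered")
    stats = _run_groups(truth, contigs, groups=("VEG",))
    agg = _aggregate(stats, "VEG")
    agg["he_x1000"] = agg["he"] * 1000 if agg["he"] is not None else None
    agg["theta_x1000"] = cfg.theta * 1000
    return agg


def collapse_scenario(seed: int, divergence: float, n_pairs: int = 6,
                      mean_depth: float = 30.0) -> dict:
    """Paralog-collapse scenario at a fixed family divergence.

    theta = 0 isolates the paralog signal: every heterozygous haploid call on
    a truth-collapsed contig stems from paralog read mapping. Returns the
    aggregate megagametophyte H_o over truth-collapsed contigs together with
    the truth set and references for oracle-based verification.
    """
    cfg = SimConfig(n_genes=2 * n_pairs, seed=seed, theta=0.0,
                    paralog_fraction=1.0, paralog_divergence=divergence,
                    mean_depth=mean_depth, error_rate=0.0,
                    expression_logsd=0.0)
    truth = simcore.simulate_population(cfg)
    contigs = simcore.build_reference(truth, "clustered")
    collapsed = {c.contig_id for c in contigs if c.truth_collapsed}
    n_het = n_obs = 0
    per_contig = {}
    for ev in simcore.simulate_site_evidence(truth, contigs):
        if ev.contig_id not in collapsed:
            continue
        calls = calling.call_genotypes_contig(ev)
        gsd = calling.filter_sites_group(calls, "ME", FilterParams())
        st = hetstats.transcript_stats(gsd)
        per_contig[ev.contig_id] = st
        n_het += st.n_het
        n_obs += st.n_obs
    return {
        "truth": truth, "contigs": contigs, "collapsed": collapsed,
        "per_contig": per_contig, "n_het": n_het, "n_obs": n_obs,
        "ho": (n_het / n_obs) if n_obs else None,
    }


def redundancy_bias(seed: int, n_genes: int = 60) -> dict:
    """Measured diploid pi under the redundant vs clustered strategy.

    Allelic redundancy splits reads across allele contigs (identical windows
    multimap and are discarded; discriminating windows reach only carriers),
    deflating measured diversity; aggregate pi over zero callable
    polymorphic observations is reported as 0 (maximal underestimation).
    """
    cfg = SimConfig(n_genes=n_genes, seed=seed, theta=0.0042, error_rate=0.0,
                    expression_logsd=0.0)
    truth = simcore.simulate_population(cfg)
    out = {}
    for strategy in ("redundant", "clustered"):
        contigs = simcore.build_reference(truth, strategy)
        stats = _run_groups(truth, contigs, groups=("VEG",))
        agg = _aggregate(stats, "VEG")
        out[strategy] = {
            "n_sites": agg["n_sites"],
            "pi": agg["he"] if agg["he"] is not None else 0.0,
        }
    truth_pi = float(np.mean([g.pairwise_diversity() for g in truth.genes]))
    out["truth_pi"] = truth_pi
    return out
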