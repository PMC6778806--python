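"""End-to-end pipeline: simulate -> build references -> evidence -> call ->
filter -> heterozygosity statistics -> screens -> report, reproducible from a
single master seed."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import calling, hetstats, pscscreen, simcore, txstats
from .config import PipelineConfig, ScreenParams

log = logging.getLogger("haplopsc")


@dataclass
class StrategyResult:
    strategy: str
    contigs: list
    stats: list                      # TranscriptHetStats for all groups
    summary: hetstats.AssemblySummary
    flags: dict                      # contig_id -> TranscriptFlags
    tables: list                     # CallableSiteTable


@dataclass
class PSCReport:
    config: PipelineConfig
    truth: simcore.TruthSet
    strategies: dict[str, StrategyResult]
    truth_eval: dict[str, dict] | None = None

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name, res in self.strategies.items():
            for g, d in res.summary.groups.items():
                rows.append({
                    "strategy": name, "group": g,
                    "n_callable_sites": d["n_sites"],
                    "He_x1000": None if d["he"] is None else d["he"] * 1000,
                    "Ho_x1000": None if d["ho"] is None else d["ho"] * 1000,
                })
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        out = {"config": dataclasses.asdict(self.config), "strategies": {}}
        for name, res in self.strategies.items():
            out["strategies"][name] = {
                "n_contigs": len(res.contigs),
                "groups": res.summary.groups,
                "ratios": res.summary.ratios,
            }
        if self.truth_eval is not None:
            out["truth_eval"] = self.truth_eval
        return json.dumps(out, indent=2, sort_keys=True)


def _expression_matrix(truth: simcore.TruthSet,
                       contigs: list) -> txstats.ExpressionMatrix:
    """Per-contig expected effective counts per sample (deterministic)."""
    sample_ids = [s for s, _ in truth.samples()]
    rows = {}
    lengths = {}
    for c in contigs:
        gene = truth.genes[truth.gene_index(c.provenance[0][0])]
        depth = truth.config.mean_depth * gene.expression_weight
        frag = depth * c.length / truth.config.read_len
        rows[c.contig_id] = {s: frag for s in sample_ids}
        lengths[c.contig_id] = c.length
    counts = pd.DataFrame(rows).T
    return txstats.ExpressionMatrix(counts, pd.Series(lengths))


def _screen_strategy(truth: simcore.TruthSet, contigs: list, stats: list,
                     screen: ScreenParams, min_callable: int) -> dict:
    """Compute all transcript flags for one reference."""
    hh = pscscreen.flag_haploid_het(stats, min_callable)

    # copy-number vs the simulated "genome": the distinct ancestral genes
    subjects = {g.gene_id: simcore.decode(g.ancestral) for g in truth.genes}
    queries = {c.contig_id: c.sequence for c in contigs if c.length > 0}
    ap = pscscreen.AlignParams(min_identity=min(80.0, screen.multi_copy_identity),
                               min_len=screen.selfhit_min_len)
    genome_hits = _family_restricted_hits(truth, contigs, subjects, ap)
    copy_class = pscscreen.classify_copy_number(
        genome_hits, {c.contig_id: c.length for c in contigs}, screen)

    self_params = pscscreen.AlignParams(min_len=screen.selfhit_min_len,
                                        min_identity=screen.selfhit_min_identity)
    self_hits = pscscreen.self_align(queries, self_params)
    mosaic = pscscreen.detect_mosaics(self_hits)

    expr = _expression_matrix(truth, contigs)
    low = txstats.low_expression_filter(expr, screen.tpm_cutoff)

    return pscscreen.combine_flags(
        [c.contig_id for c in contigs], haploid_het=hh, copy_class=copy_class,
        mosaic=mosaic, low_expression=low)


def _family_restricted_hits(truth, contigs, subjects, params):
    """Genome-wide hits, searched family-by-family: unrelated simulated genes
    are i.i.d. random sequences with no alignable similarity, so restricting
    the search to each contig's paralog family loses nothing and keeps the
    aligner desk-scale."""
    hits = []
    for c in contigs:
        if c.length == 0:
            continue
        fam = truth.family_of(c.provenance[0][0])
        subj = {g: subjects[g] for g in fam}
        hits.extend(pscscreen.align_many({c.contig_id: c.sequence}, subj, params))
    return hits


def run_strategy(truth: simcore.TruthSet, strategy: str,
                 cfg: PipelineConfig, outdir: Path | None = None) -> StrategyResult:
    contigs = simcore.build_reference(truth, strategy)
    log.info("strategy=%s: built %d contigs", strategy, len(contigs))
    stats = []
    tables = []
    all_calls = []
    for ev in simcore.simulate_site_evidence(truth, contigs, cfg.sim):
        calls = calling.call_genotypes_contig(ev, cfg.caller)
        if outdir is not None:
            all_calls.append(calls)
        for group, gsd in calling.filter_sites(calls, cfg.filters).items():
            stats.append(hetstats.transcript_stats(gsd))
            tables.append(gsd.table)
    summary = hetstats.summarize_ratios(stats, cfg.min_callable)
    flags = _screen_strategy(truth, contigs, stats, cfg.screen, cfg.min_callable)
    log.info("strategy=%s: %d transcript/group stats, %d flagged contigs",
             strategy, len(stats), len(flags))

    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        simcore.write_reference_fasta(contigs, outdir / f"{strategy}.fasta")
        simcore.write_truth_tables(truth, contigs, outdir / f"{strategy}.provenance.tsv")
        calling.write_vcf(all_calls, outdir / f"{strategy}.vcf")
        hetstats.stats_frame(stats).to_csv(
            outdir / f"{strategy}.hetstats.tsv", sep="\t", index=False)
        pscscreen.flags_frame(flags).to_csv(
            outdir / f"{strategy}.flags.tsv", sep="\t", index=False)
    return StrategyResult(strategy, contigs, stats, summary, flags, tables)


def run_pipeline(cfg: PipelineConfig, write_outputs: bool = False) -> PSCReport:
    """Execute all stages for each requested strategy over one shared truth."""
    cfg.validate()
    outdir = Path(cfg.outdir) if write_outputs else None
    log.info("master seed: %d", cfg.sim.seed)
    truth = simcore.simulate_population(cfg.sim)
    truth.check_invariants()
    strategies = {}
    for strategy in cfg.strategies:
        try:
            strategies[strategy] = run_strategy(truth, strategy, cfg, outdir)
        except Exception as exc:  # annotate failing stage, as promised
            raise RuntimeError(
                f"pipeline stage failed: strategy={strategy} "
                f"seed={cfg.sim.seed}: {exc}") from exc
    report = PSCReport(cfg, truth, strategies)
    report.truth_eval = {name: evaluate_against_truth(res, truth)
                         for name, res in strategies.items()}
    if outdir is not None:
        (outdir / "report.json").write_text(report.to_json())
        (outdir / "config.json").write_text(cfg.to_json())
    return report


def evaluate_against_truth(result: StrategyResult,
                           truth: simcore.TruthSet) -> dict:
    """Score the haploid-het PSC flag and copy-number class against truth.

    haploid_het is compared with contig-level truth collapse (>= 2 source
    genes on a clustering-built contig); copy_class against provenance
    (multi iff the contig's gene belongs to a paralog family).
    """
    if truth is None:
        raise ValueError("truth set required")
    by_id = {c.contig_id: c for c in result.contigs}
    tp = fp = fn = tn = 0
    for cid, f in result.flags.items():
        if f.haploid_het is None:
            continue
        truth_pos = by_id[cid].truth_collapsed
        if f.haploid_het and truth_pos:
            tp += 1
        elif f.haploid_het:
            fp += 1
        elif truth_pos:
            fn += 1
        else:
            tn += 1
    cc_match = cc_total = 0
    for cid, f in result.flags.items():
        c = by_id[cid]
        in_family = any(
            truth.genes[truth.gene_index(g)].family_id is not None
            for g in c.source_genes)
        expected = "multi" if (in_family or len(c.source_genes) > 1) else "single"
        if f.copy_class != "unassigned":
            cc_total += 1
            cc_match += f.copy_class == expected
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "precision": tp / (tp + fp) if tp + fp else None,
        "recall": tp / (tp + fn) if tp + fn else None,
        "fpr": fp / (fp + tn) if fp + tn else None,
        "copy_class_agreement": cc_match / cc_total if cc_total else None,
    }
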