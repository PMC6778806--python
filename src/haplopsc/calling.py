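"""Simplified genotype calling and vcftools-style site filtering.

All samples, including haploid megagametophyte tissue, are genotyped in
diploid mode: haploid heterozygous calls are the paralog-collapse signal this
pipeline measures, and would be unobservable under ploidy-1 calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from ._seq import BASES
from .config import CallerParams, FilterParams
from .simcore import GROUPS, ContigEvidence

_LN10_OVER_10 = np.log(10.0) / 10.0

# diploid genotype space over ACGT: 4 homozygous + 6 heterozygous
GENOTYPES: list[tuple[int, int]] = [(a, a) for a in range(4)] + \
    [(a, b) for a in range(4) for b in range(a + 1, 4)]
_GT_INDEX = {g: i for i, g in enumerate(GENOTYPES)}


@dataclass
class GenotypeCall:
    contig_id: str
    pos: int  # 0-based
    sample_id: str
    group: str
    alleles: tuple[str, ...]  # () when missing; 1 or 2 bases otherwise
    qual: float
    depth: int
    missing: bool
    multiallelic: bool = False

    @property
    def is_het(self) -> bool:
        return len(self.alleles) == 2 and self.alleles[0] != self.alleles[1]


@dataclass
class ContigCalls:
    """Array-backed genotype calls for one contig (all samples)."""
    contig_id: str
    length: int
    sample_ids: list[str]
    groups: list[str]
    positions: np.ndarray  # (L,) reference positions of the columns
    allele1: np.ndarray    # (S, L) int8, -1 = missing
    allele2: np.ndarray    # (S, L) int8
    qual: np.ndarray       # (S, L) float32
    depth: np.ndarray      # (S, L) int32
    multi: np.ndarray      # (S, L) bool: >2 alleles retained

    @property
    def missing(self) -> np.ndarray:
        return self.allele1 < 0

    @property
    def het(self) -> np.ndarray:
        return (self.allele1 >= 0) & (self.allele1 != self.allele2)

    def subset(self, sample_idx: np.ndarray, col_idx: np.ndarray) -> "ContigCalls":
        return ContigCalls(
            self.contig_id, self.length,
            [self.sample_ids[i] for i in sample_idx],
            [self.groups[i] for i in sample_idx],
            self.positions[col_idx],
            self.allele1[np.ix_(sample_idx, col_idx)].copy(),
            self.allele2[np.ix_(sample_idx, col_idx)].copy(),
            self.qual[np.ix_(sample_idx, col_idx)].copy(),
            self.depth[np.ix_(sample_idx, col_idx)].copy(),
            self.multi[np.ix_(sample_idx, col_idx)].copy(),
        )

    def iter_calls(self) -> Iterator[GenotypeCall]:
        for s, sid in enumerate(self.sample_ids):
            for j, pos in enumerate(self.positions):
                a1, a2 = int(self.allele1[s, j]), int(self.allele2[s, j])
                if a1 < 0:
                    yield GenotypeCall(self.contig_id, int(pos), sid,
                                       self.groups[s], (), 0.0,
                                       int(self.depth[s, j]), True)
                else:
                    alleles = (BASES[a1],) if a1 == a2 else (BASES[a1], BASES[a2])
                    yield GenotypeCall(self.contig_id, int(pos), sid,
                                       self.groups[s], alleles,
                                       float(self.qual[s, j]),
                                       int(self.depth[s, j]), False,
                                       bool(self.multi[s, j]))


def genotype_log_prob_matrix(error_rate: float) -> np.ndarray:
    """(10, 4) log P(read base | genotype) under a symmetric error model."""
    e = max(error_rate, 1e-6)
    P = np.empty((len(GENOTYPES), 4))
    for gi, (a, b) in enumerate(GENOTYPES):
        p = np.full(4, e / 3.0)
        if a == b:
            p[a] = 1.0 - e
        else:
            p[a] = p[b] = (1.0 - e) / 2.0 + e / 6.0
        P[gi] = np.log(p)
    return P


def call_genotypes_contig(ev: ContigEvidence,
                          params: CallerParams | None = None) -> ContigCalls:
    """Rule-based diploid calls with likelihood-ratio quality scores.

    An allele is retained iff count >= min_allele_count and frequency >=
    min_allele_frac. One retained allele -> homozygous; two -> heterozygous;
    more -> flagged multi-allelic. qual is the Phred-scaled likelihood ratio
    of the called genotype against the best alternative genotype.
    """
    if params is None:
        params = CallerParams()
    counts = ev.counts
    if (counts < 0).any():
        raise ValueError("negative base counts")
    S, _, L = counts.shape
    depth = counts.sum(axis=1)  # (S, L)

    retained = (counts >= params.min_allele_count) & \
        (counts >= params.min_allele_frac * depth[:, None, :]) & (depth[:, None, :] > 0)
    n_ret = retained.sum(axis=1)  # (S, L)

    # top-2 retained alleles by count (count desc, base asc for ties)
    order_key = np.where(retained, counts, -1).astype(np.int64) * 4 + \
        (3 - np.arange(4))[None, :, None]
    top = np.argsort(-order_key, axis=1)  # (S, 4, L) base indices
    a_hi = top[:, 0, :].astype(np.int8)
    a_lo = top[:, 1, :].astype(np.int8)

    missing = (depth == 0) | (n_ret == 0)
    hom = n_ret == 1
    allele1 = np.where(hom, a_hi, np.minimum(a_hi, a_lo)).astype(np.int8)
    allele2 = np.where(hom, a_hi, np.maximum(a_hi, a_lo)).astype(np.int8)
    allele1[missing] = -1
    allele2[missing] = -1
    multi = n_ret > 2

    # genotype log-likelihoods: (S, 10, L)
    logp = genotype_log_prob_matrix(params.error_rate)
    ll = np.einsum("sbl,gb->sgl", counts.astype(np.float64), logp)
    called_gt = np.zeros((S, L), dtype=np.int64)
    valid = ~missing
    g_idx = np.array([[_GT_INDEX[(min(a, b), max(a, b))] if a >= 0 else 0
                       for a, b in zip(allele1[s], allele2[s])]
                      for s in range(S)])
    called_gt[valid] = g_idx[valid]
    ll_called = np.take_along_axis(ll, called_gt[:, None, :], axis=1)[:, 0, :]
    ll_masked = ll.copy()
    np.put_along_axis(ll_masked, called_gt[:, None, :], -np.inf, axis=1)
    ll_next = ll_masked.max(axis=1)
    qual = np.maximum((ll_called - ll_next) / _LN10_OVER_10, 0.0).astype(np.float32)
    qual[missing] = 0.0

    return ContigCalls(ev.contig_id, ev.length, list(ev.sample_ids),
                       list(ev.groups), np.arange(L), allele1, allele2,
                       qual, depth.astype(np.int32), multi)


def call_genotypes(evidence: Iterable[ContigEvidence],
                   params: CallerParams | None = None) -> Iterator[ContigCalls]:
    for ev in evidence:
        yield call_genotypes_contig(ev, params)


# ---------------------------------------------------------------------------
# site filtering
# ---------------------------------------------------------------------------

@dataclass
class CallableSiteTable:
    """Callable-site accounting for one contig in one ploidy group.

    n_sites counts distinct callable positions (monomorphic + polymorphic
    passing all filters); n_obs counts surviving per-sample site observations
    (the micro-average denominator of per-bp observed heterozygosity).
    """
    contig_id: str
    group: str
    n_sites: int
    n_obs: int
    per_sample: dict[str, int]


@dataclass
class GroupSiteData:
    """Filtered per-site summaries for one contig and ploidy group."""
    contig_id: str
    group: str
    sample_ids: list[str]
    positions: np.ndarray        # kept positions
    is_polymorphic: np.ndarray   # (K,) bool
    n_obs_per_site: np.ndarray   # (K,) surviving samples
    het_per_site: np.ndarray     # (K,) het calls among surviving samples
    pooled_counts: np.ndarray    # (4, K) pooled called-allele counts
    per_sample_callable: np.ndarray  # (Sg,)
    per_sample_het: np.ndarray       # (Sg,)
    filtered_calls: ContigCalls = field(repr=False, default=None)

    @property
    def table(self) -> CallableSiteTable:
        return CallableSiteTable(
            self.contig_id, self.group, len(self.positions),
            int(self.n_obs_per_site.sum()),
            {s: int(c) for s, c in zip(self.sample_ids, self.per_sample_callable)})


def filter_sites_group(calls: ContigCalls, group: str,
                       params: FilterParams | None = None) -> GroupSiteData:
    """Apply the depth / missingness / biallelic-quality site filters.

    A sample's call is void when depth < min_depth; a site is dropped when
    its missing fraction (missing + voided) exceeds max_missing; polymorphic
    sites are kept only if biallelic SNPs with site QUAL > min_qual, where
    site QUAL is the best genotype qual among carriers of the minor allele.
    Surviving monomorphic and polymorphic sites are both callable.
    """
    if params is None:
        params = FilterParams()
    if group not in GROUPS:
        raise ValueError(f"unknown group label: {group!r}")
    sidx = np.array([i for i, g in enumerate(calls.groups) if g == group])
    if len(sidx) == 0:
        raise ValueError(f"no samples in group {group!r}")
    sub = calls.subset(sidx, np.arange(len(calls.positions)))
    Sg, L = sub.allele1.shape

    void = (sub.depth < params.min_depth) | sub.missing
    surviving = ~void
    n_surv = surviving.sum(axis=0)
    miss_frac = 1.0 - n_surv / Sg
    keep = miss_frac <= params.max_missing
    keep &= n_surv > 0

    # pooled called-allele counts over surviving calls
    pooled = np.zeros((4, L), dtype=np.int64)
    for b in range(4):
        pooled[b] = ((sub.allele1 == b) & surviving).sum(axis=0) + \
            ((sub.allele2 == b) & surviving).sum(axis=0)
    n_alleles_distinct = (pooled > 0).sum(axis=0)
    any_multi = (sub.multi & surviving).any(axis=0)

    poly = keep & (n_alleles_distinct > 1)
    mono = keep & (n_alleles_distinct == 1)
    if params.biallelic_only:
        bad_poly = poly & ((n_alleles_distinct > 2) | any_multi)
    else:
        bad_poly = poly & any_multi
    poly_ok = np.zeros(L, dtype=bool)
    for j in np.nonzero(poly & ~bad_poly)[0]:
        c = pooled[:, j]
        present = np.nonzero(c)[0]
        minor = present[np.argmin(c[present])]
        carriers = surviving[:, j] & ((sub.allele1[:, j] == minor) |
                                      (sub.allele2[:, j] == minor))
        site_qual = sub.qual[carriers, j].max()
        if site_qual > params.min_qual:
            poly_ok[j] = True
    kept = mono | poly_ok
    cols = np.nonzero(kept)[0]

    het = sub.het & surviving
    filtered = sub.subset(np.arange(Sg), cols)
    # voided calls become missing in the filtered view
    v = void[:, cols]
    filtered.allele1[v] = -1
    filtered.allele2[v] = -1
    filtered.qual[v] = 0.0
    filtered.depth[v] = 0

    return GroupSiteData(
        calls.contig_id, group, sub.sample_ids,
        sub.positions[cols], poly_ok[cols],
        n_surv[cols].astype(np.int64), het[:, cols].sum(axis=0).astype(np.int64),
        pooled[:, cols],
        (surviving & kept[None, :]).sum(axis=1).astype(np.int64),
        (het & kept[None, :]).sum(axis=1).astype(np.int64),
        filtered_calls=filtered,
    )


def filter_sites(calls: ContigCalls, params: FilterParams | None = None,
                 groups: Iterable[str] = GROUPS) -> dict[str, GroupSiteData]:
    present = set(calls.groups)
    return {g: filter_sites_group(calls, g, params)
            for g in groups if g in present}


# ---------------------------------------------------------------------------
# VCF I/O (pysam; 1-based VCF <-> 0-based internal)
# ---------------------------------------------------------------------------

_VCF_HEADER_LINES = [
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
    '##FORMAT=<ID=QS,Number=1,Type=Float,Description="Genotype quality (Phred LR)">',
]


def write_vcf(contig_calls: Iterable[ContigCalls], path,
              evidence_counts: dict[str, np.ndarray] | None = None) -> None:
    """Write calls to VCF v4.2. REF is the majority called allele per site.

    evidence_counts optionally maps contig_id -> (S, 4, L) pileup counts used
    to fill AD; without it AD is derived from called alleles and depth.
    """
    import pysam

    contig_calls = list(contig_calls)
    header = pysam.VariantHeader()
    for line in _VCF_HEADER_LINES:
        header.add_line(line)
    for cc in contig_calls:
        header.contigs.add(cc.contig_id, length=cc.length)
    if contig_calls:
        for sid in contig_calls[0].sample_ids:
            header.add_sample(sid)

    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for cc in contig_calls:
            S = len(cc.sample_ids)
            for j, pos in enumerate(cc.positions):
                a1 = cc.allele1[:, j]
                a2 = cc.allele2[:, j]
                called = a1 >= 0
                if not called.any():
                    continue
                pooled = np.zeros(4, dtype=np.int64)
                for b in range(4):
                    pooled[b] = ((a1 == b) & called).sum() + ((a2 == b) & called).sum()
                order = np.argsort(-pooled, kind="stable")
                alleles = [int(b) for b in order if pooled[b] > 0]
                ref = alleles[0]
                alts = alleles[1:]
                rec_alleles = tuple(BASES[b] for b in [ref] + alts)
                if len(rec_alleles) == 1:
                    rec_alleles = rec_alleles + ("<NON_REF>",)  # monomorphic
                rec = vf.new_record(contig=cc.contig_id, start=int(pos),
                                    stop=int(pos) + 1, alleles=rec_alleles)
                rec.qual = float(cc.qual[called, j].max())
                code = {b: i for i, b in enumerate([ref] + alts)}
                for s in range(S):
                    smp = rec.samples[cc.sample_ids[s]]
                    if a1[s] < 0:
                        smp["GT"] = (None, None)
                    else:
                        smp["GT"] = (code[int(a1[s])], code[int(a2[s])])
                        smp["QS"] = float(cc.qual[s, j])
                    smp["DP"] = int(cc.depth[s, j])
                    if evidence_counts and cc.contig_id in evidence_counts:
                        cnt = evidence_counts[cc.contig_id][s, :, int(pos)]
                        smp["AD"] = tuple(int(cnt[b]) for b in [ref] + alts)
                vf.write(rec)
    # pysam writes a trailing index-friendly file; nothing else to do


def read_vcf(path, group_map: dict[str, str]):
    """Read a VCF v4.x into GenotypeCall records grouped per contig.

    Indel records (REF or ALT longer than 1 bp) are skipped and counted,
    mirroring an indel-excluding caller configuration. Returns
    (list[ContigCalls], n_indels_skipped).
    """
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        missing_samples = [s for s in samples if s not in group_map]
        if missing_samples:
            raise ValueError(
                f"samples absent from group_map: {missing_samples}")
        lengths = {name: (ctg.length or 0) for name, ctg in vf.header.contigs.items()}
        per_contig: dict[str, list] = {}
        n_indels = 0
        for rec in vf:
            alleles = [a for a in rec.alleles
                       if a is not None and a != "<NON_REF>"]
            if any(len(a) != 1 for a in alleles):
                n_indels += 1
                continue
            per_contig.setdefault(rec.contig, []).append(rec)

    out = []
    for contig, recs in per_contig.items():
        L = len(recs)
        S = len(samples)
        allele1 = np.full((S, L), -1, dtype=np.int8)
        allele2 = np.full((S, L), -1, dtype=np.int8)
        qual = np.zeros((S, L), dtype=np.float32)
        depth = np.zeros((S, L), dtype=np.int32)
        positions = np.empty(L, dtype=np.int64)
        for j, rec in enumerate(recs):
            positions[j] = rec.start  # pysam start is already 0-based
            base_code = [BASES.index(a) if a in BASES else -1
                         for a in rec.alleles]
            for s, sid in enumerate(samples):
                smp = rec.samples[sid]
                gt = smp.get("GT")
                if smp.get("DP") is not None:
                    depth[s, j] = smp["DP"]
                if gt is None or gt[0] is None:
                    continue
                a = sorted(base_code[i] for i in gt)
                allele1[s, j] = a[0]
                allele2[s, j] = a[-1]
                if smp.get("QS") is not None:
                    qual[s, j] = smp["QS"]
        out.append(ContigCalls(contig, lengths.get(contig, int(positions.max()) + 1),
                               samples, [group_map[s] for s in samples],
                               positions, allele1, allele2, qual, depth,
                               np.zeros((S, L), dtype=bool)))
    return out, n_indels
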