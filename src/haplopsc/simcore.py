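"""Truth-set simulator: population haplotypes, paralog families, seed families,
reference-building strategies, and site-level read evidence under the mapping
rules (unique-best placement, bounded mismatch fraction).

The family design mirrors a conifer seed study: each mother tree contributes
one haploid megagametophyte sample (ME), one diploid embryo (EM) whose
maternal haplotype equals the megagametophyte haplotype, and one pooled
diploid vegetative sample (VEG) carrying the maternal genotype.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from ._seq import decode, encode, hamming, identity_fraction
from .config import SimConfig

GROUPS = ("ME", "EM", "VEG")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Haplotype:
    gene_id: str
    haplotype_id: str
    seq: np.ndarray  # uint8 codes

    @property
    def sequence(self) -> str:
        return decode(self.seq)


@dataclass
class Isoform:
    iso_id: str
    start: int  # 0-based half-open interval on the gene
    end: int
    weight: float  # share of the gene's expression


@dataclass
class GeneTruth:
    gene_id: str
    ancestral: np.ndarray
    pool: np.ndarray          # (n_pool, L) uint8
    isoforms: list[Isoform]
    expression_weight: float  # relative depth multiplier, mean ~1 over genes
    family_id: str | None = None
    partner_gene_id: str | None = None

    @property
    def length(self) -> int:
        return int(self.pool.shape[1])

    def haplotype(self, idx: int) -> Haplotype:
        return Haplotype(self.gene_id, f"{self.gene_id}.h{idx}", self.pool[idx])

    def pairwise_diversity(self) -> float:
        """All-pairs Hamming diversity per bp of the pool (truth oracle)."""
        n, L = self.pool.shape
        # per-site allele counts -> sum over pairs of differences
        total = 0.0
        counts = np.zeros((4, L), dtype=np.int64)
        for b in range(4):
            counts[b] = (self.pool == b).sum(axis=0)
        same = (counts * (counts - 1) // 2).sum()
        pairs = n * (n - 1) // 2
        total = (pairs * L - same) / (pairs * L)
        return float(total)


@dataclass
class ParalogFamily:
    family_id: str
    member_gene_ids: tuple[str, str]
    realized_divergence: float


@dataclass
class Individual:
    mother_id: int
    maternal_pair_idx: np.ndarray     # (n_genes, 2) pool indices
    megagametophyte_index: int        # 0 or 1: which maternal haplotype the seed carries
    paternal_idx: np.ndarray          # (n_genes,)

    def me_hap(self, gi: int) -> int:
        return int(self.maternal_pair_idx[gi, self.megagametophyte_index])


@dataclass
class TruthSet:
    config: SimConfig
    genes: list[GeneTruth]
    families: list[ParalogFamily]
    individuals: list[Individual]

    def gene_index(self, gene_id: str) -> int:
        return self._gi[gene_id]

    def __post_init__(self) -> None:
        self._gi = {g.gene_id: i for i, g in enumerate(self.genes)}

    # --- sample bookkeeping ------------------------------------------------
    def samples(self) -> list[tuple[str, str]]:
        """All (sample_id, group) pairs, in deterministic order."""
        out = []
        for grp in GROUPS:
            for m in range(len(self.individuals)):
                out.append((f"{grp}_{m}", grp))
        return out

    def sample_hap_indices(self, sample_id: str, gi: int) -> list[int]:
        """Pool indices of the haplotype copies a sample carries at gene gi."""
        grp, m = sample_id.split("_")
        ind = self.individuals[int(m)]
        if grp == "ME":
            return [ind.me_hap(gi)]
        if grp == "EM":
            return [ind.me_hap(gi), int(ind.paternal_idx[gi])]
        if grp == "VEG":
            return [int(ind.maternal_pair_idx[gi, 0]),
                    int(ind.maternal_pair_idx[gi, 1])]
        raise ValueError(f"unknown group in sample id {sample_id!r}")

    def true_alleles(self, gene_id: str, pos: int, sample_id: str) -> tuple[int, ...]:
        gi = self.gene_index(gene_id)
        g = self.genes[gi]
        return tuple(int(g.pool[h, pos]) for h in self.sample_hap_indices(sample_id, gi))

    def expressed_hap_indices(self, gi: int) -> list[int]:
        """Distinct pool indices expressed by any sample at gene gi (sorted)."""
        idx: set[int] = set()
        for ind in self.individuals:
            idx.update(int(x) for x in ind.maternal_pair_idx[gi])
            idx.add(int(ind.paternal_idx[gi]))
        return sorted(idx)

    def family_of(self, gene_id: str) -> tuple[str, ...]:
        g = self.genes[self.gene_index(gene_id)]
        if g.partner_gene_id is None:
            return (gene_id,)
        return tuple(sorted((gene_id, g.partner_gene_id)))

    def check_invariants(self) -> None:
        """Family design consistency: ME alleles are a subset of EM's."""
        for ind in self.individuals:
            for gi in range(len(self.genes)):
                me = ind.me_hap(gi)
                em = {me, int(ind.paternal_idx[gi])}
                if me not in em:  # pragma: no cover - structurally true
                    raise AssertionError("ME haplotype missing from EM genotype")
                veg = set(int(x) for x in ind.maternal_pair_idx[gi])
                if me not in veg:
                    raise AssertionError("ME haplotype missing from VEG genotype")


@dataclass
class Placement:
    """Maps a gene-coordinate interval onto contig coordinates."""
    gene_id: str
    gene_start: int
    gene_end: int
    contig_start: int
    hap_idx: int  # pool index whose bases were used for this block


@dataclass
class ReferenceContig:
    contig_id: str
    seq: np.ndarray
    strategy_label: str  # redundant | clustered | supertranscript
    provenance: list[tuple[str, str]]       # (gene_id, allele/isoform label)
    placements: list[Placement] = field(default_factory=list)
    duplicated_blocks: bool = False  # supertranscript appended a near-duplicate block

    @property
    def sequence(self) -> str:
        return decode(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def source_genes(self) -> tuple[str, ...]:
        return tuple(sorted({g for g, _ in self.provenance}))

    @property
    def truth_collapsed(self) -> bool:
        """PSC-positive: a clustering-built contig merging >= 2 distinct genes."""
        return self.strategy_label == "clustered" and len(self.source_genes) >= 2


@dataclass
class SiteEvidence:
    contig_id: str
    pos: int  # 0-based
    sample_id: str
    group: str
    base_counts: tuple[int, int, int, int]

    @property
    def depth(self) -> int:
        return int(sum(self.base_counts))


@dataclass
class ContigEvidence:
    """Per-contig pileup: base counts per sample over all positions."""
    contig_id: str
    length: int
    sample_ids: list[str]
    groups: list[str]
    counts: np.ndarray  # (n_samples, 4, length) int32

    def iter_sites(self) -> Iterator[SiteEvidence]:
        for s, sid in enumerate(self.sample_ids):
            for pos in range(self.length):
                c = self.counts[s, :, pos]
                if c.sum() > 0:
                    yield SiteEvidence(self.contig_id, pos, sid,
                                       self.groups[s], tuple(int(x) for x in c))


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------

def _spawn(seed: int, label: str) -> np.random.Generator:
    """Independent, reproducible substream derived from the master seed."""
    h = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:8], "little"))


def _simulate_pool(rng: np.random.Generator, ancestral: np.ndarray,
                   n_pool: int, p_seg: float) -> np.ndarray:
    L = len(ancestral)
    pool = np.tile(ancestral, (n_pool, 1))
    seg_mask = rng.random(L) < p_seg
    seg_pos = np.nonzero(seg_mask)[0]
    if len(seg_pos) == 0:
        return pool
    # derived-allele count ~ neutral SFS P(i) propto 1/i
    i_vals = np.arange(1, n_pool)
    sfs = (1.0 / i_vals) / (1.0 / i_vals).sum()
    counts = rng.choice(i_vals, size=len(seg_pos), p=sfs)
    for pos, i in zip(seg_pos, counts):
        carriers = rng.choice(n_pool, size=int(i), replace=False)
        derived = (int(ancestral[pos]) + int(rng.integers(1, 4))) % 4
        pool[carriers, pos] = derived
    return pool


def simulate_population(config: SimConfig) -> TruthSet:
    """Simulate per-gene haplotype pools, paralog families and seed families.

    Segregating sites carry derived-allele frequencies from the neutral SFS,
    with the per-site segregation probability calibrated so the pool's
    expected all-pairs pairwise diversity per bp equals theta. The 2*n_mothers
    maternal haplotypes are drawn without replacement per gene (unrelated
    mothers); paternal haplotypes are drawn uniformly (panmictic unknown
    fathers). Fully reproducible from config.seed.
    """
    config.validate()
    L = config.gene_length
    n_pool = config.n_pool_haplotypes
    p_seg = config.segregation_probability()

    n_pairs = int(round(config.paralog_fraction * config.n_genes / 2.0))

    rng_pop = _spawn(config.seed, "population")
    rng_fam = _spawn(config.seed, "families")
    rng_ind = _spawn(config.seed, "individuals")
    rng_exp = _spawn(config.seed, "expression")

    genes: list[GeneTruth] = []
    families: list[ParalogFamily] = []

    # expression weights (log-normal, normalized to mean 1)
    w = rng_exp.lognormal(config.expression_logmean,
                          config.expression_logsd, config.n_genes)
    w = w / w.mean()

    def make_isoforms(gid: str, rng: np.random.Generator) -> list[Isoform]:
        isos = [Isoform(f"{gid}.i0", 0, L, 1.0)]
        for k in range(1, config.isoforms_per_gene):
            ln = int(rng.integers(config.read_len, L + 1))
            st = int(rng.integers(0, L - ln + 1))
            isos.append(Isoform(f"{gid}.i{k}", st, st + ln, 1.0))
        if len(isos) > 1:
            shares = rng.dirichlet(np.ones(len(isos)))
            for iso, sh in zip(isos, shares):
                iso.weight = float(sh)
        return isos

    for g in range(config.n_genes):
        gid = f"g{g:05d}"
        if n_pairs > 0 and g < 2 * n_pairs and g % 2 == 1:
            # paralog partner: mutated copy of the previous gene's ancestor
            src = genes[-1]
            anc = src.ancestral.copy()
            mut = rng_fam.random(L) < config.paralog_divergence
            shifts = rng_fam.integers(1, 4, size=int(mut.sum()))
            anc[mut] = (anc[mut] + shifts) % 4
            fam_id = f"fam{g // 2:05d}"
            div = hamming(src.ancestral, anc) / L
            families.append(ParalogFamily(fam_id, (src.gene_id, gid), div))
            src.family_id = fam_id
            src.partner_gene_id = gid
            gene = GeneTruth(gid, anc, _simulate_pool(rng_pop, anc, n_pool, p_seg),
                             make_isoforms(gid, rng_exp), float(w[g]),
                             family_id=fam_id, partner_gene_id=src.gene_id)
        else:
            anc = rng_pop.integers(0, 4, size=L).astype(np.uint8)
            gene = GeneTruth(gid, anc, _simulate_pool(rng_pop, anc, n_pool, p_seg),
                             make_isoforms(gid, rng_exp), float(w[g]))
        genes.append(gene)

    individuals: list[Individual] = []
    n_m = config.n_mothers
    # per gene, one permutation supplies all 2*n_mothers maternal haplotypes
    maternal = np.empty((n_m, config.n_genes, 2), dtype=np.int64)
    paternal = np.empty((n_m, config.n_genes), dtype=np.int64)
    for gi in range(config.n_genes):
        perm = rng_ind.permutation(n_pool)[: 2 * n_m]
        for m in range(n_m):
            maternal[m, gi] = perm[2 * m: 2 * m + 2]
        paternal[:, gi] = rng_ind.integers(0, n_pool, size=n_m)
    mg = rng_ind.integers(0, 2, size=n_m)
    for m in range(n_m):
        individuals.append(Individual(m, maternal[m], int(mg[m]), paternal[m]))

    return TruthSet(config, genes, families, individuals)


# ---------------------------------------------------------------------------
# reference building
# ---------------------------------------------------------------------------

def _redundant_contigs(truth: TruthSet) -> list[ReferenceContig]:
    """One contig per distinct expressed allele/isoform sequence."""
    contigs: list[ReferenceContig] = []
    for gi, gene in enumerate(truth.genes):
        haps = truth.expressed_hap_indices(gi)
        for iso in gene.isoforms:
            seen: dict[bytes, ReferenceContig] = {}
            for h in haps:
                sub = gene.pool[h, iso.start:iso.end]
                key = sub.tobytes()
                label = f"{iso.iso_id}@h{h}"
                if key in seen:
                    seen[key].provenance.append((gene.gene_id, label))
                else:
                    cid = f"r_{gene.gene_id}_{iso.iso_id}_{len(contigs) + len(seen)}"
                    ctg = ReferenceContig(
                        cid, sub.copy(), "redundant",
                        [(gene.gene_id, label)],
                        [Placement(gene.gene_id, iso.start, iso.end, 0, h)])
                    seen[key] = ctg
            contigs.extend(seen.values())
    return contigs


def _clustered_contigs(truth: TruthSet, identity_cutoff: float) -> list[ReferenceContig]:
    """Greedy longest-first clustering (CD-HIT style) of the redundant set.

    A member joins the first representative with pairwise identity >=
    identity_cutoff; the representative sequence is retained. Comparisons are
    restricted to contigs of the same paralog family: unrelated simulated
    genes are i.i.d. random sequences (~75% divergence), far beyond any useful
    identity cutoff.
    """
    base = _redundant_contigs(truth)
    order = sorted(range(len(base)), key=lambda i: (-base[i].length, base[i].contig_id))
    by_family: dict[tuple[str, ...], list[ReferenceContig]] = {}
    out: list[ReferenceContig] = []
    for i in order:
        c = base[i]
        fam = truth.family_of(c.provenance[0][0])
        joined = False
        for rep in by_family.setdefault(fam, []):
            if identity_fraction(rep.seq, c.seq) >= identity_cutoff:
                rep.provenance.extend(c.provenance)
                rep.placements.extend(c.placements)
                joined = True
                break
        if not joined:
            rep = ReferenceContig(f"c_{len(out):05d}", c.seq.copy(), "clustered",
                                  list(c.provenance), list(c.placements))
            by_family[fam].append(rep)
            out.append(rep)
    return out


def _effective_count(truth: TruthSet, gene: GeneTruth, iso: Isoform) -> float:
    """Expected fragment count for an isoform summed over all samples."""
    n_samples = 3 * len(truth.individuals)
    depth = truth.config.mean_depth * gene.expression_weight * iso.weight
    return depth * (iso.end - iso.start) / truth.config.read_len * n_samples


def _supertranscript_contig(truth: TruthSet, gene: GeneTruth,
                            cid: str) -> ReferenceContig:
    """Merge a gene's surviving isoforms block-wise into one contig.

    Isoform blocks that match an already-placed region at >=
    block_merge_identity are absorbed; diverged blocks are appended after the
    primary sequence, producing mosaic contigs (consecutive near-duplicate
    blocks), the artifact the self-hit screen looks for.
    """
    from .txstats import isoform_prefilter  # shared pre-filter rule

    gi = truth.gene_index(gene.gene_id)
    rows = [(iso.iso_id, iso.end - iso.start, _effective_count(truth, gene, iso))
            for iso in gene.isoforms]
    kept_ids = isoform_prefilter(
        [(gene.gene_id, iid, ln, cnt) for iid, ln, cnt in rows])
    isos = [iso for iso in gene.isoforms if iso.iso_id in kept_ids]
    haps = truth.expressed_hap_indices(gi)

    # items: (interval, haplotype) expressed isoform copies, longest first
    items = [(iso, h) for iso in isos for h in haps]
    items.sort(key=lambda t: (-(t[0].end - t[0].start), t[0].start, t[1]))

    blocks: list[tuple[int, int, int]] = []  # (gene_start, gene_end, hap_idx)
    extra: list[tuple[int, int, int]] = []   # appended (mosaic) blocks
    pool = gene.pool
    thr = truth.config.block_merge_identity
    for iso, h in items:
        s, e = iso.start, iso.end
        # identity against already-placed bases over the overlap
        overlap_len = 0
        match_len = 0
        for bs, be, bh in blocks:
            os_, oe = max(s, bs), min(e, be)
            if oe > os_:
                overlap_len += oe - os_
                match_len += int((pool[h, os_:oe] == pool[bh, os_:oe]).sum())
        if overlap_len > 0 and match_len / overlap_len < thr:
            extra.append((s, e, h))
            continue
        # absorbed: fill any uncovered sub-intervals with this copy's bases
        covered = sorted((bs, be) for bs, be, _ in blocks)
        cur = s
        new: list[tuple[int, int, int]] = []
        for bs, be in covered:
            if bs > cur:
                new.append((cur, min(bs, e), h))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            new.append((cur, e, h))
        blocks.extend((a, b, h) for a, b, h in new if b > a)
        blocks.sort()

    parts: list[np.ndarray] = []
    placements: list[Placement] = []
    cpos = 0
    for bs, be, bh in blocks + extra:
        parts.append(pool[bh, bs:be])
        placements.append(Placement(gene.gene_id, bs, be, cpos, bh))
        cpos += be - bs
    seq = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
    prov = [(gene.gene_id, f"{iso.iso_id}@h{h}") for iso, h in items]
    return ReferenceContig(cid, seq, "supertranscript", prov, placements,
                           duplicated_blocks=bool(extra))


def build_reference(truth: TruthSet, strategy: str) -> list[ReferenceContig]:
    """Build a reference transcriptome from the truth set.

    strategy: 'redundant' (one contig per distinct expressed allele/isoform),
    'clustered' (greedy CD-HIT-like clustering at config.cluster_identity), or
    'supertranscript' (per-gene block-wise isoform merging after the
    short/low-expression isoform pre-filter).
    """
    if strategy == "redundant":
        return _redundant_contigs(truth)
    if strategy == "clustered":
        return _clustered_contigs(truth, truth.config.cluster_identity)
    if strategy == "supertranscript":
        return [_supertranscript_contig(truth, g, f"st_{g.gene_id}")
                for g in truth.genes]
    raise ValueError(f"unknown strategy: {strategy!r}")


# ---------------------------------------------------------------------------
# read-evidence emulation
# ---------------------------------------------------------------------------

def _window_starts(s: int, e: int, read_len: int, step: int) -> np.ndarray:
    """Window starts covering [s, e): every `step` bp, last anchored at e."""
    if e - s < read_len:
        return np.empty(0, dtype=np.int64)
    starts = np.arange(s, e - read_len + 1, step)
    if starts[-1] + read_len < e:
        starts = np.append(starts, e - read_len)
    return starts


def window_mismatch_counts(hap_seq: np.ndarray, contig_seq: np.ndarray,
                           gene_start: int, gene_end: int, contig_start: int,
                           starts: np.ndarray, read_len: int) -> np.ndarray:
    """Mismatch count of each read_len window of hap_seq (gene coordinates)
    against one placement; inf where the window is not fully inside it."""
    out = np.full(len(starts), np.inf)
    inside = (starts >= gene_start) & (starts + read_len <= gene_end)
    if not inside.any():
        return out
    a = hap_seq[gene_start:gene_end]
    b = contig_seq[contig_start:contig_start + (gene_end - gene_start)]
    diff = np.concatenate([[0], np.cumsum(a != b)])
    rel = starts[inside] - gene_start
    out[inside] = diff[rel + read_len] - diff[rel]
    return out


def simulate_site_evidence(truth: TruthSet, reference: list[ReferenceContig],
                           config: SimConfig | None = None,
                           ) -> Iterator[ContigEvidence]:
    """Emulate mapping + pileup, yielding per-contig evidence.

    Mapping is decided per read_len window of each expressed haplotype copy,
    with window starts every map_window_step bp (windows stand in for reads,
    which start at many offsets): a window maps iff its mismatch fraction
    against a contig placement is <= map_max_mismatch_frac and, when
    map_unique_only, the best placement is unique (ties discarded, as with a
    unique-locus mapping rule). Each mapped window contributes
    Poisson(mean_depth x expression share x step/read_len) reads, so expected
    coverage away from contig edges equals the expression-scaled mean depth;
    sequencing errors substitute bases to a uniformly random other base at
    error_rate.
    """
    if config is None:
        config = truth.config
    ref_gene_ids = {g for c in reference for g in c.source_genes}
    truth_gene_ids = {g.gene_id for g in truth.genes}
    if not ref_gene_ids <= truth_gene_ids:
        raise ValueError("reference refers to genes absent from the truth set")

    rng = _spawn(config.seed, "evidence")
    samples = truth.samples()
    sample_ids = [s for s, _ in samples]
    groups = [g for _, g in samples]
    s_index = {s: i for i, s in enumerate(sample_ids)}
    rl = config.read_len
    step = config.map_window_step
    max_mism = config.map_max_mismatch_frac * rl

    # group contigs by paralog family; evidence never crosses families
    fam_contigs: dict[tuple[str, ...], list[ReferenceContig]] = {}
    for c in reference:
        fam = truth.family_of(c.provenance[0][0])
        fam_contigs.setdefault(fam, []).append(c)

    for fam in sorted(fam_contigs):
        contigs = fam_contigs[fam]
        counts = [np.zeros((len(sample_ids), 4, c.length), dtype=np.int32)
                  for c in contigs]
        # distinct loci: placements deduplicated by (contig, offset, span)
        placements: list[tuple[int, Placement]] = []
        seen = set()
        for ci, ctg in enumerate(contigs):
            for p in ctg.placements:
                key = (ci, p.contig_start - p.gene_start, p.gene_start, p.gene_end)
                if key not in seen:
                    seen.add(key)
                    placements.append((ci, p))
        for gene_id in fam:
            gi = truth.gene_index(gene_id)
            gene = truth.genes[gi]
            for sid, grp in samples:
                haps = truth.sample_hap_indices(sid, gi)
                dose = 1.0 / len(haps)  # diploid copies split the gene's reads
                si = s_index[sid]
                for h in haps:
                    hap_seq = gene.pool[h]
                    for iso in gene.isoforms:
                        lam = (config.mean_depth * gene.expression_weight
                               * iso.weight * dose * step / rl)
                        starts = _window_starts(iso.start, iso.end, rl, step)
                        if len(starts) == 0:
                            continue
                        mism = np.vstack([
                            window_mismatch_counts(hap_seq, contigs[ci].seq,
                                                   p.gene_start, p.gene_end,
                                                   p.contig_start, starts, rl)
                            for ci, p in placements])
                        mism[mism > max_mism] = np.inf
                        best = mism.min(axis=0)
                        mapped = np.isfinite(best)
                        if config.map_unique_only:
                            ties = (mism == best[None, :]).sum(axis=0)
                            mapped &= ties == 1
                        choice = mism.argmin(axis=0)
                        d_w = rng.poisson(lam, size=len(starts))
                        d_w[~mapped] = 0
                        for pi, (ci, p) in enumerate(placements):
                            sel = (choice == pi) & (d_w > 0) & mapped
                            if not sel.any():
                                continue
                            span = p.gene_end - p.gene_start
                            delta = np.zeros(span + 1, dtype=np.int64)
                            rel = starts[sel] - p.gene_start
                            np.add.at(delta, rel, d_w[sel])
                            np.add.at(delta, rel + rl, -d_w[sel])
                            dep = np.cumsum(delta[:-1])
                            cov = dep > 0
                            if not cov.any():
                                continue
                            bases = hap_seq[p.gene_start:p.gene_end][cov]
                            cpos = np.arange(p.contig_start,
                                             p.contig_start + span)[cov]
                            np.add.at(counts[ci][si], (bases.astype(np.int64),
                                                       cpos), dep[cov])
        for c, cnt in zip(contigs, counts):
            if config.error_rate > 0:
                n_err = rng.binomial(cnt, config.error_rate)
                if n_err.sum() > 0:
                    cnt -= n_err
                    for b in range(4):
                        eb = n_err[:, b, :]
                        nz = eb > 0
                        if not nz.any():
                            continue
                        # split errors of base b uniformly over the other bases
                        others = [x for x in range(4) if x != b]
                        split = rng.multinomial(eb[nz], [1 / 3] * 3)
                        sidx, pidx = np.nonzero(nz)
                        for k, ob in enumerate(others):
                            np.add.at(cnt, (sidx, np.full_like(sidx, ob), pidx),
                                      split[:, k])
            yield ContigEvidence(c.contig_id, c.length, sample_ids, groups, cnt)


def simulate_hwe_site_evidence(n_sites: int, n_diploids: int, depth: int,
                               seed: int, sfs_pool_size: int = 200,
                               error_rate: float = 0.0,
                               group: str = "EM",
                               chunk: int = 20000) -> Iterator[ContigEvidence]:
    """Site-level HWE simulation: biallelic sites with derived-allele
    frequencies from the neutral SFS, diploid genotypes drawn under
    Hardy-Weinberg equilibrium at uniform per-sample depth.

    Reads of a heterozygote split Binomial(depth, 1/2) between the two
    alleles; error_rate substitutes reads to a uniformly random other base.
    Yields synthetic per-contig evidence blocks directly (no reference
    needed), for calibration experiments on the caller + filter + estimator
    chain.
    """
    rng = _spawn(seed, "hwe-sites")
    sample_ids = [f"{group}_{i}" for i in range(n_diploids)]
    groups = [group] * n_diploids
    i_vals = np.arange(1, sfs_pool_size)
    sfs = (1.0 / i_vals) / (1.0 / i_vals).sum()
    done = 0
    block = 0
    while done < n_sites:
        L = min(chunk, n_sites - done)
        p = rng.choice(i_vals, size=L, p=sfs) / sfs_pool_size
        anc = rng.integers(0, 4, size=L)
        der = (anc + rng.integers(1, 4, size=L)) % 4
        # HWE genotypes: number of derived alleles per sample ~ Binomial(2, p)
        n_der = rng.binomial(2, p[None, :].repeat(n_diploids, axis=0))
        counts = np.zeros((n_diploids, 4, L), dtype=np.int32)
        der_reads = np.where(
            n_der == 2, depth,
            np.where(n_der == 1, rng.binomial(depth, 0.5, size=n_der.shape), 0))
        anc_reads = depth - der_reads
        rows = np.arange(n_diploids)[:, None].repeat(L, axis=1)
        cols = np.arange(L)[None, :].repeat(n_diploids, axis=0)
        np.add.at(counts, (rows, der[None, :].repeat(n_diploids, 0), cols),
                  der_reads)
        np.add.at(counts, (rows, anc[None, :].repeat(n_diploids, 0), cols),
                  anc_reads)
        if error_rate > 0:
            for b in range(4):
                n_err = rng.binomial(counts[:, b, :], error_rate)
                if n_err.sum() == 0:
                    continue
                shift = rng.integers(1, 4, size=n_err.shape)
                tgt = (b + shift) % 4
                counts[:, b, :] -= n_err
                np.add.at(counts, (rows, tgt, cols), n_err)
        yield ContigEvidence(f"hwe_{block:04d}", L, sample_ids, groups, counts)
        done += L
        block += 1


def write_reference_fasta(reference: Iterable[ReferenceContig], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(c.sequence), id=c.contig_id,
                      description=f"strategy={c.strategy_label}")
            for c in reference]
    seqio_write(recs, str(path), "fasta")


def write_truth_tables(truth: TruthSet, reference: list[ReferenceContig],
                       path) -> None:
    """Contig provenance table: gene, contig, provenance labels, collapse flag."""
    import pandas as pd

    rows = []
    for c in reference:
        for gene_id, label in c.provenance:
            rows.append({"contig_id": c.contig_id, "gene_id": gene_id,
                         "source": label, "strategy": c.strategy_label,
                         "truth_collapsed": c.truth_collapsed})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
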