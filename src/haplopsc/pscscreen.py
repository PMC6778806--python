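"""Transcript screening: haploid-heterozygosity PSC flags, single/multi-copy
classification from alignment hits, mosaic self-hits, organelle and
contaminant screens, plus a small seed-and-extend local aligner for synthetic
references (BLAST-scale searches are consumed as outfmt-6 tabular input).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import encode
from .config import ScreenParams

OUTFMT6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                   "gapopen", "qstart", "qend", "sstart", "send",
                   "evalue", "bitscore"]


@dataclass
class AlignmentHit:
    """One BLAST-outfmt-6 style hit; coordinates 1-based inclusive."""
    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gapopen: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:  # orientation normalization
            self.q_start, self.q_end = self.q_end, self.q_start
            self.s_start, self.s_end = self.s_end, self.s_start
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity outside [0, 100]")


def read_blast_tab(path) -> list[AlignmentHit]:
    df = pd.read_csv(path, sep="\t", header=None, names=OUTFMT6_COLUMNS,
                     comment="#")
    return [AlignmentHit(r.qseqid, r.sseqid, float(r.pident), int(r.length),
                         int(r.mismatch), int(r.gapopen), int(r.qstart),
                         int(r.qend), int(r.sstart), int(r.send),
                         float(r.evalue), float(r.bitscore))
            for r in df.itertuples()]


def write_blast_tab(hits: list[AlignmentHit], path) -> None:
    pd.DataFrame([{
        "qseqid": h.query_id, "sseqid": h.subject_id,
        "pident": round(h.pct_identity, 3), "length": h.aln_len,
        "mismatch": h.mismatches, "gapopen": h.gapopen,
        "qstart": h.q_start, "qend": h.q_end, "sstart": h.s_start,
        "send": h.s_end, "evalue": h.evalue, "bitscore": round(h.bitscore, 1),
    } for h in hits]).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# screening rules
# ---------------------------------------------------------------------------

def flag_haploid_het(stats, min_callable: int = 100) -> dict[str, bool]:
    """PSC flag: observed heterozygosity > 0 in the haploid (ME) group.

    Only transcripts passing the min_callable reporting rule are flagged
    (others are absent from the result, i.e. unassessed).
    """
    out: dict[str, bool] = {}
    for s in stats:
        if s.group != "ME" or s.n_sites <= min_callable or s.ho_per_bp is None:
            continue
        out[s.contig_id] = s.ho_per_bp > 0
    return out


def _trimmed_interval(h: AlignmentHit, trim: int) -> tuple[int, int] | None:
    """Query interval after trimming `trim` bp from each alignment edge;
    returned 0-based half-open, or None when nothing remains."""
    a, b = h.q_start + trim, h.q_end - trim
    if b < a:
        return None
    return a - 1, b


def classify_copy_number(hits: list[AlignmentHit],
                         transcript_lengths: dict[str, int],
                         params: ScreenParams | None = None) -> dict[str, str]:
    """single / multi / unassigned per transcript from genome-wide hits.

    Each hit's query interval is trimmed (edge_trim per side). A transcript
    is multi-copy iff some query position is covered by >= 2 trimmed hits
    with identity strictly > multi_copy_identity; otherwise single-copy iff
    the trimmed hits cover >= min_coverage of the transcript length; else
    unassigned.
    """
    if params is None:
        params = ScreenParams()
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    out: dict[str, str] = {}
    for tid, length in transcript_lengths.items():
        hs = by_query.get(tid, [])
        trimmed = [(iv, h) for h in hs
                   if (iv := _trimmed_interval(h, params.edge_trim)) is not None]
        hi = sorted(iv for iv, h in trimmed
                    if h.pct_identity > params.multi_copy_identity)
        multi = False
        max_end = -1
        for a, b in hi:
            if a < max_end:
                multi = True
                break
            max_end = max(max_end, b)
        if multi:
            out[tid] = "multi"
            continue
        cov = 0
        cur_a = cur_b = None
        for a, b in sorted(iv for iv, _ in trimmed):
            if cur_b is None or a > cur_b:
                if cur_b is not None:
                    cov += cur_b - cur_a
                cur_a, cur_b = a, b
            else:
                cur_b = max(cur_b, b)
        if cur_b is not None:
            cov += cur_b - cur_a
        out[tid] = "single" if cov >= params.min_coverage * length else "unassigned"
    return out


def detect_mosaics(self_hits: list[AlignmentHit]) -> dict[str, bool]:
    """Mosaic iff a self-hit aligns two non-identical regions of a transcript
    (the full-length identity match, and any hit whose query and subject
    intervals coincide, is not evidence). Invariant to query/subject swap."""
    out: dict[str, bool] = {}
    for h in self_hits:
        if h.query_id != h.subject_id:
            continue
        out.setdefault(h.query_id, False)
        qi = (h.q_start, h.q_end)
        si = tuple(sorted((h.s_start, h.s_end)))
        if qi != si:
            out[h.query_id] = True
    return out


def screen_organelle(hits: list[AlignmentHit],
                     params: ScreenParams | None = None) -> dict[str, bool]:
    """Organelle flag: any hit with evalue <= cutoff and identity >= cutoff."""
    if params is None:
        params = ScreenParams()
    out: dict[str, bool] = {}
    for h in hits:
        ok = h.evalue <= params.organelle_evalue and \
            h.pct_identity >= params.organelle_identity
        out[h.query_id] = out.get(h.query_id, False) or ok
    return out


def screen_contaminants(hits: list[AlignmentHit],
                        params: ScreenParams | None = None) -> dict[str, bool]:
    """Contaminant flag: any hit with evalue <= cutoff and identity >= cutoff."""
    if params is None:
        params = ScreenParams()
    out: dict[str, bool] = {}
    for h in hits:
        ok = h.evalue <= params.contaminant_evalue and \
            h.pct_identity >= params.contaminant_identity
        out[h.query_id] = out.get(h.query_id, False) or ok
    return out


@dataclass
class TranscriptFlags:
    contig_id: str
    haploid_het: bool | None = None     # None = unassessed
    copy_class: str = "unassigned"      # single | multi | unassigned
    mosaic: bool = False
    organelle: bool = False
    contaminant: bool = False
    low_expression: bool = False


def combine_flags(contig_ids, haploid_het=None, copy_class=None, mosaic=None,
                  organelle=None, contaminant=None, low_expression=None
                  ) -> dict[str, TranscriptFlags]:
    def g(d, cid, default):
        return default if d is None else d.get(cid, default)

    return {cid: TranscriptFlags(
        cid,
        haploid_het=None if haploid_het is None else haploid_het.get(cid),
        copy_class=g(copy_class, cid, "unassigned"),
        mosaic=g(mosaic, cid, False),
        organelle=g(organelle, cid, False),
        contaminant=g(contaminant, cid, False),
        low_expression=g(low_expression, cid, False),
    ) for cid in contig_ids}


def flags_frame(flags: dict[str, TranscriptFlags]) -> pd.DataFrame:
    return pd.DataFrame([{
        "contig_id": f.contig_id, "haploid_het": f.haploid_het,
        "copy_class": f.copy_class, "mosaic": f.mosaic,
        "organelle": f.organelle, "contaminant": f.contaminant,
        "low_expression": f.low_expression,
    } for f in flags.values()])


# ---------------------------------------------------------------------------
# internal seed-and-extend local aligner
# ---------------------------------------------------------------------------

@dataclass
class AlignParams:
    """Seed-and-extend alignment parameters (desk-scale BLASTN substitute)."""
    k: int = 11
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5      # affine: first gapped base
    gap_extend: int = -2
    xdrop: int = 20
    min_len: int = 60
    min_identity: float = 80.0
    # Karlin-Altschul-style constants for the +1/-2 scoring (rough)
    lambda_: float = 1.28
    k_const: float = 0.46
    seed_join: int = field(default=25)  # max gap between seeds on a diagonal


def _extend_ungapped(q: np.ndarray, s: np.ndarray, qs: int, qe: int, d: int,
                     p: AlignParams) -> tuple[int, int]:
    """Extend [qs, qe) on diagonal d (spos = qpos - d) with X-drop; returns
    the best-scoring interval."""
    # right extension
    best, score, best_qe = 0, 0, qe
    j = qe
    while j < len(q) and 0 <= j - d < len(s):
        score += p.match if q[j] == s[j - d] else p.mismatch
        if score > best:
            best, best_qe = score, j + 1
        if best - score > p.xdrop:
            break
        j += 1
    qe = best_qe
    best, score, best_qs = 0, 0, qs
    j = qs - 1
    while j >= 0 and 0 <= j - d < len(s):
        score += p.match if q[j] == s[j - d] else p.mismatch
        if score > best:
            best, best_qs = score, j
        if best - score > p.xdrop:
            break
        j -= 1
    return best_qs, qe


def _kmer_index(seqs: dict[str, np.ndarray], k: int) -> dict[bytes, list]:
    idx: dict[bytes, list] = {}
    for sid, arr in seqs.items():
        b = arr.tobytes()
        for i in range(len(arr) - k + 1):
            idx.setdefault(b[i:i + k], []).append((sid, i))
    return idx


def align_many(queries: dict[str, str], subjects: dict[str, str],
               params: AlignParams | None = None) -> list[AlignmentHit]:
    """Local alignment of every query against a subject set.

    Exact k-mer seeds are grouped per (subject, diagonal), joined into runs,
    extended ungapped with X-drop, and collinear runs on nearby diagonals are
    chained under affine gap penalties. Hits above min_len and min_identity
    are reported with rough Karlin-Altschul e-values. Ungapped-first and
    forward-strand only, which matches the simulator's indel-free sequences.
    Deterministic.
    """
    if params is None:
        params = AlignParams()
    p = params
    q_enc = {qid: encode(s) for qid, s in queries.items()}
    s_enc = {sid: encode(s) for sid, s in subjects.items()}
    for name, enc_map in (("query", q_enc), ("subject", s_enc)):
        for sid, arr in enc_map.items():
            if len(arr) == 0:
                raise ValueError(f"empty {name} sequence: {sid}")
    idx = _kmer_index(s_enc, p.k)
    total_subject_len = sum(len(a) for a in s_enc.values())

    hits: list[AlignmentHit] = []
    for qid in sorted(q_enc):
        q = q_enc[qid]
        qb = q.tobytes()
        seeds: dict[tuple[str, int], list[int]] = {}
        for i in range(len(q) - p.k + 1):
            for sid, spos in idx.get(qb[i:i + p.k], ()):
                seeds.setdefault((sid, i - spos), []).append(i)
        raw: dict[str, list[tuple[int, int, int]]] = {}
        for (sid, d), qpos_list in sorted(seeds.items()):
            qpos_list.sort()
            runs: list[tuple[int, int]] = []
            rs = re_ = qpos_list[0]
            for i in qpos_list[1:]:
                if i - re_ <= p.seed_join:
                    re_ = i
                else:
                    runs.append((rs, re_ + p.k))
                    rs = re_ = i
            runs.append((rs, re_ + p.k))
            s = s_enc[sid]
            merged: list[tuple[int, int]] = []
            for rs, re_ in runs:
                qs, qe = _extend_ungapped(q, s, rs, re_, d, p)
                if merged and qs <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], qe))
                else:
                    merged.append((qs, qe))
            for qs, qe in merged:
                raw.setdefault(sid, []).append((qs, qe, d))

        for sid, segs in sorted(raw.items()):
            s = s_enc[sid]
            # affine chaining of collinear segments on nearby diagonals
            segs.sort()
            chained: list[list[tuple[int, int, int]]] = []
            for seg in segs:
                placed = False
                if chained:
                    lqs, lqe, ld = chained[-1][-1]
                    qs, qe, d = seg
                    gap_q = qs - lqe
                    gap_d = abs(d - ld)
                    if 0 <= gap_q <= 30 and 0 < gap_d <= 15:
                        gain = self_score = (qe - qs) * p.match
                        cost = -(p.gap_open + p.gap_extend * (gap_d - 1)) \
                            - gap_q * 0  # query gap bases scored as gap too
                        if gain > cost:
                            chained[-1].append(seg)
                            placed = True
                if not placed:
                    chained.append([seg])
            for chain in chained:
                qs = chain[0][0]
                qe = chain[-1][1]
                matches = 0
                aln_len = 0
                gapopen = 0
                gapbases = 0
                for i, (a, b, d) in enumerate(chain):
                    sub = s[a - d:b - d]
                    matches += int((q[a:b] == sub).sum())
                    aln_len += b - a
                    if i > 0:
                        gapopen += 1
                        gapbases += abs(d - chain[i - 1][2])
                aln_len += gapbases
                if aln_len < p.min_len:
                    continue
                ident = 100.0 * matches / aln_len
                if ident < p.min_identity:
                    continue
                mism = (aln_len - gapbases) - matches
                score = matches * p.match + mism * p.mismatch + \
                    gapopen * p.gap_open + max(gapbases - gapopen, 0) * p.gap_extend
                bits = (p.lambda_ * score - np.log(p.k_const)) / np.log(2.0)
                evalue = len(q) * total_subject_len * 2.0 ** (-bits)
                d0 = chain[0][2]
                dn = chain[-1][2]
                hits.append(AlignmentHit(qid, sid, ident, aln_len, mism,
                                         gapopen, qs + 1, qe,
                                         qs - d0 + 1, qe - dn,
                                         float(evalue), float(bits)))
    hits.sort(key=lambda h: (h.query_id, h.evalue, h.subject_id,
                             h.q_start, h.s_start))
    return hits


def local_align(query: str, subject: str,
                params: AlignParams | None = None) -> list[AlignmentHit]:
    """Pairwise local alignment (see align_many)."""
    return align_many({"query": query}, {"subject": subject}, params)


def self_align(sequences: dict[str, str],
               params: AlignParams | None = None) -> list[AlignmentHit]:
    """Self-hits of each sequence against itself (mosaic detection input)."""
    out: list[AlignmentHit] = []
    for sid in sorted(sequences):
        for h in local_align(sequences[sid], sequences[sid], params):
            h.query_id = sid
            h.subject_id = sid
            out.append(h)
    return out
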