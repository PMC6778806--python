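"""Assembly-level and expression statistics: N50, TPM, ExN50, isoform and
low-expression filters."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass
class AssemblyStats:
    n_contigs: int
    total_bases: int
    mean_length: float
    n50: int


def n50(lengths: Sequence[int]) -> int:
    """Descending-cumulative N50: the length L such that contigs >= L cover
    at least half the total bases."""
    ls = sorted((int(x) for x in lengths), reverse=True)
    if not ls:
        raise ValueError("empty length set")
    half = sum(ls) / 2.0
    cum = 0
    for L in ls:
        cum += L
        if cum >= half:
            return L
    return ls[-1]  # pragma: no cover


def assembly_stats(lengths: Sequence[int]) -> AssemblyStats:
    ls = [int(x) for x in lengths]
    if not ls:
        raise ValueError("empty assembly")
    return AssemblyStats(len(ls), sum(ls), sum(ls) / len(ls), n50(ls))


def assembly_stats_fasta(path) -> AssemblyStats:
    from Bio import SeqIO
    lengths = [len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    return assembly_stats(lengths)


@dataclass
class ExpressionMatrix:
    """Transcript x sample effective counts with lengths and derived TPM."""
    counts: pd.DataFrame   # index: transcript_id, columns: samples
    lengths: pd.Series     # bp per transcript

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.lengths.index):
            self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise ValueError("lengths missing for some transcripts")
        if (self.lengths <= 0).any():
            raise ValueError("transcript lengths must be > 0")
        if (self.counts < 0).to_numpy().any():
            raise ValueError("counts must be >= 0")

    @property
    def tpm(self) -> pd.DataFrame:
        rate = self.counts.div(self.lengths, axis=0)
        tot = rate.sum(axis=0)
        tpm = rate.div(tot.where(tot > 0), axis=1) * 1e6
        return tpm  # all-zero samples yield NaN columns (flagged undefined)

    @property
    def mean_tpm(self) -> pd.Series:
        return self.tpm.mean(axis=1)

    @property
    def total_counts(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @classmethod
    def read_tsv(cls, counts_path, lengths: pd.Series) -> "ExpressionMatrix":
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
        return cls(df, lengths)


def compute_tpm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """TPM_i = (count_i / length_i) / sum_j (count_j / length_j) * 1e6."""
    return matrix.tpm


def exn50(matrix: ExpressionMatrix, x: float = 90.0) -> int:
    """N50 of the most-expressed transcripts accounting for x% of expression.

    Expression is pooled across samples (summed counts). Transcripts are
    ranked by expression descending; the smallest prefix whose share of total
    expression reaches x% defines the set whose lengths are N50'd.
    """
    if not 0 < x <= 100:
        raise ValueError("x must be in (0, 100]")
    expr = matrix.total_counts
    total = expr.sum()
    if total <= 0:
        raise ValueError("total expression must be > 0")
    order = expr.sort_values(ascending=False, kind="stable")
    cum = order.cumsum() / total
    k = int(np.searchsorted(cum.to_numpy(), x / 100.0) + 1)
    k = min(k, len(order))
    prefix_ids = order.index[:k]
    return n50(matrix.lengths.loc[prefix_ids])


def low_expression_filter(matrix: ExpressionMatrix, tpm_cutoff: float = 10.0,
                          gene_of: dict[str, str] | None = None) -> dict[str, bool]:
    """Flag transcripts whose gene-level mean TPM is <= tpm_cutoff.

    The retention rule is strictly '> cutoff'; a gene at exactly the cutoff
    is flagged. gene_of maps transcript -> gene (identity by default);
    gene-level TPM sums transcript TPM within the gene.
    """
    mean_tpm = matrix.mean_tpm.fillna(0.0)
    if gene_of is None:
        gene_tpm = mean_tpm
        return {t: bool(gene_tpm[t] <= tpm_cutoff) for t in matrix.counts.index}
    df = pd.DataFrame({"tpm": mean_tpm})
    df["gene"] = [gene_of.get(t, t) for t in df.index]
    gene_tpm = df.groupby("gene")["tpm"].sum()
    return {t: bool(gene_tpm[df.loc[t, "gene"]] <= tpm_cutoff)
            for t in df.index}


def isoform_prefilter(isoforms: Iterable[tuple[str, str, int, float]],
                      len_min: int = 300, count_min: float = 10.0) -> set[str]:
    """Drop short (length <= len_min) or low-expressed (count <= count_min)
    isoforms; if a gene loses all isoforms, its longest is kept.

    isoforms: iterable of (gene_id, isoform_id, length, total_effective_count).
    Returns the retained isoform-id set; never empties a gene.
    """
    by_gene: dict[str, list[tuple[str, int, float]]] = {}
    for gene_id, iso_id, length, count in isoforms:
        by_gene.setdefault(gene_id, []).append((iso_id, int(length), float(count)))
    kept: set[str] = set()
    for gene_id, rows in by_gene.items():
        ok = [iid for iid, ln, cnt in rows if ln > len_min and cnt > count_min]
        if ok:
            kept.update(ok)
        else:
            # keep-longest fallback (ties broken by isoform id)
            longest = max(rows, key=lambda r: (r[1], r[0]))[0]
            kept.add(longest)
    return kept
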