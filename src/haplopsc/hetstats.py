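"""Observed and expected heterozygosity per transcript and assembly-wide.

H_o is micro-averaged: heterozygous calls summed over samples divided by
surviving per-sample site observations. Expected heterozygosity (pi) uses the
unbiased per-site estimator n/(n-1) * (1 - sum p_hat^2) on pooled called
alleles across the group's non-missing samples, averaged over callable sites;
monomorphic callable sites contribute zero, so pi is per callable bp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import GroupSiteData
from .simcore import GROUPS


@dataclass
class TranscriptHetStats:
    contig_id: str
    group: str
    n_sites: int          # distinct callable positions
    n_obs: int            # per-sample callable site observations
    n_het: int
    ho_per_bp: float | None   # None when n_obs == 0 (undefined, not 0)
    pi_per_bp: float | None   # None when no site has >= 2 pooled alleles
    pi_sum: float             # sum of per-site pi over callable sites
    n_pi_sites: int           # callable sites with >= 2 pooled alleles
    n_alleles_median: float


def site_pi(counts) -> float:
    """Unbiased per-site expected heterozygosity from pooled allele counts.

    pi_hat = n/(n-1) * (1 - sum p_k^2) = (n^2 - sum c_k^2) / (n (n-1)),
    computed as a single integer-ratio division so it equals the all-pairs
    difference fraction exactly.
    """
    c = [int(x) for x in counts]
    n = sum(c)
    if n < 2:
        raise ValueError("site_pi requires >= 2 pooled alleles")
    return (n * n - sum(x * x for x in c)) / (n * (n - 1))


def transcript_stats(gsd: GroupSiteData) -> TranscriptHetStats:
    """Combined observed + expected heterozygosity for one contig/group."""
    n_sites = len(gsd.positions)
    n_obs = int(gsd.n_obs_per_site.sum())
    n_het = int(gsd.het_per_site.sum())
    pooled_n = gsd.pooled_counts.sum(axis=0)
    ok = pooled_n >= 2
    pi_sum = float(sum(site_pi(gsd.pooled_counts[:, j])
                       for j in np.nonzero(ok)[0]))
    n_pi = int(ok.sum())
    return TranscriptHetStats(
        gsd.contig_id, gsd.group, n_sites, n_obs, n_het,
        (n_het / n_obs) if n_obs > 0 else None,
        (pi_sum / n_pi) if n_pi > 0 else None,
        pi_sum, n_pi,
        float(np.median(pooled_n[ok])) if n_pi else math.nan,
    )


def observed_het(gsd: GroupSiteData) -> float | None:
    """Micro-averaged per-bp observed heterozygosity (None when undefined)."""
    return transcript_stats(gsd).ho_per_bp


def expected_het(gsd: GroupSiteData) -> float | None:
    """Per-bp unbiased expected heterozygosity (pi) over callable sites."""
    return transcript_stats(gsd).pi_per_bp


@dataclass
class AssemblySummary:
    """Assembly-wide aggregates per ploidy group plus the ratio panel.

    Values in `groups` are per-bp internally; `to_frame` applies the x1000
    report scaling. Ratios with an undefined or zero denominator are None.
    """
    groups: dict[str, dict[str, float]]
    ratios: dict[str, float | None]
    min_callable: int

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for g, d in self.groups.items():
            rows[g] = {
                "n_callable_sites": d["n_sites"],
                "n_observations": d["n_obs"],
                "He_x1000": None if d["he"] is None else d["he"] * 1000,
                "Ho_x1000": None if d["ho"] is None else d["ho"] * 1000,
            }
        return pd.DataFrame(rows).T


def _agg(stats: list[TranscriptHetStats]) -> dict[str, float]:
    n_sites = sum(s.n_sites for s in stats)
    n_obs = sum(s.n_obs for s in stats)
    n_het = sum(s.n_het for s in stats)
    pi_sum = sum(s.pi_sum for s in stats)
    n_pi = sum(s.n_pi_sites for s in stats)
    # pi averaged over all callable sites, callable-weighted across transcripts
    return {
        "n_sites": n_sites, "n_obs": n_obs, "n_het": n_het,
        "ho": (n_het / n_obs) if n_obs else None,
        "he": (pi_sum / n_sites) if n_sites else None,
    }


def _ratio(num, den):
    if num is None or den is None or den == 0:
        return None
    return num / den


def summarize_ratios(stats: list[TranscriptHetStats],
                     min_callable: int = 100) -> AssemblySummary:
    """Aggregate per-group H_o/H_E and the haploid/diploid ratio panel.

    Transcripts with <= min_callable callable sites (per group) are excluded,
    mirroring a '>100 callable sites' reporting rule. Absent groups yield
    None ('NA') ratios.
    """
    by_group: dict[str, list[TranscriptHetStats]] = {}
    for s in stats:
        if s.n_sites > min_callable:
            by_group.setdefault(s.group, []).append(s)
    groups = {g: _agg(by_group[g]) for g in GROUPS if g in by_group}

    def get(g, k):
        return groups[g][k] if g in groups else None

    ratios = {
        "Ho_ME/EM": _ratio(get("ME", "ho"), get("EM", "ho")),
        "Ho_ME/VEG": _ratio(get("ME", "ho"), get("VEG", "ho")),
        "HoHe_ME": _ratio(get("ME", "ho"), get("ME", "he")),
        "HoHe_EM": _ratio(get("EM", "ho"), get("EM", "he")),
        "HoHe_VEG": _ratio(get("VEG", "ho"), get("VEG", "he")),
    }
    return AssemblySummary(groups, ratios, min_callable)


def stats_frame(stats: list[TranscriptHetStats]) -> pd.DataFrame:
    return pd.DataFrame([{
        "contig_id": s.contig_id, "group": s.group, "n_sites": s.n_sites,
        "n_obs": s.n_obs, "n_het": s.n_het, "ho_per_bp": s.ho_per_bp,
        "pi_per_bp": s.pi_per_bp, "n_alleles_median": s.n_alleles_median,
    } for s in stats])


def stratify_by_flags(stats: list[TranscriptHetStats],
                      flags: dict[str, "object"]) -> pd.DataFrame:
    """Per-stratum heterozygosity summary (single / multi / mosaic / other).

    Stratum precedence: multi-copy > single-copy > mosaic > other; a
    transcript appears in exactly one stratum. `flags` maps contig_id to a
    TranscriptFlags-like object with copy_class and mosaic attributes.
    """
    rows = []
    for s in stats:
        f = flags.get(s.contig_id)
        if f is None:
            stratum = "other"
        elif f.copy_class == "multi":
            stratum = "multi"
        elif f.copy_class == "single":
            stratum = "single"
        elif f.mosaic:
            stratum = "mosaic"
        else:
            stratum = "other"
        rows.append({"stratum": stratum, "group": s.group,
                     "ho": s.ho_per_bp, "pi": s.pi_per_bp,
                     "het_positive": (s.ho_per_bp or 0) > 0})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return df.groupby(["group", "stratum"]).agg(
        n_transcripts=("ho", "size"),
        n_het_positive=("het_positive", "sum"),
        mean_ho=("ho", "mean"),
        mean_pi=("pi", "mean"),
    ).reset_index()
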