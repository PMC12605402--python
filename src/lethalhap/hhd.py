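"""Homozygous haplotype deficiency scan.

Builds fixed non-overlapping marker windows over phased genotypes, labels
window haplotypes, counts carriers and homozygotes, and computes the
expected number of homozygotes and the probability of observing zero under
two models:

* random mating: with haplotype frequency ``p`` (carrier frequency
  ``C = 2p``), the expected count is ``(C^2/4) * N = p^2 * N`` and the
  zero-homozygote probability is ``(1 - C^2/4)^N``;
* carrier matings: qualifying carrier-sire x carrier-dam (or, when the dam
  is ungenotyped, carrier-sire x carrier-maternal-grand-sire) matings each
  contribute 1/4 of an expected homozygote and a 3/4 survival factor, so
  the probability of zero homozygotes is ``0.75 ** n_matings``.

Also provides the per-marker deletion screen (Hardy-Weinberg exact test and
mean log R intensity of carriers vs non-carriers).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import Pedigree, PhasedGenotypes

logger = logging.getLogger("lethalhap")


@dataclass
class HaplotypeWindow:
    window_id: str
    chromosome: object
    start_marker: int  # 0-based marker index into the full map, inclusive
    end_marker: int    # inclusive
    start_bp: int
    end_bp: int

    @property
    def length_markers(self) -> int:
        return self.end_marker - self.start_marker + 1


@dataclass
class HHDRecord:
    haplotype_id: str
    window: HaplotypeWindow
    frequency: float
    n_genotyped: int
    n_carriers: int
    obs_hom: int
    exp_random: float
    p_random: float
    n_carrier_matings: int
    exp_mating: float
    p_mating: float
    n_window: int = 0


@dataclass
class ScanConfig:
    window_length: int = 75
    min_frequency: float = 0.01  # 0.05 is the convention for 25-marker scans
    offset: int = 0
    max_obs_hom: int = 0  # only zero-homozygote haplotypes are reported


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def build_windows(marker_map, length_markers: int, offset: int = 0) -> list[HaplotypeWindow]:
    """Consecutive non-overlapping windows per chromosome starting at
    ``offset`` markers into each chromosome.  A terminal remainder shorter
    than ``length_markers / 2`` is merged into the previous window."""
    if length_markers < 2:
        raise ValueError("window length must be >= 2 markers")
    windows: list[HaplotypeWindow] = []
    widx = 0
    positions = marker_map.positions
    for chrom in marker_map.chromosomes:
        sl = marker_map.chromosome_slice(chrom)
        lo, hi = sl.start + offset, sl.stop
        if hi - lo < 2:
            logger.warning("chromosome %s has < 2 usable markers; skipped", chrom)
            continue
        starts = list(range(lo, hi, length_markers))
        bounds = []
        for s in starts:
            e = min(s + length_markers, hi) - 1
            bounds.append([s, e])
        if len(bounds) > 1 and (bounds[-1][1] - bounds[-1][0] + 1) < length_markers / 2:
            bounds[-2][1] = bounds[-1][1]
            bounds.pop()
        for s, e in bounds:
            windows.append(
                HaplotypeWindow(
                    window_id=f"w{widx}",
                    chromosome=chrom,
                    start_marker=s,
                    end_marker=e,
                    start_bp=int(positions[s]),
                    end_bp=int(positions[e]),
                )
            )
            widx += 1
    return windows


# ---------------------------------------------------------------------------
# haplotype calling and counting
# ---------------------------------------------------------------------------

def call_window_haplotypes(
    phased: PhasedGenotypes, window: HaplotypeWindow, min_frequency: float = 0.0
):
    """Label the distinct haplotypes within a window.

    Individuals with any missing allele in the window are excluded from that
    window's count.  Returns ``(labels, freq_table)`` where ``labels`` is an
    (n, 2) int array of haplotype ranks (-1 for excluded individuals) and
    ``freq_table`` is a DataFrame (rank, allele_string, count, frequency,
    discarded) sorted by descending frequency.  Frequencies sum to 1 over the
    retained chromosomes; haplotypes below ``min_frequency`` are flagged
    ``discarded`` but keep their rank.
    """
    seg = phased.haplotypes[:, :, window.start_marker : window.end_marker + 1]
    n = phased.n_individuals
    ok = ~(seg < 0).any(axis=2).any(axis=1)  # both haplotypes fully called
    labels = np.full((n, 2), -1, dtype=np.int64)
    if not ok.any():
        return labels, pd.DataFrame(
            columns=["rank", "allele_string", "count", "frequency", "discarded"]
        )
    flat = seg[ok].reshape(-1, seg.shape[2])  # 2 * n_ok haplotype vectors
    strings = np.array(["".join(map(str, row)) for row in flat])
    uniq, inverse, counts = np.unique(strings, return_inverse=True, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    rank_of = np.empty(len(uniq), dtype=np.int64)
    rank_of[order] = np.arange(len(uniq))
    labels[ok] = rank_of[inverse].reshape(-1, 2)
    total = counts.sum()
    freq_table = pd.DataFrame(
        {
            "rank": np.arange(len(uniq)),
            "allele_string": uniq[order],
            "count": counts[order],
            "frequency": counts[order] / total,
        }
    )
    freq_table["discarded"] = freq_table["frequency"] < min_frequency
    return labels, freq_table


def count_carriers_homozygotes(labels: np.ndarray, rank: int) -> tuple[int, int, int]:
    """(n_carriers, obs_hom, N) for the haplotype with the given rank; an
    individual counts toward N only when both its labels are called."""
    called = (labels >= 0).all(axis=1)
    copies = (labels[called] == rank).sum(axis=1)
    return int((copies >= 1).sum()), int((copies == 2).sum()), int(called.sum())


def expected_random(p: float, n_genotyped: int) -> tuple[float, float]:
    """Expected homozygotes and zero-homozygote probability under random
    mating: ``exp = p^2 N``; ``P = (1 - p^2)^N`` evaluated in log space."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("haplotype frequency must be in [0, 1]")
    if n_genotyped < 0:
        raise ValueError("N must be non-negative")
    exp = p * p * n_genotyped
    if p >= 1.0:
        prob = 0.0 if n_genotyped > 0 else 1.0
    else:
        prob = math.exp(n_genotyped * math.log1p(-p * p))
    return exp, prob


def expected_mating(
    carrier_status: dict, pedigree: Pedigree
) -> tuple[int, float, float]:
    """Carrier-mating expectation.

    ``carrier_status`` maps genotyped individual id -> bool (carrier of the
    candidate haplotype); individuals absent from the mapping are treated as
    ungenotyped.  For each genotyped individual: if both sire and dam are
    genotyped, a qualifying mating is counted when both are carriers; if the
    dam is ungenotyped, the sire and the maternal grand sire are checked
    instead (the dam's genotype takes precedence when available).
    """
    count = 0
    for ind in carrier_status:
        if ind not in pedigree:
            continue
        sire = pedigree.sire_of(ind)
        if sire is None or sire not in carrier_status:
            continue
        dam = pedigree.dam_of(ind)
        if dam is not None and dam in carrier_status:
            if carrier_status[sire] and carrier_status[dam]:
                count += 1
        else:
            mgs = pedigree.maternal_grand_sire_of(ind)
            if mgs is not None and mgs in carrier_status:
                if carrier_status[sire] and carrier_status[mgs]:
                    count += 1
    return count, count / 4.0, 0.75 ** count


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

def scan(
    phased: PhasedGenotypes,
    pedigree: Pedigree | None,
    config: ScanConfig,
) -> tuple[list[HHDRecord], pd.DataFrame]:
    """Scan every window and report haplotypes above the frequency cutoff
    with at most ``max_obs_hom`` (default zero) observed homozygotes.

    Expectations use N = all genotyped individuals (matching the published
    convention); the per-window N is reported alongside.  Returns the record
    list and a flat DataFrame sorted by chromosome then position.
    """
    windows = build_windows(phased.marker_map, config.window_length, config.offset)
    n_total = phased.n_individuals
    records: list[HHDRecord] = []
    for widx, window in enumerate(windows):
        labels, freq_table = call_window_haplotypes(
            phased, window, min_frequency=config.min_frequency
        )
        kept = freq_table[~freq_table["discarded"]]
        for _, row in kept.iterrows():
            rank = int(row["rank"])
            n_carriers, obs_hom, n_window = count_carriers_homozygotes(labels, rank)
            if obs_hom > config.max_obs_hom:
                continue
            p = float(row["frequency"])
            exp_r, p_r = expected_random(p, n_total)
            if pedigree is not None:
                called = (labels >= 0).all(axis=1)
                status = {
                    ind: bool((labels[i] == rank).any())
                    for i, ind in enumerate(phased.individuals)
                    if called[i]
                }
                n_mat, exp_m, p_m = expected_mating(status, pedigree)
            else:
                n_mat, exp_m, p_m = 0, float("nan"), float("nan")
            records.append(
                HHDRecord(
                    haplotype_id=f"hap{widx}-{rank}",
                    window=window,
                    frequency=p,
                    n_genotyped=n_total,
                    n_carriers=n_carriers,
                    obs_hom=obs_hom,
                    exp_random=exp_r,
                    p_random=p_r,
                    n_carrier_matings=n_mat,
                    exp_mating=exp_m,
                    p_mating=p_m,
                    n_window=n_window,
                )
            )
    table = records_to_table(records)
    return records, table


def records_to_table(records: list[HHDRecord]) -> pd.DataFrame:
    rows = [
        {
            "id": r.haplotype_id,
            "chrom": r.window.chromosome,
            "start": r.window.start_bp,
            "end": r.window.end_bp,
            "freq": r.frequency,
            "n_carriers": r.n_carriers,
            "obs_hom": r.obs_hom,
            "exp_random": r.exp_random,
            "p_random": r.p_random,
            "exp_mating": r.exp_mating,
            "p_mating": r.p_mating,
            "n_genotyped": r.n_genotyped,
            "n_window": r.n_window,
            "n_carrier_matings": r.n_carrier_matings,
        }
        for r in records
    ]
    table = pd.DataFrame(
        rows,
        columns=[
            "id", "chrom", "start", "end", "freq", "n_carriers", "obs_hom",
            "exp_random", "p_random", "exp_mating", "p_mating",
            "n_genotyped", "n_window", "n_carrier_matings",
        ],
    )
    if len(table):
        table = table.sort_values(
            ["chrom", "start"],
            kind="stable",
            key=lambda s: s.astype(str) if s.name == "chrom" else s,
        ).reset_index(drop=True)
    return table


# ---------------------------------------------------------------------------
# deletion screen
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact two-sided Hardy-Weinberg test (Wigginton et al. 2005): the sum
    of probabilities of heterozygote counts no more likely than observed,
    conditional on allele counts."""
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_rare = n_het + 2 * min(n_hom1, n_hom2)
    # probabilities over possible het counts with the same parity as n_rare
    hets = list(range(n_rare % 2, n_rare + 1, 2))
    logp = {}
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if mid % 2 != n_rare % 2:
        mid += 1
    logp[mid] = 0.0
    h = mid
    while h - 2 >= hets[0]:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        logp[h - 2] = logp[h] + math.log(h * (h - 1.0)) - math.log(
            4.0 * (hom_r + 1.0) * (hom_c + 1.0)
        )
        h -= 2
    h = mid
    while h + 2 <= hets[-1]:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        logp[h + 2] = logp[h] + math.log(4.0 * hom_r * hom_c) - math.log(
            (h + 2.0) * (h + 1.0)
        )
        h += 2
    mx = max(logp.values())
    probs = {h: math.exp(v - mx) for h, v in logp.items()}
    total = sum(probs.values())
    obs = probs[n_het]
    p = sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / total
    return min(p, 1.0)


def deletion_screen(
    phased: PhasedGenotypes,
    region: tuple,  # (chromosome, start_bp, end_bp), closed interval
    carrier_ids,
    log_r: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-marker HWE deviation and carrier/non-carrier mean log R within a
    candidate region.  ``log_r`` (optional) has columns marker, individual,
    logR; without it only the HWE column is populated (with a notice)."""
    chrom, start_bp, end_bp = region
    sl = phased.marker_map.chromosome_slice(chrom)
    positions = phased.marker_map.positions
    idx = [
        m for m in range(sl.start, sl.stop) if start_bp <= positions[m] <= end_bp
    ]
    if not idx:
        raise ValueError(f"region {region} contains no markers")
    carriers = np.array([ind in set(carrier_ids) for ind in phased.individuals])
    dos = phased.dosages()
    if log_r is not None:
        lr = log_r.pivot_table(index="individual", columns="marker", values="logR")
    else:
        logger.info("no log R intensity data; deletion screen reports HWE only")
        lr = None
    rows = []
    for m in idx:
        d = dos[:, m]
        called = ~np.isnan(d)
        n_hom_ref = int((d[called] == 0).sum())
        n_het = int((d[called] == 1).sum())
        n_hom_alt = int((d[called] == 2).sum())
        hwe_p = hwe_exact_pvalue(n_het, n_hom_ref, n_hom_alt)
        marker_id = phased.marker_map.marker_ids[m]
        if lr is not None and marker_id in lr.columns:
            vals = lr[marker_id]
            mean_c = float(np.nanmean([vals.get(i, np.nan) for i, c in zip(phased.individuals, carriers) if c]))
            mean_n = float(np.nanmean([vals.get(i, np.nan) for i, c in zip(phased.individuals, carriers) if not c]))
        else:
            mean_c = mean_n = float("nan")
        rows.append(
            {
                "marker": marker_id,
                "position_bp": int(positions[m]),
                "hwe_p": hwe_p,
                "mean_logR_carriers": mean_c,
                "mean_logR_noncarriers": mean_n,
            }
        )
    return pd.DataFrame(rows)
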