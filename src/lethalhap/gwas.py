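"""Marker QC, genomic relationships and mixed-model association.

The association model regresses a corrected phenotype on allele count with a
polygenic effect ``u ~ N(0, G s2u)``; variance components are estimated once
on the null model (no marker) and each marker is then tested by generalised
least squares with the covariance held fixed (two-stage approximation).

The genomic relationship matrix uses allele-count standardisation with equal
marker weights: ``G_jk = (1/m) sum_i (x_ji - 2 p_i)(x_ki - 2 p_i) /
(2 p_i (1 - p_i))``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .data_io import PhasedGenotypes
from .hhd import hwe_exact_pvalue

logger = logging.getLogger("lethalhap")

CHI2_NULL_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.4549...


class GWASError(Exception):
    pass


# ---------------------------------------------------------------------------
# marker and sample QC
# ---------------------------------------------------------------------------

def qc_genotypes(
    phased: PhasedGenotypes,
    max_marker_missing: float = 0.05,
    min_call_rate: float = 0.95,
    het_sd: float = 3.0,
    hwe_p: float = 1e-6,
    min_maf: float = 0.01,
) -> tuple[PhasedGenotypes, dict]:
    """Apply the QC filters in order: marker missingness -> animal call rate
    -> heterozygosity outliers (more than ``het_sd`` SD above the mean) ->
    Hardy-Weinberg deviation -> minor allele frequency.  Returns the filtered
    genotypes and a report of counts removed at each step."""
    report = {}
    dos = phased.dosages()

    marker_missing = np.isnan(dos).mean(axis=0)
    keep_m = marker_missing <= max_marker_missing
    report["markers_missingness"] = int((~keep_m).sum())
    dos = dos[:, keep_m]

    call_rate = 1.0 - np.isnan(dos).mean(axis=1)
    keep_i = call_rate >= min_call_rate
    report["animals_call_rate"] = int((~keep_i).sum())
    dos = dos[keep_i]

    het = np.nanmean(dos == 1, axis=1)
    limit = het.mean() + het_sd * het.std()
    keep_het = het <= limit
    report["animals_heterozygosity"] = int((~keep_het).sum())
    dos = dos[keep_het]

    keep_hwe = np.ones(dos.shape[1], dtype=bool)
    for m in range(dos.shape[1]):
        d = dos[:, m]
        d = d[~np.isnan(d)]
        p = hwe_exact_pvalue(int((d == 1).sum()), int((d == 0).sum()), int((d == 2).sum()))
        if p < hwe_p:
            keep_hwe[m] = False
    report["markers_hwe"] = int((~keep_hwe).sum())
    dos = dos[:, keep_hwe]

    freq = np.nanmean(dos, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep_maf = maf >= min_maf
    report["markers_maf"] = int((~keep_maf).sum())

    marker_idx = np.flatnonzero(keep_m)[keep_hwe][keep_maf]
    animal_idx = np.flatnonzero(keep_i)[keep_het]
    if marker_idx.size == 0:
        raise GWASError("QC removed every marker")
    out = phased.subset_individuals(animal_idx).subset_markers(marker_idx)
    report["markers_kept"] = int(marker_idx.size)
    report["animals_kept"] = int(animal_idx.size)
    return out, report


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------

def dosage_matrix(phased: PhasedGenotypes, impute: bool = True) -> np.ndarray:
    """Allele-count matrix (n x m); missing entries mean-imputed per marker."""
    dos = phased.dosages()
    if impute and np.isnan(dos).any():
        means = np.nanmean(dos, axis=0)
        nan_r, nan_c = np.where(np.isnan(dos))
        dos[nan_r, nan_c] = means[nan_c]
    return dos


def compute_grm(genotypes) -> np.ndarray:
    """Allele-count standardised GRM with equal marker weights.

    ``genotypes`` is a :class:`PhasedGenotypes` or an (n x m) dosage matrix.
    Monomorphic markers are excluded with a warning.  The diagonal averages
    ~1 on Hardy-Weinberg data.
    """
    dos = dosage_matrix(genotypes) if isinstance(genotypes, PhasedGenotypes) else np.asarray(genotypes, float)
    p = dos.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    if (~poly).any():
        logger.warning("excluding %d monomorphic markers from GRM", int((~poly).sum()))
    dos = dos[:, poly]
    p = p[poly]
    if dos.shape[1] == 0:
        raise GWASError("no polymorphic markers for GRM")
    S = (dos - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return (S @ S.T) / dos.shape[1]


# ---------------------------------------------------------------------------
# mixed-model association
# ---------------------------------------------------------------------------

def _null_reml(y: np.ndarray, grm: np.ndarray) -> dict:
    """REML variance components of y = mu + u + e with u ~ N(0, G s2u),
    profiled over the ratio delta = s2e / s2u after rotating into the
    eigenbasis of G (single intercept covariate)."""
    vals, U = np.linalg.eigh(grm)
    vals = np.maximum(vals, 0.0)
    yt = U.T @ y
    xt = U.T @ np.ones_like(y)
    n = len(y)

    def neg2ll(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = vals + delta
        xwx = np.sum(xt * xt / w)
        beta = np.sum(xt * yt / w) / xwx
        r = yt - xt * beta
        rss = np.sum(r * r / w)
        s2u = rss / (n - 1)
        return (n - 1) * np.log(s2u) + np.sum(np.log(w)) + np.log(xwx)

    res = minimize_scalar(neg2ll, bounds=(-12.0, 12.0), method="bounded")
    delta = float(np.exp(res.x))
    w = vals + delta
    xwx = np.sum(xt * xt / w)
    beta = np.sum(xt * yt / w) / xwx
    r = yt - xt * beta
    s2u = float(np.sum(r * r / w) / (n - 1))
    return {
        "sigma2_u": s2u,
        "sigma2_e": s2u * delta,
        "delta": delta,
        "eigvals": vals,
        "U": U,
    }


def lmm_assoc(
    y_star: np.ndarray,
    genotypes,
    grm: np.ndarray,
    marker_map=None,
    var_components: dict | None = None,
) -> pd.DataFrame:
    """Single-marker linear mixed-model association.

    ``genotypes`` is a :class:`PhasedGenotypes` (its map is used unless
    ``marker_map`` is given) or an (n x m) dosage matrix.  ``var_components``
    may fix {"sigma2_u", "sigma2_e"}; with ``sigma2_u = 0`` the test reduces
    to ordinary least-squares regression per marker.
    """
    if isinstance(genotypes, PhasedGenotypes):
        dos = dosage_matrix(genotypes)
        if marker_map is None:
            marker_map = genotypes.marker_map
    else:
        dos = np.asarray(genotypes, float)
    y = np.asarray(y_star, float)
    n, m = dos.shape
    if len(y) != n:
        raise GWASError("phenotype not aligned to genotyped individuals")

    vals, U = np.linalg.eigh(grm)
    vals = np.maximum(vals, 0.0)
    if var_components is None:
        null = _null_reml(y, grm)
        s2u, s2e = null["sigma2_u"], null["sigma2_e"]
    else:
        s2u, s2e = var_components["sigma2_u"], var_components["sigma2_e"]
    w = s2u * vals + s2e  # per-eigenvector variance of V
    if np.any(w <= 0):
        w = w + 1e-8 * np.mean(np.abs(w))
        if np.any(w <= 0):
            raise GWASError("covariance matrix not positive definite")
    yt = U.T @ y
    ones_t = U.T @ np.ones(n)
    Gt = U.T @ dos  # rotated dosages, n x m

    iw = 1.0 / w
    # GLS with X = [1, g] per marker, V fixed
    a11 = float(np.sum(ones_t * ones_t * iw))
    a1y = float(np.sum(ones_t * yt * iw))
    a1g = (ones_t * iw) @ Gt            # m
    agg = iw @ (Gt * Gt)                # m
    agy = (yt * iw) @ Gt                # m
    det = a11 * agg - a1g * a1g
    det = np.where(det <= 0, np.nan, det)
    b = (a11 * agy - a1g * a1y) / det
    se = np.sqrt(a11 / det)
    z = b / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    freq = dos.mean(axis=0) / 2.0

    if marker_map is not None:
        table = marker_map.table[["marker_id", "chromosome", "position_bp"]].copy()
        table.columns = ["marker", "chromosome", "position_bp"]
    else:
        table = pd.DataFrame(
            {"marker": [f"m{i}" for i in range(m)], "chromosome": 0, "position_bp": np.arange(m)}
        )
    table["allele_freq"] = freq
    table["b"] = b
    table["se"] = se
    table["p_value"] = pvals
    table.attrs["sigma2_u"] = float(s2u)
    table.attrs["sigma2_e"] = float(s2e)
    return table


# ---------------------------------------------------------------------------
# thresholds, hits, LD, co-location, inflation
# ---------------------------------------------------------------------------

def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def suggestive_hits(results: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """The ``k`` markers with the smallest p-values, ties broken by
    (chromosome, position, marker id) for determinism."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = results.sort_values(
        ["p_value", "chromosome", "position_bp", "marker"],
        kind="stable",
        key=lambda s: s.astype(str) if s.name in ("chromosome", "marker") else s,
    )
    return ordered.head(k).reset_index(drop=True)


def ld_r2(genotypes, marker_a: int, marker_b: int) -> float:
    """Squared correlation between two markers.

    On phased input the correlation is between haplotype allele indicators
    (faithful to haplotype linkage); on a dosage matrix the genotype-dosage
    correlation is used instead.
    """
    if isinstance(genotypes, PhasedGenotypes):
        h = genotypes.haplotypes
        a = h[:, :, marker_a].reshape(-1).astype(float)
        b = h[:, :, marker_b].reshape(-1).astype(float)
        ok = (a >= 0) & (b >= 0)
        a, b = a[ok], b[ok]
    else:
        dos = np.asarray(genotypes, float)
        a, b = dos[:, marker_a], dos[:, marker_b]
        ok = ~(np.isnan(a) | np.isnan(b))
        a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        raise GWASError("r2 undefined for a monomorphic marker")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def colocate(
    hits: pd.DataFrame,
    hhd_table: pd.DataFrame,
    marker_map,
    genotypes=None,
    window_bp: int = 1_000_000,
    r2_linked: float = 0.5,
) -> pd.DataFrame:
    """Match suggestive markers to HHD haplotypes within ``window_bp`` of the
    haplotype's [start, end] span (closed intervals).  When genotypes are
    supplied, the maximum r2 between the marker and any marker inside the
    haplotype window is attached; ``linked`` means r2 > 0.5."""
    rows = []
    for _, hit in hits.iterrows():
        pos = int(hit["position_bp"])
        same = hhd_table[hhd_table["chrom"].astype(str) == str(hit["chromosome"])]
        for _, hap in same.iterrows():
            lo, hi = int(hap["start"]), int(hap["end"])
            if not (lo - window_bp <= pos <= hi + window_bp):
                continue
            distance = 0 if lo <= pos <= hi else min(abs(pos - lo), abs(pos - hi))
            r2 = float("nan")
            if genotypes is not None:
                midx = marker_map.index_of(hit["marker"])
                sl = marker_map.chromosome_slice(hit["chromosome"])
                in_window = [
                    m
                    for m in range(sl.start, sl.stop)
                    if lo <= marker_map.positions[m] <= hi
                ]
                best = 0.0
                for m in in_window:
                    if m == midx:
                        best = 1.0
                        break
                    try:
                        best = max(best, ld_r2(genotypes, midx, m))
                    except GWASError:
                        continue
                r2 = best
            rows.append(
                {
                    "marker": hit["marker"],
                    "chromosome": hit["chromosome"],
                    "position_bp": pos,
                    "haplotype": hap["id"],
                    "hap_start": lo,
                    "hap_end": hi,
                    "distance_bp": distance,
                    "r2": r2,
                    "linked": bool(r2 > r2_linked) if np.isfinite(r2) else False,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "marker", "chromosome", "position_bp", "haplotype",
            "hap_start", "hap_end", "distance_bp", "r2", "linked",
        ],
    )


def inflation_factor(p_values) -> float:
    """Genomic inflation factor: median 1-df association chi-square divided
    by the null median (~0.4549)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_NULL_MEDIAN)


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

def manhattan_plot(results: pd.DataFrame, path, threshold: float | None = None) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, grp) in enumerate(results.groupby("chromosome", sort=False)):
        x = grp["position_bp"].to_numpy() + offset
        ax.scatter(x, -np.log10(grp["p_value"]), s=4, color="C0" if i % 2 == 0 else "C1")
        ticks.append(offset + grp["position_bp"].max() / 2)
        labels.append(str(chrom))
        offset += grp["position_bp"].max()
    if threshold is not None:
        ax.axhline(-np.log10(threshold), ls=":", color="k")
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("-log10 P")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def qq_plot(p_values, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = np.sort(np.asarray(p_values, float))
    exp = -np.log10((np.arange(len(p)) + 0.5) / len(p))
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(exp, -np.log10(p), s=5)
    lim = max(exp.max(), -np.log10(p.min()))
    ax.plot([0, lim], [0, lim], color="grey", lw=1)
    ax.set_xlabel("expected -log10 P")
    ax.set_ylabel("observed -log10 P")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
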