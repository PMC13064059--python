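"""Between-sex Weir-Cockerham F_ST and genotype QC filters.

Per-site variance components (a: between groups, b: between individuals
within groups, c: within individuals) follow the 1984 two-level estimator
with r = 2 groups (females vs males). The windowed ("weighted") value is the
ratio of sums sum(a) / sum(a+b+c) over usable sites, not the mean of
per-site ratios. A fully sex-linked configuration (all females heterozygous,
all males homozygous) gives theta = 0.5 at any equal group size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import SexedGenotypeMatrix, require_both_sexes

R_GROUPS = 2  # females, males


@dataclass(frozen=True)
class BiallelicSiteCounts:
    """Per-sex summaries of one biallelic site."""

    n_f: int  # females genotyped
    n_m: int
    p_f: float  # reference-allele frequency
    p_m: float
    h_f: float  # observed heterozygote proportion
    h_m: float

    def __post_init__(self):
        for v in (self.p_f, self.p_m, self.h_f, self.h_m):
            if not 0.0 <= v <= 1.0:
                raise ValueError("frequencies and het proportions must be in [0, 1]")
        if self.n_f < 1 or self.n_m < 1:
            raise ValueError("need >= 1 genotyped individual per group")


@dataclass(frozen=True)
class FstComponents:
    a: float
    b: float
    c: float

    @property
    def theta(self) -> float:
        denom = self.a + self.b + self.c
        if denom <= 0:
            return np.nan
        return self.a / denom


def wc_site(counts: BiallelicSiteCounts):
    """Weir-Cockerham variance components for one site; None when the site
    is monomorphic across both groups (excluded sentinel)."""
    n1, n2 = counts.n_f, counts.n_m
    p1, p2 = counts.p_f, counts.p_m
    h1, h2 = counts.h_f, counts.h_m
    if (p1 == p2) and p1 in (0.0, 1.0) and h1 == h2 == 0.0:
        return None
    r = R_GROUPS
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2 - (1.0 / (n_bar - 1)) * (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar)
    )
    c = h_bar / 2.0
    return FstComponents(a=a, b=b, c=c)


def site_counts_from_genotypes(gt: np.ndarray, is_female: np.ndarray):
    """BiallelicSiteCounts from an (n_samples, 2) allele array (-1 missing)."""
    gt = np.asarray(gt)
    called = np.all(gt >= 0, axis=1)
    out = {}
    for sex, mask in (("F", is_female), ("M", ~is_female)):
        m = mask & called
        n = int(m.sum())
        if n == 0:
            return None
        alleles = gt[m]
        out[sex] = (
            n,
            float((alleles == 0).mean()),
            float((alleles[:, 0] != alleles[:, 1]).mean()),
        )
    return BiallelicSiteCounts(
        n_f=out["F"][0], n_m=out["M"][0],
        p_f=out["F"][1], p_m=out["M"][1],
        h_f=out["F"][2], h_m=out["M"][2],
    )


def wc_components(matrix: SexedGenotypeMatrix):
    """Per-site (a, b, c) arrays; NaN rows mark excluded (monomorphic or
    single-sex-missing) sites."""
    require_both_sexes(matrix.samples)
    is_f = matrix.is_female
    a = np.full(matrix.n_sites, np.nan)
    b = np.full(matrix.n_sites, np.nan)
    c = np.full(matrix.n_sites, np.nan)
    for i in range(matrix.n_sites):
        counts = site_counts_from_genotypes(matrix.gt[i], is_f)
        if counts is None:
            continue
        comp = wc_site(counts)
        if comp is None:
            continue
        a[i], b[i], c[i] = comp.a, comp.b, comp.c
    return a, b, c


def windowed_fst(
    positions: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    chrom_length: int,
    window_size: int = 10_000,
):
    """Ratio-of-sums F_ST per fixed window.

    Sites with undefined components or with a+b+c <= 0 are excluded from the
    window sums (not clamped). Windows without usable sites are NaN.
    Returns (theta_per_window, n_sites_per_window).
    """
    positions = np.asarray(positions)
    denom_site = a + b + c
    usable = np.isfinite(denom_site) & (denom_site > 0)
    n_windows = -(-chrom_length // window_size)
    win = positions // window_size
    num = np.bincount(win[usable], weights=a[usable], minlength=n_windows)
    den = np.bincount(win[usable], weights=denom_site[usable], minlength=n_windows)
    n_sites = np.bincount(win[usable], minlength=n_windows)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where((n_sites > 0) & (den > 0), num / den, np.nan)
    return theta, n_sites


def flag_p99(values: np.ndarray, percentile: float = 0.99):
    """Genome-wide nearest-rank percentile threshold and exceedance flags.

    The threshold is the smallest observed value with at least
    ``percentile`` of non-missing windows at or below it; windows strictly
    greater are flagged.
    """
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValueError("no non-missing windows to take a percentile over")
    ordered = np.sort(finite)
    rank = int(np.ceil(percentile * ordered.size)) - 1
    threshold = float(ordered[max(rank, 0)])
    exceeds = np.isfinite(values) & (values > threshold)
    return threshold, exceeds


# ---------------------------------------------------------------------------
# genotype QC (the two hard-filter presets of the study)

QC_PRESETS = {
    # SLR / fixed-SNP set
    "slr": dict(maf=0.1, min_dp=10, max_dp=100, max_missing=1.0, min_q=None),
    # coding-sequence degeneration set
    "degeneration": dict(maf=0.1, min_dp=10, max_dp=100, max_missing=0.8, min_q=30.0),
}


def qc_filter(matrix: SexedGenotypeMatrix, preset: str = "slr", **overrides):
    """Hard-filter a genotype matrix the way the upstream VCF tools would.

    Per-genotype: calls with depth outside [min_dp, max_dp] (inclusive) are
    set missing. Per-site: keep biallelic SNPs whose minor-allele frequency
    is strictly greater than ``maf``, whose called fraction is at least
    ``max_missing`` (1.0 = no missing calls allowed) and, when ``min_q`` is
    set, whose QUAL is at least ``min_q``.
    """
    if preset not in QC_PRESETS:
        raise ValueError(f"unknown QC preset {preset!r}; choose from {sorted(QC_PRESETS)}")
    p = dict(QC_PRESETS[preset], **overrides)

    gt = matrix.gt.copy()
    dp = matrix.dp
    bad_dp = (dp < p["min_dp"]) | (dp > p["max_dp"])
    gt[bad_dp] = -1

    called = np.all(gt >= 0, axis=2)
    call_frac = called.mean(axis=1)

    # allele frequencies over called genotypes
    alt_dose = np.where(called, (gt == 1).sum(axis=2), 0)
    n_alleles = 2 * called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(n_alleles > 0, alt_dose.sum(axis=1) / n_alleles, np.nan)
    maf = np.minimum(alt_freq, 1 - alt_freq)

    keep = (
        matrix.is_biallelic()
        & matrix.is_snp()
        & (call_frac >= p["max_missing"])
        & np.isfinite(maf)
        & (maf > p["maf"])
    )
    if p["min_q"] is not None:
        keep &= matrix.qual >= p["min_q"]

    filtered = matrix.subset_sites(keep)
    filtered.gt = gt[keep]
    return filtered
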