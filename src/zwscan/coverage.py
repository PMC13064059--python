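"""Windowed depth-fraction and heterozygosity scans and base-resolution
sex-specific presence/absence calling.

The female depth fraction F/(F+M) of normalized coverage is ~0.5 in
pseudoautosomal sequence, ~1 over W-specific sequence (absent from ZZ males)
and ~1/3 over Z-specific sequence (one female copy vs two male copies).
Sex-specific sites are called strictly: present in every sample of one sex
and absent (depth at or below ``absent_max`` reads) in every sample of the
other.
"""

from __future__ import annotations

import numpy as np

from .records import (
    FEMALE,
    FLAG_FEMALE_ONLY,
    FLAG_MALE_ONLY,
    FLAG_MISSING,
    FLAG_OK,
    MALE,
    SexSpecificRegion,
    WindowTrack,
    require_both_sexes,
)

DEFAULT_ABSENT_MAX = 5  # reads; "absent" call threshold (inclusive)


def windowed_mean_depth(depth: np.ndarray, window_size: int) -> np.ndarray:
    """Mean per-base depth in fixed non-overlapping windows.

    The trailing partial window (if any) is averaged over its actual width.
    """
    depth = np.asarray(depth, dtype=float)
    n_full = len(depth) // window_size
    out = depth[: n_full * window_size].reshape(n_full, window_size).mean(axis=1)
    rem = len(depth) - n_full * window_size
    if rem:
        out = np.append(out, depth[n_full * window_size:].mean())
    return out


def normalize_depth(track: WindowTrack, reference_mean: float) -> WindowTrack:
    """Divide a depth track by the sample's reference mean depth."""
    if reference_mean <= 0:
        raise ValueError(f"reference_mean must be > 0, got {reference_mean}")
    values = track.values / reference_mean
    return WindowTrack(
        chrom=track.chrom,
        window_size=track.window_size,
        values=values,
        statistic=f"{track.statistic or 'depth'}_normalized",
        flags=track.flags.copy(),
    )


def reference_mean_depth(tracks: dict, autosomes=None) -> float:
    """Mean depth of one sample over autosome-labeled chromosomes.

    ``tracks`` maps chromosome -> per-window depth values. When no autosome
    labels are supplied the mean is taken over all windows of all
    chromosomes.
    """
    chroms = list(tracks) if not autosomes else [c for c in tracks if c in autosomes]
    if not chroms:
        raise ValueError("no chromosomes available for the normalization reference")
    values = np.concatenate([np.asarray(tracks[c], dtype=float) for c in chroms])
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("reference chromosomes contain no finite depth values")
    return float(values.mean())


def female_fraction(f_norm: WindowTrack, m_norm: WindowTrack) -> WindowTrack:
    """Per-window female share F/(F+M) of normalized depth."""
    f = f_norm.values
    m = m_norm.values
    if np.nanmin(f, initial=0.0) < 0 or np.nanmin(m, initial=0.0) < 0:
        raise ValueError("normalized depths must be >= 0")
    total = f + m
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, f / total, np.nan)
    flags = np.where(
        np.isnan(f) | np.isnan(m) | (total == 0), FLAG_MISSING, FLAG_OK
    ).astype(object)
    frac = np.where(flags == FLAG_MISSING, np.nan, frac)
    return WindowTrack(
        chrom=f_norm.chrom,
        window_size=f_norm.window_size,
        values=frac,
        statistic="female_fraction",
        flags=flags,
    )


def het_proportion_windows(
    gt: np.ndarray, positions: np.ndarray, chrom_length: int, window_size: int
) -> np.ndarray:
    """Per-window proportion of heterozygous sites for one individual.

    ``gt`` is an (n_sites, 2) allele array with -1 for missing calls; windows
    with no called site are NaN.
    """
    gt = np.asarray(gt)
    called = np.all(gt >= 0, axis=1)
    het = called & (gt[:, 0] != gt[:, 1])
    n_windows = -(-chrom_length // window_size)
    win = np.asarray(positions) // window_size
    n_called = np.bincount(win[called], minlength=n_windows).astype(float)
    n_het = np.bincount(win[het], minlength=n_windows).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_called > 0, n_het / n_called, np.nan)


def sex_mean_het(per_sample_props: np.ndarray) -> np.ndarray:
    """Average window het proportions over individuals of one sex; windows
    missing in a sample are excluded from that sample's contribution."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(np.asarray(per_sample_props, dtype=float), axis=0)


def het_ratio(f_mean: np.ndarray, m_mean: np.ndarray, chrom="", window_size=10_000) -> WindowTrack:
    """log2 female/male mean heterozygosity per window.

    A twofold female excess maps to +1. Windows with female signal but zero
    male signal have no numeric value and carry the FEMALE_ONLY flag (the
    male-only case is flagged symmetrically); windows empty in both sexes are
    missing.
    """
    f = np.asarray(f_mean, dtype=float)
    m = np.asarray(m_mean, dtype=float)
    values = np.full(f.shape, np.nan)
    flags = np.full(f.shape, FLAG_OK, dtype=object)
    both_zero = ((f == 0) & (m == 0)) | np.isnan(f) | np.isnan(m)
    female_only = (f > 0) & (m == 0)
    male_only = (m > 0) & (f == 0)
    ok = ~(both_zero | female_only | male_only)
    with np.errstate(divide="ignore", invalid="ignore"):
        values[ok] = np.log2(f[ok] / m[ok])
    flags[both_zero] = FLAG_MISSING
    flags[female_only] = FLAG_FEMALE_ONLY
    flags[male_only] = FLAG_MALE_ONLY
    return WindowTrack(
        chrom=chrom,
        window_size=window_size,
        values=values,
        statistic="het_ratio_log2",
        flags=flags,
    )


def call_presence(depth, absent_max: int = DEFAULT_ABSENT_MAX) -> np.ndarray:
    """Presence call per base: absent iff depth <= absent_max (inclusive)."""
    depth = np.asarray(depth)
    if depth.min(initial=0) < 0:
        raise ValueError("depth must be >= 0")
    return depth > absent_max


def find_sex_specific_sites(
    presence: np.ndarray, samples, absent_max=None
) -> dict:
    """Base-resolution sex-specific sites from a presence matrix.

    ``presence`` is an (n_samples, L) boolean matrix (True = present; build
    it with :func:`call_presence`). A site is female-specific iff present in
    every female and absent in every male; male-specific by the opposite
    criteria. The two sets are disjoint by construction.
    """
    require_both_sexes(samples)
    presence = np.asarray(presence, dtype=bool)
    is_f = np.array([s.sex == FEMALE for s in samples], dtype=bool)
    all_f = presence[is_f].all(axis=0)
    any_f = presence[is_f].any(axis=0)
    all_m = presence[~is_f].all(axis=0)
    any_m = presence[~is_f].any(axis=0)
    return {
        FEMALE: np.nonzero(all_f & ~any_m)[0],
        MALE: np.nonzero(all_m & ~any_f)[0],
    }


def merge_sites_to_regions(
    sites, chrom: str, sex: str, max_gap: int = 0
):
    """Merge sorted unique site positions into regions.

    Consecutive sites with an inter-site gap <= ``max_gap`` share a region
    (gap = distance minus one intervening base; adjacent bases have gap 0).
    Returns (regions, total_specific_bases) where the total counts sites, not
    region spans.
    """
    sites = np.asarray(sites, dtype=np.int64)
    if sites.size == 0:
        return [], 0
    if np.any(np.diff(sites) < 0):
        raise ValueError("sites must be sorted")
    sites = np.unique(sites)
    breaks = np.nonzero(np.diff(sites) - 1 > max_gap)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(sites) - 1]])
    regions = [
        SexSpecificRegion(
            chrom=chrom,
            start=int(sites[i]),
            end=int(sites[j]) + 1,
            sex=sex,
            n_sites=int(j - i + 1),
        )
        for i, j in zip(starts, ends)
    ]
    return regions, int(sites.size)
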