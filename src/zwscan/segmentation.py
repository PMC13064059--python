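"""SLR calling from evidence tracks and the five-way W-haplotype partition.

The SLR is called from the female depth fraction alone: windows deviating
from 0.5 by at least ``delta`` seed runs, sufficiently long runs are merged
across short gaps, and the largest merged run is the call. FST flags,
female-only heterozygosity windows and base-resolution sex-specific sites
are reported as supporting evidence and can extend the call outward at
window resolution. The partition labels PAR1 / FS1 / INV / FS2 / PAR2 from
the call, the clusters of sex-specific sites and an externally supplied
inversion interval; female-specific evidence takes precedence over the
inversion where they overlap, so labels stay disjoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .records import FLAG_FEMALE_ONLY, LabeledInterval, WindowTrack


@dataclass
class SlrCall:
    chrom: str
    start: int  # bp
    end: int
    window_start: int  # window indices [start, end)
    window_end: int
    evidence: dict = field(default_factory=dict)

    @property
    def interval(self):
        return (self.start, self.end)


@dataclass
class SlrPartition:
    """Ordered labeled intervals covering the chromosome exactly once."""

    intervals: list  # LabeledInterval, in genomic order
    chrom_length: int

    def __post_init__(self):
        pos = 0
        for iv in self.intervals:
            if iv.start != pos:
                raise ValueError("partition intervals must be contiguous from 0")
            pos = iv.end
        if pos != self.chrom_length:
            raise ValueError("partition must cover the chromosome")

    @property
    def slr(self):
        """FS1 + INV + FS2 as one interval (None when no SLR was labeled)."""
        slr_ivs = [iv for iv in self.intervals if iv.label in ("FS1", "INV", "FS2", "SLR")]
        if not slr_ivs:
            return None
        return (min(iv.start for iv in slr_ivs), max(iv.end for iv in slr_ivs))

    def label_of(self, pos: int):
        for iv in self.intervals:
            if iv.contains(pos):
                return iv.label
        return None


def _runs(mask: np.ndarray):
    """(start, end) index pairs of True runs."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return list(zip(starts, ends))


def call_slr(
    female_fraction: WindowTrack,
    delta: float = 0.1,
    min_run: int = 5,
    max_gap: int = 3,
    fst_exceeds=None,
    het_flags=None,
    sex_specific_sites=None,
):
    """Call the candidate SLR interval from the female depth fraction.

    Windows with |F/(F+M) - 0.5| >= delta seed runs; runs of at least
    ``min_run`` windows are merged when separated by at most ``max_gap``
    windows, and the largest merged run is returned. When base-resolution
    ``sex_specific_sites`` are supplied the boundaries snap outward over
    adjacent windows that contain such sites. Returns None (with no seed
    windows) or an SlrCall carrying supporting-evidence summaries.
    """
    values = female_fraction.values
    w = female_fraction.window_size
    seeds = np.isfinite(values) & (np.abs(values - 0.5) >= delta)
    runs = [r for r in _runs(seeds) if r[1] - r[0] >= min_run]
    if not runs:
        return None
    # merge runs across short gaps
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] <= max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    ws, we = max(merged, key=lambda r: r[1] - r[0])

    if sex_specific_sites is not None and len(sex_specific_sites):
        site_windows = np.unique(np.asarray(sex_specific_sites) // w)
        while ws > 0 and (ws - 1) in site_windows:
            ws -= 1
        while we < len(values) and we in site_windows:
            we += 1

    start, end = int(ws * w), int(we * w)
    evidence = {}
    if fst_exceeds is not None:
        fst_exceeds = np.asarray(fst_exceeds, dtype=bool)
        n_flagged = int(fst_exceeds.sum())
        inside = int(fst_exceeds[ws:we].sum())
        evidence["fst_flagged_windows"] = n_flagged
        evidence["fst_flagged_inside"] = inside
        evidence["fst_flagged_fraction_inside"] = inside / n_flagged if n_flagged else np.nan
    if het_flags is not None:
        het_flags = np.asarray(het_flags, dtype=object)
        evidence["het_female_only_inside"] = int(
            (het_flags[ws:we] == FLAG_FEMALE_ONLY).sum()
        )
    if sex_specific_sites is not None:
        sites = np.asarray(sex_specific_sites)
        evidence["sex_specific_sites_inside"] = int(
            ((sites >= start) & (sites < end)).sum()
        )
    return SlrCall(
        chrom=female_fraction.chrom,
        start=start,
        end=end,
        window_start=int(ws),
        window_end=int(we),
        evidence=evidence,
    )


def partition_regions(
    slr_interval,
    clusters,
    inversion,
    chrom_length: int,
):
    """Partition the chromosome into PAR1 / FS1 / INV / FS2 / PAR2.

    ``clusters`` are merged sex-specific regions (e.g. SexSpecificRegion or
    (start, end) pairs) inside the SLR call; ``inversion`` is an externally
    supplied (start, end) or None. FS1 spans from the SLR start to the
    inversion start when clusters precede the inversion; FS2 spans from the
    first cluster reaching the inversion end to the SLR end (female-specific
    evidence takes precedence over the inversion label on overlap). With no
    inversion the partition degenerates to PAR1 / SLR / PAR2.
    """
    slr_start, slr_end = slr_interval
    spans = []
    for c in clusters or []:
        s, e = (c.start, c.end) if hasattr(c, "start") else (c[0], c[1])
        if s < slr_start or e > slr_end:
            warnings.warn(
                f"sex-specific cluster [{s}, {e}) extends outside the SLR call; clipped",
                stacklevel=2,
            )
        spans.append((max(s, slr_start), min(e, slr_end)))
    spans = [(s, e) for s, e in spans if s < e]
    spans.sort()
    if not spans:
        warnings.warn("no sex-specific clusters inside the SLR call", stacklevel=2)

    if inversion is None:
        intervals = [
            LabeledInterval("PAR1", 0, slr_start),
            LabeledInterval("SLR", slr_start, slr_end),
            LabeledInterval("PAR2", slr_end, chrom_length),
        ]
        return SlrPartition([iv for iv in intervals if iv.length > 0], chrom_length)

    inv_start, inv_end = inversion
    if not (0 <= inv_start < inv_end <= chrom_length):
        raise ValueError("inversion interval must lie inside the chromosome")

    slr_end = max(slr_end, inv_end)
    has_upstream = any(s < inv_start for s, _ in spans)
    fs1_end = inv_start if has_upstream else slr_start
    # FS2 opens at the first cluster reaching the inversion end, or at the
    # inversion end itself when the SLR extends beyond it
    fs2_candidates = [s for s, e in spans if e >= inv_end]
    if slr_end > inv_end:
        fs2_candidates.append(inv_end)
    fs2_start = min(fs2_candidates) if fs2_candidates else slr_end

    intervals = [
        LabeledInterval("PAR1", 0, slr_start),
        LabeledInterval("FS1", slr_start, fs1_end),
        LabeledInterval("INV", fs1_end, fs2_start),
        LabeledInterval("FS2", fs2_start, slr_end),
        LabeledInterval("PAR2", slr_end, chrom_length),
    ]
    return SlrPartition([iv for iv in intervals if iv.length > 0], chrom_length)
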