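"""Shared domain containers for the sex-linked-region (SLR) pipeline.

Coordinates are 0-based half-open everywhere inside the package; VCF (1-based)
and GFF3 (1-based inclusive) conventions are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FEMALE = "F"
MALE = "M"

#: window-track flag values
FLAG_OK = ""
FLAG_MISSING = "MISSING"
FLAG_FEMALE_ONLY = "FEMALE_ONLY"
FLAG_MALE_ONLY = "MALE_ONLY"


@dataclass(frozen=True)
class SexedSample:
    """One sequenced unit: an individual or a pool with a sex label."""

    sample_id: str
    sex: str  # "F" or "M"
    kind: str = "individual"  # "individual" | "pool"
    pool_size: int = 1

    def __post_init__(self):
        if self.sex not in (FEMALE, MALE):
            raise ValueError(f"sex must be F or M, got {self.sex!r}")
        if self.kind not in ("individual", "pool"):
            raise ValueError(f"kind must be individual or pool, got {self.kind!r}")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")


def require_both_sexes(samples):
    """Raise if the sample sheet does not contain at least one of each sex."""
    sexes = {s.sex for s in samples}
    if sexes != {FEMALE, MALE}:
        raise ValueError(
            "between-sex analysis needs at least one female and one male sample; "
            f"sheet contains sexes {sorted(sexes)}"
        )


@dataclass
class WindowTrack:
    """A per-window statistic on one chromosome.

    ``values`` holds NaN for missing windows; ``flags`` carries the reason
    (e.g. ``FEMALE_ONLY`` for the heterozygosity ratio when males have none).
    Windows are fixed-width, non-overlapping tiles starting at 0.
    """

    chrom: str
    window_size: int
    values: np.ndarray
    statistic: str = ""
    flags: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.flags is None:
            self.flags = np.full(len(self.values), FLAG_OK, dtype=object)
        else:
            self.flags = np.asarray(self.flags, dtype=object)
        if len(self.flags) != len(self.values):
            raise ValueError("flags and values must have equal length")

    @property
    def n_windows(self) -> int:
        return len(self.values)

    @property
    def starts(self) -> np.ndarray:
        return np.arange(self.n_windows, dtype=np.int64) * self.window_size

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.window_size

    def window_of(self, pos: int) -> int:
        return int(pos) // self.window_size


@dataclass(frozen=True)
class SexSpecificRegion:
    """A merged run of base-resolution sites present in one sex only."""

    chrom: str
    start: int
    end: int
    sex: str
    n_sites: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("end must be > start")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SexedGenotypeMatrix:
    """Site-major genotype + allele-depth arrays for a sexed cohort.

    ``gt`` has shape (n_sites, n_samples, 2) with -1 for a missing allele;
    ``ad`` has shape (n_sites, n_samples, 2): reads supporting REF and the
    first ALT. ``alts`` keeps the full ALT tuple so multi-allelic sites can be
    recognized and excluded where the methods require biallelic loci.
    """

    chrom: str
    positions: np.ndarray  # 0-based
    ref: list
    alts: list  # list of tuples of ALT alleles
    gt: np.ndarray
    ad: np.ndarray
    qual: np.ndarray
    samples: list  # list[SexedSample]

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        self.ad = np.asarray(self.ad, dtype=np.int32)
        self.qual = np.asarray(self.qual, dtype=float)
        n = len(self.positions)
        if not (len(self.ref) == len(self.alts) == self.gt.shape[0] == self.ad.shape[0] == n):
            raise ValueError("inconsistent site dimensions")
        if self.gt.shape[1] != len(self.samples):
            raise ValueError("gt sample dimension does not match sample sheet")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def is_female(self) -> np.ndarray:
        return np.array([s.sex == FEMALE for s in self.samples], dtype=bool)

    @property
    def dp(self) -> np.ndarray:
        """Per-sample site depth as the allele-depth sum."""
        return self.ad.sum(axis=2)

    def is_biallelic(self) -> np.ndarray:
        return np.array([len(a) == 1 for a in self.alts], dtype=bool)

    def is_snp(self) -> np.ndarray:
        return np.array(
            [len(r) == 1 and all(len(a) == 1 for a in alt) for r, alt in zip(self.ref, self.alts)],
            dtype=bool,
        )

    def subset_sites(self, mask) -> "SexedGenotypeMatrix":
        mask = np.asarray(mask)
        idx = np.nonzero(mask)[0] if mask.dtype == bool else mask
        return SexedGenotypeMatrix(
            chrom=self.chrom,
            positions=self.positions[idx],
            ref=[self.ref[i] for i in idx],
            alts=[self.alts[i] for i in idx],
            gt=self.gt[idx],
            ad=self.ad[idx],
            qual=self.qual[idx],
            samples=self.samples,
        )


@dataclass(frozen=True)
class LabeledInterval:
    label: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def assign_region(pos, intervals) -> str | None:
    """Label a position by the first interval containing it (None otherwise)."""
    for iv in intervals:
        if iv.contains(pos):
            return iv.label
    return None
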