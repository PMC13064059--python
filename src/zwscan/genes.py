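"""ZW homolog classification, gene-loss accounting, the five-step pseudogene
pipeline, region-wise Ks summaries and inverted partial-duplicate scanning.

Homology hits are BLAST tabular (outfmt-6) records. A gene is a ZW homolog
when any hit passes the strict rule (e-value <= 1e-10, identity > 80,
alignment/query length > 70%) and haplotype-specific when no hit passes the
soft rule (e-value <= 1e-5, identity > 60, coverage > 50%); genes in the gap
between the two rules are ambiguous. Gene loss is the complement of the
haplotype's gene count over the joint count across both haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

ZW_HOMOLOG = "zw_homolog"
HAPLOTYPE_SPECIFIC = "haplotype_specific"
AMBIGUOUS = "ambiguous"

CONSERVED = "conserved"
ANCESTRAL = "ancestral"
SPECIES_SPECIFIC = "species_specific"

#: reference species per clade used for the conservation classes
CLADES = {
    "clade1": ("S_purpurea", "S_suchowensis"),
    "clade2": ("S_arbutifolia", "S_dunnii"),
    "clade3": ("P_qiongdaoensis", "P_trichocarpa"),
}
SPECIES_ORDER = tuple(sp for clade in CLADES.values() for sp in clade)


@dataclass(frozen=True)
class HomologyThresholds:
    max_evalue: float
    min_identity: float  # percent, strict >
    min_coverage: float  # alignment length / query length, strict >


STRICT = HomologyThresholds(1e-10, 80.0, 0.70)
SOFT = HomologyThresholds(1e-5, 60.0, 0.50)


def hit_passes(hit, thresholds: HomologyThresholds, qlen=None) -> bool:
    """One outfmt-6 hit row against a threshold rule. The coverage
    denominator is the query length (``qlen`` column 13 when present)."""
    qlen = qlen if qlen is not None else getattr(hit, "qlen", None)
    if qlen is None or qlen <= 0:
        raise ValueError("query length required for the coverage rule")
    return (
        hit.evalue <= thresholds.max_evalue
        and hit.pident > thresholds.min_identity
        and hit.length / qlen > thresholds.min_coverage
    )


def classify_zw(hits: pd.DataFrame, strict=STRICT, soft=SOFT) -> pd.DataFrame:
    """Classify each query gene from its hits against the other haplotype.

    The best single HSP decides (HSPs are not summed). Queries absent from
    the table are not reported; callers treat them as haplotype-specific.
    """
    rows = []
    for gene, sub in hits.groupby("qseqid", sort=True):
        any_strict = False
        any_soft = False
        best = None
        for hit in sub.itertuples(index=False):
            if hit_passes(hit, strict):
                any_strict = True
            if hit_passes(hit, soft):
                any_soft = True
            if best is None or hit.bitscore > best.bitscore:
                best = hit
        if any_strict:
            cls = ZW_HOMOLOG
        elif not any_soft:
            cls = HAPLOTYPE_SPECIFIC
        else:
            cls = AMBIGUOUS
        rows.append(
            dict(gene_id=gene, zw_class=cls, best_subject=best.sseqid,
                 best_identity=best.pident, best_evalue=best.evalue)
        )
    return pd.DataFrame(rows)


def classify_conservation(presence) -> str:
    """Conservation class from a six-species presence vector.

    conserved: present in at least one species of EACH of the three clades;
    ancestral: present in at least one species overall; otherwise
    species-specific. (Conserved genes also satisfy the ancestral condition.)
    """
    if isinstance(presence, dict):
        vec = [bool(presence[sp]) for sp in SPECIES_ORDER]
    else:
        vec = [bool(v) for v in presence]
    if len(vec) != 6:
        raise ValueError(f"presence vector must have 6 species, got {len(vec)}")
    per_clade = [vec[0] or vec[1], vec[2] or vec[3], vec[4] or vec[5]]
    if all(per_clade):
        return CONSERVED
    if any(vec):
        return ANCESTRAL
    return SPECIES_SPECIFIC


def classify_conservation_table(presence: pd.DataFrame) -> pd.Series:
    """Vectorized conservation class over a gene x species boolean table."""
    return presence.apply(
        lambda row: classify_conservation([row[sp] for sp in SPECIES_ORDER]), axis=1
    )


@dataclass(frozen=True)
class GeneLossEstimate:
    scope: str
    category: str
    n_present: int
    n_joint: int

    @property
    def loss(self) -> float:
        return 1.0 - self.n_present / self.n_joint

    @property
    def loss_2dp(self) -> float:
        """Report precision: round half-up to 2 decimals."""
        return float(Decimal(repr(self.loss)).quantize(Decimal("0.01"), ROUND_HALF_UP))


def gene_loss(n_present: int, n_joint: int, scope="", category="") -> GeneLossEstimate:
    """Proportion of the joint gene set missing from one haplotype."""
    if n_joint <= 0:
        raise ValueError("joint gene count must be > 0")
    if not 0 <= n_present <= n_joint:
        raise ValueError("need 0 <= n_present <= n_joint")
    return GeneLossEstimate(scope=scope, category=category, n_present=n_present, n_joint=n_joint)


# ---------------------------------------------------------------------------
# pseudogene pipeline (steps 3-5: filter, link, stack)

PSEUDO_MIN_IDENTITY = 40.0  # percent; matches below are removed, 40.0 kept
PSEUDO_MIN_LENGTH = 30  # aligned residues; 30 kept
PSEUDO_LINK_GAP = 50  # bp, inclusive
PSEUDO_STACK_OVERLAP = 0.80  # of the shorter interval


def pseudo_filter(
    hits: pd.DataFrame,
    min_identity: float = PSEUDO_MIN_IDENTITY,
    min_length: int = PSEUDO_MIN_LENGTH,
) -> pd.DataFrame:
    """Remove weak translated-search matches (strict-inequality removal:
    identity < 40% or match length < 30 residues go; the boundaries stay)."""
    keep = (hits["pident"] >= min_identity) & (hits["length"] >= min_length)
    return hits[keep].reset_index(drop=True)


@dataclass
class PseudoChain:
    """Adjacent same-protein hits linked along the chromosome."""

    chrom: str
    protein: str
    start: int
    end: int
    n_hits: int = 1

    @property
    def interval(self):
        return (self.start, self.end)


def pseudo_link(hits: pd.DataFrame, max_gap: int = PSEUDO_LINK_GAP) -> list:
    """Chain hits to the same protein within ``max_gap`` bp (inclusive).

    ``hits`` needs columns chrom, protein, start, end (0-based half-open
    genomic coordinates of the match). Different proteins never link here.
    """
    chains = []
    ordered = hits.sort_values(["chrom", "protein", "start", "end"])
    for (chrom, protein), sub in ordered.groupby(["chrom", "protein"], sort=True):
        current = None
        for h in sub.itertuples(index=False):
            if current is not None and h.start - current.end <= max_gap:
                current.end = max(current.end, int(h.end))
                current.n_hits += 1
            else:
                current = PseudoChain(chrom=chrom, protein=protein,
                                      start=int(h.start), end=int(h.end))
                chains.append(current)
    return chains


@dataclass
class PseudogeneLocus:
    chrom: str
    start: int
    end: int
    proteins: tuple

    @property
    def interval(self):
        return (self.start, self.end)


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _reciprocal_overlap(a, b) -> float:
    """Overlap as a fraction of the shorter interval."""
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return ov / min(a[1] - a[0], b[1] - b[0])


def pseudo_stack(chains, min_overlap: float = PSEUDO_STACK_OVERLAP) -> list:
    """Merge chains sharing at least ``min_overlap`` of the shorter interval
    into pseudogene loci (single linkage over the pairwise-overlap graph);
    one locus can list multiple matched proteins."""
    chains = sorted(chains, key=lambda c: (c.chrom, c.start, c.end, c.protein))
    uf = _UnionFind(len(chains))
    for i, ci in enumerate(chains):
        for j in range(i + 1, len(chains)):
            cj = chains[j]
            if cj.chrom != ci.chrom or cj.start >= ci.end:
                break
            if _reciprocal_overlap(ci.interval, cj.interval) >= min_overlap:
                uf.union(i, j)
    groups = {}
    for i in range(len(chains)):
        groups.setdefault(uf.find(i), []).append(chains[i])
    loci = []
    for members in groups.values():
        loci.append(
            PseudogeneLocus(
                chrom=members[0].chrom,
                start=min(c.start for c in members),
                end=max(c.end for c in members),
                proteins=tuple(sorted({c.protein for c in members})),
            )
        )
    loci.sort(key=lambda l: (l.chrom, l.start, l.end))
    return loci


# ---------------------------------------------------------------------------
# Ks summaries


def summarize_ks(records: pd.DataFrame) -> pd.DataFrame:
    """Median synonymous divergence (and Ka/Ks where present) per region.

    Values above any display cap still enter the medians. Regions without
    records are absent from the output.
    """
    out = []
    for region, sub in records.groupby("region", sort=True):
        row = dict(region=region, n_genes=len(sub), median_ks=float(sub["ks"].median()))
        if "ka_ks" in sub.columns and sub["ka_ks"].notna().any():
            row["median_ka_ks"] = float(sub["ka_ks"].median())
        out.append(row)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# complete / partial duplicate copies and inverted (hairpin candidate) pairs

COMPLETE = "complete"
PARTIAL_FIRST_EXON = "partial_first_exon"
OTHER = "other"

DUP_IDENTITY = 80.0  # percent, strict >


@dataclass(frozen=True)
class DuplicateCopy:
    locus: str
    chrom: str
    start: int
    end: int
    strand: str
    copy_class: str
    exon_identities: tuple  # ((exon_number, identity), ...)


def classify_copies(
    layout: pd.DataFrame, n_exons_query: int, min_identity: float = DUP_IDENTITY
) -> list:
    """Classify candidate loci from per-exon best-hit identities.

    ``layout`` needs columns locus, chrom, start, end, strand, exon_id
    ("exonN") and identity. complete: every query exon matched above the
    identity threshold; partial_first_exon: only exon 1 matched (above the
    threshold); anything else is other.
    """
    if n_exons_query < 1:
        raise ValueError("query gene model must have at least one exon")
    copies = []
    for locus, sub in layout.groupby("locus", sort=True):
        best = {}
        for h in sub.itertuples(index=False):
            exon = int(str(h.exon_id).removeprefix("exon"))
            best[exon] = max(best.get(exon, 0.0), float(h.identity))
        hit_exons = set(best)
        all_above = {e for e, ident in best.items() if ident > min_identity}
        if hit_exons == set(range(1, n_exons_query + 1)) and all_above == hit_exons:
            cls = COMPLETE
        elif hit_exons == {1} and 1 in all_above:
            cls = PARTIAL_FIRST_EXON
        else:
            cls = OTHER
        strands = set(sub["strand"])
        copies.append(
            DuplicateCopy(
                locus=locus,
                chrom=sub["chrom"].iloc[0],
                start=int(sub["start"].min()),
                end=int(sub["end"].max()),
                strand=strands.pop() if len(strands) == 1 else ".",
                copy_class=cls,
                exon_identities=tuple(sorted(best.items())),
            )
        )
    return copies


@dataclass
class InvertedPairSet:
    pairs: list  # [(copy_i, copy_j)] opposite strands, each copy in <= 1 pair
    unpaired: list


def pair_inverted(copies, max_pair_distance: int = 100_000) -> InvertedPairSet:
    """Greedy nearest-neighbour matching of opposite-strand copies.

    Candidate pairs on the same chromosome within ``max_pair_distance``
    (midpoint distance) are taken closest-first; each copy joins at most one
    pair and leftovers are reported unpaired. Same-strand copies never pair.
    """
    copies = list(copies)
    mid = [(c.start + c.end) / 2 for c in copies]
    candidates = []
    for i in range(len(copies)):
        for j in range(i + 1, len(copies)):
            if copies[i].chrom != copies[j].chrom:
                continue
            if copies[i].strand == copies[j].strand or "." in (
                copies[i].strand, copies[j].strand
            ):
                continue
            d = abs(mid[i] - mid[j])
            if d <= max_pair_distance:
                candidates.append((d, i, j))
    candidates.sort()
    used = set()
    pairs = []
    for _d, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        pairs.append((copies[i], copies[j]))
    unpaired = [c for k, c in enumerate(copies) if k not in used]
    return InvertedPairSet(pairs=pairs, unpaired=unpaired)
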