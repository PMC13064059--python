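"""Fixed female-specific SNPs and codon-level variant-effect classes.

A fixed female-specific SNP marks a diverged site between the W and Z
haplotypes: every female (ZW) carries both alleles, every male (ZZ) is
homozygous for the Z allele. To guard against collapsed duplications,
individuals count as heterozygous only when the minor allele holds strictly
more than ``min_minor_prop`` of their reads (default 0.3, i.e. a
minor/major ratio above 3/7 ~ 0.43).

Coding variants are classified into three bins on the standard nuclear
genetic code: nonsense (new stop codon), synonymous (same amino acid) and
missense (everything else, including stop-loss and start-codon loss).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .records import SexedGenotypeMatrix, require_both_sexes

HET = "het"
HOM = "hom"
UNRESOLVED = "unresolved"

NONSENSE = "nonsense"
MISSENSE = "missense"
SYNONYMOUS = "synonymous"

DEFAULT_MIN_MINOR_PROP = 0.3

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_STOP = "*"

_CODON_TO_AA = dict(standard_dna_table.forward_table)
_CODON_TO_AA.update({codon: _STOP for codon in standard_dna_table.stop_codons})


class RefMismatchError(ValueError):
    """The supplied REF allele disagrees with the CDS sequence."""


def call_het_by_reads(ad, gt=None, min_minor_prop: float = DEFAULT_MIN_MINOR_PROP) -> str:
    """Conservative read-backed zygosity call for one genotype.

    het iff the minor-allele read proportion is strictly greater than
    ``min_minor_prop``; hom iff no minor reads at all, or the called genotype
    is homozygous and the minor proportion stays at or below the threshold;
    otherwise (including zero total depth) unresolved.
    """
    ad = np.asarray(ad)
    total = int(ad.sum())
    if total <= 0:
        return UNRESOLVED
    minor = int(ad.min())
    prop = minor / total
    if prop > min_minor_prop:
        return HET
    if minor == 0:
        return HOM
    gt_hom = gt is not None and gt[0] == gt[1] and gt[0] >= 0
    if gt_hom:
        return HOM
    return UNRESOLVED


def find_fixed_female_snps(
    matrix: SexedGenotypeMatrix,
    min_minor_prop: float = DEFAULT_MIN_MINOR_PROP,
):
    """Sites consistently heterozygous in all females and homozygous (for one
    of the two female alleles) in all males, restricted to biallelic SNPs.

    Returns (DataFrame, clause_tally). Sites failing any clause are silently
    dropped; the tally counts first-failing clauses for diagnostics.
    """
    require_both_sexes(matrix.samples)
    is_f = matrix.is_female
    tally = Counter()
    rows = []
    biallelic = matrix.is_biallelic() & matrix.is_snp()
    for i in range(matrix.n_sites):
        if not biallelic[i]:
            tally["not_biallelic_snp"] += 1
            continue
        gt = matrix.gt[i]
        if np.any(gt < 0):
            tally["missing_genotype"] += 1
            continue
        calls = [
            call_het_by_reads(matrix.ad[i, j], gt[j], min_minor_prop)
            for j in range(matrix.n_samples)
        ]
        calls = np.array(calls)
        if not np.all(calls[is_f] == HET):
            tally["female_not_het"] += 1
            continue
        male_gt = gt[~is_f]
        if not np.all((calls[~is_f] == HOM) & (male_gt[:, 0] == male_gt[:, 1])):
            tally["male_not_hom"] += 1
            continue
        male_alleles = np.unique(male_gt[:, 0])
        if len(male_alleles) != 1:
            tally["male_alleles_differ"] += 1
            continue
        male_allele_idx = int(male_alleles[0])
        alleles = (matrix.ref[i], matrix.alts[i][0])
        rows.append(
            dict(
                chrom=matrix.chrom,
                pos=int(matrix.positions[i]),
                female_allele_1=alleles[0],
                female_allele_2=alleles[1],
                male_allele=alleles[male_allele_idx],
            )
        )
        tally["emitted"] += 1
    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "female_allele_1", "female_allele_2", "male_allele"],
    )
    return df, tally


# ---------------------------------------------------------------------------
# codon-level effect classification


@dataclass
class CdsModel:
    """A spliced coding sequence with its genomic exon layout.

    ``exons`` are 0-based half-open genomic intervals in genomic order;
    ``seq`` is the spliced CDS on the coding strand (reverse-complemented
    for minus-strand genes).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list
    seq: str

    def __post_init__(self):
        self.seq = self.seq.upper()
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if len(self.seq) != sum(e - s for s, e in self.exons):
            raise ValueError("spliced sequence length does not match exons")
        if len(self.seq) % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")

    def cds_index(self, pos: int):
        """Map a genomic position to a 0-based index into the spliced CDS;
        None when the position falls outside the exons."""
        offset = 0
        for s, e in self.exons:
            if s <= pos < e:
                g = offset + (pos - s)
                if self.strand == "+":
                    return g
                return len(self.seq) - 1 - g
            offset += e - s
        return None


def translate_codon(codon: str) -> str:
    return _CODON_TO_AA[codon.upper()]


def classify_effect(cds: CdsModel, pos: int, ref: str, alt: str):
    """Effect class of a coding SNP, or None when it falls outside the CDS."""
    idx = cds.cds_index(pos)
    if idx is None:
        return None
    ref_c, alt_c = ref.upper(), alt.upper()
    if cds.strand == "-":
        ref_c = ref_c.translate(_COMPLEMENT)
        alt_c = alt_c.translate(_COMPLEMENT)
    if cds.seq[idx] != ref_c:
        raise RefMismatchError(
            f"{cds.gene_id}: REF {ref!r} at {cds.chrom}:{pos} does not match "
            f"CDS base {cds.seq[idx]!r} (strand {cds.strand})"
        )
    codon_start = (idx // 3) * 3
    old_codon = cds.seq[codon_start:codon_start + 3]
    within = idx - codon_start
    new_codon = old_codon[:within] + alt_c + old_codon[within + 1:]
    old_aa = translate_codon(old_codon)
    new_aa = translate_codon(new_codon)
    if new_aa == _STOP and old_aa != _STOP:
        return NONSENSE
    if new_aa == old_aa:
        return SYNONYMOUS
    return MISSENSE


def classify_variants(cds_models, variants: pd.DataFrame) -> pd.DataFrame:
    """Classify each SNP against every CDS model it falls in.

    ``variants`` needs columns chrom, pos, ref, alt. A variant inside
    overlapping CDSs of two genes yields one classified row per gene.
    """
    rows = []
    by_chrom = {}
    for m in cds_models:
        by_chrom.setdefault(m.chrom, []).append(m)
    for rec in variants.itertuples(index=False):
        for m in by_chrom.get(rec.chrom, []):
            effect = classify_effect(m, rec.pos, rec.ref, rec.alt)
            if effect is not None:
                rows.append(
                    dict(chrom=rec.chrom, pos=rec.pos, gene_id=m.gene_id, effect=effect)
                )
    return pd.DataFrame(rows, columns=["chrom", "pos", "gene_id", "effect"])


def region_effect_proportions(classified: pd.DataFrame, regions) -> pd.DataFrame:
    """Per-region counts and proportions of each effect class.

    ``regions`` is a list of LabeledIntervals; overlapping labels are an
    error. Regions without coding variants appear with NaN proportions.
    """
    ordered = sorted(regions, key=lambda r: r.start)
    for left, right in zip(ordered, ordered[1:]):
        if right.start < left.end:
            raise ValueError(f"region labels overlap: {left.label} and {right.label}")
    rows = []
    for region in regions:
        if len(classified):
            sub = classified[
                (classified["pos"] >= region.start) & (classified["pos"] < region.end)
            ]
        else:
            sub = classified
        counts = {c: int((sub["effect"] == c).sum()) for c in (NONSENSE, MISSENSE, SYNONYMOUS)}
        total = sum(counts.values())
        row = dict(region=region.label, n_variants=total, **counts)
        for c in (NONSENSE, MISSENSE, SYNONYMOUS):
            row[f"prop_{c}"] = counts[c] / total if total else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
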