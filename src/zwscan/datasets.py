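"""Bundled published summary inputs.

A gene census of chromosome 15 from a haplotype-resolved assembly of the
dwarf willow (*Salix herbacea*), a ZW dioecious shrub: per-haplotype gene
counts split by ZW homology and by conservation class across three
Salicaceae clades, with the joint counts across both haplotypes used as the
gene-loss denominators. These numbers are inputs to the gene-loss
arithmetic, not outputs of this package.
"""

#: per-scope gene census; lengths in Mb
CHR15_GENE_CENSUS = {
    "W": dict(
        length_mb=15.8, n_genes=1288, zw_homologs=1075, haplotype_specific=192,
        conserved=925, ancestral=1145, lineage_specific=143,
    ),
    "Z": dict(
        length_mb=16.6, n_genes=1488, zw_homologs=1115, haplotype_specific=263,
        conserved=1026, ancestral=1250, lineage_specific=238,
    ),
    "W-SLR": dict(
        length_mb=8.4, n_genes=426, zw_homologs=300, haplotype_specific=109,
        conserved=209, ancestral=350, lineage_specific=76,
    ),
    "Z-SLR": dict(
        length_mb=8.0, n_genes=477, zw_homologs=336, haplotype_specific=120,
        conserved=251, ancestral=387, lineage_specific=90,
    ),
}

#: joint gene counts across both haplotypes (gene-loss denominators)
JOINT_GENE_COUNTS = {
    ("chr15", "conserved"): 1091,
    ("chr15", "ancestral"): 1404,
    ("SLR", "conserved"): 272,
    ("SLR", "ancestral"): 476,
}


def gene_loss_table():
    """All eight haplotype x category gene-loss estimates from the census."""
    from .genes import gene_loss

    out = []
    for scope_key, joint_key in (
        ("W", "chr15"), ("Z", "chr15"), ("W-SLR", "SLR"), ("Z-SLR", "SLR")
    ):
        for category in ("conserved", "ancestral"):
            out.append(
                gene_loss(
                    CHR15_GENE_CENSUS[scope_key][category],
                    JOINT_GENE_COUNTS[(joint_key, category)],
                    scope=scope_key,
                    category=category,
                )
            )
    return out
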