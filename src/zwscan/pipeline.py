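"""Full pipeline: chain the scans, the SLR call and the evolution analyses
over one synthetic (or reloaded) data bundle, writing every stage's files
and a JSON run manifest."""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import coverage, fst, genes, ltr, segmentation, variants
from . import io as zio
from .records import FEMALE, MALE, WindowTrack

logger = logging.getLogger("zwscan")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[zwscan %(stage)s] %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


def _log(stage, msg):
    logger.info(msg, extra={"stage": stage})


class MissingStageInputError(RuntimeError):
    pass


def female_fraction_track(result, config) -> dict:
    """Normalized per-sex mean depth and F/(F+M) per chromosome."""
    w = config["window_size"]
    is_f = result.is_female
    norm = {}
    per_chrom_windows = {
        chrom: np.array([coverage.windowed_mean_depth(result.depth[chrom][i], w)
                         for i in range(len(result.samples))])
        for chrom in result.depth
    }
    fractions = {}
    for chrom, win_depth in per_chrom_windows.items():
        f_norm = []
        m_norm = []
        for i, s in enumerate(result.samples):
            ref_mean = coverage.reference_mean_depth(
                {c: per_chrom_windows[c][i] for c in per_chrom_windows},
                autosomes={"chrA"} if "chrA" in per_chrom_windows else None,
            )
            track = coverage.normalize_depth(
                WindowTrack(chrom, w, win_depth[i], statistic="depth"), ref_mean
            )
            (f_norm if is_f[i] else m_norm).append(track.values)
        f_mean = np.mean(f_norm, axis=0)
        m_mean = np.mean(m_norm, axis=0)
        fractions[chrom] = coverage.female_fraction(
            WindowTrack(chrom, w, f_mean), WindowTrack(chrom, w, m_mean)
        )
    return fractions


def het_ratio_track(result, config, chrom="chrW") -> WindowTrack:
    w = config["window_size"]
    matrix = result.genotypes[chrom]
    L = result.depth[chrom].shape[1]
    props = np.array([
        coverage.het_proportion_windows(matrix.gt[:, j], matrix.positions, L, w)
        for j in range(matrix.n_samples)
    ])
    is_f = matrix.is_female
    f_mean = coverage.sex_mean_het(props[is_f])
    m_mean = coverage.sex_mean_het(props[~is_f])
    return coverage.het_ratio(f_mean, m_mean, chrom=chrom, window_size=w)


def fst_scan(result, config):
    """QC-filtered between-sex windowed FST with genome-wide p99 flags."""
    w = config["window_size"]
    theta = {}
    n_sites = {}
    for chrom, matrix in result.genotypes.items():
        filtered = fst.qc_filter(matrix, preset=config["qc_preset"])
        a, b, c = fst.wc_components(filtered)
        L = result.depth[chrom].shape[1]
        theta[chrom], n_sites[chrom] = fst.windowed_fst(
            filtered.positions, a, b, c, L, w
        )
    all_values = np.concatenate(list(theta.values()))
    threshold, _ = fst.flag_p99(all_values, config["percentile"])
    exceeds = {chrom: np.isfinite(t) & (t > threshold) for chrom, t in theta.items()}
    return theta, n_sites, threshold, exceeds


def sex_specific_sites(result, config, chrom="chrW"):
    presence = coverage.call_presence(result.depth[chrom], config["absent_max"])
    return coverage.find_sex_specific_sites(presence, result.samples)


def run_pipeline(result, config=None, outdir="zwscan_run", inversion=None, force=False):
    """Run every stage on an in-memory bundle; returns the manifest dict.

    ``inversion`` is the externally supplied inversion interval; when absent
    and the bundle carries truth labels, the truth inversion stands in for
    the external structural-variant call.
    """
    config = config or zio.load_config()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = {}

    # --- depth scan ---
    _log("depth-scan", "computing female depth fraction")
    fractions = female_fraction_track(result, config)
    zio.write_window_track(fractions["chrW"], outdir / "female_fraction.chrW.tsv", force)
    stages["depth-scan"] = "female_fraction.chrW.tsv"

    # --- het scan ---
    _log("het-scan", "computing log2 F/M heterozygosity ratio")
    het = het_ratio_track(result, config)
    zio.write_window_track(het, outdir / "het_ratio.chrW.tsv", force)
    stages["het-scan"] = "het_ratio.chrW.tsv"

    # --- fst scan ---
    _log("fst-scan", "computing windowed Weir-Cockerham FST")
    theta, n_sites, threshold, exceeds = fst_scan(result, config)
    for chrom in theta:
        zio.write_window_track(
            WindowTrack(chrom, config["window_size"], theta[chrom], "fst"),
            outdir / f"fst.{chrom}.tsv", force,
        )
    flagged = [
        (chrom, int(i * config["window_size"]), int((i + 1) * config["window_size"]), "p99")
        for chrom, mask in exceeds.items() for i in np.nonzero(mask)[0]
    ]
    zio.write_bed(flagged, outdir / "fst_flagged.bed", force)
    stages["fst-scan"] = "fst.chrW.tsv"

    # --- sex-specific sites ---
    _log("sexsites", "calling base-resolution sex-specific sites")
    sites = sex_specific_sites(result, config)
    regions_f, total_f = coverage.merge_sites_to_regions(
        sites[FEMALE], "chrW", FEMALE, config["max_gap_sites"]
    )
    regions_m, _ = coverage.merge_sites_to_regions(
        sites[MALE], "chrW", MALE, config["max_gap_sites"]
    )
    zio.write_bed(regions_f, outdir / "sexsites_female.bed", force)
    zio.write_bed(regions_m, outdir / "sexsites_male.bed", force)
    stages["sexsites"] = "sexsites_female.bed"

    # --- SLR call + partition ---
    _log("call-slr", "integrating evidence tracks")
    call = segmentation.call_slr(
        fractions["chrW"],
        delta=config["delta"],
        min_run=config["min_run"],
        max_gap=config["max_gap_windows"],
        fst_exceeds=exceeds["chrW"],
        het_flags=het.flags,
        sex_specific_sites=sites[FEMALE],
    )
    if call is None:
        raise MissingStageInputError("call-slr: no seed windows; cannot continue")
    if inversion is None and getattr(result, "truth", None) is not None:
        inv = result.truth.inv
        inversion = (inv.start, inv.end)
    partition = segmentation.partition_regions(
        call.interval, regions_f, inversion, result.depth["chrW"].shape[1]
    )
    zio.write_bed(
        [("chrW", call.start, call.end, "SLR")], outdir / "slr_call.bed", force
    )
    zio.write_bed(
        [("chrW", iv.start, iv.end, iv.label) for iv in partition.intervals],
        outdir / "partition.bed", force,
    )
    stages["call-slr"] = "partition.bed"

    # --- fixed female-specific SNPs ---
    _log("sexsnps", "scanning for fixed female-specific SNPs")
    filtered = fst.qc_filter(result.genotypes["chrW"], preset="slr")
    snps, tally = variants.find_fixed_female_snps(filtered, config["min_minor_prop"])
    snps.to_csv(outdir / "fixed_female_snps.tsv", sep="\t", index=False)
    stages["sexsnps"] = "fixed_female_snps.tsv"

    # --- variant effects per region ---
    _log("effects", "classifying coding effects of fixed SNPs")
    if result.genome is None:
        raise MissingStageInputError("effects: needs the genome sequence (run simulate first)")
    models = _cds_models_from_result(result)
    effect_input = _snp_alleles(filtered, snps)
    classified = variants.classify_variants(models, effect_input)
    summary = variants.region_effect_proportions(classified, partition.intervals)
    summary.to_csv(outdir / "effects_by_region.tsv", sep="\t", index=False)
    stages["effects"] = "effects_by_region.tsv"

    # --- homology / gene loss ---
    _log("homology", "classifying ZW homologs")
    zw_classes = genes.classify_zw(result.zw_hits)
    zw_classes.to_csv(outdir / "zw_classes.tsv", sep="\t", index=False)
    stages["homology"] = "zw_classes.tsv"

    _log("geneloss", "estimating gene loss per haplotype and scope")
    loss_df = gene_loss_from_tables(result.truth.gene_table)
    loss_df.to_csv(outdir / "gene_loss.tsv", sep="\t", index=False)
    stages["geneloss"] = "gene_loss.tsv"

    # --- pseudogenes ---
    _log("pseudogene", "filter/link/stack degraded-protein hits")
    hits = genes.pseudo_filter(result.pseudo_hits,
                               config["pseudo_min_identity"],
                               config["pseudo_min_length"])
    chains = genes.pseudo_link(hits, config["pseudo_link_gap"])
    loci = genes.pseudo_stack(chains, config["pseudo_stack_overlap"])
    zio.write_bed(
        [(l.chrom, l.start, l.end, ",".join(l.proteins)) for l in loci],
        outdir / "pseudogene_loci.bed", force,
    )
    stages["pseudogene"] = "pseudogene_loci.bed"

    # --- LTR dating ---
    _log("ltr-date", "dating LTR insertions")
    dated = ltr.date_ltr_pairs(
        [(e, fam, s5, s3) for e, fam, _age, s5, s3 in result.ltr_pairs],
        mu=config["mu"], aligned=False,
    )
    dated.to_csv(outdir / "ltr_dates.tsv", sep="\t", index=False)
    stages["ltr-date"] = "ltr_dates.tsv"

    # --- duplicate scan ---
    _log("dupscan", "classifying duplicates and pairing inverted copies")
    copies = genes.classify_copies(result.duplicate_layout, n_exons_query=5,
                                   min_identity=config["dup_identity"])
    partials = [c for c in copies if c.copy_class == genes.PARTIAL_FIRST_EXON]
    pairset = genes.pair_inverted(partials, config["max_pair_distance"])
    pd.DataFrame(
        [dict(locus=c.locus, copy_class=c.copy_class, strand=c.strand,
              start=c.start, end=c.end) for c in copies]
    ).to_csv(outdir / "duplicate_classes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [dict(copy_a=a.locus, copy_b=b.locus,
              distance=abs((a.start + a.end) / 2 - (b.start + b.end) / 2))
         for a, b in pairset.pairs]
    ).to_csv(outdir / "inverted_pairs.tsv", sep="\t", index=False)
    stages["dupscan"] = "inverted_pairs.tsv"

    manifest = {
        "config": {k: v for k, v in config.items()},
        "seed": getattr(result.params, "seed", None),
        "stages": stages,
        "summary": {
            "slr_call": [call.start, call.end],
            "slr_evidence": call.evidence,
            "fst_p99_threshold": threshold,
            "n_female_specific_regions": len(regions_f),
            "female_specific_total_bp": int(total_f),
            "n_fixed_female_snps": int(len(snps)),
            "snp_clause_tally": dict(tally),
            "n_pseudogene_loci": len(loci),
            "n_inverted_pairs": len(pairset.pairs),
            "n_unpaired_partials": len(pairset.unpaired),
        },
        "files": {},
    }
    for p in sorted(outdir.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][p.name] = zio.file_checksum(p)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    _log("run", f"wrote {len(stages)} stage outputs to {outdir}")
    return manifest


def _cds_models_from_result(result):
    from .variants import CdsModel

    comp = str.maketrans("ACGT", "TGCA")
    models = []
    seq_w = result.genome_seq("chrW")
    for g in result.truth.gene_table.itertuples(index=False):
        if not g.present_w:
            continue
        seq = seq_w[g.start:g.end]
        if g.strand == "-":
            seq = seq[::-1].translate(comp)
        models.append(CdsModel(gene_id=g.gene_id, chrom="chrW", strand=g.strand,
                               exons=[(g.start, g.end)], seq=seq))
    return models


def _snp_alleles(matrix, snps: pd.DataFrame) -> pd.DataFrame:
    """REF/ALT lookup for emitted fixed SNPs (the W allele is the ALT)."""
    pos_to_idx = {int(p): i for i, p in enumerate(matrix.positions)}
    rows = []
    for r in snps.itertuples(index=False):
        i = pos_to_idx[r.pos]
        rows.append(dict(chrom=r.chrom, pos=r.pos,
                         ref=matrix.ref[i], alt=matrix.alts[i][0]))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


def gene_loss_from_tables(gene_table: pd.DataFrame) -> pd.DataFrame:
    """Haplotype x scope x category gene-loss estimates from a truth-style
    gene table carrying conservation classes and per-haplotype presence."""
    rows = []
    for scope, mask in (
        ("chrW", np.ones(len(gene_table), dtype=bool)),
        ("SLR", gene_table["in_slr"].to_numpy(dtype=bool)),
    ):
        sub = gene_table[mask]
        for category in (genes.CONSERVED, genes.ANCESTRAL):
            if category == genes.CONSERVED:
                in_cat = sub["conservation"] == genes.CONSERVED
            else:  # ancestral includes conserved
                in_cat = sub["conservation"].isin([genes.CONSERVED, genes.ANCESTRAL])
            joint = sub[in_cat & (sub["present_w"] | sub["present_z"])]
            if len(joint) == 0:
                continue
            for hap, col in (("W", "present_w"), ("Z", "present_z")):
                est = genes.gene_loss(int(joint[col].sum()), len(joint),
                                      scope=f"{hap}-{scope}", category=category)
                rows.append(dict(scope=est.scope, category=category,
                                 n_present=est.n_present, n_joint=est.n_joint,
                                 loss=est.loss, loss_2dp=est.loss_2dp))
    return pd.DataFrame(rows)
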