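"""Readers and writers for the pipeline's plain-text formats.

Conventions: BED and depth tracks are 0-based half-open; VCF is 1-based;
GFF3 is 1-based inclusive. Conversions happen only here. Existing output
files are never overwritten unless ``force`` is set.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .records import SexedGenotypeMatrix, SexedSample, WindowTrack

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def _check_overwrite(path, force):
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True (or --force) to overwrite")
    path.parent.mkdir(parents=True, exist_ok=True)
    return path


# ---------------------------------------------------------------------------
# sample sheet


def write_sample_sheet(samples, path, autosomes=(), force=False):
    path = _check_overwrite(path, force)
    rows = [
        dict(sample_id=s.sample_id, sex=s.sex, kind=s.kind, pool_size=s.pool_size,
             autosomes=",".join(autosomes))
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path):
    """Returns (samples, autosome label set)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_ids in sample sheet")
    samples = [
        SexedSample(
            sample_id=r.sample_id,
            sex=r.sex,
            kind=getattr(r, "kind", "individual"),
            pool_size=int(getattr(r, "pool_size", 1)),
        )
        for r in df.itertuples(index=False)
    ]
    autosomes = set()
    if "autosomes" in df.columns and len(df):
        first = df["autosomes"].iloc[0]
        if isinstance(first, str) and first:
            autosomes = set(first.split(","))
    return samples, autosomes


# ---------------------------------------------------------------------------
# depth tracks and window tracks


def write_depth_bed(chrom, starts, ends, depths, path, force=False):
    path = _check_overwrite(path, force)
    pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": ends, "depth": depths}
    ).to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")


def read_depth_bed(path):
    """Depth intervals as a DataFrame (chrom, start, end, depth)."""
    return pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "depth"], comment="#"
    )


def depth_bed_to_windows(df, chrom, chrom_length, window_size):
    """Windowed mean depth from (possibly mixed-resolution) depth intervals."""
    sub = df[df["chrom"] == chrom]
    n_windows = -(-chrom_length // window_size)
    total = np.zeros(n_windows)
    covered = np.zeros(n_windows)
    for r in sub.itertuples(index=False):
        s, e = int(r.start), int(r.end)
        w0, w1 = s // window_size, (e - 1) // window_size
        for w in range(w0, w1 + 1):
            lo = max(s, w * window_size)
            hi = min(e, (w + 1) * window_size)
            total[w] += r.depth * (hi - lo)
            covered[w] += hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(covered > 0, total / np.maximum(covered, 1), np.nan)


def write_window_track(track: WindowTrack, path, force=False):
    path = _check_overwrite(path, force)
    pd.DataFrame(
        {
            "chrom": track.chrom,
            "start": track.starts,
            "end": track.ends,
            "value": track.values,
            "flag": [f if f else "." for f in track.flags],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_window_track(path) -> WindowTrack:
    df = pd.read_csv(path, sep="\t")
    window_size = int(df["end"].iloc[0] - df["start"].iloc[0]) if len(df) else 1
    flags = np.array(["" if f == "." else f for f in df["flag"]], dtype=object)
    return WindowTrack(
        chrom=str(df["chrom"].iloc[0]) if len(df) else "",
        window_size=window_size,
        values=df["value"].to_numpy(dtype=float),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# BED regions


def write_bed(intervals, path, force=False):
    """Write (chrom, start, end, name) tuples or objects with those fields."""
    path = _check_overwrite(path, force)
    with open(path, "w") as fh:
        for iv in intervals:
            if hasattr(iv, "chrom"):
                name = getattr(iv, "label", None) or getattr(iv, "sex", ".")
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")
            else:
                fh.write("\t".join(str(x) for x in iv) + "\n")


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    return df


# ---------------------------------------------------------------------------
# VCF


def write_vcf(matrix: SexedGenotypeMatrix, path, force=False, contig_lengths=None):
    """VCF v4.2 with GT:AD:DP, uncompressed text."""
    path = _check_overwrite(path, force)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=zwscan-simulate\n")
        for chrom, length in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        names = "\t".join(s.sample_id for s in matrix.samples)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{names}\n")
        for i in range(matrix.n_sites):
            alt = ",".join(matrix.alts[i])
            qual = "." if np.isnan(matrix.qual[i]) else f"{matrix.qual[i]:g}"
            cols = [
                matrix.chrom, str(int(matrix.positions[i]) + 1), ".",
                matrix.ref[i], alt, qual, "PASS", ".", "GT:AD:DP",
            ]
            for j in range(matrix.n_samples):
                a, b = matrix.gt[i, j]
                gt = "./." if a < 0 or b < 0 else f"{a}/{b}"
                ad_ref, ad_alt = matrix.ad[i, j]
                cols.append(f"{gt}:{ad_ref},{ad_alt}:{ad_ref + ad_alt}")
            fh.write("\t".join(cols) + "\n")


def read_vcf(path, samples=None) -> dict:
    """Read a VCF into per-chromosome SexedGenotypeMatrix objects.

    ``samples`` (a sexed sample list matching the VCF sample order) attaches
    sex labels; without it all samples default to unlabeled females-first
    ordering and must be relabeled by the caller.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    names = vcf.samples
    if samples is None:
        samples = [SexedSample(n, "F") for n in names]
    else:
        by_id = {s.sample_id: s for s in samples}
        missing = [n for n in names if n not in by_id]
        if missing:
            raise ValueError(f"VCF samples missing from sheet: {missing}")
        samples = [by_id[n] for n in names]

    per_chrom = {}
    for v in vcf:
        gts = v.genotype.array()[:, :2]
        ad = v.format("AD")
        if ad is None:
            ad = np.zeros((len(names), 2), dtype=np.int32)
        else:
            ad = np.where(ad < 0, 0, ad)[:, :2]
        per_chrom.setdefault(v.CHROM, []).append(
            (v.POS - 1, v.REF, tuple(v.ALT), gts, ad, v.QUAL if v.QUAL is not None else np.nan)
        )
    out = {}
    for chrom, rows in per_chrom.items():
        out[chrom] = SexedGenotypeMatrix(
            chrom=chrom,
            positions=np.array([r[0] for r in rows]),
            ref=[r[1] for r in rows],
            alts=[r[2] for r in rows],
            gt=np.array([r[3] for r in rows], dtype=np.int8),
            ad=np.array([r[4] for r in rows], dtype=np.int32),
            qual=np.array([r[5] for r in rows], dtype=float),
            samples=samples,
        )
    return out


# ---------------------------------------------------------------------------
# GFF3 and CDS models


def write_gff3(gene_table: pd.DataFrame, path, force=False, n_exons=1):
    """Minimal GFF3 of the genes present on the W haplotype."""
    path = _check_overwrite(path, force)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in gene_table.itertuples(index=False):
            if hasattr(g, "present_w") and not g.present_w:
                continue
            start1, end1 = g.start + 1, g.end  # 1-based inclusive
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tzwscan\tgene\t{start1}\t{end1}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\tzwscan\tmRNA\t{start1}\t{end1}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\tzwscan\tCDS\t{start1}\t{end1}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id}.cds;Parent={g.gene_id}.t1\n"
            )


def read_gff3(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "source", "type", "start", "end", "score", "strand",
               "phase", "attributes"],
    )
    return df


def _gff_attr(attributes: str, key: str):
    for part in attributes.split(";"):
        k, _, v = part.partition("=")
        if k.strip() == key:
            return v
    return None


def cds_models_from_gff(gff_path, fasta_path):
    """Build spliced CDS models from GFF3 CDS features and a genome FASTA.

    CDS features are grouped by Parent (falling back to ID); exon order is
    genomic and minus-strand models are reverse-complemented.
    """
    from pyfaidx import Fasta

    from .variants import CdsModel

    fasta = Fasta(str(fasta_path))
    df = read_gff3(gff_path)
    cds = df[df["type"] == "CDS"]
    models = []
    grouped = {}
    for r in cds.itertuples(index=False):
        parent = _gff_attr(r.attributes, "Parent") or _gff_attr(r.attributes, "ID")
        grouped.setdefault(parent, []).append(r)
    for parent, feats in grouped.items():
        feats.sort(key=lambda r: r.start)
        chrom = feats[0].chrom
        strand = feats[0].strand
        exons = [(int(r.start) - 1, int(r.end)) for r in feats]  # to 0-based half-open
        seq = "".join(str(fasta[chrom][s:e]) for s, e in exons).upper()
        if strand == "-":
            seq = seq[::-1].translate(str.maketrans("ACGT", "TGCA"))
        gene_id = parent.removesuffix(".t1").removesuffix(".cds")
        models.append(
            CdsModel(gene_id=gene_id, chrom=chrom, strand=strand, exons=exons, seq=seq)
        )
    return models


# ---------------------------------------------------------------------------
# BLAST tabular, FASTA pairs, TSV tables


def read_blast_outfmt6(path, with_qlen=None) -> pd.DataFrame:
    """BLAST -outfmt 6 (optionally with qlen as column 13)."""
    probe = pd.read_csv(path, sep="\t", header=None, nrows=1)
    ncol = probe.shape[1]
    names = list(OUTFMT6_COLUMNS)
    if with_qlen or (with_qlen is None and ncol >= 13):
        names.append("qlen")
    df = pd.read_csv(path, sep="\t", header=None, names=names + list(range(len(names), ncol)))
    return df[names]


def write_ltr_fasta(pairs, path, force=False):
    """Two records per element: <id>_5p and <id>_3p."""
    path = _check_overwrite(path, force)
    with open(path, "w") as fh:
        for element_id, superfamily, _age, seq5, seq3 in pairs:
            fh.write(f">{element_id}_5p superfamily={superfamily}\n{seq5}\n")
            fh.write(f">{element_id}_3p superfamily={superfamily}\n{seq3}\n")


def read_ltr_fasta(path):
    """Pair up <id>_5p / <id>_3p records: yields (id, superfamily, seq5, seq3)."""
    from Bio import SeqIO

    records = {}
    meta = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        base, _, side = rec.id.rpartition("_")
        records.setdefault(base, {})[side] = str(rec.seq)
        fam = "unknown"
        for token in rec.description.split():
            if token.startswith("superfamily="):
                fam = token.split("=", 1)[1]
        meta[base] = fam
    pairs = []
    for base in sorted(records):
        sides = records[base]
        if "5p" in sides and "3p" in sides:
            pairs.append((base, meta[base], sides["5p"], sides["3p"]))
    return pairs


# ---------------------------------------------------------------------------
# config


DEFAULT_CONFIG = {
    "window_size": 10_000,
    "absent_max": 5,
    "max_gap_sites": 0,
    "delta": 0.1,
    "min_run": 5,
    "max_gap_windows": 3,
    "percentile": 0.99,
    "qc_preset": "slr",
    "min_minor_prop": 0.3,
    "mu": 2.5e-9,
    "pseudo_min_identity": 40.0,
    "pseudo_min_length": 30,
    "pseudo_link_gap": 50,
    "pseudo_stack_overlap": 0.80,
    "dup_identity": 80.0,
    "max_pair_distance": 100_000,
    "seed": 0,
}

_CONFIG_CHECKS = {
    "window_size": lambda v: v >= 1,
    "absent_max": lambda v: v >= 0,
    "delta": lambda v: 0 < v <= 0.5,
    "min_run": lambda v: v >= 1,
    "max_gap_windows": lambda v: v >= 0,
    "percentile": lambda v: 0 < v < 1,
    "min_minor_prop": lambda v: 0 <= v < 0.5,
    "mu": lambda v: v > 0,
    "pseudo_stack_overlap": lambda v: 0 < v <= 1,
}


def load_config(path=None, **overrides) -> dict:
    """Merge a YAML config file over the defaults and validate."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    cfg.update({k: v for k, v in overrides.items() if v is not None})
    for key, check in _CONFIG_CHECKS.items():
        if not check(cfg[key]):
            raise ValueError(f"config value {key}={cfg[key]!r} fails validation")
    return cfg


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_bundle(bundle_dir):
    """Reconstruct an in-memory bundle from a simulator output directory.

    Windowed depth tracks are expanded to constant per-base depth, so
    base-resolution presence calling on a reloaded bundle works at window
    granularity unless per-base files (depth_base/) are present.
    """
    from pyfaidx import Fasta

    from .records import LabeledInterval
    from .simulate import SimParams, SimResult, TruthSet

    bundle_dir = Path(bundle_dir)
    with open(bundle_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    p = manifest["params"]
    params = SimParams(**{
        k: (tuple(v) if isinstance(v, list) else v) for k, v in p.items()
    })
    samples, _autosomes = read_sample_sheet(bundle_dir / "samples.tsv")

    chrom_lengths = {"chrW": params.chrom_length, "chrA": params.autosome_length}
    depth = {c: np.zeros((len(samples), L), dtype=np.uint16)
             for c, L in chrom_lengths.items()}
    base_dir = bundle_dir / "depth_base"
    for i, s in enumerate(samples):
        if base_dir.exists():
            df = read_depth_bed(base_dir / f"{s.sample_id}.per-base.bed")
            for chrom in depth:
                sub = df[df["chrom"] == chrom]
                depth[chrom][i, sub["start"].to_numpy()] = sub["depth"].to_numpy()
        else:
            df = read_depth_bed(bundle_dir / "depth" / f"{s.sample_id}.regions.tsv")
            for chrom in depth:
                sub = df[df["chrom"] == chrom]
                for r in sub.itertuples(index=False):
                    depth[chrom][i, int(r.start):int(r.end)] = int(round(r.depth))

    genotypes = read_vcf(bundle_dir / "variants.vcf", samples=samples)

    regions_df = read_bed(bundle_dir / "truth_regions.bed")
    regions = [LabeledInterval(r.name, int(r.start), int(r.end))
               for r in regions_df.itertuples(index=False) if r.name != "SLR"]
    slr = regions_df[regions_df["name"] == "SLR"].iloc[0]
    fs_path = bundle_dir / "truth_female_specific.bed"
    fs_segments = []
    if fs_path.stat().st_size:
        fs_df = read_bed(fs_path)
        fs_segments = [(int(r.start), int(r.end)) for r in fs_df.itertuples(index=False)]
    sexlinked = np.loadtxt(bundle_dir / "truth_sexlinked_sites.tsv", dtype=np.int64, ndmin=1)
    gene_table = pd.read_csv(bundle_dir / "gene_table.tsv", sep="\t")
    ltr_table = pd.read_csv(bundle_dir / "ltr_table.tsv", sep="\t")
    truth = TruthSet(
        regions=regions,
        slr_interval=(int(slr.start), int(slr.end)),
        sexlinked_site_positions=sexlinked,
        female_specific_segments=fs_segments,
        gene_table=gene_table,
        ltr_pair_table=ltr_table,
    )

    age_by_id = dict(zip(ltr_table["element_id"], ltr_table["true_age"]))
    ltr_pairs = [
        (eid, fam, float(age_by_id.get(eid, np.nan)), s5, s3)
        for eid, fam, s5, s3 in read_ltr_fasta(bundle_dir / "ltr_pairs.fasta")
    ]
    duplicate_layout = pd.read_csv(bundle_dir / "duplicates.tsv", sep="\t")
    zw_hits = read_blast_outfmt6(bundle_dir / "zw_hits.tsv")
    pseudo_hits = pd.read_csv(bundle_dir / "pseudo_hits.tsv", sep="\t")

    code = {b: k for k, b in enumerate("ACGT")}
    genome = {}
    fasta = Fasta(str(bundle_dir / "genome.fasta"))
    for chrom in fasta.keys():
        genome[chrom] = np.array(
            [code[b] for b in str(fasta[chrom][:]).upper()], dtype=np.int8
        )

    return SimResult(
        params=params, truth=truth, samples=samples, depth=depth,
        genotypes=genotypes, ltr_pairs=ltr_pairs,
        duplicate_layout=duplicate_layout, genome=genome,
        zw_hits=zw_hits, pseudo_hits=pseudo_hits,
    )


# ---------------------------------------------------------------------------
# simulator bundle


def write_sim_bundle(result, outdir, base_depth=False, force=False):
    """Write every file the downstream stages consume; returns the manifest."""
    from .coverage import windowed_mean_depth

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = result.params
    chrom_lengths = {"chrW": params.chrom_length, "chrA": params.autosome_length}

    write_sample_sheet(result.samples, outdir / "samples.tsv",
                       autosomes=("chrA",), force=force)

    depth_dir = outdir / "depth"
    for i, s in enumerate(result.samples):
        frames = []
        for chrom, L in chrom_lengths.items():
            w = windowed_mean_depth(result.depth[chrom][i], params.window_size)
            starts = np.arange(len(w)) * params.window_size
            frames.append(pd.DataFrame({
                "chrom": chrom, "start": starts,
                "end": np.minimum(starts + params.window_size, L), "depth": w,
            }))
        df = pd.concat(frames, ignore_index=True)
        path = _check_overwrite(depth_dir / f"{s.sample_id}.regions.tsv", force)
        df.to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")

    if base_depth:
        base_dir = outdir / "depth_base"
        for i, s in enumerate(result.samples):
            frames = []
            for chrom, L in chrom_lengths.items():
                d = result.depth[chrom][i]
                frames.append(pd.DataFrame({
                    "chrom": chrom, "start": np.arange(L),
                    "end": np.arange(1, L + 1), "depth": d,
                }))
            df = pd.concat(frames, ignore_index=True)
            path = _check_overwrite(base_dir / f"{s.sample_id}.per-base.bed", force)
            df.to_csv(path, sep="\t", index=False, header=False)

    # one multi-chromosome VCF
    vcf_path = _check_overwrite(outdir / "variants.vcf", force)
    with open(vcf_path, "w") as fh:
        fh.write("")
    tmp_paths = []
    for k, chrom in enumerate(["chrW", "chrA"]):
        p = outdir / f".variants.{chrom}.vcf"
        write_vcf(result.genotypes[chrom], p, force=True,
                  contig_lengths=chrom_lengths if k == 0 else {})
        tmp_paths.append(p)
    with open(vcf_path, "w") as out:
        for k, p in enumerate(tmp_paths):
            with open(p) as fh:
                for line in fh:
                    if k > 0 and line.startswith("#"):
                        continue
                    out.write(line)
            p.unlink()

    truth = result.truth
    write_bed(
        [("chrW", r.start, r.end, r.label) for r in truth.regions]
        + [("chrW", *truth.slr_interval, "SLR")],
        outdir / "truth_regions.bed", force=force,
    )
    write_bed(
        [("chrW", s, e, "female_specific") for s, e in truth.female_specific_segments],
        outdir / "truth_female_specific.bed", force=force,
    )
    np.savetxt(outdir / "truth_sexlinked_sites.tsv",
               truth.sexlinked_site_positions, fmt="%d")

    write_gff3(truth.gene_table, outdir / "genes.gff3", force=force)
    truth.gene_table.to_csv(outdir / "gene_table.tsv", sep="\t", index=False)
    ortholog_cols = ["gene_id"] + [
        c for c in truth.gene_table.columns
        if c.startswith(("S_", "P_"))
    ]
    truth.gene_table[ortholog_cols].to_csv(
        outdir / "orthologs.tsv", sep="\t", index=False
    )

    if result.genome is not None:
        with open(_check_overwrite(outdir / "genome.fasta", force), "w") as fh:
            for chrom in result.genome:
                seq = result.genome_seq(chrom)
                fh.write(f">{chrom}\n")
                for k in range(0, len(seq), 80):
                    fh.write(seq[k:k + 80] + "\n")
    if result.zw_hits is not None:
        result.zw_hits.to_csv(outdir / "zw_hits.tsv", sep="\t",
                              index=False, header=False)
    if result.pseudo_hits is not None:
        result.pseudo_hits.to_csv(outdir / "pseudo_hits.tsv", sep="\t", index=False)

    write_ltr_fasta(result.ltr_pairs, outdir / "ltr_pairs.fasta", force=force)
    truth.ltr_pair_table.to_csv(outdir / "ltr_table.tsv", sep="\t", index=False)
    result.duplicate_layout.to_csv(outdir / "duplicates.tsv", sep="\t", index=False)

    manifest = {
        "seed": params.seed,
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(params).items() if not isinstance(v, dict)},
        "files": {
            str(p.relative_to(outdir)): file_checksum(p)
            for p in sorted(outdir.rglob("*")) if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
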