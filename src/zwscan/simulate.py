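"""Truth-labeled synthetic ZW chromosome generator.

The generator emulates short-read evidence mapped to the W haplotype of a
haplotype-resolved assembly of a female (ZW) individual.  The focal
chromosome ``chrW`` is partitioned into five ordered strata
PAR1 / FS1 / INV / FS2 / PAR2; the sex-linked region (SLR) is
FS1 + INV + FS2.  A second, fully autosomal chromosome ``chrA`` provides the
normalization reference, Hardy-Weinberg sites and null differentiation
windows.

Copy-number model (reads recruited to the W haplotype, per sex):

========== ======== ======== =========================================
stratum    females  males    rationale
========== ======== ======== =========================================
PAR, chrA  2        2        both haplotypes recombine; reads map evenly
FS         1        0.5      diverged stratum: female W reads map
                             uniquely, male Z reads cross-map poorly
FS insert  1        0        W-specific sequence absent from males
INV        1.5      0.9      W-specific but still Z-collinear: female
                             W reads plus half of each sex's Z reads,
                             with slightly reduced male cross-mapping
========== ======== ======== =========================================

Per-base depth is Poisson with rate ``mean_depth * copies / 2``.  Fully
sex-linked diverged sites are emitted all-female-heterozygous and
all-male-homozygous with heterozygote allele depths ~ Binomial(depth, 1/2);
homozygote allele depths carry error reads ~ Binomial(depth, 0.005) so the
conservative 0.3 minor-read-proportion rule is exercised.

All randomness flows from ``SimParams.seed`` through per-channel child
streams (depth, genotypes, insertions, genes, LTRs, duplicates), so adding a
channel never perturbs the others and identical parameters give bit-identical
bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .records import (
    FEMALE,
    MALE,
    LabeledInterval,
    SexedGenotypeMatrix,
    SexedSample,
)

BASES = np.array(list("ACGT"))

REGION_LABELS = ("PAR1", "FS1", "INV", "FS2", "PAR2")

#: (female copies, male copies) per stratum of the W haplotype
DEFAULT_COPY_MODEL = {
    "PAR": (2.0, 2.0),
    "FS": (1.0, 0.5),
    "FS_INS": (1.0, 0.0),
    "INV": (1.5, 0.9),
}

#: superfamilies cycled over simulated LTR elements
LTR_SUPERFAMILIES = ("Copia", "Gypsy", "unknown")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic ZW data set (defaults = study conditions,
    scaled to a 2 Mb chromosome so a full pipeline run takes seconds)."""

    chrom_length: int = 2_000_000
    #: four interior breakpoints: PAR1|FS1|INV|FS2|PAR2
    region_bounds: tuple = (400_000, 750_000, 1_350_000, 1_400_000)
    n_females: int = 10
    n_males: int = 10
    mean_depth: float = 30.0
    window_size: int = 10_000
    #: variant sites per bp (one SNP every 200 bp)
    snp_density: float = 0.005
    #: fraction of FS-stratum variant sites that are fully sex-linked
    prop_sexlinked_sites: float = 0.5
    #: female-specific insertion segments per Mb of FS sequence
    insertion_rate: float = 230.0
    #: mean insertion length (bp, exponential; floor 30 bp)
    insertion_mean_length: float = 150.0
    min_insertion_length: int = 30
    gene_density: float = 80.0  # genes per Mb
    w_deletion_prob: float = 0.26  # SLR genes lost from W
    z_deletion_prob: float = 0.19  # SLR genes lost from Z
    ltr_ages: tuple = (
        2e5, 5e5, 8e5, 1e6, 1.2e6, 1.5e6, 2e6, 2.5e6,
        3e6, 4e6, 5e6, 6e6, 8e6, 1e7, 1.2e7, 1.46e7,
    )
    ltr_length: int = 1_000
    mu: float = 2.5e-9  # substitutions / site / generation
    autosome_length: int = 1_000_000
    error_rate: float = 0.005  # homozygote allele-depth noise
    copy_model: dict = field(default_factory=lambda: dict(DEFAULT_COPY_MODEL))
    seed: int = 0

    def __post_init__(self):
        b = self.region_bounds
        if len(b) != 4 or list(b) != sorted(b) or len(set(b)) != 4:
            raise ConfigurationError("region_bounds must be 4 strictly increasing breakpoints")
        if not (0 < b[0] and b[-1] < self.chrom_length):
            raise ConfigurationError("region_bounds must lie strictly inside (0, chrom_length)")
        if self.n_females < 1 or self.n_males < 1:
            raise ConfigurationError("need at least one sample of each sex")
        if self.mean_depth <= 0:
            raise ConfigurationError("mean_depth must be > 0")
        for name in ("prop_sexlinked_sites", "w_deletion_prob", "z_deletion_prob", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if any(a < 0 for a in self.ltr_ages):
            raise ConfigurationError("LTR ages must be >= 0")

    @property
    def regions(self) -> list:
        """The five ordered strata of chrW as labeled intervals."""
        b = (0, *self.region_bounds, self.chrom_length)
        return [LabeledInterval(lab, b[i], b[i + 1]) for i, lab in enumerate(REGION_LABELS)]

    @property
    def slr_interval(self) -> tuple:
        return (self.region_bounds[0], self.region_bounds[3])


@dataclass
class TruthSet:
    """Ground truth labels attached to one simulated data set."""

    regions: list  # five LabeledIntervals on chrW
    slr_interval: tuple
    sexlinked_site_positions: np.ndarray  # 0-based, chrW
    female_specific_segments: list  # [(start, end)], chrW
    gene_table: "object"  # pandas DataFrame
    ltr_pair_table: "object"  # pandas DataFrame

    @property
    def fs1(self):
        return next(r for r in self.regions if r.label == "FS1")

    @property
    def fs2(self):
        return next(r for r in self.regions if r.label == "FS2")

    @property
    def inv(self):
        return next(r for r in self.regions if r.label == "INV")


@dataclass
class SimResult:
    """In-memory synthetic data bundle plus its truth labels."""

    params: SimParams
    truth: TruthSet
    samples: list  # SexedSample, females first
    depth: dict  # chrom -> (n_samples, L) uint16 per-base depth
    genotypes: dict  # chrom -> SexedGenotypeMatrix
    ltr_pairs: list  # [(element_id, superfamily, age, seq5, seq3)]
    duplicate_layout: "object"  # pandas DataFrame
    genome: dict = None  # chrom -> int8 base codes (index into ACGT)
    zw_hits: "object" = None  # outfmt-6 DataFrame, W genes vs Z haplotype
    pseudo_hits: "object" = None  # degraded-protein hit DataFrame

    def genome_seq(self, chrom: str) -> str:
        return "".join(BASES[self.genome[chrom]])

    @property
    def is_female(self) -> np.ndarray:
        return np.array([s.sex == FEMALE for s in self.samples], dtype=bool)

    def write_bundle(self, outdir, base_depth: bool = False):
        from . import io as zio

        return zio.write_sim_bundle(self, outdir, base_depth=base_depth)


def _child_rngs(seed: int, names):
    """One independent Generator per output channel, split from the master seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _copy_arrays(params: SimParams, insertions) -> tuple:
    """Per-base expected copy numbers on chrW for females and males."""
    L = params.chrom_length
    cf = np.full(L, params.copy_model["PAR"][0], dtype=np.float32)
    cm = np.full(L, params.copy_model["PAR"][1], dtype=np.float32)
    for region in params.regions:
        key = {"FS1": "FS", "FS2": "FS", "INV": "INV"}.get(region.label)
        if key is None:
            continue
        cf[region.start:region.end] = params.copy_model[key][0]
        cm[region.start:region.end] = params.copy_model[key][1]
    for start, end in insertions:
        cf[start:end] = params.copy_model["FS_INS"][0]
        cm[start:end] = params.copy_model["FS_INS"][1]
    return cf, cm


def _draw_insertions(params: SimParams, rng) -> list:
    """Female-specific (W-only) segments inside FS1 and FS2, non-overlapping."""
    segments = []
    for region in params.regions:
        if region.label not in ("FS1", "FS2"):
            continue
        n = rng.poisson(params.insertion_rate * region.length / 1e6)
        if n == 0:
            continue
        starts = np.sort(rng.integers(region.start, region.end, size=n))
        lengths = np.maximum(
            rng.exponential(params.insertion_mean_length, size=n).astype(np.int64),
            params.min_insertion_length,
        )
        last_end = -1
        for s, ln in zip(starts, lengths):
            e = min(int(s + ln), region.end)
            if s >= e or s <= last_end:
                continue
            segments.append((int(s), e))
            last_end = e
    return segments


def _simulate_depth(params: SimParams, rng, insertions) -> dict:
    n = params.n_females + params.n_males
    cf, cm = _copy_arrays(params, insertions)
    lam = params.mean_depth / 2.0
    depth_w = np.empty((n, params.chrom_length), dtype=np.uint16)
    for i in range(n):
        copies = cf if i < params.n_females else cm
        depth_w[i] = rng.poisson(lam * copies).astype(np.uint16)
    depth_a = rng.poisson(
        params.mean_depth, size=(n, params.autosome_length)
    ).astype(np.uint16)
    return {"chrW": depth_w, "chrA": depth_a}


def _het_ad(rng, depth):
    """Allele depths for heterozygotes: REF reads ~ Binomial(depth, 1/2)."""
    ref = rng.binomial(depth, 0.5)
    return ref, depth - ref


def _hom_ad(rng, depth, error_rate):
    """Allele depths for homozygotes: minor error reads ~ Binomial(depth, err)."""
    err = rng.binomial(depth, error_rate)
    return depth - err, err


def _simulate_sites_chrA(params, rng, samples):
    """Hardy-Weinberg sites on the autosome, ALT frequency ~ Beta(0.8, 0.8)
    truncated to (0.05, 0.95)."""
    L = params.autosome_length
    n_sites = int(round(params.snp_density * L))
    n = len(samples)
    positions = np.sort(rng.choice(L, size=n_sites, replace=False))
    q = rng.beta(0.8, 0.8, size=n_sites)
    q = 0.05 + 0.9 * q  # keep sites informative, avoid quasi-fixed draws
    alt_counts = rng.binomial(2, q[:, None], size=(n_sites, n))
    return positions, q, alt_counts


def _fill_ad(rng, gt, depth, error_rate):
    """AD arrays from genotypes (alt-allele dosage matrix) and site depths."""
    n_sites, n = gt.shape
    ad = np.zeros((n_sites, n, 2), dtype=np.int32)
    het = gt == 1
    ref_h, alt_h = _het_ad(rng, np.where(het, depth, 0))
    major, minor = _hom_ad(rng, np.where(~het, depth, 0), error_rate)
    hom_alt = gt == 2
    ad[..., 0] = np.where(het, ref_h, np.where(hom_alt, minor, major))
    ad[..., 1] = np.where(het, alt_h, np.where(hom_alt, major, minor))
    return ad


def _simulate_genome(params: SimParams, rng) -> dict:
    """Random base composition for both chromosomes (integer-coded ACGT)."""
    return {
        "chrW": rng.integers(0, 4, size=params.chrom_length, dtype=np.int8),
        "chrA": rng.integers(0, 4, size=params.autosome_length, dtype=np.int8),
    }


def _simulate_genotypes(params: SimParams, rng, samples, genome) -> dict:
    """Variant sites on chrW and chrA as SexedGenotypeMatrix objects.

    chrW FS sites are fully sex-linked (all females heterozygous W/Z, all
    males homozygous Z) with probability ``prop_sexlinked_sites``; remaining
    FS and INV sites carry a Z polymorphism (females hemizygous Z plus an
    invariant W allele, diploid-coded); PAR sites follow Hardy-Weinberg.
    """
    n = len(samples)
    n_f = params.n_females
    genotypes = {}
    truth_sexlinked = None

    # --- chrW ---
    L = params.chrom_length
    n_sites = int(round(params.snp_density * L))
    positions = np.sort(rng.choice(L, size=n_sites, replace=False))
    region_starts = np.array([r.start for r in params.regions])
    region_idx = np.searchsorted(region_starts, positions, side="right") - 1
    labels = np.array(REGION_LABELS)[region_idx]
    in_fs = np.isin(labels, ("FS1", "FS2"))
    in_inv = labels == "INV"

    sexlinked = in_fs & (rng.random(n_sites) < params.prop_sexlinked_sites)
    gt = np.zeros((n_sites, n), dtype=np.int8)  # alt-allele dosage

    # PAR sites: Hardy-Weinberg
    par = ~(in_fs | in_inv)
    q_par = 0.05 + 0.9 * rng.beta(0.8, 0.8, size=n_sites)
    gt[par] = rng.binomial(2, q_par[par, None], size=(int(par.sum()), n))

    # shared (non-sex-linked) FS / INV sites: Z polymorphism, W carries REF
    shared = (in_fs | in_inv) & ~sexlinked
    qz = rng.uniform(0.05, 0.5, size=n_sites)
    z_f = rng.binomial(1, qz[:, None], size=(n_sites, n_f))  # one Z per female
    z_m = rng.binomial(2, qz[:, None], size=(n_sites, n - n_f))
    gt[shared, :n_f] = z_f[shared]
    gt[shared, n_f:] = z_m[shared]

    # fully sex-linked diverged sites: ALT = W allele
    gt[sexlinked, :n_f] = 1
    gt[sexlinked, n_f:] = 0

    depth = rng.poisson(params.mean_depth, size=(n_sites, n))
    ad = _fill_ad(rng, gt, depth, params.error_rate)

    ref_idx = genome["chrW"][positions]
    alt_shift = rng.integers(1, 4, size=n_sites)
    ref = BASES[ref_idx]
    alt = BASES[(ref_idx + alt_shift) % 4]

    gt_pairs = np.stack([(gt > 1).astype(np.int8), (gt > 0).astype(np.int8)], axis=2)
    genotypes["chrW"] = SexedGenotypeMatrix(
        chrom="chrW",
        positions=positions,
        ref=list(ref),
        alts=[(a,) for a in alt],
        gt=gt_pairs,
        ad=ad,
        qual=np.full(n_sites, 60.0),
        samples=samples,
    )
    truth_sexlinked = positions[sexlinked]

    # --- chrA ---
    pos_a, _q, alt_counts = _simulate_sites_chrA(params, rng, samples)
    depth_a = rng.poisson(params.mean_depth, size=alt_counts.shape)
    ad_a = _fill_ad(rng, alt_counts, depth_a, params.error_rate)
    ref_idx = genome["chrA"][pos_a]
    alt_shift = rng.integers(1, 4, size=len(pos_a))
    gt_pairs_a = np.stack(
        [(alt_counts > 1).astype(np.int8), (alt_counts > 0).astype(np.int8)], axis=2
    )
    genotypes["chrA"] = SexedGenotypeMatrix(
        chrom="chrA",
        positions=pos_a,
        ref=list(BASES[ref_idx]),
        alts=[(a,) for a in BASES[(ref_idx + alt_shift) % 4]],
        gt=gt_pairs_a,
        ad=ad_a,
        qual=np.full(len(pos_a), 60.0),
        samples=samples,
    )
    return genotypes, truth_sexlinked


def _simulate_genes(params: SimParams, rng):
    """Non-overlapping gene models with haplotype presence and a per-species
    ortholog presence vector over the three reference clades."""
    import pandas as pd

    species = [
        ("clade1", "S_purpurea"),
        ("clade1", "S_suchowensis"),
        ("clade2", "S_arbutifolia"),
        ("clade2", "S_dunnii"),
        ("clade3", "P_qiongdaoensis"),
        ("clade3", "P_trichocarpa"),
    ]
    L = params.chrom_length
    n_genes = int(round(params.gene_density * L / 1e6))
    slr_start, slr_end = params.slr_interval
    # evenly spaced starts with jitter keep genes non-overlapping
    pitch = L // max(n_genes, 1)
    rows = []
    for i in range(n_genes):
        start = i * pitch + int(rng.integers(0, max(pitch // 4, 1)))
        hi = max(400, min(3000, pitch - 10))
        glen = int(rng.integers(min(300, hi - 1), hi))
        glen = min(glen, L - 1 - start)
        glen -= glen % 3  # keep emitted CDS models in frame
        end = start + glen
        strand = "+" if rng.random() < 0.5 else "-"
        in_slr = slr_start <= start < slr_end
        u = rng.random()
        if u < 0.70:
            cls = "conserved"
        elif u < 0.88:
            cls = "ancestral"
        else:
            cls = "species_specific"
        presence = {}
        if cls == "species_specific":
            for _clade, sp in species:
                presence[sp] = False
        else:
            while True:
                for _clade, sp in species:
                    presence[sp] = bool(rng.random() < 0.7)
                per_clade = {}
                for clade, sp in species:
                    per_clade[clade] = per_clade.get(clade, False) or presence[sp]
                n_clades = sum(per_clade.values())
                if cls == "conserved" and n_clades == 3:
                    break
                if cls == "ancestral" and 1 <= n_clades <= 2:
                    break
        present_w = True
        present_z = True
        if in_slr:
            present_w = rng.random() >= params.w_deletion_prob
            present_z = rng.random() >= params.z_deletion_prob
        rows.append(
            dict(
                gene_id=f"g{i + 1:05d}",
                chrom="chrW",
                start=start,
                end=end,
                strand=strand,
                in_slr=in_slr,
                conservation=cls,
                present_w=present_w,
                present_z=present_z,
                **presence,
            )
        )
    return pd.DataFrame(rows)


def simulate_ltr_pair(age: float, mu: float, ltr_length: int, rng=None, seed=None):
    """One LTR element: a random ancestral repeat and its two descendant
    copies after ``age`` generations of independent substitution.

    Substitution events per copy ~ Poisson(mu * age * length), placed
    uniformly; each event replaces the base by one of the three others, so
    the expected raw 5'-3' divergence is 2 * mu * age before correction.
    """
    if age < 0:
        raise ConfigurationError("age must be >= 0")
    if ltr_length <= 0:
        raise ConfigurationError("ltr_length must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    ancestral = rng.integers(0, 4, size=ltr_length)
    copies = []
    for _ in range(2):
        seq = ancestral.copy()
        n_sub = rng.poisson(mu * age * ltr_length)
        if n_sub:
            sites = rng.integers(0, ltr_length, size=n_sub)
            shifts = rng.integers(1, 4, size=n_sub)
            seq[sites] = (seq[sites] + shifts) % 4
        copies.append("".join(BASES[seq]))
    return copies[0], copies[1], age


def _simulate_ltrs(params: SimParams, rng):
    import pandas as pd

    slr_start, slr_end = params.slr_interval
    pairs = []
    rows = []
    n = len(params.ltr_ages)
    for i, age in enumerate(params.ltr_ages):
        elem = f"LTR{i + 1:03d}"
        fam = LTR_SUPERFAMILIES[i % len(LTR_SUPERFAMILIES)]
        seq5, seq3, _ = simulate_ltr_pair(age, params.mu, params.ltr_length, rng=rng)
        start = slr_start + int((slr_end - slr_start) * (i + 0.5) / n)
        rows.append(
            dict(
                element_id=elem,
                chrom="chrW",
                start=start,
                end=start + 2 * params.ltr_length + 4000,
                superfamily=fam,
                true_age=float(age),
            )
        )
        pairs.append((elem, fam, float(age), seq5, seq3))
    return pairs, pd.DataFrame(rows)


def _simulate_duplicates(params: SimParams, rng):
    """Exon-level hit layout of partial duplicates of a floral-identity gene:
    seven adjacent opposite-strand first-exon doublets (hairpin candidates)
    split between FS1 and FS2, plus two isolated same-strand partial copies
    and one complete five-exon copy outside the SLR."""
    import pandas as pd

    fs1_start = params.region_bounds[0]
    fs2_start = params.region_bounds[2]
    rows = []
    copy_i = 0

    def add_copy(start, strand, exons):
        nonlocal copy_i
        copy_i += 1
        locus = f"dup{copy_i:02d}"
        pos = start
        for exon in exons:
            ident = float(np.round(85 + 10 * rng.random(), 1))
            rows.append(
                dict(
                    chrom="chrW",
                    start=pos,
                    end=pos + 180,
                    strand=strand,
                    locus=locus,
                    exon_id=f"exon{exon}",
                    identity=ident,
                )
            )
            pos += 400

    # 5 doublets in FS1, 2 in FS2; partners ~2 kb apart, doublets >=30 kb apart
    for k in range(5):
        base = fs1_start + 20_000 + k * 60_000
        add_copy(base, "+", [1])
        add_copy(base + 2_000, "-", [1])
    for k in range(2):
        base = fs2_start + 5_000 + k * 20_000
        add_copy(base, "+", [1])
        add_copy(base + 2_000, "-", [1])
    # two isolated same-strand partial copies deep in the inversion
    add_copy(params.region_bounds[1] + 100_000, "+", [1])
    add_copy(params.region_bounds[1] + 350_000, "+", [1])
    # one complete copy in PAR2 (all five exons)
    add_copy(params.region_bounds[3] + 50_000, "+", [1, 2, 3, 4, 5])
    return pd.DataFrame(rows)


def _simulate_homology(params: SimParams, gene_table, rng):
    """Cross-haplotype homology hits and a degraded-protein (pseudogene
    search) hit table consistent with the gene truth labels.

    Genes present on both haplotypes get a strict-passing W-vs-Z hit;
    W-specific genes get either no hit or a weak one below the soft rule.
    The pseudogene table places chained fragments of lost genes' proteins in
    the female-specific strata, with occasional overlapping second proteins.
    """
    import pandas as pd

    zw_rows = []
    pseudo_rows = []
    for g in gene_table.itertuples(index=False):
        qlen = g.end - g.start
        if not g.present_w:
            # residue of the lost W copy: 1-3 chained fragments of the protein
            n_frag = int(rng.integers(1, 4))
            pos = int(g.start)
            for _ in range(n_frag):
                flen = int(rng.integers(90, 240))
                pseudo_rows.append(
                    dict(chrom="chrW", protein=f"{g.gene_id}_prot",
                         start=pos, end=pos + flen,
                         pident=float(np.round(rng.uniform(42, 70), 1)),
                         length=flen // 3)
                )
                pos += flen + int(rng.integers(0, 45))
            if rng.random() < 0.3:  # stacked second protein on the same spot
                pseudo_rows.append(
                    dict(chrom="chrW", protein=f"{g.gene_id}_prot2",
                         start=int(g.start), end=int(g.start) + 200,
                         pident=float(np.round(rng.uniform(42, 70), 1)),
                         length=66)
                )
            continue
        if g.present_z:
            zw_rows.append(
                dict(qseqid=g.gene_id, sseqid=f"{g.gene_id}_Z",
                     pident=float(np.round(rng.uniform(82, 99), 1)),
                     length=int(qlen * rng.uniform(0.75, 0.98)),
                     mismatch=0, gapopen=0, qstart=1, qend=qlen,
                     sstart=1, send=qlen,
                     evalue=1e-50, bitscore=float(np.round(qlen * 1.8, 1)),
                     qlen=qlen)
            )
        elif rng.random() < 0.5:
            # W gene whose Z partner is lost: at most a weak spurious hit
            zw_rows.append(
                dict(qseqid=g.gene_id, sseqid=f"bg{int(rng.integers(1, 999)):03d}",
                     pident=float(np.round(rng.uniform(35, 55), 1)),
                     length=int(qlen * rng.uniform(0.1, 0.4)),
                     mismatch=0, gapopen=0, qstart=1, qend=qlen // 3,
                     sstart=1, send=qlen // 3,
                     evalue=1e-3, bitscore=50.0, qlen=qlen)
            )
    from .io import OUTFMT6_COLUMNS

    zw = pd.DataFrame(zw_rows, columns=OUTFMT6_COLUMNS + ["qlen"])
    pseudo = pd.DataFrame(
        pseudo_rows, columns=["chrom", "protein", "start", "end", "pident", "length"]
    )
    return zw, pseudo


def make_samples(n_females: int, n_males: int):
    females = [SexedSample(f"F{i + 1:02d}", FEMALE) for i in range(n_females)]
    males = [SexedSample(f"M{i + 1:02d}", MALE) for i in range(n_males)]
    return females + males


def simulate(params: SimParams) -> SimResult:
    """Generate the full truth-labeled bundle for one parameter set."""
    rngs = _child_rngs(
        params.seed,
        ["insertions", "depth", "genotypes", "genes", "ltr", "dup", "genome", "homology"],
    )
    samples = make_samples(params.n_females, params.n_males)

    insertions = (
        _draw_insertions(params, rngs["insertions"]) if params.insertion_rate > 0 else []
    )
    depth = _simulate_depth(params, rngs["depth"], insertions)
    genome = _simulate_genome(params, rngs["genome"])
    genotypes, sexlinked_positions = _simulate_genotypes(
        params, rngs["genotypes"], samples, genome
    )
    gene_table = _simulate_genes(params, rngs["genes"])
    ltr_pairs, ltr_table = _simulate_ltrs(params, rngs["ltr"])
    duplicate_layout = _simulate_duplicates(params, rngs["dup"])
    zw_hits, pseudo_hits = _simulate_homology(params, gene_table, rngs["homology"])

    truth = TruthSet(
        regions=params.regions,
        slr_interval=params.slr_interval,
        sexlinked_site_positions=sexlinked_positions,
        female_specific_segments=insertions,
        gene_table=gene_table,
        ltr_pair_table=ltr_table,
    )
    return SimResult(
        params=params,
        truth=truth,
        samples=samples,
        depth=depth,
        genotypes=genotypes,
        ltr_pairs=ltr_pairs,
        duplicate_layout=duplicate_layout,
        genome=genome,
        zw_hits=zw_hits,
        pseudo_hits=pseudo_hits,
    )
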