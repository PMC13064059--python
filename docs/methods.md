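# Methods

## Scope and model

`zwscan` treats SLR discovery as a read-evidence problem on the W haplotype
of a haplotype-resolved assembly of a ZW female. All statistics are
computed from three inputs an upstream alignment/calling stack provides:
per-sample depth tracks, a multi-sample VCF with genotypes and allele
depths (GT + AD), and annotation/hit tables. Assembly, mapping, variant
calling, structural-variant and ortholog inference are out of scope; their
outputs (notably the inversion interval and homology hit tables) are
inputs.

Internally all coordinates are 0-based half-open; VCF (1-based) and GFF3
(1-based inclusive) are converted only at the I/O boundary.

## Evidence tracks

**Depth fraction.** Each sample's windowed depth is normalized by its mean
depth over autosome-labelled chromosomes (falling back to all windows when
no labels exist; the per-sample mean is the natural scale-free reference
and makes pools and individuals flow through identical code). The statistic
is F/(F+M) of the sex-mean normalized depths; windows with zero depth in
both sexes are missing rather than 0/0.

**Weir–Cockerham FST.** Per-site variance components a (between sexes), b
(between individuals within sex) and c (within individuals) follow the
1984 two-level estimator with r = 2 groups; genotypes are used as emitted
by a diploid caller, with no ploidy correction for the hemizygous W. The
windowed value is the weighted ratio of sums Σa/Σ(a+b+c); sites with
non-positive total variance are excluded from the sums, not clamped, and
negative window values are reported as computed. The genome-wide threshold
is the nearest-rank 99th percentile (reproducible on small window counts);
windows strictly above it are flagged.

**Heterozygosity ratio.** Per-individual windowed heterozygous-site
proportions are averaged within each sex; the ratio is reported as log₂ so
a twofold female excess maps to +1. Windows with female heterozygosity but
none in males carry a FEMALE_ONLY flag instead of a number (and
symmetrically MALE_ONLY); empty windows are missing and excluded from sex
averages.

**Sex-specific sites.** A site is absent in a sample at ≤ 5 reads
(inclusive — the default models the lowest quintile of a 30× depth
distribution; a per-sample percentile mode is available) and "properly
mapped" is operationalized purely through this depth threshold.
Female-specific sites must be present in all females and absent in all
males; the male-specific rule is symmetric, so the two sets are disjoint by
construction. Merging uses an inter-site gap rule with default
`max_gap = 0`, meaning only adjacent bases join a region; the reported
total is the count of specific bases, not the region spans.

## SLR calling and partition

Windows with |F/(F+M) − 0.5| ≥ δ (default 0.1) seed the call; runs of at
least 5 seed windows merge across gaps of at most 3 windows and the
largest merged run is the SLR. Boundaries snap outward over adjacent
windows containing sex-specific sites, letting base-resolution evidence
extend a window-resolution call. FST flags, FEMALE_ONLY windows and
sex-specific site counts inside the call are reported as supporting
evidence but do not drive the call, keeping the procedure monotone in δ.

The five-way partition takes the inversion interval as an external input.
FS1 spans from the SLR start to the inversion start whenever sex-specific
clusters precede the inversion. FS2 opens at the first cluster reaching
the inversion end — female-specific evidence takes precedence over the
inversion label where they overlap, keeping labels disjoint — or at the
inversion end itself when the SLR extends beyond it; the SLR 3′ edge is
max(cluster end, inversion end). With no inversion supplied the partition
degenerates to PAR1/SLR/PAR2.

## Sex variants and degeneration

Fixed female-specific SNPs require biallelic SNP sites where every female
is heterozygous and every male homozygous for one of the two female
alleles, after the hard QC preset (MAF strictly > 0.1, per-genotype depth
in [10, 100], no missing calls). To guard against collapsed duplications a
heterozygote must show a minor-allele read proportion strictly greater
than 0.3; a male is homozygous when its minor proportion is ≤ 0.3
(read-support on males is not additionally required). Multi-allelic sites
are skipped, not decomposed.

Coding effects are classified on the standard nuclear code as nonsense
(new stop), synonymous (same residue) or missense (everything else;
stop-loss and start-codon loss fold into missense since only three bins
are reported). Variants hitting overlapping CDSs are classified once per
gene. Region summaries report per-class counts and proportions; regions
without coding variants are missing rather than zero.

## Gene evolution

Homology thresholds are strict = (e ≤ 1e-10, identity > 80,
alignment/query > 0.70) and soft = (1e-5, 60, 0.50); the e-value bounds are
read as upper bounds (a larger e-value cannot be the stricter rule).
Coverage uses the query length in the units of the hit table and the best
single HSP decides — HSPs are not summed. Conservation classes over the
six reference species require one species per clade (conserved) or one
species anywhere (ancestral; conserved ⊂ ancestral). Gene loss is
1 − n_present/n_joint, reported at two decimals with half-up rounding for
parity with printed tables.

The pseudogene pipeline removes hits strictly below 40 % identity or 30
aligned residues, links same-protein hits within 50 bp (inclusive) and
stacks chains at ≥ 80 % overlap of the shorter interval with
single-linkage (union-find) merging, so one locus can list several matched
proteins. Ks summaries report per-region medians (mean-of-middle-two for
even counts); display caps do not exclude values from medians.

Duplicate copies are complete when every query exon exceeds 80 % identity
and partial when only the first exon does. Inverted pairing greedily
matches opposite-strand copies by midpoint distance, closest first, within
100 kb; each copy joins at most one pair and copies are conserved
(2·pairs + unpaired = input).

## LTR dating

Divergence between a retroelement's two LTRs is the p-distance over
ungapped aligned columns, Jukes–Cantor corrected
(K = −¾ ln(1 − 4p/3)); both raw and corrected values are emitted since the
upstream convention varies, and elements with p ≥ 0.75 are flagged and
excluded from dating. Insertion age is T = K/(2μ) with
μ = 2.5 × 10⁻⁹ substitutions·site⁻¹·generation⁻¹ by default. Unaligned
pairs are globally aligned with fixed scoring (match +1, mismatch −1, gap
open −5, extend −1) so results are deterministic.

## Synthetic data generator

The generator emulates short reads of 10 females and 10 males mapped to
the W haplotype plus one fully autosomal reference chromosome, at a
default scale of 2 Mb (breakpoints PAR1 0–0.4, FS1 0.4–0.75, INV
0.75–1.35, FS2 1.35–1.40, PAR2 1.40–2.0 Mb) so a full run takes seconds;
larger scales are a parameter choice. Expected copy numbers recruited to
the W haplotype are PAR 2/2 (F/M), FS strata 1/0.5 (female W reads map
uniquely, male Z reads cross-map poorly), female-specific insertion
segments 1/0, and the inversion 1.5/0.9 (W-specific but still Z-collinear,
so both sexes' Z reads cross-map, males at slightly reduced efficiency).
These give expected depth fractions of 0.50, 0.67, 1.0 and 0.625 —
the whole SLR carries a coverage signal, as observed when mapping against
a haplotype-resolved W. Per-base depth is Poisson(λ·copies/2) at λ = 30.

Variant sites (1 per 200 bp) are Hardy–Weinberg on autosomal/PAR sequence
with allele frequencies from a Beta(0.8, 0.8) rescaled into (0.05, 0.95);
half of FS-stratum sites are fully sex-linked (all females heterozygous
W/Z, all males homozygous Z — the fraction of fixed-diverged sites is a
free parameter); remaining FS/INV sites carry a Z polymorphism with the W
allele invariant, at minor frequencies in (0.05, 0.5) so a fixed Z variant
cannot masquerade as a sex-linked site. Heterozygote allele depths are
Binomial(depth, ½); homozygotes carry error reads Binomial(depth, 0.005)
to exercise the 0.3 minor-read rule. Female-specific insertions arrive at
230 segments/Mb of FS sequence with exponential lengths (mean 150 bp,
floor 30 bp), mimicking many short W-specific INDELs. Gene models (80/Mb)
receive conservation classes and clade presence vectors consistent with
them; SLR genes are deleted from W with probability 0.26 and from Z with
0.19. LTR pairs evolve by Poisson substitution on each copy (expected raw
divergence 2μT). The partial-duplicate layout encodes seven opposite-strand
first-exon doublets in FS1/FS2, two isolated same-strand copies and one
complete copy outside the SLR. One independent random stream per output
channel is split from the master seed, so adding a channel never perturbs
existing channels and a seed fully determines the byte-level bundle.

**What the generator does not model:** read-level artifacts (no FASTQ,
mapping quality or duplicate reads), linkage disequilibrium and
recombination maps, repeat-driven mismapping beyond the flat allele-depth
error, overlapping genes and introns (single-exon CDS models), and
population structure. Passing recovery tests therefore demonstrates
correctness of the statistical machinery under the stated generative
model, not robustness to alignment pathology in real data.

## Numerical and reporting choices

Missing values propagate as NaN with explicit flags; percentiles are
nearest-rank; report rounding is half-up (two decimals for loss, whole
percent for shares). The allele-depth zygosity rule is strict at its
boundary (a 6/20 minor read split is not heterozygous); QC depth bounds
are inclusive ([10, 100] keeps DP = 100), matching the conventions of the
common VCF filtering tools, while MAF filtering is strictly greater
than 0.1. Monomorphic sites return an exclusion sentinel rather than a
θ of 0.

A note on fixed-SNP sensitivity: with heterozygote allele depths
Binomial(D, ½) at mean depth 30, a single female fails the strict 0.3
minor-proportion rule with probability ≈ 0.033, so the probability that a
truly sex-linked site passes in all ten females is ≈ 0.97¹⁰ ≈ 0.71. The
recovery experiments report this sensitivity as computed; per-site recall
near 0.95 would require roughly 55–60× depth under this rule. The rule
buys specificity — recovered sets show zero false discoveries in the
seeded experiments — at a quantifiable cost in sensitivity.

## Problem sizes used in tests

The shared test fixture is the default 2 Mb chromosome; file-heavy and
base-resolution tests use a 200 kb variant, Hardy–Weinberg checks use
10,000 autosomal sites, and LTR recovery uses 1,000 replicate 5 kb pairs
at a truth age of 2 × 10⁶ generations. These sizes were chosen so the
statistical assertions have narrow sampling error while a full suite run
stays interactive.
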