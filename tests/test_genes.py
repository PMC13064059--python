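"""Homology classes, conservation, gene loss, the pseudogene pipeline, Ks
summaries and inverted-duplicate pairing."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from zwscan import genes
from zwscan.genes import (
    AMBIGUOUS,
    ANCESTRAL,
    COMPLETE,
    CONSERVED,
    HAPLOTYPE_SPECIFIC,
    OTHER,
    PARTIAL_FIRST_EXON,
    SPECIES_SPECIFIC,
    ZW_HOMOLOG,
    PseudoChain,
    classify_conservation,
    classify_copies,
    classify_zw,
    gene_loss,
    pair_inverted,
    pseudo_filter,
    pseudo_link,
    pseudo_stack,
    summarize_ks,
)


def _hit(qseqid="g1", pident=85.0, length=750, evalue=1e-30, qlen=1000, bitscore=500.0):
    return dict(qseqid=qseqid, sseqid="s1", pident=pident, length=length,
                mismatch=0, gapopen=0, qstart=1, qend=length, sstart=1,
                send=length, evalue=evalue, bitscore=bitscore, qlen=qlen)


class TestClassifyZw:
    @pytest.mark.parametrize(
        "pident, length, evalue, expected",
        [
            (85.0, 750, 1e-30, ZW_HOMOLOG),  # passes strict
            (55.0, 450, 1e-30, HAPLOTYPE_SPECIFIC),  # fails soft identity
            (70.0, 600, 1e-8, AMBIGUOUS),  # soft only
        ],
    )
    def test_threshold_rules(self, pident, length, evalue, expected):
        df = pd.DataFrame([_hit(pident=pident, length=length, evalue=evalue)])
        out = classify_zw(df)
        assert out.iloc[0]["zw_class"] == expected

    def test_boundaries_are_strict(self):
        # identity exactly 80 and coverage exactly 0.70 fail the strict rule
        df = pd.DataFrame([_hit(pident=80.0, length=700, evalue=1e-30)])
        assert classify_zw(df).iloc[0]["zw_class"] == AMBIGUOUS

    def test_best_single_hsp_decides(self):
        # two HSPs covering 60% each: summed they would pass the strict
        # 70% coverage rule, but the best single HSP only passes the soft one
        df = pd.DataFrame([
            _hit(pident=90.0, length=600, evalue=1e-30),
            _hit(pident=90.0, length=600, evalue=1e-30),
        ])
        assert classify_zw(df).iloc[0]["zw_class"] == AMBIGUOUS


class TestConservation:
    def test_one_species_per_clade_is_conserved(self):
        assert classify_conservation(
            dict(S_purpurea=True, S_suchowensis=False, S_arbutifolia=False,
                 S_dunnii=True, P_qiongdaoensis=False, P_trichocarpa=True)
        ) == CONSERVED

    def test_single_species_is_ancestral(self):
        assert classify_conservation([False, False, False, True, False, False]) == ANCESTRAL

    def test_absent_everywhere_is_species_specific(self):
        assert classify_conservation([False] * 6) == SPECIES_SPECIFIC

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            classify_conservation([True] * 5)

    @given(st.lists(st.booleans(), min_size=6, max_size=6))
    def test_conserved_subset_of_ancestral(self, vec):
        cls = classify_conservation(vec)
        if cls == CONSERVED:
            assert any(vec)  # the ancestral condition holds too
        if not any(vec):
            assert cls == SPECIES_SPECIFIC


class TestGeneLoss:
    @pytest.mark.parametrize(
        "present, joint, expected",
        [(925, 1091, 0.15), (209, 272, 0.23), (1145, 1404, 0.18),
         (1026, 1091, 0.06), (1250, 1404, 0.11), (350, 476, 0.26),
         (387, 476, 0.19), (100, 100, 0.0)],
    )
    def test_two_decimal_report(self, present, joint, expected):
        assert gene_loss(present, joint).loss_2dp == pytest.approx(expected)

    def test_monotone_and_extremes(self):
        losses = [gene_loss(n, 50).loss for n in range(0, 51)]
        assert losses == sorted(losses, reverse=True)
        assert gene_loss(0, 50).loss == 1.0
        assert gene_loss(50, 50).loss == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gene_loss(5, 0)
        with pytest.raises(ValueError):
            gene_loss(10, 5)


class TestPseudogenePipeline:
    def test_filter_boundaries(self):
        df = pd.DataFrame([
            dict(chrom="c", protein="P1", start=0, end=90, pident=39.9, length=40),
            dict(chrom="c", protein="P1", start=0, end=90, pident=40.0, length=30),
            dict(chrom="c", protein="P1", start=0, end=90, pident=80.0, length=29),
        ])
        out = pseudo_filter(df)
        assert len(out) == 1 and out.iloc[0]["pident"] == 40.0
        assert len(pseudo_filter(df.iloc[:0])) == 0

    @pytest.mark.parametrize("gap, n_chains", [(50, 1), (51, 2)])
    def test_link_gap_inclusive(self, gap, n_chains):
        df = pd.DataFrame([
            dict(chrom="c", protein="P1", start=0, end=100),
            dict(chrom="c", protein="P1", start=100 + gap, end=250),
        ])
        assert len(pseudo_link(df)) == n_chains

    def test_different_proteins_never_link(self):
        df = pd.DataFrame([
            dict(chrom="c", protein="P1", start=0, end=100),
            dict(chrom="c", protein="P2", start=110, end=200),
        ])
        assert len(pseudo_link(df)) == 2

    def test_stack_merges_contained_chains(self):
        chains = [
            PseudoChain("c", "P1", 100, 400),
            PseudoChain("c", "P2", 120, 380),  # 100% of the shorter
        ]
        loci = pseudo_stack(chains)
        assert len(loci) == 1 and loci[0].proteins == ("P1", "P2")
        assert loci[0].interval == (100, 400)

    def test_stack_low_overlap_stays_separate(self):
        chains = [PseudoChain("c", "P1", 0, 200), PseudoChain("c", "P2", 100, 300)]
        assert len(pseudo_stack(chains)) == 2  # 50% of the shorter

    def test_single_linkage_transitive_merge(self):
        # A~B and B~C merge all three even though A-C barely overlap
        chains = [
            PseudoChain("c", "A", 0, 100),
            PseudoChain("c", "B", 15, 115),
            PseudoChain("c", "C", 30, 130),
        ]
        loci = pseudo_stack(chains)
        assert len(loci) == 1 and loci[0].proteins == ("A", "B", "C")

    def _brute_force_stack(self, chains, min_overlap=0.80):
        """Union-find oracle over the explicit pairwise-overlap graph."""
        n = len(chains)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(n), 2):
            if chains[i].chrom != chains[j].chrom:
                continue
            a, b = chains[i].interval, chains[j].interval
            ov = min(a[1], b[1]) - max(a[0], b[0])
            if ov > 0 and ov / min(a[1] - a[0], b[1] - b[0]) >= min_overlap:
                parent[find(j)] = find(i)
        groups = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(chains[i])
        return sorted(
            (m[0].chrom, min(c.start for c in m), max(c.end for c in m),
             tuple(sorted({c.protein for c in m})))
            for m in groups.values()
        )

    def test_stack_matches_union_find_oracle_on_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            chains = [
                PseudoChain("c", f"P{k}", int(s), int(s + ln))
                for k, (s, ln) in enumerate(
                    zip(rng.integers(0, 500, 12), rng.integers(20, 200, 12))
                )
            ]
            got = sorted(
                (l.chrom, l.start, l.end, l.proteins) for l in pseudo_stack(chains)
            )
            assert got == self._brute_force_stack(chains)

    def test_link_stack_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(8)
        rows = [
            dict(chrom="c", protein=f"P{int(rng.integers(0, 4))}",
                 start=int(s), end=int(s) + int(rng.integers(30, 120)))
            for s in rng.integers(0, 2_000, 40)
        ]
        df = pd.DataFrame(rows)
        chains = pseudo_link(df)
        loci = pseudo_stack(chains)
        # order invariance of the whole pipeline
        loci2 = pseudo_stack(pseudo_link(df.sample(frac=1.0, random_state=0)))
        key = lambda ls: [(l.chrom, l.start, l.end, l.proteins) for l in ls]
        assert key(loci) == key(loci2)
        # linking its own chains changes nothing
        chain_df = pd.DataFrame([
            dict(chrom=c.chrom, protein=c.protein, start=c.start, end=c.end)
            for c in chains
        ])
        rechained = pseudo_link(chain_df)
        assert [(c.chrom, c.protein, c.start, c.end) for c in rechained] == sorted(
            (c.chrom, c.protein, c.start, c.end) for c in chains
        )
        # restacking the loci themselves changes nothing
        loci3 = pseudo_stack([
            PseudoChain(l.chrom, "+".join(l.proteins), l.start, l.end) for l in loci
        ])
        assert [(l.chrom, l.start, l.end) for l in loci3] == [
            (l.chrom, l.start, l.end) for l in loci
        ]


class TestKsSummaries:
    def test_median_conventions(self):
        df = pd.DataFrame(
            dict(gene_id=list("abcdef"),
                 ks=[0.01, 0.02, 0.03, 0.01, 0.03, 0.5],
                 region=["FS1"] * 3 + ["FS2"] * 2 + ["FS2"])
        )
        out = summarize_ks(df).set_index("region")
        assert out.loc["FS1", "median_ks"] == pytest.approx(0.02)
        # even count: mean of the middle two; values above 0.2 still included
        assert out.loc["FS2", "median_ks"] == pytest.approx(0.03)

    def test_single_value_region(self):
        df = pd.DataFrame(dict(gene_id=["a"], ks=[0.07], region=["INV"]))
        assert summarize_ks(df).iloc[0]["median_ks"] == pytest.approx(0.07)


def _layout(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "locus", "exon_id", "identity"]
    )


class TestDuplicates:
    def test_complete_partial_other(self):
        rows = []
        for e in range(1, 6):
            rows.append(("c", e * 100, e * 100 + 50, "+", "L1", f"exon{e}", 90.0))
        rows.append(("c", 900, 950, "+", "L2", "exon1", 92.0))
        rows.append(("c", 1200, 1250, "+", "L3", "exon1", 88.0))
        rows.append(("c", 1300, 1350, "+", "L3", "exon3", 85.0))
        copies = {c.locus: c for c in classify_copies(_layout(rows), 5)}
        assert copies["L1"].copy_class == COMPLETE
        assert copies["L2"].copy_class == PARTIAL_FIRST_EXON
        assert copies["L3"].copy_class == OTHER

    def test_low_identity_first_exon_is_other(self):
        rows = [("c", 0, 50, "+", "L1", "exon1", 79.9)]
        assert classify_copies(_layout(rows), 5)[0].copy_class == OTHER

    def test_zero_exons_rejected(self):
        with pytest.raises(ValueError):
            classify_copies(_layout([("c", 0, 50, "+", "L1", "exon1", 90.0)]), 0)

    def _copies(self, layout):
        return [c for c in classify_copies(layout, 5)
                if c.copy_class == PARTIAL_FIRST_EXON]

    def test_adjacent_opposite_strands_pair(self):
        rows = [("c", 10_000, 10_180, "+", "A", "exon1", 90.0),
                ("c", 12_000, 12_180, "-", "B", "exon1", 90.0)]
        out = pair_inverted(self._copies(_layout(rows)))
        assert len(out.pairs) == 1 and not out.unpaired

    def test_same_strand_copies_never_pair(self):
        rows = [("c", 10_000, 10_180, "+", "A", "exon1", 90.0),
                ("c", 12_000, 12_180, "+", "B", "exon1", 90.0)]
        out = pair_inverted(self._copies(_layout(rows)))
        assert not out.pairs and len(out.unpaired) == 2

    def test_sixteen_copy_hairpin_layout(self):
        """Seven adjacent opposite-strand doublets plus two isolated
        same-strand copies give exactly 7 pairs and 2 unpaired, with copy
        conservation."""
        rows = []
        k = 0
        for d in range(7):
            base = 100_000 + d * 300_000
            rows.append(("c", base, base + 180, "+", f"D{k}", "exon1", 90.0)); k += 1
            rows.append(("c", base + 2_000, base + 2_180, "-", f"D{k}", "exon1", 90.0)); k += 1
        rows.append(("c", 2_500_000, 2_500_180, "+", f"D{k}", "exon1", 90.0)); k += 1
        rows.append(("c", 2_700_000, 2_700_180, "+", f"D{k}", "exon1", 90.0))
        copies = self._copies(_layout(rows))
        out = pair_inverted(copies)
        assert len(out.pairs) == 7
        assert len(out.unpaired) == 2
        assert 2 * len(out.pairs) + len(out.unpaired) == 16
        for a, b in out.pairs:
            assert {a.strand, b.strand} == {"+", "-"}

    def test_copy_conservation_random_layouts(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            rows = [
                ("c", int(p), int(p) + 180, rng.choice(["+", "-"]),
                 f"L{i}", "exon1", 90.0)
                for i, p in enumerate(rng.integers(0, 1_000_000, 12))
            ]
            copies = self._copies(_layout(rows))
            out = pair_inverted(copies)
            assert 2 * len(out.pairs) + len(out.unpaired) == len(copies)
            for a, b in out.pairs:
                assert a.strand != b.strand
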