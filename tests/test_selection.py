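import math
import warnings
from itertools import product

import numpy as np
import pandas as pd
import pytest

from spongemag.io import GeneFeature, VariantSite
from spongemag.selection import (
    SENSE_CODONS,
    OmegaEstimate,
    _CODON_TABLE,
    coding_baseline,
    compare_variability,
    filter_variants,
    gene_variability,
    jukes_cantor,
    ng86_dnds,
    ng86_pair,
    ng86_sites,
    omega_background,
    sign_flip_test,
    significance_tier,
    support_filter,
)
from spongemag.simulate import evolve_codon_alignment


def var(pos, qual=30.0, depth=20, contig="c1"):
    return VariantSite(contig, pos, qual, depth, "A", "G")


class TestFilterVariants:
    def test_qual_boundary_strict_less_than(self):
        sites = [var(1, qual=19.0), var(2, qual=20.0)]
        assert [s.pos for s in filter_variants(sites)] == [2]

    def test_depth_rule_arithmetic(self):
        """Depths (10,10,10,10,50): mean 18, cutoff 36 -> depth-50 removed."""
        sites = [var(i + 1, depth=d) for i, d in enumerate([10, 10, 10, 10, 50])]
        kept = filter_variants(sites)
        assert [s.pos for s in kept] == [1, 2, 3, 4]

    def test_empty(self):
        assert filter_variants([]) == []

    def test_all_depths_unknown_skips_rule_with_warning(self):
        sites = [VariantSite("c1", 1, 30.0, None, "A", "G")]
        with pytest.warns(UserWarning, match="depth"):
            assert filter_variants(sites) == sites

    def test_never_retains_failing_site_and_idempotent(self):
        rng = np.random.default_rng(0)
        sites = [
            var(int(p), qual=float(q), depth=int(d))
            for p, q, d in zip(
                range(1, 201),
                rng.uniform(0, 60, 200),
                rng.poisson(30, 200) + 1,
            )
        ]
        kept = filter_variants(sites)
        depths = [s.depth for s in sites]
        cutoff = 2.0 * np.mean(depths)
        for s in kept:
            assert s.qual >= 20.0 and s.depth <= cutoff
        # idempotent when the mean-depth reference is frozen at the cutoff
        again = [
            s for s in kept if s.qual >= 20.0 and s.depth <= cutoff
        ]
        assert again == kept


class TestGeneVariability:
    GENE = GeneFeature("g", "c1", 1001, 2000, "+", "geneA")

    def test_five_in_thousand(self):
        sites = [var(p) for p in (1001, 1100, 1500, 1999, 2000)]
        gd = gene_variability(sites, self.GENE)
        assert gd.n_variable_sites == 5
        assert gd.proportion == pytest.approx(0.005)

    def test_no_variants(self):
        assert gene_variability([], self.GENE).proportion == 0.0

    def test_duplicate_positions_counted_once(self):
        sites = [var(1500), var(1500), var(1600)]
        gd = gene_variability(sites, self.GENE)
        # brute-force position-set oracle
        assert gd.n_variable_sites == len({1500, 1600})

    def test_other_contig_ignored(self):
        sites = [var(1500, contig="c2")]
        assert gene_variability(sites, self.GENE).n_variable_sites == 0


class TestCodingBaseline:
    def test_arithmetic(self):
        """100 kb coding with 300 variants; 6 kb excluded holding 6 of them
        -> 294 / 94,000."""
        genes = [
            GeneFeature("g", "c1", i * 1000 + 1, (i + 1) * 1000, "+", f"g{i}")
            for i in range(100)
        ]
        # exclude the last 6 genes as one 6 kb block
        excl_ids = {f"g{i}" for i in range(94, 100)}
        rng = np.random.default_rng(0)
        variants = [
            var(int(p))
            for p in rng.choice(np.arange(1, 94_001), size=294, replace=False)
        ] + [
            var(int(p))
            for p in rng.choice(np.arange(94_001, 100_001), size=6, replace=False)
        ]
        out = coding_baseline(variants, genes, exclude=excl_ids)
        assert out == pytest.approx(294 / 94_000)

    def test_no_exclusion_equals_plain_proportion(self):
        genes = [GeneFeature("g", "c1", 1, 1000, "+", "a")]
        variants = [var(5), var(10)]
        assert coding_baseline(variants, genes) == pytest.approx(0.002)

    def test_absent_exclusion_warns(self):
        genes = [GeneFeature("g", "c1", 1, 1000, "+", "a")]
        with pytest.warns(UserWarning, match="ghost"):
            out = coding_baseline([var(5)], genes, exclude={"ghost"})
        assert out == pytest.approx(0.001)

    def test_overlapping_intervals_merged(self):
        genes = [
            GeneFeature("g", "c1", 1, 1000, "+", "a"),
            GeneFeature("g", "c1", 501, 1500, "+", "b"),
        ]
        out = coding_baseline([var(750)], genes)
        assert out == pytest.approx(1 / 1500)

    def test_everything_excluded_rejected(self):
        genes = [GeneFeature("g", "c1", 1, 1000, "+", "a")]
        with pytest.raises(ValueError):
            coding_baseline([], genes, exclude={"a"})


class TestSignFlip:
    def test_all_zero_differences(self):
        assert sign_flip_test([0.0, 0.0, 0.0]) == 1.0

    def test_exact_three_pairs(self):
        """(-1,-2,-3): only the all-minus and all-plus patterns tie |t|."""
        assert sign_flip_test([-1.0, -2.0, -3.0]) == pytest.approx(2 / 8)

    @pytest.mark.parametrize("n", [4, 8, 12])
    def test_exact_branch_equals_full_enumeration(self, n):
        rng = np.random.default_rng(n)
        d = rng.normal(-0.5, 1.0, n)

        def t(vals):
            sd = np.std(vals, ddof=1)
            if sd == 0:
                return 0.0 if np.mean(vals) == 0 else math.inf
            return abs(np.mean(vals) / (sd / math.sqrt(len(vals))))

        t_obs = t(d)
        hits = sum(
            1
            for signs in product((-1, 1), repeat=n)
            if t(np.array(signs) * d) >= t_obs - 1e-12
        )
        assert sign_flip_test(d, n_iter=2**n) == pytest.approx(hits / 2**n)

    @pytest.mark.parametrize("seed", range(3))
    def test_monte_carlo_agrees_with_exact(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(-0.8, 1.0, 10)
        exact = sign_flip_test(d, n_iter=2**10)
        mc = sign_flip_test(d, n_iter=20_000, seed=seed)
        se = math.sqrt(exact * (1 - exact) / 20_000) + 1 / 20_000
        assert abs(mc - exact) <= 3 * se


class TestCompareVariability:
    def _table(self, n_mags, ratio, seed=0, cls="Binatia"):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_mags):
            base = rng.uniform(0.002, 0.004)
            for gene in ("ERG24", "CYP51", "ERG7"):
                noise = rng.normal(1.0, 0.05)
                rows.append(
                    {
                        "mag_id": f"m{i}",
                        "class_": cls,
                        "gene_id": gene,
                        "proportion": base * ratio * noise,
                        "baseline_proportion": base,
                    }
                )
        return pd.DataFrame(rows)

    def test_planted_low_variability_reaches_three_stars(self):
        table, skipped = compare_variability(self._table(20, ratio=0.3))
        assert not skipped
        assert (table["tier"] == "***").all()
        assert (table["mean_difference"] < 0).all()

    def test_small_class_skipped_with_reason(self):
        table, skipped = compare_variability(self._table(2, ratio=0.3))
        assert len(table) == 0
        assert skipped and "2" in skipped[0][1]

    def test_null_ratio_not_significant(self):
        table, _ = compare_variability(self._table(10, ratio=1.0, seed=5))
        assert (table["tier"] == "n.s.").all()

    def test_tiers(self):
        assert significance_tier(0.04) == "*"
        assert significance_tier(0.009) == "**"
        assert significance_tier(0.0009) == "***"
        assert significance_tier(0.2) == "n.s."


def brute_force_sites(codon):
    """Independent 9-neighbour enumeration."""
    aa = _CODON_TABLE[codon]
    syn = 0
    for i, base in enumerate(codon):
        for b in "ACGT":
            if b == base:
                continue
            if _CODON_TABLE[codon[:i] + b + codon[i + 1 :]] == aa:
                syn += 1
    return syn / 3, 3 - syn / 3


class TestNg86Sites:
    def test_phenylalanine(self):
        s, n = ng86_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_tryptophan_no_synonymous_neighbour(self):
        assert ng86_sites("TGG") == (0.0, 3.0)

    def test_all_sense_codons_match_brute_force_and_conserve(self):
        for codon in SENSE_CODONS:
            s, n = ng86_sites(codon)
            bs, bn = brute_force_sites(codon)
            assert s == pytest.approx(bs)
            assert s + n == pytest.approx(3.0)

    @pytest.mark.parametrize("bad", ["TAA", "TGA", "TAG", "TTN", "TT"])
    def test_invalid_codons_rejected(self, bad):
        with pytest.raises(ValueError):
            ng86_sites(bad)


class TestNg86Pair:
    def test_single_synonymous_step_counts(self):
        from spongemag.selection import _codon_path_counts

        assert _codon_path_counts("TTT", "TTC") == (1.0, 0.0)

    def test_single_synonymous_difference_in_context(self):
        dn, ds = ng86_pair("TTTATGGCCAAA", "TTCATGGCCAAA")
        assert dn == 0.0
        assert ds > 0.0

    def test_identical(self):
        assert ng86_pair("ATGAAA", "ATGAAA") == (0.0, 0.0)

    def test_matches_biopython_reference(self):
        """Cross-check against Biopython's NG86 implementation on a
        simulated divergent pair."""
        from Bio import BiopythonWarning
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        aln = evolve_codon_alignment(400, 0.4, 0.5, seed=21)
        (n1, s1), (n2, s2) = aln
        ours_dn, ours_ds = ng86_pair(s1, s2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dn, ds = cal_dn_ds(CodonSeq(s1), CodonSeq(s2), method="NG86")
        assert ours_dn == pytest.approx(dn, abs=5e-4)
        assert ours_ds == pytest.approx(ds, abs=5e-4)


class TestNg86Gene:
    def test_identical_sequences_omega_absent(self):
        est = ng86_dnds({"a": "ATGAAA", "b": "ATGAAA"})
        assert est.dN == est.dS == 0.0
        assert est.omega is None

    def test_length_validation(self):
        with pytest.raises(ValueError):
            ng86_dnds({"a": "ATGA", "b": "ATGA"})
        with pytest.raises(ValueError):
            ng86_dnds({"a": "ATGAAA"})

    def test_recovery_true_omega_02(self):
        aln = evolve_codon_alignment(3000, 0.3, 0.2, seed=2)
        est = ng86_dnds(aln)
        assert 0.1 < est.omega < 0.35

    def test_omega_zero_gives_near_zero_dn(self):
        """With no nonsynonymous substitutions, dN is zero except for the
        fractional attribution that equal-weight pathway averaging assigns
        to multi-hit codons; omega stays far inside the purifying regime."""
        aln = evolve_codon_alignment(500, 0.3, 0.0, seed=3)
        est = ng86_dnds(aln)
        assert est.omega < 0.02
        # single-difference codons are all synonymous
        from spongemag.selection import _CODON_TABLE, _codon_path_counts

        (_, s1), (_, s2) = aln
        for i in range(0, len(s1), 3):
            c1, c2 = s1[i : i + 3], s2[i : i + 3]
            if sum(a != b for a, b in zip(c1, c2)) == 1:
                assert _codon_path_counts(c1, c2) == (1.0, 0.0)

    def test_monotone_in_true_omega(self):
        means = []
        for omega in (0.1, 0.3, 1.0, 2.0):
            vals = [
                ng86_dnds(
                    evolve_codon_alignment(1200, 0.3, omega, seed=100 + s)
                ).omega
                for s in range(4)
            ]
            means.append(np.mean(vals))
        assert means == sorted(means)


class TestSupportFilter:
    def test_threshold_inclusive(self):
        ests = [
            OmegaEstimate("a", 0.1, 0.5, 0.2, 5, mean_support=69.9),
            OmegaEstimate("b", 0.1, 0.5, 0.2, 5, mean_support=70.0),
        ]
        kept = support_filter(ests)
        assert [e.gene_id for e in kept] == ["b"]

    def test_missing_support_passes_flagged(self):
        ests = [OmegaEstimate("a", 0.1, 0.5, 0.2, 5)]
        kept = support_filter(ests)
        assert kept[0].support_missing


class TestOmegaBackground:
    def _est(self, gid, omega):
        return OmegaEstimate(gid, omega, 1.0, omega, 5)

    def test_below_all(self):
        bg = [self._est(f"b{i}", w) for i, w in enumerate([0.5, 0.8, 1.0])]
        out = omega_background([self._est("q", 0.13)], bg)
        assert out["percentile"].iloc[0] == 0.0

    def test_above_all(self):
        bg = [self._est(f"b{i}", w) for i, w in enumerate([0.5, 0.8])]
        out = omega_background([self._est("q", 2.0)], bg)
        assert out["percentile"].iloc[0] == 1.0

    def test_tie_counts_half(self):
        bg = [self._est(f"b{i}", w) for i, w in enumerate([0.2, 0.5, 0.9])]
        out = omega_background([self._est("q", 0.5)], bg)
        # brute force: 1 strictly below + 0.5 * 1 tie, over 3
        assert out["percentile"].iloc[0] == pytest.approx((1 + 0.5) / 3)


def test_jukes_cantor_domain():
    assert jukes_cantor(0.0) == 0.0
    with pytest.raises(ValueError):
        jukes_cantor(0.75)
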