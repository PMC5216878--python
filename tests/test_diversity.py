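"""Diversity estimators against brute-force oracles and worked values."""

from collections import Counter
from itertools import combinations

import numpy as np
import pytest

from beanscan.diversity import (
    UndefinedStatisticError,
    diversity_estimates,
    haplotype_stats,
    harmonic_number,
    loss_of_diversity,
    nucleotide_diversity,
    site_counts,
    summarize_dataset,
    watterson_theta,
)
from beanscan.seqdata import LocusAlignment, PopulationLabel, usable_sites

from conftest import random_alignment


# -- independent oracles ----------------------------------------------------

def oracle_pi(rows):
    seqs = list(rows.values())
    usable = [j for j in range(len(seqs[0]))
              if all(s[j] not in "N-" for s in seqs)]
    if not usable:
        raise ZeroDivisionError
    diffs = sum(s1[j] != s2[j]
                for s1, s2 in combinations(seqs, 2) for j in usable)
    n = len(seqs)
    return diffs / (n * (n - 1) / 2) / len(usable)


def oracle_counts(rows):
    seqs = list(rows.values())
    usable = [j for j in range(len(seqs[0]))
              if all(s[j] not in "N-" for s in seqs)]
    V = eta = S = Pi = 0
    for j in usable:
        c = Counter(s[j] for s in seqs)
        if len(c) < 2:
            continue
        V += 1
        eta += len(c) - 1
        counts = sorted(c.values(), reverse=True)
        S += all(x == 1 for x in counts[1:])
        Pi += sum(x >= 2 for x in counts) >= 2
    return V, eta, S, Pi


def oracle_hd(rows):
    seqs = list(rows.values())
    usable = [j for j in range(len(seqs[0]))
              if all(s[j] not in "N-" for s in seqs)]
    haps = Counter(tuple(s[j] for j in usable) for s in seqs)
    n = len(seqs)
    return len(haps), n / (n - 1) * (1 - sum((k / n) ** 2
                                             for k in haps.values()))


# -- worked examples --------------------------------------------------------

class TestSiteCounts:
    def test_monomorphic(self):
        aln = LocusAlignment("L", {f"s{i}": "A" * 10 for i in range(4)})
        c = site_counts(aln)
        assert (c.V, c.eta, c.S, c.Pi_sites) == (0, 0, 0, 0)

    def test_singleton_site(self):
        aln = LocusAlignment("L", {"a": "A", "b": "A", "c": "A", "d": "T"})
        c = site_counts(aln)
        assert (c.V, c.eta, c.S, c.Pi_sites) == (1, 1, 1, 0)

    def test_triallelic_singletons(self):
        # {A:2, T:1, G:1}: two mutations, all non-major alleles singletons
        aln = LocusAlignment("L", {"a": "A", "b": "A", "c": "T", "d": "G"})
        c = site_counts(aln)
        assert (c.V, c.eta, c.S, c.Pi_sites) == (1, 2, 1, 0)


class TestPi:
    def test_identical(self):
        aln = LocusAlignment("L", {"a": "ACGT", "b": "ACGT"})
        assert nucleotide_diversity(aln) == 0.0

    def test_hand_computed(self):
        # 4 seqs x 10 sites; pairwise diffs sum to 7 -> 7/(6*10)
        aln = LocusAlignment("L", {
            "a": "AAAAAAAAAA", "b": "AAAAAAAAAT",
            "c": "AAAAAAAATT", "d": "AAAAAAAAAA"})
        assert nucleotide_diversity(aln) == pytest.approx(7 / 60, abs=1e-15)

    def test_zero_usable_sites_undefined(self):
        aln = LocusAlignment("L", {"a": "-", "b": "A"})
        with pytest.raises(UndefinedStatisticError):
            nucleotide_diversity(aln)


class TestWatterson:
    def test_hand_computed(self):
        # n=4, S=3, L=10: theta = 3 / (11/6) / 10
        aln = LocusAlignment("L", {
            "a": "AAAAAAAAAA", "b": "TAAAAAAAAA",
            "c": "ATAAAAAAAA", "d": "AATAAAAAAA"})
        expected = 3 / (1 + 1 / 2 + 1 / 3) / 10
        assert watterson_theta(aln) == pytest.approx(expected, abs=1e-15)

    def test_n2_limit(self):
        aln = LocusAlignment("L", {"a": "AT", "b": "AA"})
        assert watterson_theta(aln) == pytest.approx(0.5)

    def test_eta_variant(self):
        aln = LocusAlignment("L", {"a": "A", "b": "T", "c": "G"})
        assert watterson_theta(aln, use_eta=True) == \
            pytest.approx(2 / harmonic_number(3))


class TestHaplotypes:
    def test_all_identical(self):
        aln = LocusAlignment("L", {f"s{i}": "ACGT" for i in range(4)})
        assert haplotype_stats(aln) == (1, 0.0)

    def test_two_haplotypes_even(self):
        aln = LocusAlignment("L", {"a": "A", "b": "A", "c": "T", "d": "T"})
        H, Hd = haplotype_stats(aln)
        assert H == 2 and Hd == pytest.approx(4 / 3 * 0.5)

    def test_all_distinct_max(self):
        aln = LocusAlignment("L", {"a": "A", "b": "T", "c": "G", "d": "C"})
        assert haplotype_stats(aln)[1] == pytest.approx(1.0)


class TestOracleEquivalence:
    def test_estimators_match_brute_force(self, rng):
        """pi, theta, Hd and site counts agree exactly with independent
        brute-force implementations on random gapped alignments."""
        for _ in range(300):
            aln = random_alignment(rng, alphabet="ACGTN-" if
                                   rng.random() < 0.3 else "ACGT")
            try:
                pi = nucleotide_diversity(aln)
            except UndefinedStatisticError:
                continue
            assert pi == pytest.approx(oracle_pi(aln.rows), abs=1e-12)
            c = site_counts(aln)
            assert (c.V, c.eta, c.S, c.Pi_sites) == oracle_counts(aln.rows)
            H, Hd = haplotype_stats(aln)
            oH, oHd = oracle_hd(aln.rows)
            assert H == oH and Hd == pytest.approx(oHd, abs=1e-12)
            L = usable_sites(aln).n_usable
            theta = watterson_theta(aln)
            assert theta == pytest.approx(
                c.V / harmonic_number(aln.n) / L, abs=1e-12)


class TestLossOfDiversity:
    def test_published_mean_values(self):
        assert round(loss_of_diversity([5.39e-3], [2.70e-3]).L_mean, 2) == 0.50
        assert round(loss_of_diversity([3.09e-3], [1.77e-3]).L_mean, 2) == 0.43

    def test_identical_vectors_zero(self):
        L = loss_of_diversity([1.0, 2.0], [1.0, 2.0])
        assert L.L_mean == 0.0 and L.L_per_locus == 0.0

    def test_monomorphic_wild_excluded_from_per_locus(self):
        L = loss_of_diversity([2.0, 0.0], [1.0, 0.0])
        assert L.n_excluded == 1
        assert L.L_per_locus == pytest.approx(0.5)
        assert L.L_mean == pytest.approx(0.5)

    def test_all_zero_wild_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            loss_of_diversity([0.0], [0.0])


class TestSummarize:
    def test_footer_aggregation(self, annotated_dataset):
        df = summarize_dataset(annotated_dataset, "whole",
                               PopulationLabel.MW)
        footer = df[df.locus == "overall"].iloc[0]
        body = df[df.locus != "overall"]
        assert footer.V == body.V.sum()
        assert footer.snp_freq == pytest.approx(
            body.V.sum() / body.L.sum())

    def test_region_additivity(self, annotated_dataset):
        """V(whole) = V(coding) + V(noncoding) for fully annotated loci."""
        parts = {}
        for region in ("whole", "coding", "noncoding"):
            df = summarize_dataset(annotated_dataset, region,
                                   PopulationLabel.MW)
            parts[region] = df[df.locus != "overall"].V.sum()
        assert parts["whole"] == parts["coding"] + parts["noncoding"]
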