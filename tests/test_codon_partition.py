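"""Polymorphism partitioning, syn/nonsyn classification, Nei-Gojobori
dN/dS and the nonparametric tests, each checked against independent
oracles."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest
from Bio.Seq import Seq
from scipy import stats

from beanscan.codon_partition import (
    CodingDataError,
    NoInformativePairsError,
    binomial_private_coding_test,
    classify_site_syn_nonsyn,
    count_syn_nonsyn,
    nei_gojobori_dn_ds,
    paired_wilcoxon,
    partition_polymorphisms,
    private_replacement_report,
    ranksum_diversity_test,
)
from beanscan.diversity import site_counts
from beanscan.seqdata import (
    Dataset,
    LocusAlignment,
    PopulationLabel,
    RegionAnnotation,
)


# ---------------------------------------------------------------------------
# shared / private partition
# ---------------------------------------------------------------------------

class TestPartition:
    def test_shared_site(self):
        w = LocusAlignment("L", {"w1": "A", "w2": "T"})
        d = LocusAlignment("L", {"d1": "A", "d2": "T"})
        p = partition_polymorphisms(w, d)
        assert p.by_region["whole"].shared == 1
        assert p.by_region["whole"].total == 1

    def test_private_dom_site(self):
        w = LocusAlignment("L", {"w1": "A", "w2": "A"})
        d = LocusAlignment("L", {"d1": "A", "d2": "T"})
        p = partition_polymorphisms(w, d)
        cc = p.by_region["whole"]
        assert (cc.shared, cc.private_wild, cc.private_dom) == (0, 0, 1)

    def test_third_allele_splits_categories(self):
        # site A/T in both plus G only in wild: 1 shared + 1 private wild
        w = LocusAlignment("L", {"w1": "A", "w2": "T", "w3": "G"})
        d = LocusAlignment("L", {"d1": "A", "d2": "T"})
        cc = partition_polymorphisms(w, d).by_region["whole"]
        assert (cc.shared, cc.private_wild, cc.private_dom) == (1, 1, 0)

    def test_fixed_difference_excluded(self):
        w = LocusAlignment("L", {"w1": "A", "w2": "A"})
        d = LocusAlignment("L", {"d1": "T", "d2": "T"})
        assert partition_polymorphisms(w, d).by_region["whole"].total == 0

    def test_partition_conservation_random(self, rng):
        """shared + private_wild + private_dom equals pooled eta restricted
        to sites variable within at least one population."""
        for _ in range(200):
            L = int(rng.integers(1, 15))
            w = LocusAlignment("L", {
                f"w{i}": "".join(rng.choice(list("AT"), size=L))
                for i in range(int(rng.integers(2, 5)))})
            d = LocusAlignment("L", {
                f"d{i}": "".join(rng.choice(list("AT"), size=L))
                for i in range(int(rng.integers(2, 5)))})
            cc = partition_polymorphisms(w, d).by_region["whole"]
            expected = 0
            for j in range(L):
                colw = [s[j] for s in w.rows.values()]
                cold = [s[j] for s in d.rows.values()]
                if len(set(colw)) < 2 and len(set(cold)) < 2:
                    continue
                expected += len(set(colw) | set(cold)) - 1
            assert cc.total == expected

    def test_region_tallies(self, annotated_dataset):
        ds = annotated_dataset
        aln = ds.loci[0]
        w = ds.population(aln, PopulationLabel.MW)
        d = ds.population(aln, PopulationLabel.MD)
        part = partition_polymorphisms(w, d, ds.annotations["L1"])
        # the single private-wild site (column 6) sits in the intron
        assert part.by_region["noncoding"].private_wild == 1
        assert part.by_region["coding"].total == 0
        assert part.by_region["whole"].total == 1


# ---------------------------------------------------------------------------
# syn / nonsyn classification
# ---------------------------------------------------------------------------

class TestSynNonsyn:
    @pytest.mark.parametrize("codons,site,expected", [
        (("GGG", "GGA"), 2, "synonymous"),     # Gly/Gly
        (("TCT", "TTT"), 1, "nonsynonymous"),  # Ser/Phe
        (("ATG", "ACG"), 1, "nonsynonymous"),  # Met/Thr
    ])
    def test_examples(self, codons, site, expected):
        aln = LocusAlignment("L", {f"s{i}": c for i, c in enumerate(codons)})
        assert classify_site_syn_nonsyn(aln, 0, site) == expected

    def test_partial_codon_rejected(self):
        aln = LocusAlignment("L", {"a": "GGGG", "b": "GGGA"})
        with pytest.raises(CodingDataError):
            classify_site_syn_nonsyn(aln, 0, 3)

    def test_count_totals(self):
        aln = LocusAlignment("L", {"a": "GGGTCT", "b": "GGATTT"})
        assert count_syn_nonsyn(aln, 0) == (1, 1)


class TestReplacementReport:
    def _dataset(self, md_variant="ATGTTTGGA", outgroup="ATGTCTGGA"):
        background = "ATGTCTGGA"  # M S G
        rows = {f"w{i}": background for i in range(3)}
        rows.update({f"d{i}": background for i in range(2)})
        rows["d2"] = md_variant
        rows["pd"] = outgroup
        manifest = {**{f"w{i}": PopulationLabel.MW for i in range(3)},
                    **{f"d{i}": PopulationLabel.MD for i in range(3)},
                    "pd": PopulationLabel.OUT_PD}
        aln = LocusAlignment("L", rows)
        ann = RegionAnnotation("L", ((0, 9, "exon"),), 0)
        return Dataset(loci=[aln], annotations={"L": ann}, manifest=manifest)

    def test_private_derived_flagged(self):
        recs = private_replacement_report(self._dataset())
        assert len(recs) == 1
        r = recs[0]
        assert (r.background_aa, r.variant_aa) == ("S", "F")
        assert r.carriers["MD"] == ["d2"] and r.derived

    def test_variant_in_wild_not_private(self):
        ds = self._dataset()
        rows = dict(ds.loci[0].rows)
        rows["w0"] = "ATGTTTGGA"
        ds.loci[0] = LocusAlignment("L", rows)
        assert private_replacement_report(ds) == []

    def test_outgroup_carrier_blocks_derived_flag(self):
        recs = private_replacement_report(
            self._dataset(outgroup="ATGTTTGGA"))
        assert len(recs) == 1 and not recs[0].derived


# ---------------------------------------------------------------------------
# Nei-Gojobori dN/dS vs an exhaustive oracle
# ---------------------------------------------------------------------------

def _oracle_translate(codon):
    return str(Seq(codon).translate())


def _oracle_syn_fraction(codon, R):
    s = 0.0
    for pos in range(3):
        wsum = wsyn = 0.0
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            w = R if {codon[pos], alt} in ({"A", "G"}, {"C", "T"}) else 1.0
            wsum += w
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if _oracle_translate(mutant) == _oracle_translate(codon):
                wsyn += w
        s += wsyn / wsum
    return s


def _oracle_path_counts(c1, c2):
    diff = [i for i in range(3) if c1[i] != c2[i]]
    paths = []
    for order in itertools.permutations(diff):
        cur, sd, nd, blocked = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _oracle_translate(nxt) == "*":
                blocked = True
            if _oracle_translate(nxt) == _oracle_translate(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, blocked))
    valid = [p for p in paths if not p[2]] or paths
    return (sum(p[0] for p in valid) / len(valid),
            sum(p[1] for p in valid) / len(valid))


def _oracle_pair_dnds(s1, s2, R):
    codons1 = [s1[i:i + 3] for i in range(0, len(s1), 3)]
    codons2 = [s2[i:i + 3] for i in range(0, len(s2), 3)]
    S = 0.5 * (sum(_oracle_syn_fraction(c, R) for c in codons1)
               + sum(_oracle_syn_fraction(c, R) for c in codons2))
    N = 3 * len(codons1) - S
    sd = nd = 0.0
    for a, b in zip(codons1, codons2):
        x, y = _oracle_path_counts(a, b)
        sd, nd = sd + x, nd + y
    def jc(p):
        return math.nan if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)
    return jc(nd / N if N > 0 else 0.0), jc(sd / S if S > 0 else 0.0)


def _random_coding_seq(rng, n_codons):
    out = []
    while len(out) < n_codons:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if _oracle_translate(c) != "*":
            out.append(c)
    return "".join(out)


class TestNeiGojobori:
    def test_identical_sequences_zero(self):
        est = nei_gojobori_dn_ds(["ATGGGA", "ATGGGA"], n_boot=5, seed=0)
        assert est.dN == 0.0 and est.dS == 0.0

    def test_single_synonymous_difference(self):
        # GGG->GGA is synonymous; 3 codons of Gly have 3 syn sites total
        est = nei_gojobori_dn_ds(["GGGGGGGGG", "GGAGGGGGG"], R=1,
                                 n_boot=5, seed=0)
        assert est.dS == pytest.approx(-0.75 * math.log(5 / 9), abs=1e-12)
        assert est.dN == 0.0

    def test_internal_stop_rejected(self):
        with pytest.raises(CodingDataError):
            nei_gojobori_dn_ds(["TAAGGG", "TAAGGG"], n_boot=5, seed=0)

    def test_oracle_equivalence_random_pairs(self, rng):
        """Pairwise dN/dS matches an independent pathway-enumeration
        oracle (Biopython translation table) on random codon pairs."""
        for _ in range(200):
            n_codons = int(rng.integers(1, 6))
            R = float(rng.choice([0.5, 1.0, 2.0]))
            s1 = _random_coding_seq(rng, n_codons)
            s2 = _random_coding_seq(rng, n_codons)
            est = nei_gojobori_dn_ds([s1, s2], R=R, n_boot=2, seed=1)
            odn, ods = _oracle_pair_dnds(s1, s2, R)
            if math.isnan(odn) or math.isnan(ods):
                assert est.jc_undefined
                continue
            assert est.dN == pytest.approx(odn, abs=1e-12)
            assert est.dS == pytest.approx(ods, abs=1e-12)

    def test_bootstrap_reproducible_and_shrinking(self, rng):
        # low-divergence panel: a few codon substitutions on one backbone
        base = _random_coding_seq(rng, 40)
        seqs = []
        for _ in range(4):
            s = list(base)
            for ci in rng.choice(40, size=4, replace=False):
                s[3 * ci:3 * ci + 3] = _random_coding_seq(rng, 1)
            seqs.append("".join(s))
        seqs_long = [s * 4 for s in seqs]
        a = nei_gojobori_dn_ds(seqs, n_boot=200, seed=7)
        b = nei_gojobori_dn_ds(seqs, n_boot=200, seed=7)
        assert (a.se_dN, a.se_dS) == (b.se_dN, b.se_dS)
        c = nei_gojobori_dn_ds(seqs_long, n_boot=200, seed=7)
        # quadrupling the codon count should roughly halve the SEs
        assert c.se_dN < a.se_dN and c.se_dS < a.se_dS


# ---------------------------------------------------------------------------
# nonparametric tests vs full enumeration
# ---------------------------------------------------------------------------

def oracle_signed_rank(diffs, alternative):
    d = [x for x in diffs if x != 0]
    ranks = stats.rankdata([abs(x) for x in d])
    w_obs = sum(r for x, r in zip(d, ranks) if x > 0)
    stats_all = []
    for signs in itertools.product([1, -1], repeat=len(d)):
        stats_all.append(sum(r for s, r in zip(signs, ranks) if s > 0))
    stats_all = np.array(stats_all)
    p_ge = np.mean(stats_all >= w_obs - 1e-9)
    p_le = np.mean(stats_all <= w_obs + 1e-9)
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


def oracle_ranksum(x, y):
    pooled = list(x) + list(y)
    ranks = stats.rankdata(pooled)
    n = len(x)
    mu = n * (len(pooled) + 1) / 2
    obs = abs(ranks[:n].sum() - mu)
    devs = [abs(sum(ranks[list(c)]) - mu)
            for c in itertools.combinations(range(len(pooled)), n)]
    return np.mean(np.array(devs) >= obs - 1e-9)


class TestWilcoxon:
    def test_no_informative_pairs(self):
        with pytest.raises(NoInformativePairsError):
            paired_wilcoxon([1, 2], [1, 2])

    def test_all_positive_one_sided(self):
        _, p = paired_wilcoxon([1, 2, 3], [0, 0, 0], alternative="greater")
        assert p == pytest.approx(1 / 8)

    def test_exact_matches_enumeration(self, rng):
        for _ in range(120):
            n = int(rng.integers(1, 9))
            x = rng.integers(-4, 5, size=n).astype(float)
            y = rng.integers(-4, 5, size=n).astype(float)
            if np.all(x == y):
                continue
            for alt in ("two-sided", "greater", "less"):
                _, p = paired_wilcoxon(x, y, alternative=alt)
                assert p == pytest.approx(
                    oracle_signed_rank(x - y, alt), abs=1e-12)

    def test_matches_scipy_without_ties(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        _, p = paired_wilcoxon(x, y)
        ref = stats.wilcoxon(x, y, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


class TestRankSum:
    def test_complete_separation(self):
        _, p = ranksum_diversity_test([1, 2, 3, 4], [5, 6, 7, 8])
        assert p == pytest.approx(2 / 70)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ranksum_diversity_test([], [1.0])

    def test_exact_matches_enumeration(self, rng):
        for _ in range(120):
            n = int(rng.integers(1, 6))
            m = int(rng.integers(1, 6))
            x = rng.integers(0, 5, size=n).astype(float)
            y = rng.integers(0, 5, size=m).astype(float)
            _, p = ranksum_diversity_test(x, y)
            assert p == pytest.approx(oracle_ranksum(x, y), abs=1e-12)


class TestBinomial:
    def _partition(self, pwc, pwn, pdc, pdn, lc=100, ln=100):
        return {"private_wild_coding": pwc, "private_wild_noncoding": pwn,
                "private_dom_coding": pdc, "private_dom_noncoding": pdn,
                "region_lengths": {"coding": lc, "noncoding": ln}}

    def test_direct_summation(self):
        p = binomial_private_coding_test(self._partition(1, 1, 8, 4))
        assert p == pytest.approx(794 / 4096, abs=1e-12)

    def test_observed_zero_gives_one(self):
        with pytest.raises(ValueError):
            binomial_private_coding_test(self._partition(1, 1, 0, 0))
        p = binomial_private_coding_test(self._partition(1, 1, 0, 3))
        assert p == pytest.approx(stats.binom.sf(-1, 3, 0.5))

    def test_degenerate_p_one(self):
        p = binomial_private_coding_test(self._partition(5, 0, 3, 0))
        assert p == pytest.approx(1.0)

    def test_length_standardized_mode(self):
        # unequal region lengths shift p0 away from the raw fraction
        part = self._partition(10, 10, 4, 2, lc=100, ln=400)
        p_raw = binomial_private_coding_test(part, "raw_count")
        p_std = binomial_private_coding_test(part, "length_standardized")
        # per-bp wild rates: 0.1 coding vs 0.025 noncoding -> p0 = 0.8
        assert p_std == pytest.approx(stats.binom.sf(3, 6, 0.8), abs=1e-12)
        assert p_std != p_raw
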