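"""Shared/private polymorphism partitioning, synonymous/nonsynonymous
classification, private-replacement reporting, Nei-Gojobori dN/dS and the
accompanying nonparametric tests.

A mutation (an allele beyond the baseline at a variable site) is *shared*
when the allele segregates in both the wild and the domesticated population,
and *private* to the population that alone carries it.  Coding-region
mutations are further classified as synonymous or nonsynonymous from the
observed whole-haplotype codons.  dN and dS use the (modified) Nei-Gojobori
pathway-counting method with transition/transversion-weighted site counts
and the Jukes-Cantor multiple-hit correction, with bootstrap-over-codons
standard errors.
"""

from __future__ import annotations

import functools
import itertools
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .seqdata import (
    Dataset,
    EmptyRegionError,
    LocusAlignment,
    NONCODING_CLASSES,
    PopulationLabel,
    RegionAnnotation,
    slice_region,
    usable_sites,
)

# standard nuclear genetic code; '*' = stop
_BASES = "TCAG"
_AMINO = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
GENETIC_CODE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class CodingDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# shared / private polymorphism partition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoryCounts:
    shared: int = 0
    private_wild: int = 0
    private_dom: int = 0

    @property
    def total(self) -> int:
        return self.shared + self.private_wild + self.private_dom

    def __add__(self, other: "CategoryCounts") -> "CategoryCounts":
        return CategoryCounts(self.shared + other.shared,
                              self.private_wild + other.private_wild,
                              self.private_dom + other.private_dom)


@dataclass
class PolymorphismPartition:
    """Mutation-pattern tallies for one locus, per region class.

    ``by_region`` maps 'whole' / 'coding' / 'noncoding' to
    :class:`CategoryCounts`; ``coding_syn`` / ``coding_nonsyn`` break the
    coding tallies down by effect; ``region_lengths`` holds usable lengths
    for length-standardized rates.
    """

    locus_id: str
    by_region: dict[str, CategoryCounts] = field(default_factory=dict)
    coding_syn: CategoryCounts = CategoryCounts()
    coding_nonsyn: CategoryCounts = CategoryCounts()
    region_lengths: dict[str, int] = field(default_factory=dict)

    def rate(self, region: str, category: str) -> float:
        L = self.region_lengths.get(region, 0)
        if not L:
            return math.nan
        return getattr(self.by_region[region], category) / L


def _site_mutations(col_w: str, col_d: str) -> CategoryCounts:
    """Classify the mutations at one usable column.

    Baseline allele: one present in both populations if any exists, else the
    fixed allele of a monomorphic population.  Sites variable in neither
    population (monomorphic or pure fixed differences) contribute nothing.
    """
    aw, ad = set(col_w), set(col_d)
    if len(aw) < 2 and len(ad) < 2:
        return CategoryCounts()
    both = aw & ad
    if both:
        baseline = {min(both)}
    elif len(aw) == 1:
        baseline = aw
    elif len(ad) == 1:
        baseline = ad
    else:  # disjoint allele sets, both polymorphic: wild major as baseline
        baseline = {Counter(col_w).most_common(1)[0][0]}
    sm = pw = pd_ = 0
    for allele in (aw | ad) - baseline:
        if allele in aw and allele in ad:
            sm += 1
        elif allele in aw:
            pw += 1
        else:
            pd_ += 1
    return CategoryCounts(sm, pw, pd_)


def _partition_columns(aln_wild: LocusAlignment, aln_dom: LocusAlignment
                       ) -> tuple[list[CategoryCounts], np.ndarray]:
    pooled = LocusAlignment(
        aln_wild.locus_id, {**dict(aln_wild.rows), **dict(aln_dom.rows)})
    mask = usable_sites(pooled).usable
    per_col = []
    for j in range(pooled.length):
        if not mask[j]:
            per_col.append(CategoryCounts())
            continue
        col_w = "".join(s[j] for s in aln_wild.rows.values())
        col_d = "".join(s[j] for s in aln_dom.rows.values())
        per_col.append(_site_mutations(col_w, col_d))
    return per_col, mask


def partition_polymorphisms(aln_wild: LocusAlignment,
                            aln_dom: LocusAlignment,
                            ann: RegionAnnotation | None = None
                            ) -> PolymorphismPartition:
    """Shared/private mutation tallies per region class for one locus.

    Without an annotation only the 'whole' region is reported.  Coding
    tallies include a synonymous/nonsynonymous breakdown from the observed
    haplotype codons of the pooled sample.
    """
    per_col, mask = _partition_columns(aln_wild, aln_dom)
    part = PolymorphismPartition(aln_wild.locus_id)
    part.by_region["whole"] = sum(per_col, CategoryCounts())
    part.region_lengths["whole"] = int(mask.sum())
    if ann is None:
        return part

    for region, classes in (("coding", {"exon"}),
                            ("noncoding", NONCODING_CLASSES)):
        cols = ann.columns_of(classes)
        if not cols:
            continue
        part.by_region[region] = sum((per_col[j] for j in cols),
                                     CategoryCounts())
        part.region_lengths[region] = int(mask[cols].sum())

    if "coding" in part.by_region:
        pooled = LocusAlignment(
            aln_wild.locus_id, {**dict(aln_wild.rows), **dict(aln_dom.rows)})
        exon = slice_region(pooled, ann, {"exon"})
        exon_mask = usable_sites(exon).usable
        cols = ann.columns_of({"exon"})
        effect = {}  # exon-local site -> 'synonymous' / 'nonsynonymous'
        for local in range(exon.length):
            if not exon_mask[local]:
                continue
            try:
                cls = classify_site_syn_nonsyn(exon, ann.frame_offset, local,
                                               exon_mask)
            except CodingDataError:
                continue
            if cls is not None:
                effect[local] = cls
        syn = nonsyn = CategoryCounts()
        for local, j in enumerate(cols):
            cc = per_col[j]
            if cc.total == 0:
                continue
            if effect.get(local) == "synonymous":
                syn = syn + cc
            else:  # nonsynonymous or mixed-effect sites count as replacement
                nonsyn = nonsyn + cc
        part.coding_syn, part.coding_nonsyn = syn, nonsyn
    return part


# ---------------------------------------------------------------------------
# synonymous / nonsynonymous site classification
# ---------------------------------------------------------------------------

def _codon_bounds(frame_offset: int, site: int, length: int
                  ) -> tuple[int, int] | None:
    """Start/end of the complete codon containing exon-local ``site``."""
    if site < frame_offset:
        return None
    start = frame_offset + 3 * ((site - frame_offset) // 3)
    end = start + 3
    if end > length:
        return None  # trailing partial codon
    return start, end


def classify_site_syn_nonsyn(exon_aln: LocusAlignment, frame_offset: int,
                             site: int,
                             mask: np.ndarray | None = None) -> str | None:
    """Effect of the variation at one exon-local site.

    Translates each observed whole-haplotype codon: 'synonymous' if every
    pair of codons differing at the site encodes the same amino acid,
    'nonsynonymous' if every differing pair changes it, 'mixed' otherwise.
    Returns None for monomorphic sites.  Sites outside a complete codon or in
    codons containing masked columns raise :class:`CodingDataError`.
    """
    bounds = _codon_bounds(frame_offset, site, exon_aln.length)
    if bounds is None:
        raise CodingDataError(f"site {site} not inside a complete codon")
    start, end = bounds
    if mask is not None and not mask[start:end].all():
        raise CodingDataError(f"codon at {start} contains masked columns")
    codons = {s[start:end] for s in exon_aln.rows.values()}
    if any(set(c) - set("ACGT") for c in codons):
        raise CodingDataError("codon contains gap/N")
    pos = site - start
    same = diff = 0
    for c1, c2 in itertools.combinations(sorted(codons), 2):
        if c1[pos] == c2[pos]:
            continue
        if GENETIC_CODE[c1] == GENETIC_CODE[c2]:
            same += 1
        else:
            diff += 1
    if same + diff == 0:
        return None
    if diff == 0:
        return "synonymous"
    if same == 0:
        return "nonsynonymous"
    return "mixed"


def count_syn_nonsyn(exon_aln: LocusAlignment,
                     frame_offset: int) -> tuple[int, int]:
    """(Syn, Nonsyn) mutation totals for one population's exon alignment.

    Counts (alleles - 1) per variable usable site, classified by the
    site-effect rule; mixed-effect sites count as nonsynonymous.
    """
    mask = usable_sites(exon_aln).usable
    arr = exon_aln.to_array()
    syn = nonsyn = 0
    for j in range(exon_aln.length):
        if not mask[j]:
            continue
        k = len(set(arr[:, j].tobytes().decode()))
        if k < 2:
            continue
        try:
            cls = classify_site_syn_nonsyn(exon_aln, frame_offset, j, mask)
        except CodingDataError:
            continue
        if cls == "synonymous":
            syn += k - 1
        elif cls is not None:
            nonsyn += k - 1
    return syn, nonsyn


# ---------------------------------------------------------------------------
# private replacement report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReplacementRecord:
    locus_id: str
    codon_index: int                  # 0-based within the exon reading frame
    background_codon: str
    variant_codon: str
    background_aa: str
    variant_aa: str
    carriers: dict[str, list[str]]    # population label -> variant carriers
    counts: dict[str, int]            # population label -> panel size
    derived: bool                     # absent from every other population
                                      # and from the outgroups


_OUTGROUPS = {PopulationLabel.OUT_PD, PopulationLabel.OUT_PC}


def private_replacement_report(dataset: Dataset,
                               focal: PopulationLabel = PopulationLabel.MD
                               ) -> list[ReplacementRecord]:
    """Nonsynonymous codon variants private to the focal population.

    A variant amino acid is private when, among the P. vulgaris populations,
    only focal accessions carry it; it is additionally flagged *derived*
    (recent, post-domestication) when the outgroup species also carry the
    background state.
    """
    records = []
    vulgaris = [l for l in PopulationLabel if l not in _OUTGROUPS]
    for aln in dataset.loci:
        ann = dataset.annotations.get(aln.locus_id)
        if ann is None or "exon" not in ann.classes_present:
            continue
        exon = slice_region(aln, ann, {"exon"})
        mask = usable_sites(exon).usable
        fo = ann.frame_offset
        n_codons = (exon.length - fo) // 3
        for ci in range(n_codons):
            start = fo + 3 * ci
            if not mask[start:start + 3].all():
                continue
            codons = {a: s[start:start + 3] for a, s in exon.rows.items()}
            if any(set(c) - set("ACGT") for c in codons.values()):
                continue
            aas = {a: GENETIC_CODE[c] for a, c in codons.items()}
            focal_accs = [a for a in exon.accessions
                          if dataset.manifest[a] is focal]
            other_vulgaris = [a for a in exon.accessions
                              if dataset.manifest[a] in vulgaris
                              and dataset.manifest[a] is not focal]
            outgroup_accs = [a for a in exon.accessions
                             if dataset.manifest[a] in _OUTGROUPS]
            other_aas = {aas[a] for a in other_vulgaris}
            for var_aa in sorted({aas[a] for a in focal_accs} - other_aas):
                carriers_focal = [a for a in focal_accs if aas[a] == var_aa]
                background = Counter(
                    codons[a] for a in other_vulgaris).most_common(1)
                if not background:
                    continue
                bg_codon = background[0][0]
                if GENETIC_CODE[bg_codon] == var_aa:
                    continue  # not a replacement
                derived = all(aas[a] != var_aa for a in outgroup_accs)
                carriers = {
                    l.value: [a for a in exon.accessions
                              if dataset.manifest[a] is l and aas[a] == var_aa]
                    for l in PopulationLabel
                }
                counts = {
                    l.value: sum(dataset.manifest[a] is l
                                 for a in exon.accessions)
                    for l in PopulationLabel
                }
                records.append(ReplacementRecord(
                    locus_id=aln.locus_id, codon_index=ci,
                    background_codon=bg_codon,
                    variant_codon=codons[carriers_focal[0]],
                    background_aa=GENETIC_CODE[bg_codon], variant_aa=var_aa,
                    carriers=carriers, counts=counts, derived=derived))
    return records


# ---------------------------------------------------------------------------
# Nei-Gojobori dN / dS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DnDsEstimate:
    dN: float
    dS: float
    se_dN: float
    se_dS: float
    R: float
    jc_undefined: bool = False  # some pairwise p-distance reached 3/4


def _syn_fraction(codon: str, R: float) -> float:
    """R-weighted synonymous fraction summed over the codon's 3 positions.

    Transitions weigh R, transversions 1; changes creating stop codons count
    as nonsynonymous.  R = 1 recovers the original (unweighted) method.
    """
    if GENETIC_CODE[codon] == "*":
        raise CodingDataError(f"stop codon {codon} in data")
    s = 0.0
    for pos in range(3):
        wsum = wsyn = 0.0
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            w = R if (codon[pos], alt) in TRANSITIONS else 1.0
            wsum += w
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if GENETIC_CODE[mutant] == GENETIC_CODE[codon]:
                wsyn += w
        s += wsyn / wsum
    return s


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Mean (synonymous, nonsynonymous) differences between two codons over
    all mutational pathways; pathways passing through stop codons are
    excluded when any stop-free pathway exists."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if GENETIC_CODE[nxt] == "*":
                blocked = True
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, blocked))
    valid = [p for p in paths if not p[2]] or paths
    sd = sum(p[0] for p in valid) / len(valid)
    nd = sum(p[1] for p in valid) / len(valid)
    return sd, nd


def _jc(p: float) -> float:
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _pair_dnds(codons1: list[str], codons2: list[str],
               R: float) -> tuple[float, float]:
    S1 = sum(_syn_fraction(c, R) for c in codons1)
    S2 = sum(_syn_fraction(c, R) for c in codons2)
    S = 0.5 * (S1 + S2)
    N = 3 * len(codons1) - S
    sd = nd = 0.0
    for c1, c2 in zip(codons1, codons2):
        s, n = _pathway_counts(c1, c2)
        sd += s
        nd += n
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    return _jc(pN), _jc(pS)


_ALL_CODONS = ["".join(c) for c in itertools.product("TCAG", repeat=3)]
_CODON_INDEX = {c: i for i, c in enumerate(_ALL_CODONS)}


@functools.lru_cache(maxsize=8)
def _codon_tables(R: float):
    """Precomputed per-codon synonymous site fractions and per-pair pathway
    difference counts, indexed by codon number (0..63).  Stop codons get
    NaN site fractions; validated data never reaches them."""
    syn = np.full(64, np.nan)
    for c, i in _CODON_INDEX.items():
        if GENETIC_CODE[c] != "*":
            syn[i] = _syn_fraction(c, R)
    SD = np.zeros((64, 64))
    ND = np.zeros((64, 64))
    for c1, i in _CODON_INDEX.items():
        for c2, j in _CODON_INDEX.items():
            if GENETIC_CODE[c1] == "*" or GENETIC_CODE[c2] == "*":
                continue
            SD[i, j], ND[i, j] = _pathway_counts(c1, c2)
    return syn, SD, ND


def nei_gojobori_dn_ds(seqs: list[str], R: float = 1.0, n_boot: int = 1000,
                       seed: int | None = None) -> DnDsEstimate:
    """Average pairwise dN and dS for a codon alignment.

    ``seqs`` are equal-length, gap-free coding sequences whose length is a
    multiple of 3 in frame 0 (trim upstream).  Differences are pathway
    counted; site totals use the R-weighted fractions; both p-distances are
    Jukes-Cantor corrected per pair and averaged across all pairs.  Standard
    errors come from ``n_boot`` bootstrap resamples over codons.
    """
    if len(seqs) < 2:
        raise CodingDataError("need >= 2 sequences")
    if len({len(s) for s in seqs}) != 1 or len(seqs[0]) % 3:
        raise CodingDataError("sequences must share a length divisible by 3")
    codon_rows = [[s[i:i + 3] for i in range(0, len(s), 3)] for s in seqs]
    for row in codon_rows:
        for c in row:
            if GENETIC_CODE[c] == "*":
                raise CodingDataError(f"internal stop codon {c}")
    syn_tab, SD, ND = _codon_tables(R)
    # rows as codon-index arrays; all pair arithmetic via table lookups,
    # with per-pair per-codon difference vectors shared across bootstraps
    row_idx = np.array([[_CODON_INDEX[c] for c in row]
                        for row in codon_rows])
    n_seq, n_codons = row_idx.shape
    ai, bi = map(np.array, zip(
        *itertools.combinations(range(n_seq), 2)))
    pair_sd = SD[row_idx[ai], row_idx[bi]]   # (n_pairs, n_codons)
    pair_nd = ND[row_idx[ai], row_idx[bi]]
    row_syn = syn_tab[row_idx]               # (n_seq, n_codons)

    def estimate(sel: np.ndarray) -> tuple[float, float, bool]:
        syn_sums = row_syn[:, sel].sum(axis=1)
        S = 0.5 * (syn_sums[ai] + syn_sums[bi])
        N = 3.0 * sel.size - S
        sd = pair_sd[:, sel].sum(axis=1)
        nd = pair_nd[:, sel].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            pS = np.where(S > 0, sd / np.where(S > 0, S, 1.0), 0.0)
            pN = np.where(N > 0, nd / np.where(N > 0, N, 1.0), 0.0)
        ok = (pS < 0.75) & (pN < 0.75)
        if not ok.any():
            return math.nan, math.nan, True
        dn = -0.75 * np.log(1.0 - 4.0 * pN[ok] / 3.0)
        ds = -0.75 * np.log(1.0 - 4.0 * pS[ok] / 3.0)
        return float(dn.mean()), float(ds.mean()), bool((~ok).any())

    all_codons = np.arange(n_codons)
    dN, dS, undef = estimate(all_codons)
    rng = np.random.default_rng(seed)
    boot_dn, boot_ds = [], []
    for _ in range(n_boot):
        bn, bs, _ = estimate(rng.integers(0, n_codons, size=n_codons))
        boot_dn.append(bn)
        boot_ds.append(bs)
    se_dn = float(np.nanstd(boot_dn, ddof=1)) if n_boot > 1 else math.nan
    se_ds = float(np.nanstd(boot_ds, ddof=1)) if n_boot > 1 else math.nan
    return DnDsEstimate(dN=dN, dS=dS, se_dN=se_dn, se_dS=se_ds, R=R,
                        jc_undefined=undef)


# ---------------------------------------------------------------------------
# nonparametric tests
# ---------------------------------------------------------------------------

class NoInformativePairsError(ValueError):
    pass


def _signed_rank_distribution(ranks2: list[int]) -> np.ndarray:
    """Exact null distribution of 2*W+ over all sign assignments.

    ``ranks2`` are the doubled midranks (integers); returns counts indexed by
    the doubled positive-rank sum.
    """
    total = sum(ranks2)
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    return counts


def paired_wilcoxon(x, y, alternative: str = "two-sided",
                    exact_max_n: int = 25) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired per-locus estimates.

    Zero differences are discarded (Wilcoxon's original convention); ties get
    midranks.  The tail is exact (full sign-assignment distribution) for up
    to ``exact_max_n`` informative pairs and a continuity-corrected normal
    approximation beyond.  Returns (W+, P).  ``alternative`` 'greater' tests
    for x > y.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise NoInformativePairsError("no nonzero paired differences")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = n * (n + 1) / 2
    if n <= exact_max_n:
        ranks2 = [int(round(2 * r)) for r in ranks]
        dist = _signed_rank_distribution(ranks2)
        m = dist.sum()
        w2 = int(round(2 * w_plus))
        p_ge = dist[w2:].sum() / m
        p_le = dist[:w2 + 1].sum() / m
    else:
        mu = total / 2
        tie_term = (np.bincount(np.int64(2 * ranks)) ** 3).sum() / 96.0
        sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24 - tie_term)
        p_ge = stats.norm.sf((w_plus - 0.5 - mu) / sigma)
        p_le = stats.norm.cdf((w_plus + 0.5 - mu) / sigma)
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2 * min(p_ge, p_le))
    return w_plus, float(p)


def paired_wilcoxon_dnds(values_mw, values_md,
                         alternative: str = "two-sided") -> tuple[float, float]:
    """Paired test of per-locus dN/dS-type estimates, MD vs MW.

    'greater' tests whether the domesticated estimates exceed the wild ones.
    """
    return paired_wilcoxon(values_md, values_mw, alternative=alternative)


def ranksum_diversity_test(values_mw, values_md,
                           alternative: str = "two-sided",
                           exact_max_comb: int = 200_000) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum test on independent per-locus estimates
    (equivalent to a two-group Kruskal-Wallis).

    Exact P by enumeration of all group assignments when C(n+m, n) is small
    enough; otherwise the tie-corrected normal approximation with continuity
    correction.  Returns (rank sum of the first sample, P).
    """
    x = np.asarray(values_mw, dtype=float)
    y = np.asarray(values_md, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n].sum())
    mu = n * (n + m + 1) / 2
    if math.comb(n + m, n) <= exact_max_comb:
        devs = []
        for comb in itertools.combinations(range(n + m), n):
            devs.append(abs(ranks[list(comb)].sum() - mu))
        devs = np.asarray(devs)
        obs_dev = abs(w - mu)
        if alternative == "two-sided":
            p = float((devs >= obs_dev - 1e-9).mean())
        else:
            sums = devs  # recompute signed sums for one-sided tails
            sums = np.asarray([
                ranks[list(c)].sum()
                for c in itertools.combinations(range(n + m), n)])
            if alternative == "greater":
                p = float((sums >= w - 1e-9).mean())
            else:
                p = float((sums <= w + 1e-9).mean())
    else:
        tie_counts = np.unique(ranks, return_counts=True)[1]
        N = n + m
        tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (N * (N - 1))
        sigma = math.sqrt(n * m / 12 * (N + 1 - tie_term))
        if sigma == 0:
            return w, 1.0
        if alternative == "greater":
            p = float(stats.norm.sf((w - 0.5 - mu) / sigma))
        elif alternative == "less":
            p = float(stats.norm.cdf((w + 0.5 - mu) / sigma))
        else:
            z = (abs(w - mu) - 0.5) / sigma
            p = float(2 * stats.norm.sf(z))
    return w, min(1.0, p)


def binomial_private_coding_test(partition: PolymorphismPartition | dict,
                                 null_mode: str = "raw_count") -> float:
    """One-sided binomial test for an excess of domesticated-private
    mutations in coding regions.

    X ~ Binomial(n, p0) with n = total private-MD mutations (coding +
    noncoding) and the observed count the coding ones.  Under 'raw_count'
    p0 is the coding fraction of the private-MW mutations (the null stated
    with the published P value); under 'length_standardized' p0 is the
    coding share of the per-bp private-MW mutation rates, i.e. both
    categories are first standardized by their region lengths.
    """
    if isinstance(partition, PolymorphismPartition):
        pw_c = partition.by_region["coding"].private_wild
        pw_n = partition.by_region["noncoding"].private_wild
        pd_c = partition.by_region["coding"].private_dom
        pd_n = partition.by_region["noncoding"].private_dom
        lengths = partition.region_lengths
    else:
        pw_c, pw_n = partition["private_wild_coding"], partition["private_wild_noncoding"]
        pd_c, pd_n = partition["private_dom_coding"], partition["private_dom_noncoding"]
        lengths = partition.get("region_lengths", {})
    n_trials = pd_c + pd_n
    if n_trials < 1:
        raise ValueError("no private domesticated mutations to test")
    if null_mode == "raw_count":
        denom = pw_c + pw_n
        if denom == 0:
            raise ValueError("p0 undefined: no private wild mutations")
        p0 = pw_c / denom
    elif null_mode == "length_standardized":
        Lc, Ln = lengths.get("coding"), lengths.get("noncoding")
        if not Lc or not Ln:
            raise ValueError("region lengths required for standardization")
        rate_c, rate_n = pw_c / Lc, pw_n / Ln
        if rate_c + rate_n == 0:
            raise ValueError("p0 undefined: zero private-wild rates")
        p0 = rate_c / (rate_c + rate_n)
    else:
        raise ValueError(f"unknown null_mode {null_mode!r}")
    return float(stats.binom.sf(pd_c - 1, n_trials, p0))
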