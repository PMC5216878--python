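"""Per-locus, per-region diversity estimators and loss-of-diversity statistics.

Implements the standard per-locus summaries for haploid sequence panels:
variable sites V, total mutations eta (k-1 alleles per variable site),
singletons S, parsimony-informative sites Pi, haplotype number H and
diversity Hd (Nei's unbiased estimator), nucleotide diversity pi (Tajima) and
Watterson's theta, all restricted to usable (gap/N-free) columns.  The
loss-of-diversity statistic for a domesticated vs wild contrast is
L = 1 - (d/w), computed either from across-locus mean estimates or averaged
over per-locus losses.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqdata import (
    Dataset,
    EmptyRegionError,
    LocusAlignment,
    NONCODING_CLASSES,
    PopulationLabel,
    SiteMask,
    slice_region,
    usable_sites,
)

BASES = (b"A", b"C", b"G", b"T")


class UndefinedStatisticError(ValueError):
    """Statistic has no value on this input (e.g. zero usable sites)."""


@dataclass(frozen=True)
class SiteCounts:
    V: int        # variable sites
    eta: int      # total mutations: sum over variable sites of (alleles - 1)
    S: int        # singleton variable sites
    Pi_sites: int # parsimony-informative sites

    def __post_init__(self):
        if not (0 <= self.S + self.Pi_sites <= self.V <= self.eta):
            raise ValueError(f"inconsistent site counts {self}")


@dataclass(frozen=True)
class DiversityEstimates:
    n: int
    L: int
    counts: SiteCounts
    H: int
    Hd: float
    pi: float
    thetaW: float

    @property
    def snp_freq(self) -> float:
        return self.counts.V / self.L if self.L else 0.0


@dataclass(frozen=True)
class LossOfDiversity:
    L_mean: float          # from across-locus mean estimates
    L_per_locus: float     # mean of per-locus 1 - d_i/w_i
    n_loci: int
    n_excluded: int        # loci with wild estimate 0, excluded from L_per_locus


def _usable_array(aln: LocusAlignment, mask: SiteMask | None) -> np.ndarray:
    arr = aln.to_array()
    if mask is None:
        mask = usable_sites(aln)
    return arr[:, mask.usable]


def _allele_counts(col: np.ndarray) -> list[int]:
    return sorted(Counter(col.tobytes().decode()).values(), reverse=True)


def site_counts(aln: LocusAlignment, mask: SiteMask | None = None) -> SiteCounts:
    """Tabulate V, eta, S and Pi over usable columns.

    A variable site is a singleton iff every non-major allele occurs exactly
    once (so tri-allelic sites with two lone minor alleles count as
    singleton-variable, consistently for every population).
    """
    if aln.n < 2:
        raise UndefinedStatisticError("site counts need n >= 2")
    arr = _usable_array(aln, mask)
    V = eta = S = Pi = 0
    for j in range(arr.shape[1]):
        counts = _allele_counts(arr[:, j])
        k = len(counts)
        if k < 2:
            continue
        V += 1
        eta += k - 1
        if all(c == 1 for c in counts[1:]):
            S += 1
        if sum(c >= 2 for c in counts) >= 2:
            Pi += 1
    return SiteCounts(V, eta, S, Pi)


def nucleotide_diversity(aln: LocusAlignment,
                         mask: SiteMask | None = None) -> float:
    """Tajima's estimator: mean pairwise differences per usable site."""
    if aln.n < 2:
        raise UndefinedStatisticError("pi needs n >= 2")
    arr = _usable_array(aln, mask)
    n, L = arr.shape
    if L == 0:
        raise UndefinedStatisticError("pi undefined with zero usable sites")
    diffs = 0
    for i in range(n):
        for j in range(i + 1, n):
            diffs += int((arr[i] != arr[j]).sum())
    return diffs / (n * (n - 1) / 2) / L


def harmonic_number(n: int) -> float:
    return float(sum(1.0 / i for i in range(1, n)))


def watterson_theta(aln: LocusAlignment, mask: SiteMask | None = None,
                    use_eta: bool = False) -> float:
    """Watterson's estimator per site, from segregating sites by default or
    from eta (total mutations) when ``use_eta`` is set."""
    if aln.n < 2:
        raise UndefinedStatisticError("theta needs n >= 2")
    arr = _usable_array(aln, mask)
    n, L = arr.shape
    if L == 0:
        raise UndefinedStatisticError("theta undefined with zero usable sites")
    counts = site_counts(aln, mask)
    s = counts.eta if use_eta else counts.V
    return s / harmonic_number(n) / L


def haplotype_stats(aln: LocusAlignment,
                    mask: SiteMask | None = None) -> tuple[int, float]:
    """Haplotype count H and Nei's unbiased haplotype diversity Hd."""
    if aln.n < 2:
        raise UndefinedStatisticError("haplotype stats need n >= 2")
    arr = _usable_array(aln, mask)
    n = arr.shape[0]
    haps = Counter(arr[i].tobytes() for i in range(n))
    H = len(haps)
    freqs = np.array(list(haps.values())) / n
    Hd = n / (n - 1) * (1.0 - float((freqs ** 2).sum()))
    return H, Hd


def diversity_estimates(aln: LocusAlignment,
                        mask: SiteMask | None = None,
                        use_eta: bool = False) -> DiversityEstimates:
    if mask is None:
        mask = usable_sites(aln)
    counts = site_counts(aln, mask)
    H, Hd = haplotype_stats(aln, mask)
    L = mask.n_usable
    if L:
        pi = nucleotide_diversity(aln, mask)
        theta = watterson_theta(aln, mask, use_eta=use_eta)
    else:
        pi = theta = 0.0
    return DiversityEstimates(n=aln.n, L=L, counts=counts, H=H, Hd=Hd,
                              pi=pi, thetaW=theta)


def loss_of_diversity(stat_wild: Sequence[float],
                      stat_dom: Sequence[float]) -> LossOfDiversity:
    """L = 1 - (domesticated / wild), from the means and per locus.

    Per-locus losses skip loci where the wild estimate is zero (undefined
    ratio); mean-based L keeps every locus, since monomorphic loci contribute
    zero to both means.
    """
    w = np.asarray(stat_wild, dtype=float)
    d = np.asarray(stat_dom, dtype=float)
    if w.shape != d.shape:
        raise ValueError("per-locus vectors must align")
    if not np.any(w > 0):
        raise UndefinedStatisticError("all wild estimates are zero")
    L_mean = 1.0 - d.mean() / w.mean()
    ok = w > 0
    per_locus = 1.0 - d[ok] / w[ok]
    return LossOfDiversity(
        L_mean=float(L_mean),
        L_per_locus=float(per_locus.mean()),
        n_loci=len(w),
        n_excluded=int((~ok).sum()),
    )


REGION_SELECTIONS = {
    "whole": None,
    "coding": frozenset({"exon"}),
    "noncoding": NONCODING_CLASSES,
}


def region_alignment(dataset: Dataset, aln: LocusAlignment,
                     region: str) -> LocusAlignment:
    """The locus restricted to a named region selection.

    ``whole`` returns the full alignment.  For ``coding``/``noncoding`` the
    locus must have an annotation containing the requested classes, else an
    :class:`EmptyRegionError` propagates (the "/" cells of the reports).
    """
    classes = REGION_SELECTIONS[region]
    if classes is None:
        return aln
    ann = dataset.annotations.get(aln.locus_id)
    if ann is None:
        raise EmptyRegionError(f"{aln.locus_id}: no annotation")
    return slice_region(aln, ann, classes)


def summarize_dataset(dataset: Dataset, region: str,
                      label: PopulationLabel,
                      use_eta: bool = False) -> pd.DataFrame:
    """Per-locus diversity table for one population and region selection.

    The footer row (locus = "overall") aggregates the way the study's summary
    table does: means for n, H, Hd, pi, theta; sums for L, V, eta, S, Pi; and
    SNP frequency as sum(V)/sum(L).
    """
    from .codon_partition import count_syn_nonsyn  # late: avoids cycle

    rows = []
    for aln in dataset.loci:
        try:
            reg = region_alignment(dataset, aln, region)
        except EmptyRegionError:
            continue
        pop = dataset.population(reg, label)
        if pop.n < 2:
            continue
        est = diversity_estimates(pop, use_eta=use_eta)
        syn = nonsyn = np.nan
        if region == "coding":
            ann = dataset.annotations[aln.locus_id]
            syn, nonsyn = count_syn_nonsyn(pop, ann.frame_offset)
        rows.append({
            "locus": aln.locus_id, "region": region, "n": est.n, "L": est.L,
            "V": est.counts.V, "eta": est.counts.eta, "S": est.counts.S,
            "Pi": est.counts.Pi_sites, "Syn": syn, "Nonsyn": nonsyn,
            "H": est.H, "Hd": est.Hd,
            "pi": est.pi, "thetaW": est.thetaW, "snp_freq": est.snp_freq,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    sumL, sumV = df["L"].sum(), df["V"].sum()
    footer = {
        "locus": "overall", "region": region,
        "n": df["n"].mean(), "L": sumL,
        "V": sumV, "eta": df["eta"].sum(), "S": df["S"].sum(),
        "Pi": df["Pi"].sum(),
        "Syn": df["Syn"].sum() if region == "coding" else np.nan,
        "Nonsyn": df["Nonsyn"].sum() if region == "coding" else np.nan,
        "H": df["H"].mean(), "Hd": df["Hd"].mean(),
        "pi": df["pi"].mean(), "thetaW": df["thetaW"].mean(),
        "snp_freq": sumV / sumL if sumL else 0.0,
    }
    return pd.concat([df, pd.DataFrame([footer])], ignore_index=True)
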