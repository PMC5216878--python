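"""Population differentiation: Hudson FST with permutation tests and
two-level AMOVA (Phi_ST).

Hudson's FST is 1 - Hw/Hb where Hw is the mean within-population pairwise
difference per site (the two populations weighted equally) and Hb the mean
between-population pairwise difference per site.  Values can be slightly
negative by sampling noise and are reported as computed.  AMOVA decomposes
the molecular variance of pairwise haplotype differences into among- and
within-population components (Excoffier's framework, haplotypic distance =
number of pairwise differences); Phi_ST = among / (among + within).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqdata import LocusAlignment, SiteMask, usable_sites


class UndefinedFstError(ValueError):
    """FST has no value here (pooled data monomorphic): the "na" cells."""


def pairwise_difference_matrix(arr: np.ndarray) -> np.ndarray:
    """Full n x n matrix of pairwise mismatch counts between rows."""
    n = arr.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        D[i, i + 1:] = (arr[i + 1:] != arr[i]).sum(axis=1)
    return D + D.T


def _mean_within(D: np.ndarray, idx: np.ndarray) -> float:
    k = len(idx)
    if k < 2:
        raise UndefinedFstError("population needs >= 2 sequences")
    sub = D[np.ix_(idx, idx)]
    return float(sub.sum() / (k * (k - 1)))


def hudson_fst_from_matrix(D: np.ndarray, labels: np.ndarray) -> float:
    """Hudson FST from a pairwise difference matrix and binary labels."""
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two populations required")
    i1 = np.flatnonzero(labels == groups[0])
    i2 = np.flatnonzero(labels == groups[1])
    hw = 0.5 * (_mean_within(D, i1) + _mean_within(D, i2))
    hb = float(D[np.ix_(i1, i2)].mean())
    if hb == 0.0:
        raise UndefinedFstError("no between-population differences")
    return 1.0 - hw / hb


def hudson_fst(aln_pop1: LocusAlignment, aln_pop2: LocusAlignment,
               mask: SiteMask | None = None) -> float:
    """Hudson FST between two populations of one locus.

    The usable-site mask is computed over the union of the two populations
    unless supplied.  Monomorphic pooled data raise
    :class:`UndefinedFstError`.
    """
    if set(aln_pop1.accessions) & set(aln_pop2.accessions):
        raise ValueError("populations share accessions")
    pooled = LocusAlignment(
        aln_pop1.locus_id, {**dict(aln_pop1.rows), **dict(aln_pop2.rows)})
    if mask is None:
        mask = usable_sites(pooled)
    arr = pooled.to_array()[:, mask.usable]
    labels = np.array([0] * aln_pop1.n + [1] * aln_pop2.n)
    D = pairwise_difference_matrix(arr)
    if D.sum() == 0:
        raise UndefinedFstError("pooled alignment monomorphic")
    return hudson_fst_from_matrix(D, labels)


def fst_permutation_test(aln_pop1: LocusAlignment, aln_pop2: LocusAlignment,
                         n_perm: int = 1000, seed: int | None = None,
                         mask: SiteMask | None = None) -> tuple[float, float]:
    """Permutation P for Hudson FST, shuffling population labels with fixed
    group sizes.  Uses the add-one estimator
    p = (1 + #{FST_perm >= FST_obs}) / (n_perm + 1)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pooled = LocusAlignment(
        aln_pop1.locus_id, {**dict(aln_pop1.rows), **dict(aln_pop2.rows)})
    if mask is None:
        mask = usable_sites(pooled)
    arr = pooled.to_array()[:, mask.usable]
    labels = np.array([0] * aln_pop1.n + [1] * aln_pop2.n)
    D = pairwise_difference_matrix(arr)
    if D.sum() == 0:
        raise UndefinedFstError("pooled alignment monomorphic")
    obs = hudson_fst_from_matrix(D, labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        try:
            f = hudson_fst_from_matrix(D, perm)
        except UndefinedFstError:
            # no between-group differences under this labelling: treat as
            # maximally undifferentiated, below any defined observed value
            f = -np.inf
        if f >= obs - 1e-12:
            exceed += 1
    return obs, (1 + exceed) / (n_perm + 1)


@dataclass(frozen=True)
class AmovaResult:
    sigma_among: float
    sigma_within: float
    phi_st: float
    p_perm: float | None = None


def _amova_components(D2: np.ndarray,
                      labels: np.ndarray) -> tuple[float, float]:
    """Variance components from squared distances (here: difference counts)."""
    N = len(labels)
    groups = [np.flatnonzero(labels == g) for g in np.unique(labels)]
    P = len(groups)
    if P < 2 or any(len(g) < 2 for g in groups):
        raise ValueError(">= 2 populations with >= 2 sequences each required")
    ss_total = D2.sum() / (2 * N)
    ss_within = sum(D2[np.ix_(g, g)].sum() / (2 * len(g)) for g in groups)
    ss_among = ss_total - ss_within
    df_among, df_within = P - 1, N - P
    sigma_within = ss_within / df_within
    n0 = (N - sum(len(g) ** 2 for g in groups) / N) / df_among
    sigma_among = (ss_among / df_among - sigma_within) / n0
    return sigma_among, sigma_within


def phi_st_from_matrix(D2: np.ndarray, labels: np.ndarray) -> float:
    a, w = _amova_components(D2, labels)
    total = a + w
    if total == 0:
        raise UndefinedFstError("no molecular variance")
    return a / total


def amova_two_level(arr: np.ndarray, labels: np.ndarray,
                    n_perm: int = 0, seed: int | None = None) -> AmovaResult:
    """Two-level AMOVA on a (sequences x sites) character array.

    Distances are pairwise difference counts (squared Euclidean on the
    haplotype mismatch indicator).  A permutation P (individuals shuffled
    among populations) is computed when ``n_perm`` > 0.
    """
    labels = np.asarray(labels)
    D2 = pairwise_difference_matrix(arr)
    if D2.sum() == 0:
        raise UndefinedFstError("all sequences identical")
    a, w = _amova_components(D2, labels)
    phi = a / (a + w)
    p = None
    if n_perm:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            try:
                if phi_st_from_matrix(D2, rng.permutation(labels)) >= phi - 1e-12:
                    exceed += 1
            except UndefinedFstError:
                pass
        p = (1 + exceed) / (n_perm + 1)
    return AmovaResult(sigma_among=a, sigma_within=w, phi_st=phi, p_perm=p)
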