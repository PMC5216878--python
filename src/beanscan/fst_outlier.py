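"""FST-outlier detection for biallelic SNP panels (FDIST-style).

Observed per-marker FST is compared, conditional on expected heterozygosity,
against quantile envelopes built from neutral island-model coalescent
simulations whose migration rate is solved so the simulated mean FST matches
a target (by default the observed multilocus mean).  Markers above the upper
envelope suggest directional selection, markers below the lower envelope
balancing selection.  A "forced mean" mode iteratively drops current
outliers, recomputes the target mean and re-simulates.

Per-locus FST is Hudson's estimator 1 - Hw/Hb computed from allele
frequencies (with the small-sample correction on the within-population
heterozygosities), for both the observed markers and the simulated cloud, so
the two live on one scale.  Each simulated locus carries a single mutation
placed uniformly at random on its coalescent tree (a biallelic rendering of
the infinite-alleles simulation scheme), which spreads the cloud over the
full heterozygosity range.
"""

from __future__ import annotations

from dataclasses import dataclass

import msprime
import numpy as np
import pandas as pd


class FilterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# SNP matrix filtering and per-marker statistics
# ---------------------------------------------------------------------------

def filter_snps(genotypes: pd.DataFrame, max_missing: float = 0.05,
                min_maf: float = 0.01) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop markers with too much missing data or a minor allele at or
    below the frequency threshold.

    ``genotypes`` is markers x individuals with entries 0/1/NaN (haploid
    coding).  Returns the filtered matrix and a per-marker exclusion report.
    Filtering is idempotent.
    """
    G = genotypes.astype(float)
    miss = G.isna().mean(axis=1)
    p = G.mean(axis=1, skipna=True)
    maf = np.minimum(p, 1 - p)
    report = pd.DataFrame({
        "missing_fraction": miss,
        "maf": maf,
        "excluded_missing": miss > max_missing,
        "excluded_maf": maf <= min_maf,
    })
    keep = ~(report.excluded_missing | report.excluded_maf)
    if not keep.any():
        raise FilterError("all markers removed by filters")
    return genotypes.loc[keep], report


def _hudson_fst_freqs(p1: float, n1: int, p2: float, n2: int) -> float:
    """Hudson FST from two population allele frequencies; NaN if the
    between-population diversity is zero."""
    hw1 = n1 / (n1 - 1) * 2 * p1 * (1 - p1)
    hw2 = n2 / (n2 - 1) * 2 * p2 * (1 - p2)
    hb = p1 * (1 - p2) + p2 * (1 - p1)
    if hb == 0:
        return np.nan
    return 1.0 - 0.5 * (hw1 + hw2) / hb


def marker_stats(genotypes: pd.DataFrame,
                 populations: pd.Series) -> pd.DataFrame:
    """Per-marker expected heterozygosity and Hudson FST for a two-
    population panel.  ``populations`` maps individual -> label (exactly two
    labels)."""
    labels = populations.loc[genotypes.columns]
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError("exactly two populations required")
    rows = []
    for marker, row in genotypes.iterrows():
        stats = {}
        for g in groups:
            vals = row[labels[labels == g].index].dropna()
            stats[g] = (float(vals.mean()), int(len(vals)))
        (p1, n1), (p2, n2) = stats[groups[0]], stats[groups[1]]
        if min(n1, n2) < 2:
            continue
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        rows.append({
            "marker": marker,
            "He": 2 * pbar * (1 - pbar),
            "fst": _hudson_fst_freqs(p1, n1, p2, n2),
        })
    return pd.DataFrame(rows).set_index("marker")


# ---------------------------------------------------------------------------
# neutral island-model cloud
# ---------------------------------------------------------------------------

def solve_migration_rate(target_fst: float, demes: int,
                         deme_size: float) -> float:
    """Migration rate giving expected Hudson FST = target in a symmetric
    island model of haploid demes.

    From the coalescent expectations T_within = d*N and
    T_between = d*N + (d-1)/(2m): FST = 1/(1 + 2*m*d*N/(d-1)).
    """
    if not (0 < target_fst < 1):
        raise ValueError("target mean FST must be in (0, 1)")
    return (demes - 1) * (1 - target_fst) / (2 * demes * deme_size
                                             * target_fst)


def expected_island_fst(m: float, demes: int, deme_size: float) -> float:
    return 1.0 / (1.0 + 2 * m * demes * deme_size / (demes - 1))


def simulate_fdist_cloud(n_sims: int = 50_000, demes: int = 20,
                         sample_sizes: tuple[int, int] = (19, 20),
                         target_fst: float = 0.16,
                         deme_size: float = 50.0,
                         seed: int | None = None,
                         calibrate: bool = True,
                         pilot_sims: int = 2_000) -> pd.DataFrame:
    """Simulate the neutral (He, FST) cloud.

    Each locus is one non-recombining coalescent tree from the island model
    with two sampled demes; a single mutation is dropped uniformly on the
    tree (resampled if it fixes in the sample), and He and Hudson FST are
    recorded.  The migration rate is first solved from the island-model
    coalescent expectation and then (``calibrate``) adjusted with a pilot
    run so the realized mean of the per-locus estimator hits the target
    (the mean of single-SNP FST ratios sits below the time-ratio
    parametric value).  Deterministic under ``seed``.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if not (0 < target_fst < 1):
        raise ValueError("target mean FST must be in (0, 1)")
    # the island-model cost per replicate scales as (1-F)/F: near-panmictic
    # targets are clamped to a practical floor (their envelopes are
    # indistinguishable in the sampled statistic anyway)
    target_fst = min(max(target_fst, 0.02), 0.95)
    rng = np.random.default_rng(seed)
    m_cap = solve_migration_rate(0.02, demes, deme_size)
    m = solve_migration_rate(target_fst, demes, deme_size)
    if calibrate and n_sims > pilot_sims:
        for _ in range(3):
            pilot = _simulate_cloud_at(m, pilot_sims, demes, sample_sizes,
                                       deme_size, rng)
            realized = float(pilot.fst.mean())
            realized = min(max(realized, 1e-3), 1 - 1e-3)
            if abs(realized - target_fst) < 0.01 * target_fst:
                break
            # one-parameter response model mean_fst(m) = 1/(1 + beta*m)
            beta = (1.0 / realized - 1.0) / m
            m = min((1.0 / target_fst - 1.0) / beta, m_cap)
    return _simulate_cloud_at(m, n_sims, demes, sample_sizes, deme_size, rng)


def _simulate_cloud_at(m: float, n_sims: int, demes: int,
                       sample_sizes: tuple[int, int], deme_size: float,
                       rng: np.random.Generator) -> pd.DataFrame:
    demography = msprime.Demography.island_model(
        [deme_size] * demes, migration_rate=m / (demes - 1))
    n1, n2 = sample_sizes
    reps = msprime.sim_ancestry(
        samples={0: n1, 1: n2}, demography=demography, ploidy=1,
        num_replicates=n_sims, random_seed=int(rng.integers(1, 2 ** 31 - 1)))
    he, fst = [], []
    ntot = n1 + n2
    for ts in reps:
        tree = ts.first()
        nodes = [u for u in tree.nodes() if tree.parent(u) != -1]
        lengths = np.array([tree.branch_length(u) for u in nodes])
        cum = np.cumsum(lengths)
        for _ in range(100):
            u = nodes[int(np.searchsorted(cum, rng.uniform(0, cum[-1])))]
            samples = list(tree.samples(u))
            if 0 < len(samples) < ntot:
                break
        else:
            continue  # tree shape leaves no polymorphic branch choice
        d1 = sum(s < n1 for s in samples)
        d2 = len(samples) - d1
        p1, p2 = d1 / n1, d2 / n2
        pbar = len(samples) / ntot
        he.append(2 * pbar * (1 - pbar))
        fst.append(_hudson_fst_freqs(p1, n1, p2, n2))
    return pd.DataFrame({"He": he, "fst": fst}).dropna()


def cloud_mean_fst(cloud: pd.DataFrame) -> float:
    """Multilocus mean as the across-loci ratio estimator implied by
    averaging the Hudson numerator and denominator separately is not
    recoverable from (He, FST) pairs; the simple mean of defined per-locus
    values is used for both cloud and data."""
    return float(cloud["fst"].mean())


# ---------------------------------------------------------------------------
# envelope and classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Envelope:
    bin_centers: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    he_min: float
    he_max: float
    #: with ci = 1.0 the envelope must enclose the whole cloud, so bounds
    #: take the extremes of the two neighbouring bins instead of an
    #: interpolated (possibly cloud-crossing) line
    conservative: bool = False

    def bounds_at(self, he: float) -> tuple[float, float]:
        if self.conservative:
            j = int(np.searchsorted(self.bin_centers, he))
            near = slice(max(j - 1, 0), min(j + 1, len(self.bin_centers)))
            return float(self.lower[near].min()), float(self.upper[near].max())
        lo = float(np.interp(he, self.bin_centers, self.lower))
        hi = float(np.interp(he, self.bin_centers, self.upper))
        return lo, hi


def envelope_from_cloud(cloud: pd.DataFrame, ci: float = 0.99,
                        n_bins: int = 20) -> Envelope:
    """Quantile envelope of the cloud, conditional on He.

    The cloud is split into ``n_bins`` equal-count He bins; per-bin
    empirical FST quantiles at (1-ci)/2 and 1-(1-ci)/2 are interpolated
    linearly across bin median He values."""
    if not (0 < ci <= 1):
        raise ValueError("ci must be in (0, 1]")
    df = cloud.sort_values("He").reset_index(drop=True)
    alpha = (1 - ci) / 2
    bins = np.array_split(np.arange(len(df)), n_bins)
    centers, lower, upper = [], [], []
    for idx in bins:
        if len(idx) == 0:
            continue
        sub = df.iloc[idx]
        centers.append(float(sub.He.median()))
        if ci == 1.0:
            lower.append(float(sub.fst.min()))
            upper.append(float(sub.fst.max()))
        else:
            lower.append(float(sub.fst.quantile(alpha)))
            upper.append(float(sub.fst.quantile(1 - alpha)))
    return Envelope(np.array(centers), np.array(lower), np.array(upper),
                    he_min=float(df.He.min()), he_max=float(df.He.max()),
                    conservative=(ci == 1.0))


def classify_markers(stats: pd.DataFrame, cloud: pd.DataFrame,
                     ci: float = 0.99, n_bins: int = 20,
                     tol: float = 1e-9) -> pd.DataFrame:
    """Classify markers against the cloud envelope.

    ``tol`` guards the envelope comparison: SNP panels take the same
    discrete (He, FST) values as the simulated cloud, and a marker exactly
    on the quantile boundary is neutral, not an outlier.
    """
    env = envelope_from_cloud(cloud, ci=ci, n_bins=n_bins)
    out = stats.copy()
    classes, lowers, uppers = [], [], []
    for _, row in stats.iterrows():
        if not (env.he_min <= row.He <= env.he_max):
            classes.append("unclassified")
            lowers.append(np.nan)
            uppers.append(np.nan)
            continue
        lo, hi = env.bounds_at(row.He)
        lowers.append(lo)
        uppers.append(hi)
        if np.isnan(row.fst):
            classes.append("unclassified")
        elif row.fst > hi + tol:
            classes.append("directional")
        elif row.fst < lo - tol:
            classes.append("balancing")
        else:
            classes.append("neutral")
    out["lower"], out["upper"], out["class"] = lowers, uppers, classes
    return out


def envelope_and_classify(stats: pd.DataFrame, cloud: pd.DataFrame,
                          ci: float = 0.99, forced_mean: bool = False,
                          n_bins: int = 20, max_iter: int = 5,
                          n_sims: int | None = None,
                          demes: int = 100, deme_size: float = 50.0,
                          sample_sizes: tuple[int, int] = (19, 20),
                          seed: int | None = None) -> pd.DataFrame:
    """Classify markers against the neutral envelope.

    With ``forced_mean`` the test iterates: drop current outliers,
    recompute the multilocus mean FST from the remainder, re-simulate a
    cloud at that target and reclassify, until the outlier set stabilizes
    or ``max_iter`` is reached.
    """
    result = classify_markers(stats, cloud, ci=ci, n_bins=n_bins)
    if not forced_mean:
        return result
    rng = np.random.default_rng(seed)
    n_sims = n_sims or len(cloud)
    prev_outliers: set | None = None
    for _ in range(max_iter):
        outliers = set(result.index[result["class"].isin(
            ["directional", "balancing"])])
        if outliers == prev_outliers:
            break
        prev_outliers = outliers
        neutral_mean = float(
            result.loc[~result.index.isin(outliers), "fst"].mean())
        neutral_mean = min(max(neutral_mean, 1e-3), 1 - 1e-3)
        cloud = simulate_fdist_cloud(
            n_sims=n_sims, demes=demes, sample_sizes=sample_sizes,
            target_fst=neutral_mean, deme_size=deme_size,
            seed=int(rng.integers(1, 2 ** 31 - 1)))
        result = classify_markers(stats, cloud, ci=ci, n_bins=n_bins)
    return result
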