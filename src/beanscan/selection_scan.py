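"""Composite selection index, coalescent null distributions under
domestication demography, empirical p-values and FDR calling.

The scan contrasts the wild (MW) and domesticated (MD) Mesoamerican
populations fragment by fragment.  For each polymorphic exonic or intronic
fragment three statistics are computed: a molecular FST (the AMOVA Phi
between the two populations), the branch-length statistic -ln(1 - FST), and
the standardized diversity difference (pi_w - pi_d)/(pi_w + pi_d).  Each is
z-scored with normalization constants estimated from the observed fragment
panel, and their sum is the selection index.  The null distribution of the
index comes from neutral coalescent simulations under an explicit
domestication demography (two- or four-population), with fragment lengths
resampled from the observed length distribution and class-specific mutation
rates (intron mean 1e-8 /site/generation, exons 10-fold lower).  Empirical
p-values are the fraction of simulated indices larger than the observed one,
corrected by Benjamini-Hochberg; fragments with q < FDR are flagged.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import msprime
import numpy as np
import pandas as pd

from .differentiation import (
    UndefinedFstError,
    pairwise_difference_matrix,
    phi_st_from_matrix,
)
from .seqdata import (
    Dataset,
    EmptyRegionError,
    LocusAlignment,
    NONCODING_CLASSES,
    PopulationLabel,
    slice_region,
    usable_sites,
)

FRAGMENT_CLASSES = ("exonic", "intronic")

#: Mean mutation rates per site per generation by fragment class.
DEFAULT_MU = {"intronic": 1.0e-8, "exonic": 1.0e-9}

_EPS = 1e-9


class MonomorphicFragmentError(ValueError):
    """Pooled fragment carries no polymorphism; excluded from the scan."""


# ---------------------------------------------------------------------------
# demographic models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DemographicModel:
    """Domestication demography for the Mesoamerican/Andean gene pools.

    Times are in generations before present (annual crop: one generation per
    year); sizes are haploid effective population sizes; bottleneck
    intensities I are the bottleneck size as a percent of the pre-bottleneck
    wild size, applied over the corresponding domestication window;
    migration rates are per-lineage per-generation fractions.

    ``model_id`` 1 places the Andean founder bottleneck recently and keeps
    wild sizes constant; 2 places it just after the Mesoamerica/Andes split
    and lets the wild populations grow exponentially to their present sizes.
    """

    model_id: int = 1
    # times (generations, backward from present)
    T_ANC: float = 100_000.0
    T_BAB: float = 40_000.0
    T_EAB: float = 30_000.0
    T_BMD: float = 8_000.0
    T_BAD: float = 8_000.0
    T_EMD: float = 6_000.0
    T_EAD: float = 6_000.0
    # sizes (haploid)
    N_ANC: float = 250_000.0
    N_BA: float = 5_000.0
    N_MWANC: float = 250_000.0
    N_AWANC: float = 100_000.0
    N_MD: float = 200_000.0
    N_MW: float = 250_000.0
    N_AW: float = 100_000.0
    N_AD: float = 80_000.0
    # bottleneck intensities (percent of the pre-bottleneck wild size)
    I_MD: float = 0.2
    I_AD: float = 0.2
    # migration rates (M_WD: wild-to-domesticated introgression, forward
    # in time; lineage escape from MD into MW backward in time)
    M_WD: float = 5.0e-5
    M_DW: float = 0.0
    M_MWAW: float = 0.0
    M_AWMW: float = 0.0

    def validate(self) -> None:
        if self.model_id not in (1, 2):
            raise ValueError("model_id must be 1 or 2")
        for name in ("T_ANC", "T_BAB", "T_EAB", "T_BMD", "T_BAD",
                     "T_EMD", "T_EAD"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (self.T_EMD < self.T_BMD <= self.T_ANC):
            raise ValueError("need T_EMD < T_BMD <= T_ANC")
        if not (self.T_EAD < self.T_BAD <= self.T_ANC):
            raise ValueError("need T_EAD < T_BAD <= T_ANC")
        if not (self.T_EAB < self.T_BAB <= self.T_ANC):
            raise ValueError("need T_EAB < T_BAB <= T_ANC")
        for name in ("N_ANC", "N_BA", "N_MWANC", "N_AWANC", "N_MD", "N_MW",
                     "N_AW", "N_AD"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("I_MD", "I_AD"):
            v = getattr(self, name)
            if not (0 < v <= 100):
                raise ValueError(f"{name} must be in (0, 100]")
        for name in ("M_WD", "M_DW", "M_MWAW", "M_AWMW"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def bottleneck_size_md(self) -> float:
        return self.I_MD / 100.0 * self.N_MWANC

    @property
    def bottleneck_size_ad(self) -> float:
        return self.I_AD / 100.0 * self.N_AWANC

    def replace(self, **kw) -> "DemographicModel":
        return dataclasses.replace(self, **kw)

    # -- msprime translation ------------------------------------------------

    def to_demography(self, two_population: bool = True) -> msprime.Demography:
        """Build the msprime demography (backward in time).

        ``two_population`` keeps only MW and MD (the contrast the scan
        tests); the full four-population topology adds the Andean wild and
        domesticated populations with their founder bottleneck.
        """
        self.validate()
        d = msprime.Demography()
        growth = 0.0
        if self.model_id == 2 and self.N_MW != self.N_MWANC:
            growth = math.log(self.N_MW / self.N_MWANC) / self.T_BMD
        d.add_population(name="MW", initial_size=self.N_MW,
                         growth_rate=growth)
        d.add_population(name="MD", initial_size=self.N_MD)
        if not two_population:
            aw_growth = 0.0
            if self.model_id == 2 and self.N_AW != self.N_AWANC:
                aw_growth = math.log(self.N_AW / self.N_AWANC) / self.T_BAD
            d.add_population(name="AW", initial_size=self.N_AW,
                             growth_rate=aw_growth)
            d.add_population(name="AD", initial_size=self.N_AD)
        if self.M_DW:
            d.set_migration_rate(source="MW", dest="MD", rate=self.M_DW)
        if self.M_WD:
            d.set_migration_rate(source="MD", dest="MW", rate=self.M_WD)

        # Mesoamerican domestication: bottleneck between T_EMD and T_BMD,
        # then merge into the wild population.
        d.add_population_parameters_change(
            time=self.T_EMD, population="MD",
            initial_size=self.bottleneck_size_md, growth_rate=0)
        d.add_mass_migration(time=self.T_BMD, source="MD", dest="MW",
                             proportion=1.0)
        d.add_population_parameters_change(
            time=self.T_BMD, population="MW", initial_size=self.N_MWANC,
            growth_rate=0)

        if not two_population:
            if self.M_AWMW:
                d.set_migration_rate(source="MW", dest="AW", rate=self.M_AWMW)
            if self.M_MWAW:
                d.set_migration_rate(source="AW", dest="MW", rate=self.M_MWAW)
            d.add_population_parameters_change(
                time=self.T_EAD, population="AD",
                initial_size=self.bottleneck_size_ad, growth_rate=0)
            d.add_mass_migration(time=self.T_BAD, source="AD", dest="AW",
                                 proportion=1.0)
            d.add_population_parameters_change(
                time=self.T_BAD, population="AW", initial_size=self.N_AWANC,
                growth_rate=0)
            # Andean founder bottleneck window
            d.add_population_parameters_change(
                time=self.T_EAB, population="AW", initial_size=self.N_BA)
            d.add_population_parameters_change(
                time=self.T_BAB, population="AW", initial_size=self.N_AWANC)
            d.add_mass_migration(time=self.T_ANC, source="AW", dest="MW",
                                 proportion=1.0)
        d.add_population_parameters_change(
            time=self.T_ANC, population="MW", initial_size=self.N_ANC)
        d.sort_events()
        return d


def model1(**kw) -> DemographicModel:
    return DemographicModel(model_id=1, **kw)


def model2(**kw) -> DemographicModel:
    return DemographicModel(model_id=2, **kw)


# ---------------------------------------------------------------------------
# parameter priors (reconstruction; the originals are not published)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    family: str            # 'fixed' | 'uniform' | 'loguniform'
    lo: float
    hi: float = float("nan")

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "fixed":
            return self.lo
        if self.family == "uniform":
            return float(rng.uniform(self.lo, self.hi))
        if self.family == "loguniform":
            return float(np.exp(rng.uniform(np.log(self.lo), np.log(self.hi))))
        raise ValueError(f"unknown prior family {self.family!r}")


@dataclass
class ParameterPriors:
    """Per-parameter priors plus class-specific mutation-rate priors.

    The shipped defaults are *reconstructions* (wide uniform/log-uniform
    ranges around literature-scale values); validation-grade runs use a
    fixed, known model instead.
    """

    demography: dict[str, PriorSpec] = field(default_factory=dict)
    mutation_rate: dict[str, PriorSpec] = field(default_factory=lambda: {
        "intronic": PriorSpec("fixed", DEFAULT_MU["intronic"]),
        "exonic": PriorSpec("fixed", DEFAULT_MU["exonic"]),
    })
    max_rejections: int = 1000

    def sample_model(self, base: DemographicModel,
                     rng: np.random.Generator) -> DemographicModel:
        """Draw a model; invalid draws (ordering violations) are rejected
        and redrawn."""
        for _ in range(self.max_rejections):
            kw = {name: spec.sample(rng)
                  for name, spec in self.demography.items()}
            model = base.replace(**kw)
            try:
                model.validate()
            except ValueError:
                continue
            return model
        raise RuntimeError("prior rejection limit exceeded")

    def sample_mu(self, frag_class: str, rng: np.random.Generator) -> float:
        return self.mutation_rate[frag_class].sample(rng)


def reconstructed_priors(base: DemographicModel) -> ParameterPriors:
    """Wide reconstruction of the unpublished demographic priors."""
    return ParameterPriors(
        demography={
            "N_ANC": PriorSpec("loguniform", base.N_ANC / 4, base.N_ANC * 4),
            "N_MWANC": PriorSpec("loguniform", base.N_MWANC / 4,
                                 base.N_MWANC * 4),
            "N_MW": PriorSpec("loguniform", base.N_MW / 4, base.N_MW * 4),
            "N_MD": PriorSpec("loguniform", base.N_MD / 4, base.N_MD * 4),
            "I_MD": PriorSpec("loguniform", 0.1, 10.0),
            "T_BMD": PriorSpec("uniform", 7_000, 10_000),
            "T_EMD": PriorSpec("uniform", 4_000, 7_000),
        },
        mutation_rate={
            "intronic": PriorSpec("loguniform", 1.0e-8 / 3, 1.0e-8 * 3),
            "exonic": PriorSpec("loguniform", 1.0e-9 / 3, 1.0e-9 * 3),
        },
    )


# ---------------------------------------------------------------------------
# component statistics and the index
# ---------------------------------------------------------------------------

def component_stats_from_matrix(G: np.ndarray,
                                n_wild: int) -> tuple[float, float, float]:
    """(fst_mol, branch_len, delta_div) from a (sites x samples) genotype
    matrix whose first ``n_wild`` columns are the wild accessions.

    fst_mol is the two-population AMOVA Phi on pairwise difference counts;
    branch_len = -ln(1 - fst) with fst clamped to [0, 1); delta_div is the
    normalized wild-minus-domesticated diversity difference (the per-site
    scaling cancels in the ratio).
    """
    n = G.shape[1]
    if G.shape[0] == 0:
        raise MonomorphicFragmentError("no segregating sites")
    arr = G.T  # samples x sites
    labels = np.array([0] * n_wild + [1] * (n - n_wild))
    D = pairwise_difference_matrix(arr)
    if D.sum() == 0:
        raise MonomorphicFragmentError("all haplotypes identical")
    try:
        phi = phi_st_from_matrix(D, labels)
    except UndefinedFstError as exc:
        raise MonomorphicFragmentError(str(exc)) from None
    clamped = min(max(phi, 0.0), 1.0 - _EPS)
    branch = -math.log(1.0 - clamped)
    iw = np.arange(n_wild)
    idx_d = np.arange(n_wild, n)
    pw = D[np.ix_(iw, iw)].sum() / (n_wild * (n_wild - 1))
    pd_ = D[np.ix_(idx_d, idx_d)].sum() / (len(idx_d) * (len(idx_d) - 1))
    denom = pw + pd_
    delta = (pw - pd_) / denom if denom > 0 else 0.0
    return float(phi), float(branch), float(delta)


def component_stats(frag_wild: LocusAlignment,
                    frag_dom: LocusAlignment) -> tuple[float, float, float]:
    """Component statistics from two population alignments of one fragment.

    Columns with gaps or missing data in the pooled sample are removed
    before anything is computed.
    """
    pooled = LocusAlignment(
        frag_wild.locus_id, {**dict(frag_wild.rows), **dict(frag_dom.rows)})
    mask = usable_sites(pooled).usable
    arr = pooled.to_array()[:, mask]
    variable = np.array([len(set(arr[:, j].tobytes().decode())) > 1
                         for j in range(arr.shape[1])], dtype=bool)
    if not variable.any():
        raise MonomorphicFragmentError(f"{frag_wild.locus_id}: monomorphic")
    codes = np.zeros(arr[:, variable].shape, dtype=np.int8)
    sub = arr[:, variable]
    for code, b in enumerate((b"A", b"C", b"G", b"T", b"N", b"-")):
        codes[sub == b] = code
    return component_stats_from_matrix(codes.T, frag_wild.n)


@dataclass(frozen=True)
class Normalization:
    means: np.ndarray  # length 3
    sds: np.ndarray    # length 3; a zero sd silences that component

    @classmethod
    def from_components(cls, comps: np.ndarray) -> "Normalization":
        if comps.ndim != 2 or comps.shape[1] != 3:
            raise ValueError("components must be (n, 3)")
        return cls(means=comps.mean(axis=0), sds=comps.std(axis=0, ddof=0))


def selection_index(components: np.ndarray, norm: Normalization) -> np.ndarray:
    """Sum of the three z-scored components per fragment."""
    comps = np.atleast_2d(np.asarray(components, dtype=float))
    z = np.zeros_like(comps)
    for k in range(3):
        if norm.sds[k] > 0:
            z[:, k] = (comps[:, k] - norm.means[k]) / norm.sds[k]
    return z.sum(axis=1)


# ---------------------------------------------------------------------------
# coalescent null
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    """Simulated component statistics per fragment class.

    ``components[cls]`` is an (n_polymorphic, 3) array; monomorphic
    simulated fragments are counted in ``n_monomorphic`` and excluded, so
    empirical p-values are taken over polymorphic simulations only.
    """

    components: dict[str, np.ndarray]
    lengths: dict[str, np.ndarray]
    n_sims: int
    n_monomorphic: dict[str, int]
    seed: int | None

    def index(self, cls: str, norm: Normalization) -> np.ndarray:
        return selection_index(self.components[cls], norm)


def _simulate_batch(model: DemographicModel, length: int, count: int,
                    sample_sizes: Mapping[str, int],
                    rng: np.random.Generator):
    seed = int(rng.integers(1, 2 ** 31 - 1))
    return msprime.sim_ancestry(
        samples=dict(sample_sizes), demography=model.to_demography(),
        sequence_length=length, ploidy=1, num_replicates=count,
        random_seed=seed)


def simulate_null(model: DemographicModel,
                  observed_lengths: Mapping[str, Sequence[int]],
                  n_sims: int = 100_000,
                  sample_sizes: Mapping[str, int] | None = None,
                  priors: ParameterPriors | None = None,
                  seed: int | None = None) -> NullDistribution:
    """Neutral null distribution of the component statistics.

    For each simulation a fragment length is drawn (with replacement) from
    the observed class-specific length multiset and a mutation rate from the
    class prior; a neutral coalescent is run under ``model`` (parameters
    redrawn from ``priors`` per simulation when given, fixed otherwise) and
    the component statistics of the sampled MW/MD panel are recorded.
    Fully reproducible under ``seed``.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    sample_sizes = dict(sample_sizes or {"MW": 19, "MD": 20})
    n_wild = sample_sizes["MW"]
    mu_priors = priors.mutation_rate if priors else {
        cls: PriorSpec("fixed", DEFAULT_MU[cls]) for cls in FRAGMENT_CLASSES}
    rng = np.random.default_rng(seed)
    components: dict[str, list] = {}
    lengths_out: dict[str, list] = {}
    n_mono: dict[str, int] = {}
    for cls, lens in observed_lengths.items():
        lens = np.asarray(lens, dtype=int)
        if lens.size == 0:
            components[cls] = []
            lengths_out[cls] = []
            n_mono[cls] = 0
            continue
        drawn = rng.choice(lens, size=n_sims, replace=True)
        mus = np.array([mu_priors[cls].sample(rng) for _ in range(n_sims)])
        comps, out_lens, mono = [], [], 0
        if priors is not None and priors.demography:
            # per-simulation parameter draws: no tree-sequence batching
            for L, mu in zip(drawn, mus):
                m = priors.sample_model(model, rng)
                ts = next(_simulate_batch(m, int(L), 1, sample_sizes, rng))
                mts = msprime.sim_mutations(
                    ts, rate=mu, random_seed=int(rng.integers(1, 2 ** 31 - 1)))
                try:
                    comps.append(component_stats_from_matrix(
                        mts.genotype_matrix(), n_wild))
                    out_lens.append(int(L))
                except MonomorphicFragmentError:
                    mono += 1
        else:
            order = np.argsort(drawn, kind="stable")
            for L in np.unique(drawn):
                sel = order[drawn[order] == L]
                reps = _simulate_batch(model, int(L), len(sel),
                                       sample_sizes, rng)
                for i, ts in zip(sel, reps):
                    mts = msprime.sim_mutations(
                        ts, rate=mus[i],
                        random_seed=int(rng.integers(1, 2 ** 31 - 1)))
                    try:
                        comps.append(component_stats_from_matrix(
                            mts.genotype_matrix(), n_wild))
                        out_lens.append(int(L))
                    except MonomorphicFragmentError:
                        mono += 1
        components[cls] = comps
        lengths_out[cls] = out_lens
        n_mono[cls] = mono
    return NullDistribution(
        components={c: np.array(v, dtype=float).reshape(-1, 3)
                    for c, v in components.items()},
        lengths={c: np.array(v, dtype=int) for c, v in lengths_out.items()},
        n_sims=n_sims, n_monomorphic=n_mono, seed=seed)


def empirical_p(observed: float, null: np.ndarray,
                add_one: bool = False) -> float:
    """Fraction of simulated indices larger than the observed value."""
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    exceed = int((null > observed).sum())
    if add_one:
        return (1 + exceed) / (null.size + 1)
    return exceed / null.size


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, stable under ties."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

def observed_fragments(dataset: Dataset,
                       wild: PopulationLabel = PopulationLabel.MW,
                       dom: PopulationLabel = PopulationLabel.MD
                       ) -> pd.DataFrame:
    """Per-fragment component statistics for the observed panel.

    Each annotated gene is split into its exonic and its intronic
    (intron + UTR) fragment; unannotated genes and pooled-monomorphic
    fragments are excluded, as are genes with no polymorphic fragment.
    """
    rows = []
    for aln in dataset.loci:
        ann = dataset.annotations.get(aln.locus_id)
        if ann is None:
            continue
        for cls, classes in (("exonic", {"exon"}),
                             ("intronic", NONCODING_CLASSES)):
            try:
                frag = slice_region(aln, ann, classes)
            except EmptyRegionError:
                continue
            try:
                w = dataset.population(frag, wild)
                d = dataset.population(frag, dom)
            except Exception:
                continue
            if w.n < 2 or d.n < 2:
                continue
            try:
                fst, branch, delta = component_stats(w, d)
            except MonomorphicFragmentError:
                continue
            rows.append({"gene": aln.locus_id, "fragment_class": cls,
                         "length": frag.length, "fst_mol": fst,
                         "branch_len": branch, "delta_div": delta})
    return pd.DataFrame(rows)


def scan(dataset: Dataset, model: DemographicModel, n_sims: int = 100_000,
         fdr: float = 0.05, seed: int | None = None,
         priors: ParameterPriors | None = None,
         null: NullDistribution | None = None,
         wild: PopulationLabel = PopulationLabel.MW,
         dom: PopulationLabel = PopulationLabel.MD
         ) -> tuple[pd.DataFrame, pd.DataFrame, NullDistribution]:
    """Run the full selection scan.

    Returns (per-fragment table, per-gene rollup, null distribution).  The
    normalization constants are estimated from the observed panel and
    applied unchanged to the simulated fragments, so observed and simulated
    indices share one scale.  A precomputed ``null`` may be supplied to
    amortize simulations across runs.
    """
    obs = observed_fragments(dataset, wild, dom)
    if obs.empty:
        return obs, pd.DataFrame(), null  # no polymorphic fragments
    comps = obs[["fst_mol", "branch_len", "delta_div"]].to_numpy()
    norm = Normalization.from_components(comps)
    obs = obs.copy()
    obs["index"] = selection_index(comps, norm)

    if null is None:
        lengths = {
            cls: obs.loc[obs.fragment_class == cls, "length"].to_numpy()
            for cls in FRAGMENT_CLASSES
        }
        sample_sizes = {"MW": len(dataset.accessions_of(wild)),
                        "MD": len(dataset.accessions_of(dom))}
        null = simulate_null(model, lengths, n_sims=n_sims,
                             sample_sizes=sample_sizes, priors=priors,
                             seed=seed)
    null_index = {cls: null.index(cls, norm)
                  for cls in null.components if null.components[cls].size}
    p_raw = np.array([
        empirical_p(row["index"], null_index[row.fragment_class])
        for _, row in obs.iterrows()
    ])
    obs["p_raw"] = p_raw
    obs["q_bh"] = bh_adjust(p_raw)
    obs["flagged"] = obs["q_bh"] < fdr
    obs["model_id"] = model.model_id

    genes = (obs.groupby("gene")
             .agg(n_fragments=("fragment_class", "size"),
                  min_q=("q_bh", "min"),
                  flagged=("flagged", "any"))
             .reset_index())
    return obs, genes, null
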