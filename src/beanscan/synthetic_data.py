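"""Synthetic dataset generator with known truth.

Emulates the study design end to end: ~49 gene fragments of 150-900 bp with
exon/intron/UTR mosaic structure, sequenced in 19 wild (MW) and 20
domesticated (MD) haploid inbred accessions, where the domesticated
population passed through a domestication bottleneck that roughly halves its
diversity.  Selective sweeps are emulated demographically: a swept locus is
re-simulated with an intensified locus-specific bottleneck whose size is set
so a pair of domesticated lineages survives the domestication window with
probability equal to the configured retention fraction, producing the
reduced pi_MD and elevated FST the scan is meant to detect.

Exon columns mutate 10-fold slower than noncoding ones (rate map), and exon
mutations that would create an internal stop codon in any accession are
rewritten (or, as a last resort, removed), so every generated exon
translates cleanly in the annotated frame.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np

from .codon_partition import GENETIC_CODE
from .seqdata import (
    Dataset,
    LocusAlignment,
    PopulationLabel,
    RegionAnnotation,
)
from .selection_scan import DEFAULT_MU, DemographicModel

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


@dataclass(frozen=True)
class SweepSpec:
    loci: tuple[str, ...] = ()
    retention: float = 0.05  # post-domestication diversity retention fraction
    #: differentiation boost: extra divergence of the swept haplotype, in
    #: units of the ancestral wild size (selection on a divergent standing
    #: variant makes the domesticated allele coalesce with the wild sample
    #: deeper than the domestication split).  The default is sized so the
    #: swept haplotype's stem branch carries several marking mutations at
    #: intron rates (2 * boost * N * mu * L of order 5 for a median
    #: fragment), i.e. the sweep is unambiguous at the sequence level.
    divergence_boost: float = 4.0

    def __post_init__(self):
        if not (0 < self.retention <= 1):
            raise ValueError("retention must be in (0, 1]")
        if self.divergence_boost < 0:
            raise ValueError("divergence_boost must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    n_loci: int = 49
    length_range: tuple[int, int] = (150, 900)
    n_wild: int = 19
    n_dom: int = 20
    demography: DemographicModel = field(default_factory=DemographicModel)
    mu_exon: float = DEFAULT_MU["exonic"]
    mu_noncoding: float = DEFAULT_MU["intronic"]
    #: fraction of loci with no structural annotation (4/49 in the study)
    frac_unannotated: float = 4 / 49
    #: among annotated loci, fraction carrying exon regions
    frac_with_exons: float = 42 / 45
    sweeps: SweepSpec = SweepSpec()
    seed: int = 1


@dataclass
class TruthRecord:
    """Ground truth of one generated dataset, serializable to JSON."""

    config_seed: int
    demography: dict
    swept_loci: list[str]
    retention: float
    locus_lengths: dict[str, int]
    mu_exon: float
    mu_noncoding: float

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# analytic expectations (used for calibration checks)
# ---------------------------------------------------------------------------

def expected_pairwise_time(phases: list[tuple[float, float]]) -> float:
    """E[T2] for two lineages under piecewise-constant haploid sizes.

    ``phases`` is a list of (duration, size) with the last duration allowed
    to be infinite.  E[T2] = sum over phases of S_k * N_k * (1 - e^{-d/N}),
    with S_k the probability of reaching the phase uncoalesced.
    """
    expect = 0.0
    survive = 1.0
    for duration, size in phases:
        if math.isinf(duration):
            expect += survive * size
            break
        expect += survive * size * (1.0 - math.exp(-duration / size))
        survive *= math.exp(-duration / size)
    return expect


def _md_phases(m: DemographicModel,
               bottleneck_size: float | None = None,
               n_md: float | None = None) -> list[tuple[float, float]]:
    nb = bottleneck_size if bottleneck_size is not None else m.bottleneck_size_md
    nmd = n_md if n_md is not None else m.N_MD
    return [(m.T_EMD, nmd),
            (m.T_BMD - m.T_EMD, nb),
            (m.T_ANC - m.T_BMD, m.N_MWANC),
            (math.inf, m.N_ANC)]


def _mw_phases(m: DemographicModel) -> list[tuple[float, float]]:
    return [(m.T_BMD, m.N_MW),
            (m.T_ANC - m.T_BMD, m.N_MWANC),
            (math.inf, m.N_ANC)]


def expected_pi(model: DemographicModel, population: str, mu: float) -> float:
    """Expected per-site pairwise diversity (no migration, constant MW)."""
    phases = _mw_phases(model) if population == "MW" else _md_phases(model)
    return 2.0 * mu * expected_pairwise_time(phases)


def expected_loss_pi(model: DemographicModel) -> float:
    """Expected mean-based L_pi for the configured demography (the mutation
    rate cancels in the ratio)."""
    return 1.0 - (expected_pairwise_time(_md_phases(model))
                  / expected_pairwise_time(_mw_phases(model)))


def sweep_bottleneck_size(model: DemographicModel, retention: float) -> float:
    """Bottleneck size making a domesticated lineage pair survive the
    domestication window with probability ``retention``."""
    window = model.T_BMD - model.T_EMD
    return window / (-math.log(retention))


# ---------------------------------------------------------------------------
# structure templates
# ---------------------------------------------------------------------------

def _draw_structure(rng: np.random.Generator, length: int,
                    with_exons: bool) -> list[tuple[int, int, str]]:
    """A plausible exon/intron/UTR mosaic covering [0, length)."""
    segments: list[str] = []
    if not with_exons:
        segments = ["utr5", "intron", "utr3"] if length > 120 else ["intron"]
    else:
        if rng.random() < 0.4:
            segments.append("utr5")
        n_exons = 1 + int(rng.random() < 0.6)
        for i in range(n_exons):
            if i:
                segments.append("intron")
            segments.append("exon")
        if rng.random() < 0.5 and n_exons == 1 and length > 250:
            segments.append("intron")
        if rng.random() < 0.4:
            segments.append("utr3")
    weights = rng.uniform(0.5, 1.5, size=len(segments))
    sizes = np.maximum(30, (weights / weights.sum() * length).astype(int))
    while sizes.sum() > length:
        sizes[np.argmax(sizes)] -= 1
    sizes[-1] += length - sizes.sum()
    intervals = []
    pos = 0
    for seg, size in zip(segments, sizes):
        intervals.append((pos, pos + int(size), seg))
        pos += int(size)
    return intervals


def _reference_sequence(rng: np.random.Generator,
                        intervals: list[tuple[int, int, str]],
                        length: int) -> str:
    ref = list(rng.choice(list(_BASES), size=length))
    exon_cols = [i for s, e, c in intervals if c == "exon"
                 for i in range(s, e)]
    # rebuild the concatenated exon sequence codon-wise without stops
    n = len(exon_cols)
    coding = []
    while len(coding) < n:
        codon = "".join(rng.choice(list(_BASES), size=3))
        if GENETIC_CODE[codon] != "*":
            coding.extend(codon)
    for col, base in zip(exon_cols, coding):
        ref[col] = base
    return "".join(ref)


# ---------------------------------------------------------------------------
# stop-codon repair
# ---------------------------------------------------------------------------

def _repair_stops(matrix: np.ndarray, exon_cols: list[int],
                  rng: np.random.Generator, max_iter: int = 200) -> None:
    """Rewrite or remove exon mutations creating internal stop codons.

    Operates in place on the (n, L) unicode character matrix.  Offending
    derived alleles are first re-drawn among substitute bases (preserving
    the mutation count); if no substitute clears every carrier, the allele
    collapses to the column majority (removing the mutation).  Termination
    is guaranteed because collapsing strictly reduces variation.
    """
    n_codons = len(exon_cols) // 3
    for _ in range(max_iter):
        offending = None
        for ci in range(n_codons):
            cols = exon_cols[3 * ci:3 * ci + 3]
            codons = ["".join(matrix[i, cols]) for i in range(matrix.shape[0])]
            bad_rows = [i for i, c in enumerate(codons) if c in _STOPS]
            if bad_rows:
                offending = (cols, bad_rows)
                break
        if offending is None:
            return
        cols, bad_rows = offending
        # pick a column where the offending rows deviate from the majority
        col = None
        for c in cols:
            column = matrix[:, c]
            values, counts = np.unique(column, return_counts=True)
            major = values[np.argmax(counts)]
            if any(matrix[i, c] != major for i in bad_rows):
                col = c
                break
        if col is None:  # stop present in the majority background: re-draw it
            col = cols[0]
        column = matrix[:, col]
        values, counts = np.unique(column, return_counts=True)
        major = values[np.argmax(counts)]
        allele = matrix[bad_rows[0], col]
        carriers = column == allele
        fixed = False
        for sub in rng.permutation(list(set(_BASES) - set(values))):
            matrix[carriers, col] = sub
            # re-check just the affected codon
            if all("".join(matrix[i, cols]) not in _STOPS
                   for i in np.flatnonzero(carriers)):
                fixed = True
                break
            matrix[carriers, col] = allele
        if not fixed:
            matrix[carriers, col] = major  # collapse the mutation
    # final safety: collapse any residual stop codons outright
    for ci in range(n_codons):
        cols = exon_cols[3 * ci:3 * ci + 3]
        for i in range(matrix.shape[0]):
            if "".join(matrix[i, cols]) in _STOPS:
                for c in cols:
                    column = matrix[:, c]
                    values, counts = np.unique(column, return_counts=True)
                    matrix[i, c] = values[np.argmax(counts)]


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def _simulate_locus(config: GeneratorConfig, model: DemographicModel,
                    length: int, intervals: list[tuple[int, int, str]],
                    rng: np.random.Generator) -> np.ndarray:
    """Character matrix (n_wild + n_dom, length) for one locus."""
    ts = msprime.sim_ancestry(
        samples={"MW": config.n_wild, "MD": config.n_dom},
        demography=model.to_demography(), sequence_length=length,
        ploidy=1, random_seed=int(rng.integers(1, 2 ** 31 - 1)))
    if intervals:
        pos, rates, cur = [0.0], [], 0.0
        for start, end, cls in intervals:
            rate = config.mu_exon if cls == "exon" else config.mu_noncoding
            pos.append(float(end))
            rates.append(rate)
        rate_map = msprime.RateMap(position=pos, rate=rates)
    else:
        rate_map = config.mu_noncoding
    mts = msprime.sim_mutations(
        ts, rate=rate_map, random_seed=int(rng.integers(1, 2 ** 31 - 1)))

    ref = _reference_sequence(rng, intervals,
                              length) if intervals else "".join(
        rng.choice(list(_BASES), size=length))
    n = config.n_wild + config.n_dom
    matrix = np.array([list(ref)] * n, dtype="U1")
    for var in mts.variants():
        j = int(var.site.position)
        matrix[:, j] = np.array(var.alleles)[var.genotypes]
    exon_cols = [i for s, e, c in intervals if c == "exon"
                 for i in range(s, e)]
    if exon_cols:
        _repair_stops(matrix, exon_cols, rng)
    return matrix


def generate_dataset(config: GeneratorConfig) -> tuple[Dataset, TruthRecord]:
    """Generate a full synthetic dataset plus its truth record.

    Deterministic under ``config.seed``: the same configuration produces
    byte-identical alignments.
    """
    rng = np.random.default_rng(config.seed)
    config.demography.validate()
    wild_ids = [f"MW{i:03d}" for i in range(config.n_wild)]
    dom_ids = [f"MD{i:03d}" for i in range(config.n_dom)]
    manifest = {a: PopulationLabel.MW for a in wild_ids}
    manifest.update({a: PopulationLabel.MD for a in dom_ids})

    locus_ids = [f"SYN-L{i + 1:02d}" for i in range(config.n_loci)]
    unknown = set(rng.choice(
        locus_ids, size=round(config.frac_unannotated * config.n_loci),
        replace=False))
    missing_sweeps = set(config.sweeps.loci) - set(locus_ids)
    if missing_sweeps:
        raise ValueError(f"swept loci not in dataset: {sorted(missing_sweeps)}")
    if set(config.sweeps.loci) & unknown:
        # sweeps must be scannable, hence annotated
        unknown -= set(config.sweeps.loci)

    # Sweeps are emulated demographically: an intensified locus-specific
    # bottleneck sized so a domesticated lineage pair survives the original
    # domestication window with probability = retention, a proportionally
    # reduced modern size, no wild introgression at the locus (selection
    # removes migrant alleles there), and a divergence boost that pushes the
    # swept haplotype's coalescence with the wild sample deeper in time
    # (selection on divergent standing variation), with the locus staying at
    # the bottleneck size throughout the extended isolation.
    demog = config.demography
    sweep_model = demog.replace(
        I_MD=100.0 * sweep_bottleneck_size(demog, config.sweeps.retention)
        / demog.N_MWANC,
        N_MD=demog.N_MD * config.sweeps.retention,
        T_BMD=demog.T_BMD
        + config.sweeps.divergence_boost * demog.N_MWANC,
        T_ANC=max(demog.T_ANC, demog.T_BMD
                  + config.sweeps.divergence_boost * demog.N_MWANC),
        M_WD=0.0, M_DW=0.0,
    )

    loci, annotations, lengths = [], {}, {}
    for locus_id in locus_ids:
        length = int(rng.integers(config.length_range[0],
                                  config.length_range[1] + 1))
        lengths[locus_id] = length
        if locus_id in unknown:
            intervals = []
        else:
            with_exons = (locus_id in config.sweeps.loci
                          or rng.random() < config.frac_with_exons)
            intervals = _draw_structure(rng, length, with_exons)
        model = (sweep_model if locus_id in config.sweeps.loci
                 else config.demography)
        matrix = _simulate_locus(config, model, length, intervals, rng)
        rows = {a: "".join(matrix[i])
                for i, a in enumerate(wild_ids + dom_ids)}
        loci.append(LocusAlignment(locus_id, rows))
        if intervals:
            annotations[locus_id] = RegionAnnotation(
                locus_id, tuple(intervals), frame_offset=0)

    truth = TruthRecord(
        config_seed=config.seed,
        demography=dataclasses.asdict(config.demography),
        swept_loci=sorted(config.sweeps.loci),
        retention=config.sweeps.retention,
        locus_lengths=lengths,
        mu_exon=config.mu_exon,
        mu_noncoding=config.mu_noncoding,
    )
    return Dataset(loci=loci, annotations=annotations,
                   manifest=manifest), truth


def write_truth(truth: TruthRecord, outdir: str | Path) -> None:
    Path(outdir, "truth.json").write_text(truth.to_json())


def read_truth(indir: str | Path) -> TruthRecord:
    return TruthRecord.from_json(Path(indir, "truth.json").read_text())


# ---------------------------------------------------------------------------
# worked fixtures
# ---------------------------------------------------------------------------

def make_worked_fixtures(which: tuple[str, ...] = ("alignments", "tables")
                         ) -> dict:
    """Tiny hand-built alignments exercising the estimator branches, plus
    the transcribed published summary tables (loaded from package data)."""
    if not which:
        raise ValueError("empty fixture bundle requested")
    bundle: dict = {}
    if "alignments" in which:
        # serine->phenylalanine replacement private to one MD accession
        background = "ATGTCTGGA"   # M S G
        variant = "ATGTTTGGA"      # M F G
        rows = {f"MW{i}": background for i in range(4)}
        rows.update({f"MD{i}": background for i in range(3)})
        rows["MD3"] = variant
        rows["PD0"] = background
        replacement = Dataset(
            loci=[LocusAlignment("FIX-SF", rows)],
            annotations={"FIX-SF": RegionAnnotation(
                "FIX-SF", ((0, 9, "exon"),), 0)},
            manifest={**{f"MW{i}": PopulationLabel.MW for i in range(4)},
                      **{f"MD{i}": PopulationLabel.MD for i in range(4)},
                      "PD0": PopulationLabel.OUT_PD},
        )
        # two haplotypes 2/2, one segregating site, with an intron
        hap = LocusAlignment("FIX-HAP", {
            "a": "AAACCC", "b": "AAACCC", "c": "AAGCCC", "d": "AAGCCC"})
        bundle["alignments"] = {
            "replacement": replacement,
            "haplotypes": hap,
        }
    if "tables" in which:
        from . import published
        bundle["tables"] = {
            "diversity_summary": published.load_diversity_summary(),
            "loss": published.load_loss_table(),
            "fst_mutations": published.load_fst_mutation_table(),
            "effect_counts": published.load_effect_sharing_counts(),
        }
    return bundle
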