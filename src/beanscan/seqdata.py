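"""Data model and I/O for aligned gene fragments, region annotations and
population manifests.

The analysis operates on per-locus multiple sequence alignments (one row per
inbred accession, treated as a haploid sequence), a per-locus annotation that
partitions alignment columns into exon / intron / UTR intervals with an exon
reading frame, and a manifest mapping each accession to its population
(Mesoamerican wild MW, Mesoamerican domesticated MD, Andean wild/domesticated
AW/AD, the phaseolin-I wild group PHI, and the two outgroup species).

Coordinates are 0-based half-open internally; GFF-style annotation input is
1-based inclusive.  Alignment columns containing a gap or an N in any analyzed
row are masked out ("complete deletion"), so indels never enter the
statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = set("ACGTN-")

REGION_CLASSES = ("exon", "intron", "utr5", "utr3", "unknown")

#: Region classes pooled as "noncoding" throughout the analysis.
NONCODING_CLASSES = frozenset({"intron", "utr5", "utr3"})


class SeqDataError(ValueError):
    """Base class for data-model violations."""


class AlignmentError(SeqDataError):
    pass


class AlphabetError(SeqDataError):
    pass


class AnnotationError(SeqDataError):
    pass


class ManifestError(SeqDataError):
    pass


class EmptyRegionError(SeqDataError):
    """Raised when a locus has no columns of the requested region classes.

    Mirrors the "/" cells of the per-locus report: the locus simply has no
    coding (or noncoding) sequence, so the statistic is structurally absent
    rather than undefined.
    """


class PopulationLabel(str, Enum):
    MW = "MW"          # Mesoamerican wild
    MD = "MD"          # Mesoamerican domesticated
    AW = "AW"          # Andean wild
    AD = "AD"          # Andean domesticated
    PHI = "PHI"        # phaseolin type I wild (N Peru / Ecuador)
    OUT_PD = "OUT_PD"  # P. dumosus outgroup
    OUT_PC = "OUT_PC"  # P. coccineus outgroup

    def __str__(self) -> str:  # manifests print the bare code
        return self.value


@dataclass(frozen=True)
class LocusAlignment:
    """A gapped multiple sequence alignment for one locus.

    ``rows`` maps accession id -> sequence over {A,C,G,T,N,-}; all rows have
    exactly ``length`` characters.
    """

    locus_id: str
    rows: Mapping[str, str]
    length: int = field(default=0)

    def __post_init__(self):
        rows = dict(self.rows)
        if not rows:
            raise AlignmentError(f"{self.locus_id}: empty alignment")
        lengths = {len(s) for s in rows.values()}
        if len(lengths) != 1:
            raise AlignmentError(
                f"{self.locus_id}: rows have unequal lengths {sorted(lengths)}")
        (length,) = lengths
        object.__setattr__(self, "length", length)
        for acc, seq in rows.items():
            bad = set(seq) - ALPHABET
            if bad:
                raise AlphabetError(
                    f"{self.locus_id}/{acc}: illegal characters {sorted(bad)}")
        object.__setattr__(self, "rows", rows)

    @property
    def accessions(self) -> list[str]:
        return list(self.rows)

    @property
    def n(self) -> int:
        return len(self.rows)

    def subset(self, accessions: Iterable[str]) -> "LocusAlignment":
        keep = [a for a in accessions if a in self.rows]
        if not keep:
            raise AlignmentError(f"{self.locus_id}: empty accession subset")
        return LocusAlignment(self.locus_id, {a: self.rows[a] for a in keep})

    def to_array(self) -> np.ndarray:
        """(n, length) array of single-byte characters, row order = insertion order."""
        return np.frombuffer(
            "".join(self.rows.values()).encode(), dtype="S1"
        ).reshape(self.n, self.length)

    def columns(self, idx: Sequence[int]) -> "LocusAlignment":
        rows = {a: "".join(s[i] for i in idx) for a, s in self.rows.items()}
        return LocusAlignment(self.locus_id, rows)


@dataclass(frozen=True)
class RegionAnnotation:
    """Typed, non-overlapping intervals over one locus, 0-based half-open."""

    locus_id: str
    intervals: tuple[tuple[int, int, str], ...]
    frame_offset: int = 0

    def __post_init__(self):
        ivs = tuple(sorted(self.intervals))
        prev_end = 0
        for start, end, cls in ivs:
            if cls not in REGION_CLASSES:
                raise AnnotationError(f"{self.locus_id}: unknown class {cls!r}")
            if start < 0 or end <= start:
                raise AnnotationError(
                    f"{self.locus_id}: bad interval ({start}, {end})")
            if start < prev_end:
                raise AnnotationError(
                    f"{self.locus_id}: overlapping intervals at {start}")
            prev_end = end
        if not (0 <= self.frame_offset <= 2):
            raise AnnotationError(f"{self.locus_id}: frame_offset must be 0-2")
        object.__setattr__(self, "intervals", ivs)

    def check_within(self, length: int) -> None:
        for start, end, _ in self.intervals:
            if end > length:
                raise AnnotationError(
                    f"{self.locus_id}: interval ({start}, {end}) exceeds "
                    f"alignment length {length}")

    def columns_of(self, class_set: Iterable[str]) -> list[int]:
        wanted = set(class_set)
        cols: list[int] = []
        for start, end, cls in self.intervals:
            if cls in wanted:
                cols.extend(range(start, end))
        return cols

    @property
    def classes_present(self) -> set[str]:
        return {cls for _, _, cls in self.intervals}


@dataclass(frozen=True)
class SiteMask:
    locus_id: str
    usable: np.ndarray  # boolean per alignment column

    @property
    def n_usable(self) -> int:
        return int(self.usable.sum())


@dataclass
class Dataset:
    """All loci of one study plus annotations and the population manifest."""

    loci: list[LocusAlignment]
    annotations: dict[str, RegionAnnotation]
    manifest: dict[str, PopulationLabel]

    def __post_init__(self):
        for aln in self.loci:
            missing = [a for a in aln.accessions if a not in self.manifest]
            if missing:
                raise ManifestError(
                    f"{aln.locus_id}: accessions missing from manifest: "
                    f"{missing[:5]}")
            if aln.locus_id in self.annotations:
                self.annotations[aln.locus_id].check_within(aln.length)

    def accessions_of(self, label: PopulationLabel) -> list[str]:
        return [a for a, l in self.manifest.items() if l is label]

    def population(self, aln: LocusAlignment,
                   label: PopulationLabel) -> LocusAlignment:
        return aln.subset(a for a in aln.accessions
                          if self.manifest[a] is label)

    def locus(self, locus_id: str) -> LocusAlignment:
        for aln in self.loci:
            if aln.locus_id == locus_id:
                return aln
        raise KeyError(locus_id)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _data_lines(path: str | Path) -> list[list[str]]:
    """TSV rows, tolerant of CRLF, blank lines and '#' comments."""
    out = []
    for raw in Path(path).read_text().splitlines():
        line = raw.rstrip("\r\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        out.append(line.split("\t"))
    return out


def read_alignment(path: str | Path, locus_id: str | None = None) -> LocusAlignment:
    """Read a pre-aligned FASTA file; record ids become accession ids."""
    path = Path(path)
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise AlignmentError(f"{path.name}: duplicate record {rec.id}")
        rows[rec.id] = str(rec.seq).upper()
    if not rows:
        raise AlignmentError(f"{path.name}: no FASTA records")
    return LocusAlignment(locus_id or path.stem, rows)


def write_alignment(aln: LocusAlignment, path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=a, description="") for a, s in aln.rows.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_manifest(path: str | Path) -> dict[str, PopulationLabel]:
    out: dict[str, PopulationLabel] = {}
    for fields in _data_lines(path):
        if len(fields) < 2:
            raise ManifestError(f"manifest row too short: {fields}")
        acc, label = fields[0].strip(), fields[1].strip()
        if acc in out:
            raise ManifestError(f"duplicate accession {acc!r}")
        try:
            out[acc] = PopulationLabel(label)
        except ValueError:
            raise ManifestError(f"unknown population label {label!r}") from None
    return out


def write_manifest(manifest: Mapping[str, PopulationLabel],
                   path: str | Path) -> None:
    with open(path, "w") as fh:
        for acc, label in manifest.items():
            fh.write(f"{acc}\t{label.value}\n")


def read_annotation(path: str | Path) -> dict[str, RegionAnnotation]:
    """GFF-style TSV: locus_id, start, end, class, frame (1-based inclusive)."""
    per_locus: dict[str, list[tuple[int, int, str]]] = {}
    frames: dict[str, int] = {}
    for fields in _data_lines(path):
        if len(fields) < 4:
            raise AnnotationError(f"annotation row too short: {fields}")
        locus, start1, end1, cls = fields[:4]
        frame = int(fields[4]) if len(fields) > 4 and fields[4].strip() else 0
        start1, end1 = int(start1), int(end1)
        if start1 < 1 or end1 < start1:
            raise AnnotationError(
                f"{locus}: bad 1-based interval {start1}..{end1}")
        per_locus.setdefault(locus, []).append((start1 - 1, end1, cls.strip()))
        if cls.strip() == "exon":
            frames.setdefault(locus, frame)
    return {
        locus: RegionAnnotation(locus, tuple(ivs), frames.get(locus, 0))
        for locus, ivs in per_locus.items()
    }


def write_annotation(anns: Mapping[str, RegionAnnotation],
                     path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# locus\tstart\tend\tclass\tframe (1-based inclusive)\n")
        for ann in anns.values():
            for start, end, cls in ann.intervals:
                frame = ann.frame_offset if cls == "exon" else ""
                fh.write(f"{ann.locus_id}\t{start + 1}\t{end}\t{cls}\t{frame}\n")


def write_dataset(dataset: Dataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    (outdir / "alignments").mkdir(parents=True, exist_ok=True)
    for aln in dataset.loci:
        write_alignment(aln, outdir / "alignments" / f"{aln.locus_id}.fasta")
    write_manifest(dataset.manifest, outdir / "manifest.tsv")
    write_annotation(dataset.annotations, outdir / "annotations.tsv")
    (outdir / "loci.json").write_text(
        json.dumps([aln.locus_id for aln in dataset.loci]))


def read_dataset(indir: str | Path) -> Dataset:
    indir = Path(indir)
    order = json.loads((indir / "loci.json").read_text())
    loci = [read_alignment(indir / "alignments" / f"{locus}.fasta", locus)
            for locus in order]
    return Dataset(
        loci=loci,
        annotations=read_annotation(indir / "annotations.tsv"),
        manifest=read_manifest(indir / "manifest.tsv"),
    )


# ---------------------------------------------------------------------------
# region slicing and site masking
# ---------------------------------------------------------------------------

def slice_region(aln: LocusAlignment, ann: RegionAnnotation,
                 class_set: Iterable[str]) -> LocusAlignment:
    """Concatenate the columns of the requested region classes, genomic order.

    For exon slices the concatenated sequence keeps the annotation's reading
    frame (``frame_offset`` refers to the concatenated exon sequence), so
    codon phase is recoverable downstream.
    """
    ann.check_within(aln.length)
    cols = ann.columns_of(class_set)
    if not cols:
        raise EmptyRegionError(
            f"{aln.locus_id}: no columns of classes {sorted(set(class_set))}")
    return aln.columns(cols)


def usable_sites(aln: LocusAlignment,
                 accessions: Iterable[str] | None = None) -> SiteMask:
    """Complete-deletion mask: a column is unusable if any retained row
    carries '-' or 'N'.  Different population subsets may therefore yield
    different masks for the same locus."""
    sub = aln if accessions is None else aln.subset(accessions)
    arr = sub.to_array()
    usable = ~np.isin(arr, [b"-", b"N"]).any(axis=0)
    return SiteMask(aln.locus_id, usable)
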