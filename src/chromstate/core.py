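"""Strand-aware genomic interval model and flat-file readers/writers.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``. Chromosome names are compared as exact strings (no
``chr`` aliasing).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")

GENOTYPES = ("control", "knockout")

#: closed vocabulary of assay labels a FragmentSet may carry
CHIP_TARGETS = (
    "H3K4me3",
    "H3K27me3",
    "H3K4me1",
    "H3K27ac",
    "factorA",
    "factorB",
    "factorC",
)


class BedParseError(ValueError):
    """Raised for malformed BED lines; carries the offending line number."""


class GeneTableError(ValueError):
    """Raised for schema violations in the flat gene annotation table."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """≥1 bp overlap under half-open semantics: [a,b) never meets [b,c)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True, slots=True)
class GeneRecord:
    """A gene reduced to the fields the pipeline needs.

    ``length`` is the exonic length in bp used for RPKM, not the genomic span.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"gene length must be > 0, got {self.length}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}")
        if self.tss < 0:
            raise ValueError("tss must be >= 0")


@dataclass
class PeakSet:
    """A named, sorted collection of peak intervals (one factor/condition)."""

    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": np.asarray([iv.start for iv in self.intervals], dtype=int),
                "end": np.asarray([iv.end for iv in self.intervals], dtype=int),
                "strand": [iv.strand for iv in self.intervals],
            }
        )


@dataclass
class FragmentSet:
    """Sequenced fragments for one sample/replicate.

    Fragments are held as a DataFrame with columns ``chrom``, ``start``,
    ``end`` (half-open, so size = end - start). ``assay`` is ``"atac"`` or
    ``"chip:<target>"`` with the target drawn from :data:`CHIP_TARGETS`.
    """

    sample_id: str
    genotype: str
    assay: str
    fragments: pd.DataFrame
    chrom_sizes: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(
                f"genotype must be one of {GENOTYPES}, got {self.genotype!r}"
            )
        if self.assay != "atac":
            kind, _, target = self.assay.partition(":")
            if kind != "chip" or target not in CHIP_TARGETS:
                raise ValueError(
                    f"assay must be 'atac' or 'chip:<target>' with target in "
                    f"{CHIP_TARGETS}, got {self.assay!r}"
                )
        frags = self.fragments
        required = {"chrom", "start", "end"}
        if not required.issubset(frags.columns):
            raise ValueError(f"fragment frame needs columns {sorted(required)}")
        sizes = frags["end"].to_numpy() - frags["start"].to_numpy()
        if len(sizes) and (sizes <= 0).any():
            raise ValueError("all fragment sizes must be > 0")
        self.fragments = frags.sort_values(
            ["chrom", "start", "end"], kind="mergesort"
        ).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.fragments)

    @property
    def sizes(self) -> np.ndarray:
        return (
            self.fragments["end"].to_numpy() - self.fragments["start"].to_numpy()
        )

    def by_chrom(self) -> dict[str, pd.DataFrame]:
        return {str(c): g for c, g in self.fragments.groupby("chrom", sort=True)}


def tss_window(gene: GeneRecord, flank: int) -> GenomicInterval:
    """Symmetric window ``[tss - flank, tss + flank)`` clipped at 0.

    The window is symmetric in genomic coordinates regardless of strand (the
    strand is retained on the output); promoter counting does not need
    transcriptional orientation because the window is symmetric.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    return GenomicInterval(
        gene.chrom, max(0, gene.tss - flank), gene.tss + flank, gene.strand
    )


def read_bed(path) -> PeakSet:
    """Read BED3/BED6 into a sorted :class:`PeakSet`.

    Strand is taken from column 6 when present, otherwise ``"."``. Malformed
    lines raise :class:`BedParseError` naming the 1-based line number.
    """
    import os

    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in STRANDS else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, strand))
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
    return PeakSet(name=os.path.splitext(os.path.basename(str(path)))[0],
                   intervals=intervals)


def write_bed(peaks: PeakSet, path) -> None:
    """Write BED6 such that ``read_bed(write_bed(x))`` reproduces ``x``."""
    with open(path, "w") as fh:
        for iv in peaks.intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{peaks.name}\t0\t{iv.strand}\n"
            )


GENE_TABLE_COLUMNS = ("gene_id", "chrom", "tss", "strand", "length")


def read_gene_table(path) -> list[GeneRecord]:
    """Read the flat TSV gene annotation (gene_id, chrom, tss, strand, length)."""
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    missing = set(GENE_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise GeneTableError(f"{path}: missing required columns {sorted(missing)}")
    dupes = table["gene_id"][table["gene_id"].duplicated()]
    if len(dupes):
        raise GeneTableError(
            f"{path}: duplicate gene_id values: {sorted(set(dupes))[:5]}"
        )
    return [
        GeneRecord(
            gene_id=row.gene_id,
            chrom=row.chrom,
            tss=int(row.tss),
            strand=row.strand,
            length=int(row.length),
        )
        for row in table.itertuples(index=False)
    ]


def write_gene_table(genes: Sequence[GeneRecord], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "tss": [g.tss for g in genes],
            "strand": [g.strand for g in genes],
            "length": [g.length for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def fragments_from_arrays(
    chrom: Iterable[str],
    start: np.ndarray,
    end: np.ndarray,
    *,
    sample_id: str,
    genotype: str,
    assay: str,
    chrom_sizes: Mapping[str, int] | None = None,
) -> FragmentSet:
    """Convenience constructor used by the simulator and BED ingestion."""
    frame = pd.DataFrame(
        {"chrom": list(chrom), "start": np.asarray(start, dtype=int),
         "end": np.asarray(end, dtype=int)}
    )
    return FragmentSet(
        sample_id=sample_id,
        genotype=genotype,
        assay=assay,
        fragments=frame,
        chrom_sizes=chrom_sizes,
    )


def read_fragments_bed(
    path, *, sample_id: str, genotype: str, assay: str,
    chrom_sizes: Mapping[str, int] | None = None,
) -> FragmentSet:
    """Ingest a BED-like fragment file as a :class:`FragmentSet`."""
    peaks = read_bed(path)
    frame = peaks.to_frame()[["chrom", "start", "end"]]
    return FragmentSet(
        sample_id=sample_id, genotype=genotype, assay=assay,
        fragments=frame, chrom_sizes=chrom_sizes,
    )


def write_fragments_bed(frags: FragmentSet, path) -> None:
    frags.fragments[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )
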