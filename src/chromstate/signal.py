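"""Fragment-level signal quantification.

Coverage uses the fragment-count convention: a fragment adds 1 to every
bin it overlaps (not a per-bp pileup). Nucleosome occupancy instead
assigns each fragment to the bin of its midpoint, since a fragment
localizes a single dyad.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import FragmentSet, GeneRecord, GenomicInterval, PeakSet


@dataclass
class CoverageTrack:
    chrom: str
    bin_size: int
    values: np.ndarray
    origin: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("coverage values must be >= 0")

    def to_bedgraph(self, path, mode: str = "w") -> None:
        with open(path, mode) as fh:
            for i, v in enumerate(self.values):
                if v != 0:
                    fh.write(
                        f"{self.chrom}\t{i * self.bin_size}"
                        f"\t{(i + 1) * self.bin_size}\t{v:g}\n"
                    )


@dataclass
class MetaProfile:
    """Anchor-centered averaged profile, edge-normalized to background 1."""

    flank: int
    bin_size: int
    values: np.ndarray
    n_anchors: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != 2 * self.flank // self.bin_size:
            raise ValueError("profile length must equal 2*flank/bin_size")

    @property
    def edge_mean(self) -> float:
        return float(np.mean(np.r_[self.values[:5], self.values[-5:]]))

    def to_tsv(self, path) -> None:
        offsets = np.arange(len(self.values)) * self.bin_size - self.flank
        pd.DataFrame({"offset": offsets, "value": self.values}).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class NucleosomeProfile:
    """Per-bin nucleosomal fraction; bins with no fragments are NaN (missing)."""

    region: GenomicInterval
    bin_size: int
    occupancy: np.ndarray
    n_fragments: np.ndarray
    sub_range: tuple
    mono_range: tuple

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        finite = occ[np.isfinite(occ)]
        if len(finite) and ((finite < 0).any() or (finite > 1).any()):
            raise ValueError("occupancy scores must lie in [0, 1]")
        self.occupancy = occ


def bin_coverage(
    frags: FragmentSet,
    bin_size: int,
    chrom_sizes: Mapping[str, int] | None = None,
) -> dict[str, CoverageTrack]:
    """Per-chromosome binned fragment counts (one per overlapped bin)."""
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    chrom_sizes = chrom_sizes or frags.chrom_sizes
    if chrom_sizes is None:
        raise ValueError("chrom_sizes required (not recorded on FragmentSet)")
    tracks: dict[str, CoverageTrack] = {}
    grouped = frags.by_chrom()
    for chrom, length in chrom_sizes.items():
        n_bins = int(np.ceil(length / bin_size))
        diff = np.zeros(n_bins + 1)
        if chrom in grouped:
            g = grouped[chrom]
            starts = g["start"].to_numpy()
            ends = g["end"].to_numpy()
            if (ends > length).any():
                bad = g[ends > length].iloc[0]
                raise ValueError(
                    f"fragment [{bad['start']}, {bad['end']}) beyond end of "
                    f"{chrom} ({length} bp)"
                )
            first = starts // bin_size
            last = (ends - 1) // bin_size  # inclusive last overlapped bin
            np.add.at(diff, first, 1)
            np.add.at(diff, last + 1, -1)
        tracks[chrom] = CoverageTrack(
            chrom, bin_size, np.cumsum(diff[:-1]), origin=frags.sample_id
        )
    unknown = set(grouped) - set(chrom_sizes)
    if unknown:
        raise ValueError(f"fragments on chromosomes without sizes: {sorted(unknown)}")
    return tracks


class _ChromIndex:
    """Sorted start/end arrays per chromosome for O(log n) window counts."""

    def __init__(self, frags: FragmentSet):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, g in frags.by_chrom().items():
            self._starts[chrom] = np.sort(g["start"].to_numpy())
            self._ends[chrom] = np.sort(g["end"].to_numpy())

    def count(self, window: GenomicInterval) -> int:
        starts = self._starts.get(window.chrom)
        if starts is None:
            return 0
        ends = self._ends[window.chrom]
        # overlap >= 1 bp under half-open coords: start < w.end and end > w.start
        n_start_ok = np.searchsorted(starts, window.end, side="left")
        n_end_bad = np.searchsorted(ends, window.start, side="right")
        return int(n_start_ok - n_end_bad)


def window_count(frags: FragmentSet, window: GenomicInterval) -> int:
    """Number of fragments overlapping ``window`` by >= 1 bp."""
    return _ChromIndex(frags).count(window)


def window_counts(frags: FragmentSet, windows: Sequence[GenomicInterval]) -> np.ndarray:
    """Vectorized :func:`window_count` over many windows (index built once)."""
    index = _ChromIndex(frags)
    return np.array([index.count(w) for w in windows], dtype=int)


def cpm_normalize(count, library_size: int):
    """Counts per million: count * 1e6 / library_size."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return np.asarray(count, dtype=float) * 1e6 / library_size


def rpkm(count, gene_length, library_size: int):
    """Reads per kilobase per million mapped reads."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    gene_length = np.asarray(gene_length, dtype=float)
    if (gene_length <= 0).any():
        raise ValueError("gene_length must be > 0")
    return np.asarray(count, dtype=float) * 1e9 / (gene_length * library_size)


def metaprofile(
    frags: FragmentSet,
    anchors: Sequence,
    flank: int,
    bin_size: int = 10,
) -> MetaProfile:
    """Average fragment count per bin around anchors, edge-normalized.

    Anchors may be :class:`GeneRecord` (anchored at the TSS) or
    :class:`GenomicInterval` (anchored at the center). Profiles are oriented
    by anchor strand (minus-strand profiles reversed) so upstream/downstream
    are comparable, then averaged and divided by the mean of the first five
    and last five bins — the background level is thereby set to one.
    """
    if len(anchors) == 0:
        raise ValueError("at least one anchor required")
    if flank < 10 * bin_size:
        raise ValueError("flank must be >= 10*bin_size so edge bins exist")
    n_bins = 2 * flank // bin_size
    grouped = frags.by_chrom()
    total = np.zeros(n_bins)
    for anchor in anchors:
        if isinstance(anchor, GeneRecord):
            chrom, center, strand = anchor.chrom, anchor.tss, anchor.strand
        else:
            chrom = anchor.chrom
            center = (anchor.start + anchor.end) // 2
            strand = anchor.strand
        left = center - flank
        g = grouped.get(chrom)
        vals = np.zeros(n_bins)
        if g is not None:
            starts = g["start"].to_numpy() - left
            ends = g["end"].to_numpy() - left
            sel = (starts < 2 * flank) & (ends > 0)
            starts = np.clip(starts[sel], 0, None)
            ends = np.minimum(ends[sel], 2 * flank)
            first = starts // bin_size
            last = (ends - 1) // bin_size
            diff = np.zeros(n_bins + 1)
            np.add.at(diff, first, 1)
            np.add.at(diff, last + 1, -1)
            vals = np.cumsum(diff[:-1])
        if strand == "-":
            vals = vals[::-1]
        total += vals
    mean_profile = total / len(anchors)
    denom = np.mean(np.r_[mean_profile[:5], mean_profile[-5:]])
    if denom == 0:
        raise ValueError("zero signal in edge bins; cannot normalize background")
    return MetaProfile(flank, bin_size, mean_profile / denom, len(anchors))


def call_peaks_simple(
    treatment: CoverageTrack,
    control: CoverageTrack,
    fold_threshold: float,
    min_width: int,
    treatment_library: int | None = None,
    control_library: int | None = None,
    epsilon: float = 1.0,
    name: str = "peaks",
) -> PeakSet:
    """Threshold caller: maximal bin runs with fold enrichment over control.

    Control is scaled to the treatment library size; the pseudo-count
    ``epsilon`` (1 by default) keeps the ratio defined at empty bins without
    moving high-signal calls. Candidate runs separated by gaps of at most
    one bin are merged; runs shorter than ``min_width`` are dropped.
    """
    if treatment.bin_size != control.bin_size or treatment.chrom != control.chrom:
        raise ValueError("treatment and control tracks must share chrom and bin size")
    if len(treatment.values) != len(control.values):
        raise ValueError("treatment and control tracks must have equal bin counts")
    t = treatment.values
    c = control.values
    lib_t = treatment_library if treatment_library is not None else t.sum()
    lib_c = control_library if control_library is not None else c.sum()
    scale = (lib_t / lib_c) if lib_c > 0 else 1.0
    ratio = (t + epsilon) / (c * scale + epsilon)
    hot = ratio >= fold_threshold

    intervals = []
    bs = treatment.bin_size
    run_start = None
    gap = 0
    last_hot = None
    for i, h in enumerate(np.r_[hot, False]):
        if h:
            if run_start is None:
                run_start = i
            last_hot = i
            gap = 0
        elif run_start is not None:
            gap += 1
            if gap > 1 or i == len(hot):
                if (last_hot - run_start + 1) * bs >= min_width:
                    intervals.append(
                        GenomicInterval(
                            treatment.chrom, run_start * bs, (last_hot + 1) * bs
                        )
                    )
                run_start, last_hot, gap = None, None, 0
    return PeakSet(name=name, intervals=intervals)


def _merge_intervals(ivs: list[GenomicInterval]) -> list[GenomicInterval]:
    merged: list[list] = []
    for iv in sorted(ivs, key=lambda x: (x.chrom, x.start, x.end)):
        if merged and merged[-1][0] == iv.chrom and iv.start <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], iv.end)
        else:
            merged.append([iv.chrom, iv.start, iv.end])
    return [GenomicInterval(c, s, e) for c, s, e in merged]


def reproducible_peaks(
    replicate_sets: Sequence[PeakSet], min_support: int = 2
) -> PeakSet:
    """Keep merged loci supported by >= ``min_support`` replicates.

    A merged locus (union-merge of all replicate peaks) is supported by a
    replicate when at least one of its peaks overlaps the locus by >= 1 bp;
    kept loci carry the union coordinates of their contributing peaks.
    """
    if min_support > len(replicate_sets):
        raise ValueError(
            f"min_support={min_support} exceeds {len(replicate_sets)} replicates"
        )
    all_ivs = [iv for ps in replicate_sets for iv in ps.intervals]
    loci = _merge_intervals(all_ivs)
    kept = []
    for locus in loci:
        support = sum(
            any(iv.overlaps(locus) for iv in ps.intervals)
            for ps in replicate_sets
        )
        if support >= min_support:
            kept.append(locus)
    return PeakSet(name="reproducible", intervals=kept)


def nucleosome_occupancy(
    atac: FragmentSet,
    region: GenomicInterval,
    bin_size: int,
    sub_range: tuple = (30, 100),
    mono_range: tuple = (180, 247),
) -> NucleosomeProfile:
    """Fragment-size nucleosome occupancy summary over ``region``.

    Per bin (fragments assigned by midpoint), occupancy is
    ``n_mono / (n_mono + n_sub)`` using the sub-nucleosomal
    (``[sub_range[0], sub_range[1])``, i.e. below 100 bp by default) and
    mono-nucleosomal (``[mono_range[0], mono_range[1]]``, 180-247 bp)
    bands. Bins without band fragments are reported as NaN, not 0.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    n_bins = int(np.ceil(region.width / bin_size))
    g = atac.by_chrom().get(region.chrom)
    n_sub = np.zeros(n_bins)
    n_mono = np.zeros(n_bins)
    if g is not None:
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        mids = (starts + ends) // 2
        sizes = ends - starts
        inside = (mids >= region.start) & (mids < region.end)
        mids, sizes = mids[inside], sizes[inside]
        bins = (mids - region.start) // bin_size
        is_sub = (sizes >= sub_range[0]) & (sizes < sub_range[1])
        is_mono = (sizes >= mono_range[0]) & (sizes <= mono_range[1])
        np.add.at(n_sub, bins[is_sub], 1)
        np.add.at(n_mono, bins[is_mono], 1)
    total = n_sub + n_mono
    occupancy = np.full(n_bins, np.nan)
    nz = total > 0
    occupancy[nz] = n_mono[nz] / total[nz]
    return NucleosomeProfile(
        region=region,
        bin_size=bin_size,
        occupancy=occupancy,
        n_fragments=total,
        sub_range=sub_range,
        mono_range=mono_range,
    )
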