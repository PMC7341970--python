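"""Promoter H3K4me3/H3K27me3 ratio statistic and derived analyses.

The promoter chromatin state is summarized as the ratio of CPM-normalized
H3K4me3 to H3K27me3 fragment counts in a symmetric window (default
+/- 3 kb) around the annotated TSS, with a pseudo-count alpha (1 CPM) on
both marks so the ratio stays defined and rank-stable at low counts.
Knockout effects are expressed as the per-gene relative ratio
(knockout ratio / control ratio). The relationship between ratio and
expression is assessed by a sliding-window Spearman correlation: genes are
ordered by expression, both series are averaged within a 100-observation
window advanced 1 gene at a time, and the windowed means are rank-correlated.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import FragmentSet, GeneRecord, GenomicInterval, tss_window
from .signal import cpm_normalize, window_counts

PROMOTER_CLASSES = ("K4_only", "K27_only", "bivalent", "neither")


@dataclass
class BivalencyTable:
    """Per-gene K4/K27 window signal and ratio for one genotype.

    ``records`` columns: gene_id (index), k4_signal, k27_signal, ratio,
    log2_ratio, and (after classification / genotype comparison)
    promoter_class and relative_ratio.
    """

    genotype: str
    flank: int
    alpha: float
    records: pd.DataFrame

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# genotype={self.genotype} flank={self.flank} "
                     f"alpha={self.alpha} (CPM units)\n")
            self.records.to_csv(fh, sep="\t")


def promoter_signal(
    k4: FragmentSet,
    k27: FragmentSet,
    genes: Sequence[GeneRecord],
    flank: int = 3000,
    alpha: float = 1.0,
) -> BivalencyTable:
    """CPM-normalized K4/K27 window counts and pseudo-counted ratio per gene."""
    if k4.genotype != k27.genotype:
        raise ValueError(
            f"genotype mismatch between marks: {k4.genotype} vs {k27.genotype}"
        )
    if len(genes) == 0:
        raise ValueError("genes must be non-empty")
    windows = [tss_window(g, flank) for g in genes]
    k4_cpm = cpm_normalize(window_counts(k4, windows), len(k4))
    k27_cpm = cpm_normalize(window_counts(k27, windows), len(k27))
    ratio = (k4_cpm + alpha) / (k27_cpm + alpha)
    records = pd.DataFrame(
        {
            "k4_signal": k4_cpm,
            "k27_signal": k27_cpm,
            "ratio": ratio,
            "log2_ratio": np.log2(ratio),
        },
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
    )
    return BivalencyTable(k4.genotype, flank, alpha, records)


def classify_promoter(
    k4_signal: float, k27_signal: float, k4_threshold: float, k27_threshold: float
) -> str:
    """Three-category promoter class from mark signals and CPM thresholds."""
    if k4_threshold <= 0 or k27_threshold <= 0:
        raise ValueError("thresholds must be > 0 (CPM units)")
    k4_on = k4_signal > k4_threshold
    k27_on = k27_signal > k27_threshold
    if k4_on and k27_on:
        return "bivalent"
    if k4_on:
        return "K4_only"
    if k27_on:
        return "K27_only"
    return "neither"


def classify_table(
    table: BivalencyTable, k4_threshold: float, k27_threshold: float
) -> BivalencyTable:
    """Attach ``promoter_class`` to every record (returns the same table)."""
    table.records["promoter_class"] = [
        classify_promoter(r.k4_signal, r.k27_signal, k4_threshold, k27_threshold)
        for r in table.records.itertuples()
    ]
    return table


def background_threshold(
    frags: FragmentSet,
    genes: Sequence[GeneRecord],
    chrom_sizes: dict,
    flank: int = 3000,
    n_windows: int = 500,
    quantile: float = 0.95,
    seed: int = 0,
) -> float:
    """Mark-enrichment CPM threshold from random non-promoter windows.

    Draws windows of promoter width uniformly, rejecting any within
    2*flank of an annotated TSS, and returns the given quantile of their
    CPM (the default 95th percentile serves as the per-mark 'enriched'
    cutoff for promoter classification).
    """
    rng = np.random.default_rng(seed)
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, [])
        tss_by_chrom[g.chrom].append(g.tss)
    tss_by_chrom = {c: np.array(v) for c, v in tss_by_chrom.items()}
    chroms = list(chrom_sizes)
    windows = []
    attempts = 0
    while len(windows) < n_windows and attempts < n_windows * 50:
        attempts += 1
        chrom = chroms[rng.integers(len(chroms))]
        center = int(rng.integers(flank, chrom_sizes[chrom] - flank))
        near = tss_by_chrom.get(chrom)
        if near is not None and np.abs(near - center).min() < 2 * flank:
            continue
        windows.append(GenomicInterval(chrom, center - flank, center + flank))
    if not windows:
        raise ValueError("could not place background windows; genome too dense")
    cpm = cpm_normalize(window_counts(frags, windows), len(frags))
    return float(np.quantile(cpm, quantile))


def relative_ratio(
    ko_table: BivalencyTable, wt_table: BivalencyTable
) -> pd.Series:
    """Per-gene knockout/control ratio of ratios (1 = no change)."""
    if ko_table.flank != wt_table.flank or ko_table.alpha != wt_table.alpha:
        raise ValueError("tables computed with different flank or alpha")
    if not ko_table.records.index.equals(wt_table.records.index):
        if set(ko_table.records.index) != set(wt_table.records.index):
            raise ValueError("gene universes differ between tables")
        wt_table = BivalencyTable(
            wt_table.genotype, wt_table.flank, wt_table.alpha,
            wt_table.records.loc[ko_table.records.index],
        )
    rel = ko_table.records["ratio"] / wt_table.records["ratio"]
    ko_table.records["relative_ratio"] = rel
    return rel.rename("relative_ratio")


def rank_genes_by_ratio_change(
    ko_table: BivalencyTable, wt_table: BivalencyTable
) -> pd.DataFrame:
    """Genes sorted by descending relative ratio; ties broken by gene_id."""
    rel = relative_ratio(ko_table, wt_table)
    out = rel.to_frame().reset_index()
    out = out.sort_values(
        ["relative_ratio", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out


def mean_of_replicate_ratios(tables: Sequence[BivalencyTable]) -> BivalencyTable:
    """Combine replicate tables by the per-gene mean of per-replicate ratios."""
    if not tables:
        raise ValueError("no tables to combine")
    first = tables[0]
    for t in tables[1:]:
        if t.flank != first.flank or t.alpha != first.alpha:
            raise ValueError("replicate tables differ in flank or alpha")
        if not t.records.index.equals(first.records.index):
            raise ValueError("replicate tables differ in gene universe")
    records = pd.DataFrame(
        {
            "k4_signal": np.mean([t.records["k4_signal"] for t in tables], axis=0),
            "k27_signal": np.mean([t.records["k27_signal"] for t in tables], axis=0),
            "ratio": np.mean([t.records["ratio"] for t in tables], axis=0),
        },
        index=first.records.index,
    )
    records["log2_ratio"] = np.log2(records["ratio"])
    return BivalencyTable(first.genotype, first.flank, first.alpha, records)


def sliding_window_spearman(
    ratios: Sequence[float],
    expression: Sequence[float],
    window: int = 100,
    step: int = 1,
) -> tuple[float, int]:
    """Spearman rho between windowed means of ratio and expression.

    Genes are ordered by expression; both series are averaged in a sliding
    window of ``window`` observations advanced by ``step``; the two
    windowed-mean series are Spearman rank-correlated (ties mid-ranked).
    Returns ``(rho, n_windows)``.
    """
    r = np.asarray(ratios, dtype=float)
    e = np.asarray(expression, dtype=float)
    if r.shape != e.shape or r.ndim != 1:
        raise ValueError("ratios and expression must be equal-length 1-D arrays")
    if not (np.isfinite(r).all() and np.isfinite(e).all()):
        raise ValueError("inputs must be finite")
    n = len(r)
    if n < window:
        raise ValueError(
            f"need >= {window} genes for window={window}; got {n} "
            f"(use a smaller window)"
        )
    order = np.argsort(e, kind="mergesort")
    r, e = r[order], e[order]
    kernel = np.ones(window) / window
    r_win = np.convolve(r, kernel, mode="valid")[::step]
    e_win = np.convolve(e, kernel, mode="valid")[::step]
    if len(r_win) < 2 or np.all(r_win == r_win[0]) or np.all(e_win == e_win[0]):
        return float("nan"), len(r_win)
    rho = stats.spearmanr(e_win, r_win).statistic
    return float(rho), len(r_win)


def gene_set_ratio_test(
    relative_ratios: pd.Series,
    gene_set: Sequence[str],
    method: str = "mannwhitney",
) -> tuple[float, float]:
    """Compare relative ratios of a gene set against all other genes.

    Returns ``(median_of_set, p_value)``. ``method`` is ``"mannwhitney"``
    (default, robust at small replicate counts) or ``"ttest"`` (Welch, on
    log2 relative ratios).
    """
    in_set = relative_ratios.index.isin(set(gene_set))
    a = relative_ratios[in_set].to_numpy()
    b = relative_ratios[~in_set].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("gene set must be a non-trivial subset of the universe")
    if method == "mannwhitney":
        p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    elif method == "ttest":
        p = stats.ttest_ind(np.log2(a), np.log2(b), equal_var=False).pvalue
    else:
        raise ValueError("method must be 'mannwhitney' or 'ttest'")
    return float(np.median(a)), float(p)
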