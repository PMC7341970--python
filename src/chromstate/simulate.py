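"""Synthetic epigenome generator with known ground truth.

Emulates the data structure the downstream statistics assume: promoters in
three chromatin states (H3K4me3-only, H3K27me3-only, bivalent), a knockout
genotype that raises H3K4me3 and accessibility at a designated responsive
("PrE-like") subset of bivalent genes, three partially co-localizing
factor peak sets at promoters, ATAC fragment-size mixtures encoding
nucleosome occupancy, and negative-binomial expression counts whose mean
tracks the promoter K4/K27 ratio.

Fragments are drawn from a two-component inhomogeneous Poisson process
(enriched windows vs uniform background); there is no PCR-duplicate,
GC or mappability modelling. Every generator is bit-reproducible under a
fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .core import (
    FragmentSet,
    GeneRecord,
    GenomicInterval,
    PeakSet,
    fragments_from_arrays,
)

PROMOTER_STATES = ("k4_only", "k27_only", "bivalent", "neither")

_MARK_CODES = {
    "H3K4me3": 1,
    "H3K27me3": 2,
    "H3K4me1": 3,
    "H3K27ac": 4,
    "factorA": 5,
    "factorB": 6,
    "factorC": 7,
    "atac": 8,
    "expression": 9,
    "annotation": 10,
}

_GENOTYPE_CODES = {"control": 1, "knockout": 2}

#: factor-membership combinations at a promoter, ordered for multinomial draws
FACTOR_COMBOS = ("none", "A", "B", "C", "AB", "AC", "BC", "ABC")


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """All knobs of the synthetic epigenome.

    Defaults define the desk-scale study conditions: 2 chromosomes x 5 Mb,
    500 genes of which 50 bivalent genes respond to the knockout, depth
    2e5 fragments per sample, 3 replicates per genotype.
    """

    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 500
    state_fractions: dict = field(
        default_factory=lambda: {
            "k4_only": 0.30,
            "k27_only": 0.20,
            "bivalent": 0.30,
            "neither": 0.20,
        }
    )
    n_pre_like: int = 50
    # knockout effect sizes
    ko_k4_fold: float = 3.0        # H3K4me3 gain at responsive promoters
    ko_atac_fold: float = 4.0      # accessibility gain at responsive loci
    ko_expr_log2fc: float = 2.0    # expression gain at responsive genes
    enhancer_per_gene: int = 1
    # joint factor-binding design at promoters (probabilities over combos)
    factor_combo_probs: dict = field(
        default_factory=lambda: {
            "none": 0.35,
            "A": 0.05,
            "B": 0.05,
            "C": 0.05,
            "AB": 0.08,
            "AC": 0.07,
            "BC": 0.05,
            "ABC": 0.30,
        }
    )
    # fragment geometry
    chip_fragment_size_range: tuple = (200, 500)   # sonication range, bp
    atac_sub_range: tuple = (30, 100)              # sub-nucleosomal, bp
    atac_mono_range: tuple = (180, 247)            # mono-nucleosomal, bp
    atac_mix_weights: tuple = (0.6, 0.4)           # (sub, mono)
    # enrichment geometry
    promoter_halfwidth: int = 1500   # ChIP mark enrichment half-window
    factor_halfwidth: int = 1000     # factor binding half-window at TSS
    enhancer_halfwidth: int = 500
    # sampling
    chip_signal_fraction: float = 0.5
    atac_signal_fraction: float = 0.6
    depth: int = 200_000
    n_replicates: int = 3
    # expression model
    expr_baseline_log2: float = 7.0
    expr_link_coef: float = 1.0      # log2-mean slope on true promoter log2-ratio
    expr_dispersion: float = 0.1
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        fr = self.state_fractions
        if set(fr) != set(PROMOTER_STATES):
            raise SimulationError(f"state_fractions must have keys {PROMOTER_STATES}")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise SimulationError("state fractions must sum to 1")
        if abs(sum(self.factor_combo_probs.values()) - 1.0) > 1e-9:
            raise SimulationError("factor combo probabilities must sum to 1")
        if set(self.factor_combo_probs) != set(FACTOR_COMBOS):
            raise SimulationError(f"factor_combo_probs must have keys {FACTOR_COMBOS}")
        w = self.atac_mix_weights
        if abs(sum(w) - 1.0) > 1e-9:
            raise SimulationError("ATAC size-mixture weights must sum to 1")
        for name in ("n_chroms", "chrom_length", "n_genes", "depth",
                     "n_replicates", "enhancer_per_gene"):
            if getattr(self, name) < (0 if name == "enhancer_per_gene" else 1):
                raise SimulationError(f"{name} must be positive")
        for name in ("ko_k4_fold", "ko_atac_fold", "expr_dispersion"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be > 0")
        return self

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise SimulationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("chip_fragment_size_range", "atac_sub_range",
                    "atac_mono_range", "atac_mix_weights"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw).validate()


@dataclass
class SyntheticTruth:
    """Ground-truth labels backing parameter-recovery tests.

    ``table`` is indexed by gene_id with the promoter state, the responsive
    flag, per-genotype expected mark intensities and factor memberships;
    ``enhancers`` and ``dyads`` carry the regulatory geometry.
    """

    config: SimulationConfig
    genes: list
    table: pd.DataFrame
    enhancers: pd.DataFrame      # chrom, start, end, gene_id, state
    dyads: pd.DataFrame          # chrom, pos, gene_id
    chrom_sizes: dict

    @property
    def responsive_genes(self) -> list[str]:
        return list(self.table.index[self.table["responsive"]])

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def _rng(seed: int, *codes: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *[int(c) for c in codes]])


def simulate_annotation(config: SimulationConfig) -> tuple[list, SyntheticTruth]:
    """Place genes, draw promoter states and factor memberships, build truth.

    Genes sit on an evenly spaced grid so promoter windows never overlap;
    a genome too small for ``n_genes`` raises a capacity error.
    """
    config.validate()
    rng = _rng(config.seed, _MARK_CODES["annotation"])
    min_spacing = 16_000  # 2 * max flank (4 kb clusters) * safety margin
    per_chrom = int(np.ceil(config.n_genes / config.n_chroms))
    spacing = config.chrom_length // (per_chrom + 1)
    if spacing < min_spacing:
        raise SimulationError(
            f"genome too small: {config.n_genes} genes on {config.n_chroms} x "
            f"{config.chrom_length} bp gives spacing {spacing} < {min_spacing}"
        )
    chrom_sizes = {
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)
    }

    states = rng.choice(
        PROMOTER_STATES,
        size=config.n_genes,
        p=[config.state_fractions[s] for s in PROMOTER_STATES],
    )
    bivalent_idx = np.flatnonzero(states == "bivalent")
    if config.n_pre_like > len(bivalent_idx):
        raise SimulationError(
            f"n_pre_like={config.n_pre_like} exceeds number of bivalent genes "
            f"({len(bivalent_idx)}) drawn for this seed"
        )
    responsive = np.zeros(config.n_genes, dtype=bool)
    responsive[rng.choice(bivalent_idx, size=config.n_pre_like, replace=False)] = True

    combos = rng.choice(
        FACTOR_COMBOS,
        size=config.n_genes,
        p=[config.factor_combo_probs[c] for c in FACTOR_COMBOS],
    )
    strands = rng.choice(["+", "-"], size=config.n_genes)
    lengths = np.maximum(200, rng.lognormal(7.5, 0.5, config.n_genes)).astype(int)

    genes: list[GeneRecord] = []
    rows = []
    enh_rows = []
    dyad_rows = []
    for i in range(config.n_genes):
        chrom = f"chr{(i % config.n_chroms) + 1}"
        slot = i // config.n_chroms
        tss = int((slot + 1) * spacing + rng.integers(-spacing // 8, spacing // 8))
        tss = int(np.clip(tss, 5000, config.chrom_length - 5000))
        gid = f"gene{i:04d}"
        genes.append(GeneRecord(gid, chrom, tss, strands[i], int(lengths[i])))

        state = states[i]
        k4 = 1.0 if state in ("k4_only", "bivalent") else 0.0
        k27 = 1.0 if state in ("k27_only", "bivalent") else 0.0
        atac = 1.0 if state in ("k4_only", "bivalent") else 0.2
        k4_ko = k4 * (config.ko_k4_fold if responsive[i] else 1.0)
        atac_ko = atac * (config.ko_atac_fold if responsive[i] else 1.0)
        combo = combos[i]
        rows.append(
            {
                "gene_id": gid,
                "chrom": chrom,
                "tss": tss,
                "strand": strands[i],
                "state": state,
                "responsive": bool(responsive[i]),
                "factorA": "A" in combo,
                "factorB": "B" in combo,
                "factorC": "C" in combo,
                "k4_control": k4,
                "k4_knockout": k4_ko,
                "k27_control": k27,
                "k27_knockout": k27,
                "atac_control": atac,
                "atac_knockout": atac_ko,
            }
        )
        # flanking nucleosomes around the promoter NFR
        for off in (-400, -200, 200, 400):
            dyad_rows.append({"chrom": chrom, "pos": tss + off, "gene_id": gid})
        for _ in range(config.enhancer_per_gene):
            sign = rng.choice([-1, 1])
            dist = int(rng.integers(10_000, 50_000))
            center = int(np.clip(tss + sign * dist, 1000,
                                 config.chrom_length - 1000))
            hw = config.enhancer_halfwidth
            enh_rows.append(
                {
                    "chrom": chrom,
                    "start": center - hw,
                    "end": center + hw,
                    "gene_id": gid,
                    # bivalent promoters carry poised enhancers, active marks
                    # (H3K27ac) appear only at enhancers of K4-marked genes
                    "state": "poised" if state in ("bivalent", "k27_only")
                             else "active",
                }
            )
            for off in (-200, 200):
                dyad_rows.append({"chrom": chrom, "pos": center + off,
                                  "gene_id": gid})

    truth = SyntheticTruth(
        config=config,
        genes=genes,
        table=pd.DataFrame(rows).set_index("gene_id"),
        enhancers=pd.DataFrame(enh_rows),
        dyads=pd.DataFrame(dyad_rows),
        chrom_sizes=chrom_sizes,
    )
    return genes, truth


def _enrichment_windows(truth: SyntheticTruth, mark: str, genotype: str):
    """(chrom, center, halfwidth, intensity) arrays for one mark/genotype.

    Intensities are the control-genotype base rates scaled by the knockout
    folds where the truth says so; the Poisson means derived from them are
    NOT renormalized in the knockout, so a responsive window's expected
    count scales by exactly the configured fold.
    """
    cfg = truth.config
    t = truth.table
    if mark == "H3K4me3":
        inten = t[f"k4_{genotype}"].to_numpy()
        base = t["k4_control"].to_numpy()
        hw = cfg.promoter_halfwidth
        chroms, centers = t["chrom"].to_numpy(), t["tss"].to_numpy()
    elif mark == "H3K27me3":
        inten = t[f"k27_{genotype}"].to_numpy()
        base = t["k27_control"].to_numpy()
        hw = cfg.promoter_halfwidth
        chroms, centers = t["chrom"].to_numpy(), t["tss"].to_numpy()
    elif mark in ("factorA", "factorB", "factorC"):
        inten = t[mark].to_numpy().astype(float)
        base = inten
        hw = cfg.factor_halfwidth
        chroms, centers = t["chrom"].to_numpy(), t["tss"].to_numpy()
    elif mark in ("H3K4me1", "H3K27ac"):
        e = truth.enhancers
        if mark == "H3K4me1":
            inten = np.ones(len(e))
        else:
            inten = (e["state"] == "active").to_numpy().astype(float)
        base = inten
        hw = cfg.enhancer_halfwidth
        chroms = e["chrom"].to_numpy()
        centers = ((e["start"] + e["end"]) // 2).to_numpy()
    else:
        raise SimulationError(f"unknown ChIP target {mark!r}")
    keep = base > 0
    return chroms[keep], centers[keep], hw, inten[keep], base[keep].sum()


def simulate_chip_fragments(
    truth: SyntheticTruth,
    mark_or_factor: str,
    genotype: str,
    depth: int | None = None,
    replicate: int = 0,
    seed: int | None = None,
) -> FragmentSet:
    """Draw ChIP fragments: enriched windows plus uniform background.

    Expected total fragment count equals ``depth`` in the control genotype
    (knockout totals drift upward with the enrichment folds, as in a real
    per-library sequencing run the depth would be re-normalized downstream).
    """
    cfg = truth.config
    if genotype not in _GENOTYPE_CODES:
        raise SimulationError(f"unknown genotype {genotype!r}")
    if mark_or_factor not in _MARK_CODES or mark_or_factor in ("atac", "expression",
                                                               "annotation"):
        raise SimulationError(f"unknown ChIP target {mark_or_factor!r}")
    depth = int(depth if depth is not None else cfg.depth)
    if depth <= 0:
        raise SimulationError("depth must be > 0")
    seed = cfg.seed if seed is None else seed
    rng = _rng(seed, _MARK_CODES[mark_or_factor],
               _GENOTYPE_CODES[genotype], replicate)

    chroms, centers, hw, inten, base_total = _enrichment_windows(
        truth, mark_or_factor, genotype
    )
    sig_mean = depth * cfg.chip_signal_fraction
    bg_mean = depth * (1.0 - cfg.chip_signal_fraction)

    out_chrom, out_start, out_end = [], [], []
    smin, smax = cfg.chip_fragment_size_range

    if base_total > 0:
        window_means = sig_mean * inten / base_total
        counts = rng.poisson(window_means)
        for c, center, n in zip(chroms, centers, counts):
            if n == 0:
                continue
            mids = rng.normal(center, hw / 2.0, n)
            sizes = rng.integers(smin, smax + 1, n)
            starts = np.clip((mids - sizes / 2).astype(int), 0, None)
            ends = starts + sizes
            limit = truth.chrom_sizes[c]
            over = ends > limit
            starts[over] = limit - sizes[over]
            out_chrom.extend([c] * int(n))
            out_start.append(starts)
            out_end.append(starts + sizes)

    n_bg = rng.poisson(bg_mean)
    if n_bg:
        chrom_names = list(truth.chrom_sizes)
        bg_chrom_idx = rng.integers(0, len(chrom_names), n_bg)
        sizes = rng.integers(smin, smax + 1, n_bg)
        lens = np.array([truth.chrom_sizes[chrom_names[i]] for i in bg_chrom_idx])
        starts = (rng.random(n_bg) * (lens - sizes)).astype(int)
        out_chrom.extend(chrom_names[i] for i in bg_chrom_idx)
        out_start.append(starts)
        out_end.append(starts + sizes)

    starts = np.concatenate(out_start) if out_start else np.array([], dtype=int)
    ends = np.concatenate(out_end) if out_end else np.array([], dtype=int)
    return fragments_from_arrays(
        out_chrom, starts, ends,
        sample_id=f"{mark_or_factor}_{genotype}_rep{replicate}",
        genotype=genotype,
        assay=f"chip:{mark_or_factor}",
        chrom_sizes=truth.chrom_sizes,
    )


def _atac_loci(truth: SyntheticTruth, genotype: str):
    """Accessible loci (promoters + enhancers) with per-genotype intensity."""
    cfg = truth.config
    t = truth.table
    rows = []
    for gid, row in t.iterrows():
        rows.append(
            {
                "locus_id": f"prom_{gid}",
                "chrom": row["chrom"],
                "center": int(row["tss"]),
                "halfwidth": cfg.factor_halfwidth,
                "intensity": float(row[f"atac_{genotype}"]),
                "responsive": bool(row["responsive"]),
                "gene_id": gid,
            }
        )
    resp = set(truth.responsive_genes)
    for j, row in truth.enhancers.iterrows():
        base = 1.0 if row["state"] == "active" else 0.5
        is_resp = row["gene_id"] in resp
        inten = base * (cfg.ko_atac_fold if (is_resp and genotype == "knockout")
                        else 1.0)
        rows.append(
            {
                "locus_id": f"enh_{row['gene_id']}_{j}",
                "chrom": row["chrom"],
                "center": int((row["start"] + row["end"]) // 2),
                "halfwidth": cfg.enhancer_halfwidth,
                "intensity": inten,
                "responsive": is_resp,
                "gene_id": row["gene_id"],
            }
        )
    return pd.DataFrame(rows)


def simulate_atac_fragments(
    truth: SyntheticTruth,
    genotype: str,
    depth: int | None = None,
    replicate: int = 0,
    seed: int | None = None,
) -> FragmentSet:
    """Draw ATAC fragments with a sub/mono-nucleosomal size mixture.

    Sub-nucleosomal fragments localize the nucleosome-free region at each
    accessible locus; mono-nucleosomal fragments center on the truth dyads
    flanking it; background fragments are uniform. Knockout multiplies the
    sampling rate at responsive loci by ``ko_atac_fold``.
    """
    cfg = truth.config
    if genotype not in _GENOTYPE_CODES:
        raise SimulationError(f"unknown genotype {genotype!r}")
    depth = int(depth if depth is not None else cfg.depth)
    if depth <= 0:
        raise SimulationError("depth must be > 0")
    seed = cfg.seed if seed is None else seed
    rng = _rng(seed, _MARK_CODES["atac"], _GENOTYPE_CODES[genotype], replicate)

    w_sub, w_mono = cfg.atac_mix_weights
    loci = _atac_loci(truth, genotype)
    base = _atac_loci(truth, "control")["intensity"].to_numpy()
    sig_mean = depth * cfg.atac_signal_fraction
    bg_mean = depth * (1.0 - cfg.atac_signal_fraction)
    dyads_by_gene = {
        g: d["pos"].to_numpy() for g, d in truth.dyads.groupby("gene_id")
    }

    out_chrom, out_mid, out_size = [], [], []
    means = sig_mean * loci["intensity"].to_numpy() / base.sum()
    counts = rng.poisson(means)
    for (_, locus), n in zip(loci.iterrows(), counts):
        if n == 0:
            continue
        is_mono = rng.random(n) < w_mono
        n_mono = int(is_mono.sum())
        n_sub = n - n_mono
        mids = np.empty(n)
        sizes = np.empty(n, dtype=int)
        if n_sub:
            mids[~is_mono] = rng.normal(locus["center"], 50.0, n_sub)
            sizes[~is_mono] = rng.integers(*cfg.atac_sub_range, n_sub)
        if n_mono:
            gd = dyads_by_gene[locus["gene_id"]]
            near = gd[np.abs(gd - locus["center"]) <= locus["halfwidth"] + 500]
            if len(near) == 0:
                near = gd
            mids[is_mono] = rng.choice(near, n_mono) + rng.normal(0, 20.0, n_mono)
            sizes[is_mono] = rng.integers(cfg.atac_mono_range[0],
                                          cfg.atac_mono_range[1] + 1, n_mono)
        out_chrom.extend([locus["chrom"]] * int(n))
        out_mid.append(mids)
        out_size.append(sizes)

    n_bg = rng.poisson(bg_mean)
    if n_bg:
        chrom_names = list(truth.chrom_sizes)
        idx = rng.integers(0, len(chrom_names), n_bg)
        is_mono = rng.random(n_bg) < w_mono
        sizes = np.where(
            is_mono,
            rng.integers(cfg.atac_mono_range[0], cfg.atac_mono_range[1] + 1, n_bg),
            rng.integers(*cfg.atac_sub_range, n_bg),
        )
        lens = np.array([truth.chrom_sizes[chrom_names[i]] for i in idx])
        mids = rng.random(n_bg) * (lens - sizes) + sizes / 2
        out_chrom.extend(chrom_names[i] for i in idx)
        out_mid.append(mids)
        out_size.append(sizes)

    mids = np.concatenate(out_mid) if out_mid else np.array([])
    sizes = (np.concatenate(out_size) if out_size else np.array([], dtype=int))
    starts = np.clip((mids - sizes / 2).astype(int), 0, None)
    lims = np.array([truth.chrom_sizes[c] for c in out_chrom], dtype=int) \
        if out_chrom else np.array([], dtype=int)
    over = starts + sizes > lims
    if over.any():
        starts[over] = lims[over] - sizes[over]
    return fragments_from_arrays(
        out_chrom, starts, starts + sizes,
        sample_id=f"atac_{genotype}_rep{replicate}",
        genotype=genotype,
        assay="atac",
        chrom_sizes=truth.chrom_sizes,
    )


def true_promoter_log2_ratio(truth: SyntheticTruth, genotype: str,
                             alpha: float = 0.25) -> pd.Series:
    """Expected promoter log2(K4/K27) from truth intensities (pseudo-count alpha)."""
    t = truth.table
    return np.log2(
        (t[f"k4_{genotype}"] + alpha) / (t[f"k27_{genotype}"] + alpha)
    ).rename("true_log2_ratio")


def simulate_expression(
    truth: SyntheticTruth,
    genotype: str,
    n_replicates: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Negative-binomial counts; log2 mean linear in the true promoter log2-ratio.

    Responsive genes shift their mean by ``ko_expr_log2fc`` in the knockout.
    Returns a genes x replicates DataFrame.
    """
    cfg = truth.config
    if genotype not in _GENOTYPE_CODES:
        raise SimulationError(f"unknown genotype {genotype!r}")
    n_replicates = cfg.n_replicates if n_replicates is None else n_replicates
    if n_replicates < 2:
        raise SimulationError("n_replicates must be >= 2")
    if cfg.expr_dispersion <= 0:
        raise SimulationError("dispersion must be > 0")
    seed = cfg.seed if seed is None else seed
    rng = _rng(seed, _MARK_CODES["expression"], _GENOTYPE_CODES[genotype])

    ratio = true_promoter_log2_ratio(truth, "control")
    log2_mu = cfg.expr_baseline_log2 + cfg.expr_link_coef * ratio
    if genotype == "knockout":
        log2_mu = log2_mu + cfg.ko_expr_log2fc * truth.table["responsive"]
    mu = np.power(2.0, log2_mu.to_numpy())
    r = 1.0 / cfg.expr_dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(
        r, p[:, None], size=(len(mu), n_replicates)
    )
    return pd.DataFrame(
        counts,
        index=truth.table.index,
        columns=[f"{genotype}_rep{i + 1}" for i in range(n_replicates)],
    )


def emit_true_peaks(truth: SyntheticTruth, factor: str) -> PeakSet:
    """Exact truth binding windows for one factor (no peak calling needed)."""
    if factor not in ("factorA", "factorB", "factorC"):
        raise SimulationError(f"unknown factor {factor!r}")
    cfg = truth.config
    hw = cfg.factor_halfwidth
    rows = truth.table[truth.table[factor]]
    intervals = [
        GenomicInterval(r["chrom"], max(0, int(r["tss"]) - hw), int(r["tss"]) + hw)
        for _, r in rows.iterrows()
    ]
    return PeakSet(name=factor, intervals=intervals)


def emit_accessible_peaks(truth: SyntheticTruth) -> tuple[PeakSet, pd.DataFrame]:
    """Consensus accessible loci (promoters + enhancers) and their labels.

    Returns the PeakSet plus a frame (locus_id, chrom, start, end,
    responsive) aligned with it; the responsive flag marks the loci whose
    accessibility the knockout elevates.
    """
    loci = _atac_loci(truth, "control").copy()
    loci["start"] = (loci["center"] - loci["halfwidth"]).clip(lower=0)
    loci["end"] = loci["center"] + loci["halfwidth"]
    loci = loci.sort_values(["chrom", "start"]).reset_index(drop=True)
    peaks = PeakSet(
        name="accessible",
        intervals=[
            GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]))
            for _, r in loci.iterrows()
        ],
    )
    return peaks, loci[["locus_id", "chrom", "start", "end", "responsive",
                        "gene_id"]]


def make_venn_fixture(
    combo_counts: dict[str, int],
    peak_width: int = 400,
    gap: int = 600,
    chrom: str = "chrV",
) -> dict[str, PeakSet]:
    """Deterministic peak sets realizing exact per-combination locus counts.

    ``combo_counts`` maps a membership string over {A, B, C} (e.g. ``"AB"``)
    to the number of loci carried by exactly those sets. Each locus is one
    shared interval per member set, so pairwise overlaps are one-to-one and
    the merged union has exactly ``sum(combo_counts.values())`` loci.
    """
    sets: dict[str, list[GenomicInterval]] = {"A": [], "B": [], "C": []}
    pos = 0
    for combo in sorted(combo_counts):
        members = set(combo)
        if not members or not members.issubset({"A", "B", "C"}):
            raise ValueError(f"combo must be a non-empty subset of ABC: {combo!r}")
        for _ in range(int(combo_counts[combo])):
            iv = GenomicInterval(chrom, pos, pos + peak_width)
            for m in members:
                sets[m].append(iv)
            pos += peak_width + gap
    return {name: PeakSet(name=name, intervals=ivs) for name, ivs in sets.items()}
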