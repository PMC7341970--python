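"""Count-based differential tests, BH FDR control, and qPCR utilities.

One documented negative-binomial test serves both expression and
accessibility contrasts. Per feature, replicate counts are normalized by
total-count scaling to a common library size; the NB dispersion is
estimated by the method of moments (``(var - mean) / mean^2``), pooled
across features as the median of positive per-feature estimates with a
floor of 0.01. The test statistic is the 1-df NB deviance between the
common-mean and the two-group-mean fits, divided by a quasi-likelihood
scale (the mean across features of the within-group residual deviance per
residual degree of freedom); the scaled deviance is referred to chi-square
with 1 df, two-sided by construction. The global scale absorbs both the
small-replicate inflation of the deviance and the downward bias of the
moment dispersion, which keeps the test calibrated at 2-3 replicates per
group without sacrificing the power a per-feature small-df reference would
cost. log2 fold changes carry a pseudo-count of 0.5 on the normalized
means. Significance follows the FDR < 0.05 and |log2FC| > 1 rule
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GenomicInterval, PeakSet

DISPERSION_FLOOR = 0.01
LOG2FC_PSEUDOCOUNT = 0.5


@dataclass
class DiffResult:
    """Per-feature differential table with BH-adjusted significance calls."""

    table: pd.DataFrame  # feature_id index; baseMean1, baseMean2, log2FC, p, q
    fdr_threshold: float = 0.05
    lfc_threshold: float = 1.0

    def __post_init__(self) -> None:
        t = self.table
        if ((t["p"] < 0) | (t["p"] > 1)).any() or ((t["q"] < 0) | (t["q"] > 1)).any():
            raise ValueError("p and q values must lie in [0, 1]")
        t["significant"] = (t["q"] < self.fdr_threshold) & (
            t["log2FC"].abs() > self.lfc_threshold
        )

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def _normalize(counts: np.ndarray) -> np.ndarray:
    """Total-count scaling of a features x samples matrix to the mean depth."""
    lib = counts.sum(axis=0).astype(float)
    target = lib.mean() if lib.sum() > 0 else 1.0
    scale = np.where(lib > 0, target / lib, 1.0)
    return counts * scale


def _moment_dispersion(norm1: np.ndarray, norm2: np.ndarray) -> float:
    """Pooled method-of-moments NB dispersion with a floor.

    Per feature and group, ``phi = (var - mean) / mean^2``; the pooled value
    is the median of positive estimates across features, floored at 0.01.
    """
    phis = []
    for grp in (norm1, norm2):
        m = grp.mean(axis=1)
        v = grp.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = (v - m) / np.square(m)
        phis.append(phi[np.isfinite(phi)])
    allphi = np.concatenate(phis) if phis else np.array([])
    positive = allphi[allphi > 0]
    if len(positive) == 0:
        return DISPERSION_FLOOR
    return max(float(np.median(positive)), DISPERSION_FLOOR)


def _nb_loglik(x: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Elementwise NB log-likelihood (size 1/phi), safe at mu or x of 0."""
    from scipy.special import gammaln

    r = 1.0 / phi
    mu = np.maximum(mu, 1e-8)
    return (
        gammaln(x + r) - gammaln(r) - gammaln(x + 1)
        + r * np.log(r / (r + mu))
        + x * np.log(mu / (r + mu))
    )


def nb_test(
    counts_group1: np.ndarray, counts_group2: np.ndarray
) -> pd.DataFrame:
    """Two-sided NB test per feature (quasi-likelihood-scaled deviance).

    ``counts_group1``/``counts_group2`` are features x replicates arrays
    (>= 2 replicates each). Returns a frame with baseMean1, baseMean2,
    log2FC (group2 over group1) and p. Features with zero counts in both
    groups get ``p = 1`` and ``log2FC = 0``.
    """
    c1 = np.atleast_2d(np.asarray(counts_group1, dtype=float))
    c2 = np.atleast_2d(np.asarray(counts_group2, dtype=float))
    if c1.shape[0] != c2.shape[0]:
        raise ValueError("groups must share the feature axis")
    n1, n2 = c1.shape[1], c2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 replicates per group")

    norm = _normalize(np.hstack([c1, c2]))
    norm1, norm2 = norm[:, :n1], norm[:, n1:]
    m1 = norm1.mean(axis=1)
    m2 = norm2.mean(axis=1)
    m0 = norm.mean(axis=1)
    phi = _moment_dispersion(norm1, norm2)

    # 1-df deviance: common mean vs per-group means
    dev = 2.0 * (
        _nb_loglik(norm1, m1[:, None], phi).sum(axis=1)
        + _nb_loglik(norm2, m2[:, None], phi).sum(axis=1)
        - _nb_loglik(norm, m0[:, None], phi).sum(axis=1)
    )
    # within-group residual deviance (saturated vs fitted), pooled into a
    # global quasi-likelihood scale with n1+n2-2 residual df per feature
    dres = 2.0 * (
        (_nb_loglik(norm1, norm1, phi)
         - _nb_loglik(norm1, m1[:, None], phi)).sum(axis=1)
        + (_nb_loglik(norm2, norm2, phi)
           - _nb_loglik(norm2, m2[:, None], phi)).sum(axis=1)
    )
    finite = np.isfinite(dres)
    scale = max(
        float(np.mean(dres[finite]) / (n1 + n2 - 2)) if finite.any() else 1.0,
        1e-8,
    )
    p = stats.chi2.sf(np.maximum(dev, 0.0) / scale, df=1)

    log2fc = np.log2((m2 + LOG2FC_PSEUDOCOUNT) / (m1 + LOG2FC_PSEUDOCOUNT))
    allzero = (m1 == 0) & (m2 == 0)
    p = np.where(allzero | ~np.isfinite(p), 1.0, np.clip(p, 0.0, 1.0))
    log2fc = np.where(allzero, 0.0, log2fc)
    return pd.DataFrame(
        {"baseMean1": m1, "baseMean2": m2, "log2FC": log2fc, "p": p}
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_test(
    counts_group1,
    counts_group2,
    feature_ids=None,
    fdr: float = 0.05,
    lfc: float = 1.0,
) -> DiffResult:
    """NB test + BH adjustment + significance flags in one step."""
    table = nb_test(counts_group1, counts_group2)
    table["q"] = bh_fdr(table["p"].to_numpy())
    if feature_ids is not None:
        table.index = pd.Index(feature_ids, name="feature_id")
    else:
        table.index.name = "feature_id"
    return DiffResult(table, fdr_threshold=fdr, lfc_threshold=lfc)


def call_deg(
    result: DiffResult, fdr: float = 0.05, lfc: float = 1.0
) -> dict[str, list]:
    """Split significant features into up/down (group2 relative to group1)."""
    t = result.table
    sig = (t["q"] < fdr) & (t["log2FC"].abs() > lfc)
    return {
        "up": list(t.index[sig & (t["log2FC"] > lfc)]),
        "down": list(t.index[sig & (t["log2FC"] < -lfc)]),
    }


def diff_accessibility(
    peak_counts_wt, peak_counts_ko, peak_ids=None,
    fdr: float = 0.05, lfc: float = 1.0,
) -> DiffResult:
    """Differential accessibility over a fixed consensus peak set.

    Same NB test and FDR < 0.05 & |log2FC| > 1 rule as expression, applied
    to per-peak replicate fragment counts (knockout over control).
    """
    return differential_test(
        peak_counts_wt, peak_counts_ko, feature_ids=peak_ids, fdr=fdr, lfc=lfc
    )


def classify_dependent_peaks(
    diff: DiffResult,
    peaks: PeakSet,
    direction: str = "increase_in_KO",
) -> tuple[PeakSet, PeakSet]:
    """Partition consensus peaks into factor-dependent and -independent sets.

    Dependent = significant with log2FC in the stated direction
    (``increase_in_KO`` keeps log2FC > 0, ``decrease_in_KO`` keeps < 0);
    everything else is independent. The two sets partition the input.
    """
    if direction not in ("increase_in_KO", "decrease_in_KO"):
        raise ValueError("direction must be increase_in_KO or decrease_in_KO")
    if len(diff.table) != len(peaks):
        raise ValueError("diff table and peak set lengths differ")
    sign_ok = (
        diff.table["log2FC"] > 0
        if direction == "increase_in_KO"
        else diff.table["log2FC"] < 0
    )
    dep_mask = (diff.table["significant"] & sign_ok).to_numpy()
    dep = [iv for iv, m in zip(peaks.intervals, dep_mask) if m]
    indep = [iv for iv, m in zip(peaks.intervals, dep_mask) if not m]
    return (
        PeakSet(name=f"{peaks.name}_dependent", intervals=dep),
        PeakSet(name=f"{peaks.name}_independent", intervals=indep),
    )


def ddct_fold_change(
    ct_target_cond: float,
    ct_ref_cond: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCt method."""
    ddct = (ct_target_cond - ct_ref_cond) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))


def percent_input(ct_input: float, ct_ip: float, input_fraction: float) -> float:
    """ChIP-qPCR enrichment as percent of input chromatin.

    The input Ct is first adjusted for the fraction of chromatin it
    represents (``ct_input - log2(1/input_fraction)``), then
    ``100 * 2^(ct_input_adj - ct_ip)``.
    """
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must lie in (0, 1]")
    ct_input_adj = ct_input - np.log2(1.0 / input_fraction)
    return float(100.0 * 2.0 ** (ct_input_adj - ct_ip))
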