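"""Transcript- and gene-level differential expression with overlap analysis.

The test is a self-contained negative-binomial Wald test: library sizes are
normalised by median-of-ratios, per-feature dispersions are estimated by
method of moments and shrunk toward a mean-dispersion trend, and the Wald
statistic on the log2 fold change (condition 2 over condition 1) uses the NB
variance of the log group means.  Benjamini-Hochberg FDR is applied across
tested features, separately at transcript and gene level.  A feature is
called differentially expressed when |log2FC| > 1 and FDR < 0.05.

An adapter (:func:`read_external_results`) ingests per-feature results
produced by an external tool (id, log2FC, padj) so the exact upstream
toolchain can be reproduced when desired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LOG2FC_CUTOFF = 1.0
FDR_CUTOFF = 0.05


@dataclass
class DeResult:
    feature_id: str
    level: str  # "transcript" | "gene"
    base_mean: float
    log2fc: float
    pvalue: float
    fdr: float
    call: bool


def normalize(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and normalised counts.

    The size factor of a sample is the median, over features positive in all
    samples, of count / geometric row mean.  If no feature is positive in all
    samples, total-count scaling is used with a warning.
    """
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    if (counts.values < 0).any():
        raise ValueError("counts must be nonnegative")
    mat = counts.values.astype(float)
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        warnings.warn(
            "no feature positive in all samples; falling back to "
            "total-count scaling"
        )
        totals = mat.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(totals)))
    else:
        logmat = np.log(mat[allpos])
        loggeo = logmat.mean(axis=1)
        sf = np.exp(np.median(logmat - loggeo[:, None], axis=0))
    size_factors = pd.Series(sf, index=counts.columns)
    return size_factors, counts / size_factors


def _dispersion_estimates(norm: np.ndarray, groups: list[np.ndarray]):
    """Method-of-moments dispersions shrunk toward a 1/mu + a0 trend."""
    means = norm.mean(axis=1)
    mom = np.zeros(norm.shape[0])
    for g in groups:
        sub = norm[:, g]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = (v - m) / np.maximum(m, 1e-8) ** 2
        mom += np.where(np.isfinite(d), d, 0.0)
    mom /= len(groups)
    mom = np.clip(mom, 1e-8, 10.0)
    # fit dispersion trend alpha(mu) = a1/mu + a0 by least squares on the
    # per-feature estimates (gamma-family style trend)
    x = 1.0 / np.maximum(means, 1e-8)
    keep = means > 0
    if keep.sum() >= 10:
        A = np.column_stack([x[keep], np.ones(keep.sum())])
        coef, *_ = np.linalg.lstsq(A, mom[keep], rcond=None)
        a1, a0 = max(coef[0], 0.0), max(coef[1], 1e-6)
    else:
        a1, a0 = 0.0, max(float(np.median(mom)), 1e-6)
    trend = a1 * x + a0
    # shrink on the log scale toward the trend
    shrunk = np.exp(0.5 * np.log(mom) + 0.5 * np.log(trend))
    return np.clip(shrunk, 1e-8, 10.0)


def de_test(
    counts: pd.DataFrame,
    groups: list[str],
    level: str = "transcript",
) -> list[DeResult]:
    """Per-feature NB Wald test between the two conditions in ``groups``.

    ``groups`` assigns each column to a condition (exactly two distinct
    labels, >= 2 replicates each).  Features with all-zero counts are
    excluded from testing and from the BH denominator.
    """
    labels = list(dict.fromkeys(groups))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 conditions, got {labels}")
    g1 = np.array([g == labels[0] for g in groups])
    g2 = np.array([g == labels[1] for g in groups])
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValueError("each condition needs >= 2 replicates")
    _, norm_df = normalize(counts)
    norm = norm_df.values.astype(float)
    nonzero = norm.sum(axis=1) > 0
    alpha = _dispersion_estimates(norm[nonzero], [g1, g2])

    sub = norm[nonzero]
    mu1 = sub[:, g1].mean(axis=1)
    mu2 = sub[:, g2].mean(axis=1)
    n1, n2 = g1.sum(), g2.sum()
    eps = 0.5
    lfc = np.log2((mu2 + eps) / (mu1 + eps))
    # delta-method variance of log2 of an NB group mean
    var_log1 = (1.0 / np.maximum(mu1, eps) + alpha) / n1
    var_log2 = (1.0 / np.maximum(mu2, eps) + alpha) / n2
    se = np.sqrt(var_log1 + var_log2) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = lfc / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals = np.clip(pvals, 0.0, 1.0)
    _, fdr, *_ = multipletests(pvals, method="fdr_bh")

    base_mean = sub.mean(axis=1)
    results: list[DeResult] = []
    ids = counts.index[nonzero]
    for i, fid in enumerate(ids):
        call = bool(abs(lfc[i]) > LOG2FC_CUTOFF and fdr[i] < FDR_CUTOFF)
        results.append(
            DeResult(
                str(fid), level, float(base_mean[i]), float(lfc[i]),
                float(pvals[i]), float(fdr[i]), call,
            )
        )
    return results


def gene_level(
    counts: pd.DataFrame, tx2gene: dict[str, str]
) -> pd.DataFrame:
    """Gene count matrix: sum of member-transcript counts per sample."""
    missing = [t for t in counts.index if t not in tx2gene]
    if missing:
        raise ValueError(
            f"{len(missing)} transcripts with no gene: {missing[:5]}"
        )
    gene_ids = pd.Series({t: tx2gene[t] for t in counts.index})
    out = counts.groupby(gene_ids).sum()
    out.index.name = counts.index.name
    return out


@dataclass
class OverlapReport:
    n_det: int
    n_detg: int
    n_deg: int
    n_overlap: int
    pct_of_detg: float
    pct_of_deg: float


def overlap_report(
    det: list[DeResult], deg: list[DeResult], tx2gene: dict[str, str]
) -> OverlapReport:
    """Overlap between genes owning >= 1 called transcript and called genes."""
    from .summary import percentage

    det_called = [r for r in det if r.call]
    detg = {tx2gene[r.feature_id] for r in det_called}
    deg_called = {r.feature_id for r in deg if r.call}
    inter = detg & deg_called
    return OverlapReport(
        n_det=len(det_called),
        n_detg=len(detg),
        n_deg=len(deg_called),
        n_overlap=len(inter),
        pct_of_detg=percentage(len(inter), len(detg)) if detg else 0.0,
        pct_of_deg=percentage(len(inter), len(deg_called)) if deg_called else 0.0,
    )


def results_table(results: list[DeResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "level": r.level,
                "baseMean": r.base_mean,
                "log2FC": r.log2fc,
                "pvalue": r.pvalue,
                "FDR": r.fdr,
                "call": r.call,
            }
            for r in results
        ]
    )


def read_external_results(path, level: str = "transcript") -> list[DeResult]:
    """Adapter for externally produced per-feature tables (id, log2FC, padj)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    idc = cols.get("id") or df.columns[0]
    lfc = cols.get("log2fc") or cols.get("log2foldchange")
    padj = cols.get("padj") or cols.get("fdr")
    out = []
    for _, row in df.iterrows():
        l2 = float(row[lfc])
        q = float(row[padj]) if pd.notna(row[padj]) else 1.0
        out.append(
            DeResult(
                str(row[idc]), level, float("nan"), l2, float("nan"), q,
                bool(abs(l2) > LOG2FC_CUTOFF and q < FDR_CUTOFF),
            )
        )
    return out
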