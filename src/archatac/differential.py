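"""Count-based differential testing and accessibility-transcription correlation.

A self-contained negative-binomial Wald test on feature x library count
tables: median-of-ratios size factors, per-feature method-of-moments
dispersion pooled within groups, delta-method standard error on the log2
fold change, normal reference p-values and Benjamini-Hochberg q-values.
No empirical-Bayes dispersion shrinkage is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import CountTable, FragmentSet, GenomeAnnotation

_LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if len(p) == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors, rescaled to geometric mean 1.

    Uses only features with nonzero counts in every library (the geometric
    mean is otherwise zero).
    """
    arr = counts.to_numpy(dtype=float)
    all_nonzero = (arr > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no feature with nonzero counts in all libraries")
    sub = arr[all_nonzero]
    gmean = np.exp(np.log(sub).mean(axis=1))
    factors = np.median(sub / gmean[:, None], axis=0)
    factors = factors / np.exp(np.log(factors).mean())
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _group_moments(norm: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    mean = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1) if norm.shape[1] > 1 else np.zeros(len(norm))
    return mean, var, norm.shape[1]


def nb_differential(
    table: CountTable | pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-feature NB Wald test of group B vs group A.

    Counts are normalized by size factors; the NB dispersion alpha is
    estimated per feature by method of moments on normalized counts,
    pooled across the two groups and floored.  With a single library in
    a group the test falls back to Poisson dispersion (alpha = 0) with a
    warning.
    """
    counts = table.counts if isinstance(table, CountTable) else table
    missing = [c for c in group_a + group_b if c not in counts.columns]
    if missing:
        raise ValueError(f"unknown libraries: {missing}")
    libs = list(group_a) + list(group_b)
    sf = size_factors(counts[libs])
    norm = counts[libs].to_numpy(dtype=float) / sf.to_numpy()
    norm_a = norm[:, : len(group_a)]
    norm_b = norm[:, len(group_a):]

    mean_a, var_a, n_a = _group_moments(norm_a)
    mean_b, var_b, n_b = _group_moments(norm_b)
    if n_a < 2 or n_b < 2:
        warnings.warn(
            "a group has a single library; falling back to Poisson dispersion",
            stacklevel=2,
        )
        alpha = np.zeros(len(counts))
    else:
        # method of moments: var = mean + alpha mean^2, pooled over groups
        with np.errstate(divide="ignore", invalid="ignore"):
            a_a = (var_a - mean_a) / np.square(mean_a)
            a_b = (var_b - mean_b) / np.square(mean_b)
        a_a = np.nan_to_num(a_a, nan=0.0, posinf=0.0, neginf=0.0)
        a_b = np.nan_to_num(a_b, nan=0.0, posinf=0.0, neginf=0.0)
        w_a, w_b = n_a - 1, n_b - 1
        alpha = (w_a * a_a + w_b * a_b) / (w_a + w_b)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    log2fc = np.log2(mean_b + pseudocount) - np.log2(mean_a + pseudocount)
    var_mean_a = (mean_a + alpha * np.square(mean_a)) / n_a
    var_mean_b = (mean_b + alpha * np.square(mean_b)) / n_b
    se = np.sqrt(
        var_mean_a / np.square(mean_a + pseudocount)
        + var_mean_b / np.square(mean_b + pseudocount)
    ) / _LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    p = 2 * stats.norm.sf(np.abs(z))
    q = bh_fdr(p)
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "dispersion": alpha,
            "stat": z,
            "p": p,
            "q": q,
        },
        index=counts.index,
    )


@dataclass
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int
    data: pd.DataFrame

    def __repr__(self) -> str:  # compact report, interpretation left to the user
        return (
            f"CorrelationResult(n={self.n}, r={self.pearson_r:.3f} "
            f"(p={self.pearson_p:.3g}), rho={self.spearman_rho:.3f} "
            f"(p={self.spearman_p:.3g}))"
        )


def signal_correlation(
    x: pd.Series,
    y: pd.Series,
    transform: str = "log2",
    pseudocount: float = 1.0,
) -> CorrelationResult:
    """Pearson and Spearman correlation of paired per-feature signals.

    ``transform="log2"`` applies log2(value + pseudocount) to both inputs
    (for normalized count levels); ``"none"`` uses values as-is (for
    paired log2 fold changes).  Features zero in both inputs are dropped.
    """
    df = pd.DataFrame({"x": x, "y": y}).dropna()
    if transform == "log2":
        df = df[(df["x"] > 0) | (df["y"] > 0)]
        df = np.log2(df + pseudocount)
    elif transform != "none":
        raise ValueError("transform must be 'log2' or 'none'")
    if len(df) < 3:
        raise ValueError("need at least 3 paired features")
    if df["x"].nunique() == 1 or df["y"].nunique() == 1:
        raise ValueError("correlation undefined for a constant vector")
    pr = stats.pearsonr(df["x"], df["y"])
    sr = stats.spearmanr(df["x"], df["y"])
    return CorrelationResult(
        float(pr.statistic), float(pr.pvalue),
        float(sr.statistic), float(sr.pvalue),
        len(df), df,
    )


def feature_counts(
    libraries: dict[str, FragmentSet],
    annotation: GenomeAnnotation,
    feature: str = "promoter",
    promoter_halfwidth: int = 250,
) -> CountTable:
    """Fragment-midpoint counts over promoters (TSS +/- 250 bp) or gene bodies."""
    if feature not in ("promoter", "gene_body"):
        raise ValueError("feature must be 'promoter' or 'gene_body'")
    coords = []
    for g in annotation.genes:
        L = annotation.replicon(g.replicon).length
        if feature == "promoter":
            lo = max(g.tss - promoter_halfwidth, 0)
            hi = min(g.tss + promoter_halfwidth + 1, L)
        else:
            lo, hi = g.start, g.end
        coords.append((g.gene_id, g.replicon, lo, hi))
    coord_df = pd.DataFrame(
        coords, columns=["gene_id", "replicon", "start", "end"]
    ).set_index("gene_id")
    data = {}
    for lib, frags in libraries.items():
        col = np.zeros(len(coord_df), dtype=np.int64)
        for rep, grp_idx in coord_df.groupby("replicon").groups.items():
            starts, ends = frags.on(str(rep))
            mids = np.sort((starts + ends) // 2)
            sub = coord_df.loc[grp_idx]
            lo = np.searchsorted(mids, sub["start"].to_numpy())
            hi = np.searchsorted(mids, sub["end"].to_numpy())
            col[coord_df.index.get_indexer(grp_idx)] = hi - lo
        data[lib] = col
    counts = pd.DataFrame(data, index=coord_df.index)
    return CountTable(counts, coords=coord_df)
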