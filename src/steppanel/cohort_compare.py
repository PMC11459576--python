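"""Group-level expression profiling across histologies.

Operates on the log2-ratio matrix plus the sample sheet: screening for
genes with high mean expression in a group (mean log2 ratio ≥ 1),
per-gene prevalence of high expression, per-gene two-group differential
tests (Mann–Whitney U by default, Welch t optional) with
Benjamini–Hochberg adjustment, and gene–gene correlation within a group
(e.g. the immune-checkpoint panel LAG3 / PDCD1 / CTLA4 / TIGIT).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DegenerateInputError, SchemaError
from .concordance import PairedCorrelation
from .normalization import ExpressionRatios
from .subtyping import DEFAULT_CUTOFF

__all__ = [
    "GroupGeneSummary",
    "high_mean_screen",
    "prevalence_high",
    "differential_by_group",
    "gene_pair_correlation",
]

HIGH_MEAN_THRESHOLD = 1.0


@dataclass(frozen=True)
class GroupGeneSummary:
    gene: str
    group: str
    mean_log2: float
    prevalence_high: float
    n: int


def _group_columns(
    ratios: ExpressionRatios,
    samples: pd.DataFrame,
    group: str,
) -> list[str]:
    """Tumor (non-reference) sample ids of one histology group."""
    meta = samples.loc[[s for s in ratios.ratios.columns if s in samples.index]]
    if group not in set(meta["histology"]):
        raise ValueError(f"unknown group label {group!r}")
    refs = ratios.reference_samples
    cols = [
        s for s in meta.index
        if meta.at[s, "histology"] == group and s not in refs
    ]
    if not cols:
        raise ValueError(f"group {group!r} has no non-reference samples")
    return cols


def high_mean_screen(
    ratios: ExpressionRatios,
    samples: pd.DataFrame,
    group: str,
    threshold: float = HIGH_MEAN_THRESHOLD,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Genes whose mean log2 ratio in the group is ≥ threshold.

    Returns a frame (gene, mean_log2, n) sorted by mean descending, then
    gene name for determinism.
    """
    cols = _group_columns(ratios, samples, group)
    sub = ratios.ratios[cols] if genes is None else ratios.ratios.loc[genes, cols]
    means = sub.mean(axis=1)
    hits = means[means >= threshold]
    out = (
        hits.rename("mean_log2")
        .reset_index()
        .rename(columns={"index": "gene"})
        .sort_values(["mean_log2", "gene"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    out["n"] = len(cols)
    return out


def prevalence_high(
    ratios: ExpressionRatios,
    samples: pd.DataFrame,
    group: str,
    gene: str,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[int, int, float]:
    """(count high, n, fraction) of samples in the group with ratio ≥ cutoff."""
    cols = _group_columns(ratios, samples, group)
    if gene not in ratios.ratios.index:
        raise SchemaError(f"gene {gene!r} not in ratio matrix")
    vals = ratios.ratios.loc[gene, cols].to_numpy(dtype=float)
    count = int((vals >= cutoff).sum())
    n = len(cols)
    return count, n, count / n


def differential_by_group(
    ratios: ExpressionRatios,
    samples: pd.DataFrame,
    group_a: str,
    group_b: str,
    method: str = "mann_whitney",
    adjust: str = "benjamini_hochberg",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene two-sided two-group test on log2 ratios with BH adjustment.

    Returns a frame indexed by gene with columns statistic, p, q,
    direction (``higher_in_a`` / ``higher_in_b`` / ``ns``; significance at
    ``q < alpha``, direction from group medians).
    """
    cols_a = _group_columns(ratios, samples, group_a)
    cols_b = _group_columns(ratios, samples, group_b)
    if len(cols_a) < 3 or len(cols_b) < 3:
        raise ConfigurationError("need ≥3 samples per group for differential testing")
    a = ratios.ratios[cols_a].to_numpy(dtype=float)
    b = ratios.ratios[cols_b].to_numpy(dtype=float)
    if method == "mann_whitney":
        res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided")
        statistic, p = res.statistic, res.pvalue
    elif method == "welch_t":
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        statistic, p = res.statistic, res.pvalue
    else:
        raise ConfigurationError(f"unknown test method {method!r}")
    p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)
    if adjust == "benjamini_hochberg":
        q = multipletests(p, method="fdr_bh")[1]
    elif adjust == "none":
        q = p.copy()
    else:
        raise ConfigurationError(f"unknown adjustment {adjust!r}")
    med_a = np.median(a, axis=1)
    med_b = np.median(b, axis=1)
    direction = np.where(
        q < alpha,
        np.where(med_a > med_b, "higher_in_a", "higher_in_b"),
        "ns",
    )
    # guard: significant but equal medians is still reported as ns
    direction = np.where((q < alpha) & (med_a == med_b), "ns", direction)
    return pd.DataFrame(
        {
            "statistic": statistic,
            "p": p,
            "q": np.maximum(q, p),  # adjusted never below raw
            "direction": direction,
        },
        index=ratios.ratios.index.rename("gene"),
    )


def gene_pair_correlation(
    ratios: ExpressionRatios,
    samples: pd.DataFrame,
    group: str,
    gene_a: str,
    gene_b: str,
    method: str = "spearman",
) -> PairedCorrelation:
    """Correlation between two genes' log2 ratios within one group."""
    cols = _group_columns(ratios, samples, group)
    for g in (gene_a, gene_b):
        if g not in ratios.ratios.index:
            raise SchemaError(f"gene {g!r} not in ratio matrix")
    x = ratios.ratios.loc[gene_a, cols].to_numpy(dtype=float)
    y = ratios.ratios.loc[gene_b, cols].to_numpy(dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise DegenerateInputError("need ≥3 samples with finite ratios")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance in one of the genes")
    if method == "spearman":
        res = stats.spearmanr(x, y)
    elif method == "pearson":
        res = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return PairedCorrelation(
        method=method, scale="log2",
        r=float(res.statistic), p=float(res.pvalue), n=int(x.size),
    )
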