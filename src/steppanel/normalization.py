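"""Control-based normalization and universal-reference log2 ratios.

The normalization chain mirrors conventional processing of a
hybridization-counting panel:

1. **Background floor** — per sample, counts are floored at
   ``b_s = mean + k·SD`` of the negative-control probes (default k = 2).
   Flooring (rather than subtraction) keeps every count positive so log2
   is always defined.
2. **Positive-control scaling** — each sample is scaled by
   ``p_s = gm(all samples' positive geometric means) / gm(sample s)``,
   compensating lane-to-lane hybridization efficiency. The geometric mean
   of the returned factors is 1 by construction.
3. **geNorm housekeeping selection and content scaling** — the most stably
   expressed housekeeping genes are chosen by iterative elimination on the
   stability measure M (mean across partner genes of the SD over samples of
   the pairwise log2 expression ratio), with the pairwise-variation
   stopping rule V(n, n+1) < 0.15; the sample is then scaled by the
   geometric mean of the selected genes.

Finally, expression is summarized as the **normalized log2 ratio**
``R[g, s] = log2(norm[g, s]) − log2(norm[g, ref(batch(s))])`` against the
pooled-tissue universal mRNA reference sample run in the same batch — the
panel's core statistic ("high" expression at R ≥ 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .panel_io import CountMatrix

__all__ = [
    "GeNormResult",
    "NormalizationModel",
    "ExpressionRatios",
    "background_threshold",
    "positive_factors",
    "genorm_m_values",
    "genorm_select",
    "housekeeping_factors",
    "normalize",
    "log2_ratio_vs_reference",
    "normalize_and_ratio",
]

DEFAULT_BACKGROUND_K_SD = 2.0
DEFAULT_V_THRESHOLD = 0.15
DEFAULT_MIN_HOUSEKEEPERS = 3
DEFAULT_PSEUDO_COUNT = 0.5


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeNormResult:
    """Trace of the geNorm reference-gene selection.

    ``m_values`` are stabilities of the full candidate set before any
    elimination; ``elimination_order`` lists removed genes least-stable
    first; ``v_series`` maps (n, n+1) → pairwise variation; ``selected``
    is the chosen housekeeping set. ``converged`` is False when no n met
    the V threshold and all candidates were kept.
    """

    m_values: dict[str, float]
    elimination_order: list[str]
    v_series: dict[tuple[int, int], float]
    selected: frozenset[str]
    converged: bool = True


@dataclass(frozen=True)
class NormalizationModel:
    """Per-sample normalization factors and the geNorm trace.

    The overall per-sample factor is ``NF_s = p_s · h_s``; both factor
    families have geometric mean 1 across the cohort.
    """

    background: pd.Series          # sample → threshold b_s (counts)
    pos_factor: pd.Series          # sample → p_s
    hk_factor: pd.Series           # sample → h_s
    genorm: GeNormResult

    @property
    def total_factor(self) -> pd.Series:
        return self.pos_factor * self.hk_factor


@dataclass(frozen=True)
class ExpressionRatios:
    """Normalized log2 ratios vs. the in-batch universal reference.

    ``ratios`` is genes × samples (log2 units); reference samples are kept
    with all-zero columns but should be excluded from cohort summaries.
    """

    ratios: pd.DataFrame
    reference_map: dict[str, str] = field(default_factory=dict)

    @property
    def reference_samples(self) -> set[str]:
        return set(self.reference_map.values())

    def tumor_samples(self) -> list[str]:
        return [s for s in self.ratios.columns if s not in self.reference_samples]


# ---------------------------------------------------------------------------
# Control-probe factors
# ---------------------------------------------------------------------------

def background_threshold(
    counts_negative: np.ndarray | pd.Series,
    k_sd: float = DEFAULT_BACKGROUND_K_SD,
) -> float:
    """Background threshold b = mean + k·SD of one sample's negative controls.

    Uses the n−1 sample standard deviation. At least two negative probes
    are required.
    """
    x = np.asarray(counts_negative, dtype=float)
    if x.size < 2:
        raise ConfigurationError("need ≥2 negative-control probes for background")
    return float(x.mean() + k_sd * x.std(ddof=1))


def _geometric_mean(values: np.ndarray, axis: int = 0) -> np.ndarray:
    return np.exp(np.mean(np.log(values), axis=axis))


def positive_factors(counts: CountMatrix) -> pd.Series:
    """Positive-control scaling factors p_s, geometric mean 1 across samples."""
    pos_genes = counts.genes_of_class("Positive")
    pos = counts.counts.loc[pos_genes].astype(float)
    zero = pos.columns[(pos <= 0).any(axis=0)]
    if len(zero):
        raise ValueError(f"zero positive-control count in sample(s) {list(zero)}")
    sample_gm = pd.Series(_geometric_mean(pos.to_numpy(), axis=0), index=pos.columns)
    cohort_gm = float(_geometric_mean(sample_gm.to_numpy()))
    return cohort_gm / sample_gm


def housekeeping_factors(
    scaled_counts: pd.DataFrame,
    selected: set[str] | frozenset[str] | list[str],
) -> pd.Series:
    """Content scaling factors h_s from the selected housekeeping genes.

    ``scaled_counts`` are counts after positive-control scaling.
    """
    selected = sorted(selected)
    if not selected:
        raise ConfigurationError("empty housekeeping set")
    hk = scaled_counts.loc[selected].astype(float)
    zero = hk.columns[(hk <= 0).any(axis=0)]
    if len(zero):
        raise ValueError(f"zero housekeeping count in sample(s) {list(zero)}")
    sample_gm = pd.Series(_geometric_mean(hk.to_numpy(), axis=0), index=hk.columns)
    cohort_gm = float(_geometric_mean(sample_gm.to_numpy()))
    return cohort_gm / sample_gm


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------

def genorm_m_values(log_expr: pd.DataFrame) -> pd.Series:
    """geNorm stability M per candidate gene.

    ``M_j = mean over k ≠ j of SD over samples of (log2 a_j − log2 a_k)``,
    with the n−1 SD. Lower M = more stable. Computed from the sample
    covariance matrix: Var(x_j − x_k) = V_jj + V_kk − 2 V_jk.
    """
    if log_expr.shape[0] < 3:
        raise ConfigurationError("geNorm needs ≥3 candidate genes")
    if log_expr.shape[1] < 3:
        raise ConfigurationError("geNorm needs ≥3 samples")
    x = log_expr.to_numpy(dtype=float)
    cov = np.cov(x, ddof=1)
    var_diag = np.diag(cov)
    pair_var = var_diag[:, None] + var_diag[None, :] - 2.0 * cov
    pair_sd = np.sqrt(np.clip(pair_var, 0.0, None))
    n = pair_sd.shape[0]
    m = (pair_sd.sum(axis=1)) / (n - 1)  # diagonal contributes 0
    return pd.Series(m, index=log_expr.index, name="M")


def genorm_select(
    log_expr: pd.DataFrame,
    v_threshold: float = DEFAULT_V_THRESHOLD,
    min_housekeepers: int = DEFAULT_MIN_HOUSEKEEPERS,
) -> GeNormResult:
    """Select stable reference genes by iterative elimination on M.

    The least stable gene (highest M, recomputed each round) is removed
    down to two genes. Stability ranking = final two genes (by last-round
    M, ties alphabetical) followed by the elimination order reversed.
    ``V(n, n+1)`` is the SD over samples of ``log2(NF_n / NF_{n+1})`` where
    ``NF_n`` is the geometric mean of the n most stable genes; the selected
    set is the smallest n ≥ ``min_housekeepers`` with V < ``v_threshold``,
    or every candidate (with a warning) when no n qualifies.
    """
    initial_m = genorm_m_values(log_expr)
    remaining = list(log_expr.index)
    elimination: list[str] = []
    last_round_m = initial_m
    while len(remaining) > 2:
        m = genorm_m_values(log_expr.loc[remaining])
        # deterministic tie handling: among equal-max M drop the
        # lexicographically last gene
        worst_m = m.max()
        worst = sorted(m.index[m == worst_m])[-1]
        elimination.append(worst)
        remaining.remove(worst)
        last_round_m = m
    final_two = sorted(remaining, key=lambda g: (last_round_m.get(g, 0.0), g))
    ranking = final_two + list(reversed(elimination))  # most stable first

    k = len(ranking)
    x = log_expr.loc[ranking].to_numpy(dtype=float)
    v_series: dict[tuple[int, int], float] = {}
    for n in range(2, k):
        lognf_n = x[:n].mean(axis=0)
        lognf_n1 = x[: n + 1].mean(axis=0)
        v_series[(n, n + 1)] = float(np.std(lognf_n - lognf_n1, ddof=1))

    selected: frozenset[str] | None = None
    converged = True
    for n in range(max(2, min_housekeepers), k):
        if v_series[(n, n + 1)] < v_threshold:
            selected = frozenset(ranking[:n])
            break
    if selected is None:
        if k <= min_housekeepers:
            selected = frozenset(ranking)
        else:
            converged = False
            selected = frozenset(ranking)
            warnings.warn(
                "geNorm pairwise variation never fell below "
                f"{v_threshold}; keeping all {k} candidates",
                stacklevel=2,
            )
    return GeNormResult(
        m_values=initial_m.to_dict(),
        elimination_order=elimination,
        v_series=v_series,
        selected=selected,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Full normalization chain
# ---------------------------------------------------------------------------

def normalize(
    counts: CountMatrix,
    *,
    k_sd: float = DEFAULT_BACKGROUND_K_SD,
    v_threshold: float = DEFAULT_V_THRESHOLD,
    min_housekeepers: int = DEFAULT_MIN_HOUSEKEEPERS,
) -> tuple[pd.DataFrame, NormalizationModel]:
    """Run the full chain: background floor → positive scaling → housekeeping.

    Returns the normalized count matrix (floats, genes × samples) and the
    fitted :class:`NormalizationModel`. Cohorts too small for geNorm
    elimination (fewer than 3 housekeeping candidates or 3 samples) fall
    back to using every housekeeping gene, recorded as an empty trace.
    """
    raw = counts.counts.astype(float)
    neg_genes = counts.genes_of_class("Negative")
    background = pd.Series(
        {s: background_threshold(raw.loc[neg_genes, s], k_sd) for s in raw.columns},
        name="background",
    )
    floored = raw.clip(lower=background, axis=1)

    p = positive_factors(counts)
    scaled = floored.mul(p, axis=1)

    hk_genes = counts.genes_of_class("Housekeeping")
    if not hk_genes:
        raise ConfigurationError("panel has no housekeeping genes")
    if len(hk_genes) >= 3 and scaled.shape[1] >= 3:
        log_hk = np.log2(scaled.loc[hk_genes])
        genorm = genorm_select(log_hk, v_threshold, min_housekeepers)
    else:
        genorm = GeNormResult(
            m_values={}, elimination_order=[], v_series={},
            selected=frozenset(hk_genes), converged=True,
        )
    h = housekeeping_factors(scaled, genorm.selected)
    normalized = scaled.mul(h, axis=1)
    model = NormalizationModel(
        background=background, pos_factor=p, hk_factor=h, genorm=genorm
    )
    return normalized, model


def log2_ratio_vs_reference(
    normalized: pd.DataFrame,
    counts: CountMatrix,
    pseudo_count: float = DEFAULT_PSEUDO_COUNT,
) -> ExpressionRatios:
    """Log2 ratio of each sample against its batch's universal reference.

    Ratios are computed for endogenous and housekeeping genes. If any
    retained normalized count is 0 (possible when a sample's background
    threshold is 0), ``pseudo_count`` is added throughout before log2 so
    the ratio is always finite. A reference sample against itself is
    exactly 0 for every gene.
    """
    ref_map = counts.reference_map()
    meta = counts.samples.loc[normalized.columns]
    keep = counts.genes_of_class("Endogenous") + counts.genes_of_class("Housekeeping")
    values = normalized.loc[keep]
    if (values.to_numpy() <= 0).any():
        values = values + pseudo_count
    log2v = np.log2(values)
    ratios = pd.DataFrame(index=values.index, columns=values.columns, dtype=float)
    for s in values.columns:
        batch = str(meta.at[s, "batch_id"])
        if batch not in ref_map:
            raise ValidationError(f"batch {batch!r} has no reference sample")
        ratios[s] = log2v[s] - log2v[ref_map[batch]]
    return ExpressionRatios(ratios=ratios, reference_map=ref_map)


def normalize_and_ratio(
    counts: CountMatrix,
    *,
    k_sd: float = DEFAULT_BACKGROUND_K_SD,
    v_threshold: float = DEFAULT_V_THRESHOLD,
    min_housekeepers: int = DEFAULT_MIN_HOUSEKEEPERS,
    pseudo_count: float = DEFAULT_PSEUDO_COUNT,
) -> tuple[ExpressionRatios, NormalizationModel]:
    """Convenience wrapper: normalization chain followed by log2 ratios."""
    normalized, model = normalize(
        counts, k_sd=k_sd, v_threshold=v_threshold, min_housekeepers=min_housekeepers
    )
    ratios = log2_ratio_vs_reference(normalized, counts, pseudo_count)
    return ratios, model
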