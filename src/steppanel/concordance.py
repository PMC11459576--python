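"""Agreement between panel calls and orthogonal assays (IHC, RNA-Seq).

Binary concordance follows the standard method-comparison framework: the
panel high-call is the *test*, the orthogonal assay the *reference*, and a
2×2 table yields positive/negative percent agreement (PPA/NPA — the
sensitivity/specificity analogues when no gold standard exists), the
predictive agreements (PPV/NPV) and overall percent agreement (OPA), each
with a Wilson 95% confidence interval. A metric whose denominator is
empty is *not assessable* and reported as such, never as 0 or 100.

IHC positivity uses a strict H-score cutoff (> 10); panel positivity uses
the inclusive log2-ratio cutoff (≥ 1) — the two conventions differ on
purpose and are preserved exactly.

Continuous concordance (panel vs. RNA-Seq TPM) is a paired correlation on
either the log2 or the linear scale.

:func:`reconstruct_marker_tables` inverts printed agreement percentages
back to the underlying 2×2 cell counts by exhaustive enumeration — useful
when a report states only the percentages. It raises unless the joint
solution across markers is unique.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import DegenerateInputError

logger = logging.getLogger(__name__)

__all__ = [
    "AgreementTable",
    "AgreementMetrics",
    "PairedCorrelation",
    "binarize_ihc",
    "agreement_table",
    "agreement_metrics",
    "correlate_paired",
    "reconstruct_marker_tables",
    "DEFAULT_H_SCORE_CUTOFF",
]

DEFAULT_H_SCORE_CUTOFF = 10
METRIC_NAMES = ("PPA", "NPA", "PPV", "NPV", "OPA")


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementTable:
    """2×2 cross-tabulation: test (panel) vs. reference (orthogonal assay)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("2×2 cells must be non-negative")
        if self.n < 1:
            raise ValueError("2×2 table must contain at least one sample")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "AgreementTable") -> "AgreementTable":
        return AgreementTable(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


@dataclass(frozen=True)
class AgreementMetrics:
    """Agreement percentages with Wilson 95% CIs.

    Metrics are in percent (0–100); a metric is ``None`` when its
    denominator is empty (not assessable), and then absent from ``ci``.
    """

    ppa: float | None
    npa: float | None
    ppv: float | None
    npv: float | None
    opa: float | None
    ci: dict[str, tuple[float, float]]
    table: AgreementTable

    def as_dict(self) -> dict[str, float | None]:
        return {"PPA": self.ppa, "NPA": self.npa, "PPV": self.ppv,
                "NPV": self.npv, "OPA": self.opa}


@dataclass(frozen=True)
class PairedCorrelation:
    """Correlation between two paired measurement vectors."""

    method: str   # "pearson" | "spearman"
    scale: str    # "log2" | "linear"
    r: float
    p: float
    n: int


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def binarize_ihc(h_score: float, cutoff: float = DEFAULT_H_SCORE_CUTOFF) -> bool:
    """IHC positivity: H-score strictly greater than the cutoff."""
    if not (0 <= h_score <= 300):
        raise ValueError(f"H-score {h_score!r} outside [0, 300]")
    return h_score > cutoff


def agreement_table(
    test_calls: Mapping[str, bool] | pd.Series,
    reference_calls: Mapping[str, bool] | pd.Series,
) -> AgreementTable:
    """Cross-tabulate aligned boolean calls by shared sample id.

    Samples present on only one side are excluded (logged); zero overlap
    is an error.
    """
    test = pd.Series(test_calls).astype(bool)
    ref = pd.Series(reference_calls).astype(bool)
    shared = test.index.intersection(ref.index)
    dropped = (len(test) - len(shared)) + (len(ref) - len(shared))
    if dropped:
        logger.info("agreement_table: excluded %d unmatched samples", dropped)
    if len(shared) == 0:
        raise ValueError("no overlapping samples between test and reference calls")
    t, r = test.loc[shared], ref.loc[shared]
    return AgreementTable(
        tp=int((t & r).sum()),
        fp=int((t & ~r).sum()),
        fn=int((~t & r).sum()),
        tn=int((~t & ~r).sum()),
    )


def _proportion_pct(num: int, den: int) -> float | None:
    if den == 0:
        return None
    return 100.0 * num / den


def agreement_metrics(
    tables: AgreementTable | Iterable[AgreementTable],
) -> AgreementMetrics:
    """PPA/NPA/PPV/NPV/OPA (percent) with Wilson 95% CIs.

    Multiple tables are pooled by summing cells first (micro-average);
    pooled metrics are never averages of per-table percentages.
    """
    if isinstance(tables, AgreementTable):
        pooled = tables
    else:
        tables = list(tables)
        if not tables:
            raise ValueError("no agreement tables given")
        pooled = tables[0]
        for t in tables[1:]:
            pooled = pooled + t

    t = pooled
    parts = {
        "PPA": (t.tp, t.tp + t.fn),
        "NPA": (t.tn, t.tn + t.fp),
        "PPV": (t.tp, t.tp + t.fp),
        "NPV": (t.tn, t.tn + t.fn),
        "OPA": (t.tp + t.tn, t.n),
    }
    values = {k: _proportion_pct(num, den) for k, (num, den) in parts.items()}
    ci = {}
    for k, (num, den) in parts.items():
        if den > 0:
            lo, hi = proportion_confint(num, den, alpha=0.05, method="wilson")
            point = values[k]
            # guard float round-trip: the interval must contain the estimate
            # and stay inside [0, 100]
            lo = min(max(0.0, 100.0 * float(lo)), point)
            hi = max(min(100.0, 100.0 * float(hi)), point)
            ci[k] = (lo, hi)
    return AgreementMetrics(
        ppa=values["PPA"], npa=values["NPA"], ppv=values["PPV"],
        npv=values["NPV"], opa=values["OPA"], ci=ci, table=pooled,
    )


def correlate_paired(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    method: str = "pearson",
    scale: str = "log2",
    pseudo: float = 0.5,
) -> PairedCorrelation:
    """Paired correlation on the log2 (``log2(v + pseudo)``) or linear scale.

    Requires ≥3 finite pairs; zero variance in either vector raises
    :class:`DegenerateInputError` rather than returning NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be aligned")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise DegenerateInputError(f"need ≥3 finite pairs, got {x.size}")
    if scale == "log2":
        if ((x + pseudo) <= 0).any() or ((y + pseudo) <= 0).any():
            raise ValueError("log2 scale requires values > -pseudo")
        x, y = np.log2(x + pseudo), np.log2(y + pseudo)
    elif scale != "linear":
        raise ValueError(f"unknown scale {scale!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance in one of the vectors")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return PairedCorrelation(
        method=method, scale=scale,
        r=float(res.statistic), p=float(res.pvalue), n=int(x.size),
    )


# ---------------------------------------------------------------------------
# Reconstruction of 2×2 tables from printed percentages
# ---------------------------------------------------------------------------

def _matches(value: float | None, printed: float | None, tol: float) -> bool:
    if printed is None:                 # printed "not assessable"
        return value is None
    if value is None:
        return False
    return abs(value - printed) < tol


def reconstruct_marker_tables(
    per_marker: Mapping[str, Mapping[str, float | None]],
    n_per_marker: int,
    pooled: Mapping[str, float] | None = None,
    tol: float = 0.05,
) -> dict[str, AgreementTable]:
    """Invert printed agreement percentages to unique 2×2 cell counts.

    ``per_marker`` maps marker → {metric: printed percent or None for
    "not assessable"} (metrics among PPA/NPA/PPV/NPV/OPA); ``pooled``
    optionally constrains the micro-averaged metrics across markers.
    Every candidate table with ``n_per_marker`` samples is enumerated per
    marker, then the joint combination is filtered by the pooled
    constraints. Raises ``ValueError`` unless exactly one joint solution
    remains. ``tol`` = 0.05 accepts values that round to the printed
    1-decimal percent.
    """
    candidates: dict[str, list[AgreementTable]] = {}
    for marker, constraints in per_marker.items():
        found = []
        for tp, fp, fn in itertools.product(range(n_per_marker + 1), repeat=3):
            tn = n_per_marker - tp - fp - fn
            if tn < 0:
                continue
            table = AgreementTable(tp, fp, fn, tn)
            m = agreement_metrics(table).as_dict()
            if all(_matches(m[k], v, tol) for k, v in constraints.items()):
                found.append(table)
        if not found:
            raise ValueError(f"no 2×2 table matches printed values for {marker!r}")
        candidates[marker] = found

    markers = list(per_marker)
    solutions = []
    for combo in itertools.product(*(candidates[m] for m in markers)):
        if pooled is not None:
            metrics = agreement_metrics(list(combo)).as_dict()
            if not all(_matches(metrics[k], v, tol) for k, v in pooled.items()):
                continue
        solutions.append(dict(zip(markers, combo)))
    if len(solutions) != 1:
        raise ValueError(
            f"expected a unique joint reconstruction, found {len(solutions)}"
        )
    return solutions[0]
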