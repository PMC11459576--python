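"""High-expression calling and transcription-regulator subtyping for SCLC.

A gene is called "high" in a sample when its normalized log2 ratio against
the universal reference is at or above the cutoff (default 1.0; the
assay's original validation used 2.0 — both are exposed). The sample's
subtype label is the *dominant* transcription regulator: among ASCL1,
NEUROD1, POU2F3 and YAP1, the gene with the highest log2 ratio, provided
that maximum reaches the cutoff; otherwise the label is ``NONE``. Exact
ties are reported as ``TIE(...)`` rather than silently broken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import SchemaError
from .normalization import ExpressionRatios

__all__ = [
    "REGULATORS",
    "PROFILES",
    "SubtypeCall",
    "CohortSubtypeSummary",
    "call_high",
    "dominant_regulator",
    "tie_members",
    "profile_label",
    "subtype_sample",
    "subtype_cohort",
    "subtype_cohort_summary",
    "format_percent",
    "calls_frame",
]

#: The SCLC transcription-regulator quartet, in canonical order.
REGULATORS: tuple[str, ...] = ("ASCL1", "NEUROD1", "POU2F3", "YAP1")

PROFILES = ("NONE_HIGH", "SINGLE", "DOUBLE", "TRIPLE", "QUAD")

DEFAULT_CUTOFF = 1.0
LEGACY_CUTOFF = 2.0  # validation-era criterion

NONE_LABEL = "NONE"


def call_high(ratio: float, cutoff: float = DEFAULT_CUTOFF) -> bool:
    """True when the log2 ratio meets the high-expression cutoff (inclusive ≥)."""
    if not math.isfinite(ratio):
        raise ValueError(f"non-finite log2 ratio: {ratio!r}")
    return ratio >= cutoff


def dominant_regulator(
    regulator_ratios: Mapping[str, float],
    cutoff: float = DEFAULT_CUTOFF,
    regulators: Sequence[str] = REGULATORS,
) -> str:
    """Dominant-regulator label: argmax gene, ``NONE``, or ``TIE(a|b)``.

    Returns ``NONE`` when no regulator reaches the cutoff; exact ties among
    the maxima are reported as ``TIE(g1|g2|...)`` with members sorted.
    """
    missing = [g for g in regulators if g not in regulator_ratios]
    if missing:
        raise SchemaError(f"missing regulator ratios: {missing}")
    values = {g: float(regulator_ratios[g]) for g in regulators}
    top = max(values.values())
    if not call_high(top, cutoff):
        return NONE_LABEL
    winners = sorted(g for g, v in values.items() if v == top)
    if len(winners) == 1:
        return winners[0]
    return "TIE(" + "|".join(winners) + ")"


def tie_members(label: str) -> frozenset[str]:
    """Member genes of a ``TIE(...)`` label; empty set for other labels."""
    if label.startswith("TIE(") and label.endswith(")"):
        return frozenset(label[4:-1].split("|"))
    return frozenset()


def profile_label(
    high_regulators: Iterable[str],
    regulators: Sequence[str] = REGULATORS,
) -> str:
    """Multi-marker profile over the regulator quartet."""
    high = set(high_regulators)
    outside = high - set(regulators)
    if outside:
        raise SchemaError(f"genes outside the regulator set: {sorted(outside)}")
    return PROFILES[len(high)]


@dataclass(frozen=True)
class SubtypeCall:
    """Per-sample subtyping result."""

    sample_id: str
    high_genes: frozenset[str]
    dominant: str
    profile: str
    regulator_ratios: dict[str, float]


@dataclass(frozen=True)
class CohortSubtypeSummary:
    """Cohort-level counts and prevalences of the subtyping calls."""

    n: int
    prevalence_high: dict[str, float]
    dominant_counts: dict[str, int]
    profile_counts: dict[str, int]


def subtype_sample(
    sample_id: str,
    ratios: Mapping[str, float] | pd.Series,
    cutoff: float = DEFAULT_CUTOFF,
    regulators: Sequence[str] = REGULATORS,
) -> SubtypeCall:
    """Call one sample: high-gene set, dominant regulator, profile label.

    ``ratios`` maps every assayed gene (at least the regulators) to its
    log2 ratio; the high set spans all provided genes.
    """
    reg_ratios = {g: float(ratios[g]) for g in regulators if g in ratios}
    if len(reg_ratios) < len(regulators):
        missing = [g for g in regulators if g not in reg_ratios]
        raise SchemaError(f"sample {sample_id!r} lacks regulator ratios: {missing}")
    high = frozenset(
        g for g in ratios.keys() if call_high(float(ratios[g]), cutoff)
    )
    dominant = dominant_regulator(reg_ratios, cutoff, regulators)
    profile = profile_label(high & set(regulators), regulators)
    return SubtypeCall(
        sample_id=str(sample_id),
        high_genes=high,
        dominant=dominant,
        profile=profile,
        regulator_ratios=reg_ratios,
    )


def subtype_cohort(
    ratios: ExpressionRatios | pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
    regulators: Sequence[str] = REGULATORS,
    exclude_reference: bool = True,
) -> list[SubtypeCall]:
    """Subtype every (non-reference) sample of a ratio matrix."""
    if isinstance(ratios, ExpressionRatios):
        frame = ratios.ratios
        columns = ratios.tumor_samples() if exclude_reference else list(frame.columns)
    else:
        frame = ratios
        columns = list(frame.columns)
    return [subtype_sample(s, frame[s], cutoff, regulators) for s in columns]


def subtype_cohort_summary(
    calls: Sequence[SubtypeCall],
    regulators: Sequence[str] = REGULATORS,
) -> CohortSubtypeSummary:
    """Exact counting of high-prevalence, dominant labels and profiles."""
    if not calls:
        raise ValueError("empty call list")
    n = len(calls)
    prevalence = {
        g: sum(g in c.high_genes for c in calls) / n for g in regulators
    }
    dominant_counts: dict[str, int] = {}
    for c in calls:
        dominant_counts[c.dominant] = dominant_counts.get(c.dominant, 0) + 1
    profile_counts: dict[str, int] = {}
    for c in calls:
        profile_counts[c.profile] = profile_counts.get(c.profile, 0) + 1
    return CohortSubtypeSummary(
        n=n,
        prevalence_high=prevalence,
        dominant_counts=dominant_counts,
        profile_counts=profile_counts,
    )


def format_percent(
    fraction: float,
    decimals: int = 1,
    mode: str = "half_up",
) -> str:
    """Render a fraction as a percentage string.

    ``half_up`` rounds 26/35 → ``"74.3"``; the ``truncate`` mode drops the
    excess digits instead (→ ``"74.2"``), matching reports that truncate.
    """
    pct = Decimal(fraction * 100.0)
    quantum = Decimal(1).scaleb(-decimals)
    if mode == "half_up":
        return str(pct.quantize(quantum, rounding=ROUND_HALF_UP))
    if mode == "truncate":
        return str(pct.quantize(quantum, rounding="ROUND_DOWN"))
    raise ValueError(f"unknown percent mode {mode!r}")


def calls_frame(
    calls: Sequence[SubtypeCall],
    regulators: Sequence[str] = REGULATORS,
) -> pd.DataFrame:
    """Tabulate calls for reporting: one row per sample."""
    rows = []
    for c in calls:
        row: dict[str, object] = {"sample_id": c.sample_id}
        for g in regulators:
            row[g] = c.regulator_ratios.get(g, math.nan)
        row["high_genes"] = "|".join(sorted(c.high_genes))
        row["dominant"] = c.dominant
        row["profile"] = c.profile
        rows.append(row)
    return pd.DataFrame(rows)
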