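"""Intra-patient, multi-site heterogeneity of regulator expression.

A patient with samples from several tumor sites (e.g. a rapid-autopsy
donor with primary and metastatic tissues) is summarized as a site ×
regulator matrix of high-calls. Heterogeneity is operationalized as the
set of discordant genes (called high at some sites and not others), a
dominant-subtype *switch* flag (the dominant-regulator label differs
between sites, with NONE and TIE treated as labels in their own right),
and pairwise Hamming distances between the sites' call vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import InsufficientDataError
from .subtyping import REGULATORS, SubtypeCall

__all__ = ["SiteCallMatrix", "HeterogeneityReport", "site_call_matrix", "discordance"]


@dataclass(frozen=True)
class SiteCallMatrix:
    """Per-site calls for one patient: sites × genes."""

    patient_id: str
    high: pd.DataFrame      # bool, index = site labels
    ratios: pd.DataFrame    # log2 ratios, same shape
    dominant: pd.Series     # site → dominant label (incl. NONE / TIE(...))

    @property
    def sites(self) -> list[str]:
        return self.high.index.tolist()


@dataclass(frozen=True)
class HeterogeneityReport:
    """Discordance summary for one patient across tumor sites."""

    patient_id: str
    discordant_genes: frozenset[str]
    switch: bool
    pairwise: dict[tuple[str, str], int]   # (site_i, site_j) → Hamming distance


def site_call_matrix(
    calls: Sequence[SubtypeCall],
    samples: pd.DataFrame,
    patient_id: str,
    genes: Sequence[str] = REGULATORS,
) -> SiteCallMatrix:
    """Assemble the site × gene call matrix for one patient.

    ``samples`` is the sample sheet (indexed by sample_id, with
    ``patient_id`` and ``tissue_site`` columns). Duplicate site labels get
    a numeric suffix. At least two sites are required.
    """
    by_id = {c.sample_id: c for c in calls}
    sel = samples[(samples["patient_id"].astype(str) == str(patient_id))]
    sel = sel.loc[[s for s in sel.index if s in by_id]]
    if len(sel) < 2:
        raise InsufficientDataError(
            f"patient {patient_id!r} has {len(sel)} called samples; need ≥2 sites"
        )
    labels: list[str] = []
    seen: dict[str, int] = {}
    for sid in sel.index:
        site = str(sel.at[sid, "tissue_site"]) or str(sid)
        seen[site] = seen.get(site, 0) + 1
        labels.append(site if seen[site] == 1 else f"{site}_{seen[site]}")

    high_rows, ratio_rows, dominants = [], [], []
    for sid in sel.index:
        c = by_id[sid]
        high_rows.append([g in c.high_genes for g in genes])
        ratio_rows.append([c.regulator_ratios.get(g, float("nan")) for g in genes])
        dominants.append(c.dominant)
    idx = pd.Index(labels, name="site")
    return SiteCallMatrix(
        patient_id=str(patient_id),
        high=pd.DataFrame(high_rows, index=idx, columns=list(genes)),
        ratios=pd.DataFrame(ratio_rows, index=idx, columns=list(genes)),
        dominant=pd.Series(dominants, index=idx, name="dominant"),
    )


def discordance(matrix: SiteCallMatrix) -> HeterogeneityReport:
    """Discordant genes, dominant-switch flag and pairwise Hamming distances."""
    high = matrix.high
    discordant = frozenset(
        g for g in high.columns if high[g].any() and not high[g].all()
    )
    switch = matrix.dominant.nunique() > 1
    pairwise: dict[tuple[str, str], int] = {}
    sites = matrix.sites
    for i, si in enumerate(sites):
        for sj in sites[i + 1:]:
            dist = int((high.loc[si] != high.loc[sj]).sum())
            pairwise[(si, sj)] = dist
    return HeterogeneityReport(
        patient_id=matrix.patient_id,
        discordant_genes=discordant,
        switch=switch,
        pairwise=pairwise,
    )
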