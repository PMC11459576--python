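"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a hybridization-counting run of a targeted
expression panel: per batch one pooled-tissue universal reference lane
whose endogenous means define the baseline; tumor lanes whose endogenous
counts are negative-binomial around ``baseline · 2^(true log2 ratio) ·
lane factor``; low-variance housekeeping probes (log-normal around their
baseline, no subtype effect); a noiseless positive-control concentration
ladder scaled by the lane factor; and Poisson negative-control background.
Subtype structure enters through the regulator quartet: each simulated
tumor carries one dominant regulator (or none) whose true log2 ratio is
drawn around the high mean, the remaining regulators around the low mean,
with optional co-expressed genes coupled to a regulator (DLL3 follows
ASCL1 by default).

Paired orthogonal measurements are generated with noisy monotone links:
IHC H-scores increase with the true linear fold-change, RNA-Seq log2 TPM
is linear in the true log2 ratio.

Reproducibility: every sample owns an RNG stream keyed by
``(seed, sample index)``, so enlarging a cohort never perturbs existing
samples; cohort-level draws (gene baselines) and the IHC/TPM links use
dedicated streams.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError
from .panel_io import (
    CountMatrix,
    PanelDefinition,
    write_count_table,
    write_panel,
    write_rcc,
    write_sample_sheet,
)
from .subtyping import REGULATORS, dominant_regulator

__all__ = [
    "SimConfig",
    "SimTruth",
    "default_panel",
    "simulate_cohort",
    "simulate_ihc",
    "simulate_rnaseq",
    "write_cohort",
]

# RNG stream keys (second word of the seed sequence); tumor samples use
# their 0-based index, so these offsets must stay clear of any cohort size.
_STREAM_GENES = 2**20
_STREAM_REFERENCE = 2**20 + 1  # + batch index
_STREAM_IHC = 2**21
_STREAM_RNASEQ = 2**22

#: Genes of clinical interest placed on the default panel by name.
_NAMED_ENDOGENOUS = (
    "ASCL1", "NEUROD1", "POU2F3", "YAP1",
    "DLL3", "EZH2", "TERT", "RET",
    "LAG3", "PDCD1", "CTLA4", "TIGIT", "CD274",
    "MYC", "CDKN2A", "NCAM1", "EGFR", "ERBB2", "MET", "ROS1",
    "MAGEA1", "MAGEA3", "CDK4", "MKI67",
)
_HOUSEKEEPERS = ("ACTB", "GAPDH", "TUBB", "POLR2A", "TBP", "GUSB")
DEFAULT_POS_LADDER = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)


def default_panel(n_endogenous: int = 204) -> PanelDefinition:
    """A 204-target panel with 6 housekeeping, 6 positive and 8 negative probes."""
    if n_endogenous < len(REGULATORS):
        raise ConfigurationError("panel must include the regulator quartet")
    endo = list(_NAMED_ENDOGENOUS[:n_endogenous])
    endo += [f"PNL{i:03d}" for i in range(len(endo) + 1, n_endogenous + 1)]
    records: list[tuple] = [(g, "Endogenous") for g in endo]
    records += [(g, "Housekeeping") for g in _HOUSEKEEPERS]
    records += [
        (f"POS_{chr(ord('A') + i)}", "Positive", conc)
        for i, conc in enumerate(DEFAULT_POS_LADDER)
    ]
    records += [(f"NEG_{chr(ord('A') + i)}", "Negative") for i in range(8)]
    return PanelDefinition.from_records(records)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a simulated cohort.

    Defaults mirror a 35-sample SCLC panel run: mostly ASCL1-dominant
    tumors, a 3-log2-unit separation between high and low regulator
    means, moderate count overdispersion and ±20% lane-to-lane size
    variation. ``nb_dispersion`` is the quadratic overdispersion α in
    ``Var = μ + α·μ²`` (α = 0 gives deterministic counts at the mean,
    the noiseless limit used to validate the pipeline algebra).
    """

    n_samples: int = 35
    n_batches: int = 4
    panel: PanelDefinition = field(default_factory=default_panel)
    subtype_props: dict[str, float] = field(
        default_factory=lambda: {
            "ASCL1": 0.74, "NEUROD1": 0.20, "POU2F3": 0.03, "NONE": 0.03,
        }
    )
    regulator_high_mean: float = 2.0     # log2 units
    regulator_low_mean: float = -1.0     # log2 units
    regulator_sd: float = 0.5            # log2 units
    gene_noise_sd: float = 0.3           # log2 biological noise, other endogenous
    nb_dispersion: float = 0.1           # Var = μ + α μ²
    lane_size_sd: float = 0.2            # SD of ln(lane factor)
    hk_sd: float = 0.1                   # log2 units
    neg_mean: float = 5.0                # Poisson mean, counts
    pos_ladder: tuple[float, ...] = DEFAULT_POS_LADDER   # fM
    pos_counts_per_fm: float = 30.0
    baseline_count: float = 512.0
    baseline_log2_sd: float = 1.0        # per-gene baseline spread
    coupled_genes: dict[str, str] = field(default_factory=lambda: {"DLL3": "ASCL1"})
    gene_effects: dict[str, float] = field(default_factory=dict)
    histology: str = "SCLC"
    ihc_slope: float = 50.0              # H-score units per linear fold above 1
    ihc_noise_sd: float = 15.0           # H-score units
    tpm_intercept: float = 3.0           # log2 TPM at ratio 0
    tpm_noise_sd: float = 0.3            # log2 units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_batches < 1:
            raise ConfigurationError("need ≥1 sample and ≥1 batch")
        total = sum(self.subtype_props.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigurationError(f"subtype_props sum to {total}, expected 1")
        unknown = set(self.subtype_props) - set(REGULATORS) - {"NONE"}
        if unknown:
            raise ConfigurationError(f"unknown subtype labels: {sorted(unknown)}")
        for name in ("regulator_sd", "gene_noise_sd", "nb_dispersion",
                     "lane_size_sd", "hk_sd", "neg_mean", "baseline_log2_sd",
                     "ihc_noise_sd", "tpm_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be ≥ 0")

    def noiseless(self, **overrides) -> "SimConfig":
        """Copy with every noise source off (the exact-recovery limit)."""
        params = dict(
            regulator_sd=0.0, gene_noise_sd=0.0, nb_dispersion=0.0,
            lane_size_sd=0.0, hk_sd=0.0, baseline_log2_sd=0.0,
            ihc_noise_sd=0.0, tpm_noise_sd=0.0,
        )
        params.update(overrides)
        return dataclasses.replace(self, **params)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated cohort, for recovery testing."""

    subtype: pd.Series          # tumor sample → latent subtype label
    true_log2: pd.DataFrame     # endogenous genes × samples (references: 0)
    lane_factor: pd.Series      # sample → multiplicative lane size factor
    config: SimConfig

    def tumor_samples(self) -> list[str]:
        return self.subtype.index.tolist()

    def true_dominant(self, cutoff: float = 1.0) -> pd.Series:
        """Dominant-regulator label implied by the *true* log2 ratios."""
        labels = {
            s: dominant_regulator(
                {g: float(self.true_log2.at[g, s]) for g in REGULATORS}, cutoff
            )
            for s in self.tumor_samples()
        }
        return pd.Series(labels, name="true_dominant")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative-binomial counts with Var = μ + α μ²; deterministic at α = 0."""
    mean = np.asarray(mean, dtype=float)
    if alpha == 0.0:
        return np.round(mean).astype(np.int64)
    lam = rng.gamma(shape=1.0 / alpha, scale=mean * alpha)
    return rng.poisson(lam).astype(np.int64)


def _sample_true_ratios(
    rng: np.random.Generator,
    cfg: SimConfig,
    subtype: str,
    endo_genes: list[str],
) -> pd.Series:
    true = pd.Series(0.0, index=endo_genes)
    high_set = {subtype} if subtype != "NONE" else set()
    for gene, source in cfg.coupled_genes.items():
        if gene in true.index and source in high_set:
            high_set.add(gene)
    for g in REGULATORS:
        mu = cfg.regulator_high_mean if g in high_set else cfg.regulator_low_mean
        true[g] = mu + rng.normal(0.0, cfg.regulator_sd) if cfg.regulator_sd else mu
    for g in endo_genes:
        if g in REGULATORS:
            continue
        if g in high_set:
            mu = cfg.regulator_high_mean
        else:
            mu = cfg.gene_effects.get(g, 0.0)
        true[g] = mu + (rng.normal(0.0, cfg.gene_noise_sd) if cfg.gene_noise_sd else 0.0)
    return true


def simulate_cohort(config: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Simulate one cohort; fully reproducible for a fixed config and seed.

    Returns the raw :class:`CountMatrix` (reference lanes included, one
    per batch) and the :class:`SimTruth` needed for recovery tests.
    """
    cfg = config
    panel = cfg.panel
    endo = panel.genes_of_class("Endogenous")
    hk = panel.genes_of_class("Housekeeping")
    pos = panel.positive_ladder  # gene → fM, descending
    neg = panel.genes_of_class("Negative")
    missing = [g for g in REGULATORS if g not in endo]
    if missing:
        raise ConfigurationError(f"panel lacks regulator genes: {missing}")

    gene_rng = np.random.default_rng([cfg.seed, _STREAM_GENES])
    n_base = len(endo) + len(hk)
    spread = (
        np.exp2(gene_rng.normal(0.0, cfg.baseline_log2_sd, size=n_base))
        if cfg.baseline_log2_sd
        else np.ones(n_base)
    )
    baseline = pd.Series(cfg.baseline_count * spread, index=endo + hk)

    subtype_labels = sorted(cfg.subtype_props)
    subtype_p = np.array([cfg.subtype_props[k] for k in subtype_labels])

    columns: dict[str, pd.Series] = {}
    meta_rows: list[dict] = []
    lane_factors: dict[str, float] = {}
    truth_cols: dict[str, pd.Series] = {}
    subtypes: dict[str, str] = {}

    def lane_counts(
        rng: np.random.Generator,
        true_ratio: pd.Series,
        lane: float,
        is_reference: bool = False,
    ) -> pd.Series:
        endo_mean = baseline[endo].to_numpy() * np.exp2(true_ratio[endo].to_numpy()) * lane
        if is_reference and cfg.nb_dispersion > 0:
            # the universal reference is the same pooled RNA in every run:
            # only counting (Poisson) noise applies, not tumor overdispersion
            endo_counts = rng.poisson(endo_mean).astype(np.int64)
        else:
            endo_counts = _nb_draw(rng, endo_mean, cfg.nb_dispersion)
        hk_noise = (
            np.exp2(rng.normal(0.0, cfg.hk_sd, size=len(hk))) if cfg.hk_sd else 1.0
        )
        hk_counts = np.round(baseline[hk].to_numpy() * hk_noise * lane).astype(np.int64)
        pos_counts = np.round(
            cfg.pos_counts_per_fm * pos.to_numpy() * lane
        ).astype(np.int64)
        neg_counts = rng.poisson(cfg.neg_mean, size=len(neg))
        return pd.Series(
            np.concatenate([endo_counts, hk_counts, pos_counts, neg_counts]),
            index=endo + hk + list(pos.index) + neg,
        )

    # reference lane per batch: endogenous means are the baseline itself
    for b in range(cfg.n_batches):
        rng = np.random.default_rng([cfg.seed, _STREAM_REFERENCE + b])
        lane = float(np.exp(rng.normal(0.0, cfg.lane_size_sd))) if cfg.lane_size_sd else 1.0
        sid = f"REF_B{b + 1}"
        zero = pd.Series(0.0, index=endo)
        columns[sid] = lane_counts(rng, zero, lane, is_reference=True)
        truth_cols[sid] = zero
        lane_factors[sid] = lane
        meta_rows.append(
            dict(sample_id=sid, batch_id=f"B{b + 1}", patient_id="", tissue_site="",
                 histology="Other", is_reference=True, tumor_pct=np.nan)
        )

    for i in range(cfg.n_samples):
        rng = np.random.default_rng([cfg.seed, i])
        sid = f"S{i + 1:03d}"
        batch = f"B{(i % cfg.n_batches) + 1}"
        subtype = subtype_labels[rng.choice(len(subtype_labels), p=subtype_p)]
        lane = float(np.exp(rng.normal(0.0, cfg.lane_size_sd))) if cfg.lane_size_sd else 1.0
        true = _sample_true_ratios(rng, cfg, subtype, endo)
        columns[sid] = lane_counts(rng, true, lane)
        truth_cols[sid] = true
        lane_factors[sid] = lane
        subtypes[sid] = subtype
        meta_rows.append(
            dict(sample_id=sid, batch_id=batch, patient_id=f"P{i + 1:03d}",
                 tissue_site="", histology=cfg.histology,
                 is_reference=False, tumor_pct=np.nan)
        )

    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    counts = pd.DataFrame(columns).astype(int)
    cm = CountMatrix(counts=counts, panel=panel, samples=samples)
    truth = SimTruth(
        subtype=pd.Series(subtypes, name="subtype"),
        true_log2=pd.DataFrame(truth_cols).loc[endo],
        lane_factor=pd.Series(lane_factors, name="lane_factor"),
        config=cfg,
    )
    return cm, truth


def simulate_ihc(truth: SimTruth, markers: list[str]) -> pd.DataFrame:
    """Paired IHC H-scores with a noisy monotone link to true expression.

    ``H = clamp(0, 300, round(slope · max(0, fold − 1) + noise))`` with
    ``fold = 2^(true log2 ratio)``: expression at or below the reference
    level maps to 0 in expectation.
    """
    cfg = truth.config
    unknown = [m for m in markers if m not in truth.true_log2.index]
    if unknown:
        raise SchemaError(f"markers not simulated: {unknown}")
    rng = np.random.default_rng([cfg.seed, _STREAM_IHC])
    rows = []
    for sid in truth.tumor_samples():
        for marker in markers:
            fold = float(np.exp2(truth.true_log2.at[marker, sid]))
            noise = rng.normal(0.0, cfg.ihc_noise_sd) if cfg.ihc_noise_sd else 0.0
            h = int(np.clip(round(cfg.ihc_slope * max(0.0, fold - 1.0) + noise), 0, 300))
            rows.append(dict(sample_id=sid, marker=marker, h_score=h))
    return pd.DataFrame(rows)


def simulate_rnaseq(truth: SimTruth) -> pd.DataFrame:
    """Paired RNA-Seq TPM: log2 TPM = intercept + true log2 ratio + noise."""
    cfg = truth.config
    rng = np.random.default_rng([cfg.seed, _STREAM_RNASEQ])
    cols = truth.tumor_samples()
    base = truth.true_log2[cols].to_numpy(dtype=float)
    noise = (
        rng.normal(0.0, cfg.tpm_noise_sd, size=base.shape)
        if cfg.tpm_noise_sd else 0.0
    )
    tpm = np.exp2(cfg.tpm_intercept + base + noise)
    return pd.DataFrame(np.maximum(tpm, 0.0), index=truth.true_log2.index, columns=cols)


def write_cohort(
    cm: CountMatrix,
    truth: SimTruth,
    out_dir: str | Path,
    *,
    file_format: str = "rcc",
    ihc: pd.DataFrame | None = None,
    tpm: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write a simulated cohort to disk (RCC files or one count table).

    Always writes the panel definition, sample sheet and truth table;
    returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    code_classes = cm.panel.table["code_class"]
    if file_format == "rcc":
        for sid in cm.sample_ids:
            p = out / f"{sid}.RCC"
            write_rcc(p, sid, cm.counts[sid], code_classes)
        paths["rcc_dir"] = out
    elif file_format == "table":
        paths["counts"] = out / "counts.tsv"
        write_count_table(cm, paths["counts"])
    else:
        raise ConfigurationError(f"unknown file format {file_format!r}")
    paths["panel"] = out / "panel.tsv"
    write_panel(cm.panel, paths["panel"])
    paths["sheet"] = out / "samples.tsv"
    write_sample_sheet(cm.samples, paths["sheet"])
    paths["truth"] = out / "truth.tsv"
    truth_table = truth.true_log2.T
    truth_table.insert(0, "subtype", truth.subtype.reindex(truth_table.index).fillna(""))
    truth_table.insert(1, "lane_factor", truth.lane_factor)
    truth_table.rename_axis("sample_id").to_csv(paths["truth"], sep="\t")
    if ihc is not None:
        paths["ihc"] = out / "ihc.tsv"
        ihc.to_csv(paths["ihc"], sep="\t", index=False)
    if tpm is not None:
        paths["tpm"] = out / "tpm.tsv"
        tpm.rename_axis("gene").to_csv(paths["tpm"], sep="\t")
    return paths
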