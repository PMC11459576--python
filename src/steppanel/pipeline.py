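"""End-to-end orchestration: counts → normalization → ratios → calls → reports.

The pipeline is a thin, deterministic composition of the library modules:
running it equals calling the module operations individually with the same
parameters. The whole configuration is validated before stage 1 (fail
fast — a clinical-style pipeline must not leave partial silent output);
on any stage error the outputs written so far are removed. A manifest
records the package version, a hash of the configuration and per-stage
row counts, so identical inputs give identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, DegenerateInputError
from .concordance import (
    agreement_metrics,
    agreement_table,
    binarize_ihc,
    correlate_paired,
)
from .cohort_compare import differential_by_group, high_mean_screen
from .heterogeneity import discordance, site_call_matrix
from .normalization import (
    DEFAULT_BACKGROUND_K_SD,
    DEFAULT_MIN_HOUSEKEEPERS,
    DEFAULT_PSEUDO_COUNT,
    DEFAULT_V_THRESHOLD,
    normalize_and_ratio,
)
from .panel_io import (
    read_count_table,
    read_ihc,
    read_panel,
    read_rcc_dir,
    read_sample_sheet,
    read_tpm,
    write_report,
)
from .subtyping import (
    DEFAULT_CUTOFF,
    REGULATORS,
    calls_frame,
    format_percent,
    subtype_cohort,
    subtype_cohort_summary,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; serializable to/from YAML."""

    panel: str
    sheet: str
    out_dir: str
    counts: str | None = None          # gene × sample count table
    rcc_dir: str | None = None         # or a directory of RCC lane files
    cutoff: float = DEFAULT_CUTOFF
    regulators: tuple[str, ...] = REGULATORS
    background_k_sd: float = DEFAULT_BACKGROUND_K_SD
    genorm_v_threshold: float = DEFAULT_V_THRESHOLD
    genorm_min_housekeepers: int = DEFAULT_MIN_HOUSEKEEPERS
    ratio_pseudo_count: float = DEFAULT_PSEUDO_COUNT
    percent_mode: str = "half_up"
    concordance: bool = False
    ihc: str | None = None
    ihc_cutoff: float = 10.0
    tpm: str | None = None
    compare_groups: tuple[str, str] | None = None
    compare_method: str = "mann_whitney"
    heterogeneity_patients: tuple[str, ...] = ()
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("regulators", "heterogeneity_patients", "compare_groups"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_canonical_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_canonical_json().encode()).hexdigest()

    def validate(self) -> None:
        """Fail-fast validation of the entire configuration."""
        if (self.counts is None) == (self.rcc_dir is None):
            raise ConfigurationError("exactly one of counts / rcc_dir must be set")
        for name in ("panel", "sheet", "counts", "rcc_dir", "ihc", "tpm"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise ConfigurationError(f"{name} path does not exist: {value}")
        if self.concordance and self.ihc is None and self.tpm is None:
            raise ConfigurationError("concordance enabled but no IHC/TPM table given")
        if not (0 <= self.ihc_cutoff <= 300):
            raise ConfigurationError("ihc_cutoff must lie in [0, 300]")
        if self.background_k_sd < 0 or self.genorm_v_threshold <= 0:
            raise ConfigurationError("background/geNorm parameters out of range")
        if self.genorm_min_housekeepers < 2:
            raise ConfigurationError("genorm_min_housekeepers must be ≥ 2")
        if self.ratio_pseudo_count <= 0:
            raise ConfigurationError("ratio_pseudo_count must be > 0")
        if self.percent_mode not in ("half_up", "truncate"):
            raise ConfigurationError(f"unknown percent_mode {self.percent_mode!r}")
        if self.compare_method not in ("mann_whitney", "welch_t"):
            raise ConfigurationError(f"unknown compare_method {self.compare_method!r}")


def _concordance_frame(calls, ihc_df, config) -> pd.DataFrame:
    """Per-marker 2×2 tables and metrics vs. IHC, plus a pooled row."""
    panel_high = {
        c.sample_id: {g: g in c.high_genes for g in config.regulators} for c in calls
    }
    rows = []
    tables = []
    for marker in config.regulators:
        sub = ihc_df[ihc_df["marker"] == marker]
        ref = {
            str(r["sample_id"]): binarize_ihc(float(r["h_score"]), config.ihc_cutoff)
            for _, r in sub.iterrows()
        }
        test = {
            s: flags[marker] for s, flags in panel_high.items() if s in ref
        }
        if not test:
            continue
        table = agreement_table(test, ref)
        tables.append(table)
        rows.append((marker, table))
    if not rows:
        raise ConfigurationError("no IHC markers overlap the regulator set")
    out = []
    for marker, table in rows + [("POOLED", None)]:
        metrics = agreement_metrics(tables if table is None else table)
        t = metrics.table
        rec: dict[str, object] = dict(marker=marker, tp=t.tp, fp=t.fp, fn=t.fn, tn=t.tn)
        for name, value in metrics.as_dict().items():
            rec[name] = float("nan") if value is None else value
            lo, hi = metrics.ci.get(name, (float("nan"), float("nan")))
            rec[f"{name}_lo"], rec[f"{name}_hi"] = lo, hi
        out.append(rec)
    return pd.DataFrame(out)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns the run manifest."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {
        "package": "steppanel",
        "version": __version__,
        "config_hash": config.config_hash(),
        "stages": {},
        "outputs": [],
    }

    def emit(name: str, frame: pd.DataFrame, stage: str) -> None:
        path = out_dir / name
        write_report(frame, path)
        written.append(path)
        manifest["outputs"].append(name)
        manifest["stages"][stage] = manifest["stages"].get(stage, 0) + len(frame)

    try:
        logger.info("stage=load")
        if config.counts is not None:
            cm = read_count_table(config.counts, config.panel, config.sheet)
        else:
            panel = read_panel(config.panel)
            sheet = read_sample_sheet(config.sheet)
            cm = read_rcc_dir(config.rcc_dir, panel, sheet)
        manifest["stages"]["load"] = int(cm.counts.size)

        logger.info("stage=normalize")
        ratios, model = normalize_and_ratio(
            cm,
            k_sd=config.background_k_sd,
            v_threshold=config.genorm_v_threshold,
            min_housekeepers=config.genorm_min_housekeepers,
            pseudo_count=config.ratio_pseudo_count,
        )
        ratio_frame = ratios.ratios.round(4).rename_axis("gene").reset_index()
        emit("ratios.tsv", ratio_frame, "normalize")
        factors = pd.DataFrame(
            {
                "sample_id": model.pos_factor.index,
                "background": model.background.values,
                "pos_factor": model.pos_factor.values,
                "hk_factor": model.hk_factor.values,
            }
        )
        emit("normalization_factors.tsv", factors, "normalize")

        logger.info("stage=subtype")
        calls = subtype_cohort(ratios, config.cutoff, config.regulators)
        emit("calls.tsv", calls_frame(calls, config.regulators), "subtype")
        summary = subtype_cohort_summary(calls, config.regulators)
        srows = [
            {
                "metric": f"prevalence_high_{g}",
                "count": int(round(summary.prevalence_high[g] * summary.n)),
                "n": summary.n,
                "value_pct": float(
                    format_percent(summary.prevalence_high[g], mode=config.percent_mode)
                ),
            }
            for g in config.regulators
        ]
        for label, count in sorted(summary.dominant_counts.items()):
            srows.append(
                {
                    "metric": f"dominant_{label}",
                    "count": count,
                    "n": summary.n,
                    "value_pct": float(
                        format_percent(count / summary.n, mode=config.percent_mode)
                    ),
                }
            )
        for label, count in sorted(summary.profile_counts.items()):
            srows.append(
                {
                    "metric": f"profile_{label}",
                    "count": count,
                    "n": summary.n,
                    "value_pct": float(
                        format_percent(count / summary.n, mode=config.percent_mode)
                    ),
                }
            )
        emit("summary.tsv", pd.DataFrame(srows), "subtype")

        if config.concordance and config.ihc is not None:
            logger.info("stage=concordance_ihc")
            ihc_df = read_ihc(config.ihc)
            emit("concordance_ihc.tsv", _concordance_frame(calls, ihc_df, config),
                 "concordance_ihc")
        if config.concordance and config.tpm is not None:
            logger.info("stage=concordance_rnaseq")
            tpm = read_tpm(config.tpm)
            shared = [c.sample_id for c in calls if c.sample_id in tpm.columns]
            rows = []
            for g in config.regulators:
                if g not in tpm.index:
                    continue
                panel_log2 = [
                    c.regulator_ratios[g] for c in calls if c.sample_id in shared
                ]
                seq = tpm.loc[g, shared].to_numpy(dtype=float)
                try:
                    corr = correlate_paired(
                        2.0 ** pd.Series(panel_log2), seq, method="pearson", scale="log2"
                    )
                except DegenerateInputError as exc:
                    logger.warning("skipping %s in RNA-Seq concordance: %s", g, exc)
                    continue
                rows.append(dict(gene=g, method=corr.method, scale=corr.scale,
                                 r=corr.r, p=corr.p, n=corr.n))
            emit("concordance_rnaseq.tsv", pd.DataFrame(rows), "concordance_rnaseq")

        if config.compare_groups is not None:
            logger.info("stage=compare")
            group_a, group_b = config.compare_groups
            sheet = cm.samples
            diff = differential_by_group(
                ratios, sheet, group_a, group_b, method=config.compare_method
            )
            emit("differential.tsv", diff.reset_index(), "compare")
            screen = high_mean_screen(ratios, sheet, group_a)
            emit("high_mean_screen.tsv", screen, "compare")

        for patient in config.heterogeneity_patients:
            logger.info("stage=heterogeneity patient=%s", patient)
            matrix = site_call_matrix(calls, cm.samples, patient, config.regulators)
            report = discordance(matrix)
            rows = []
            for site in matrix.sites:
                for g in matrix.high.columns:
                    rows.append(
                        dict(patient_id=patient, site=site, gene=g,
                             ratio=float(matrix.ratios.at[site, g]),
                             high=bool(matrix.high.at[site, g]),
                             dominant=matrix.dominant[site])
                    )
            rows.append(
                dict(patient_id=patient, site="SUMMARY",
                     gene="|".join(sorted(report.discordant_genes)),
                     ratio=float("nan"), high=report.switch, dominant="")
            )
            emit(f"heterogeneity_{patient}.tsv", pd.DataFrame(rows), "heterogeneity")

        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written.append(manifest_path)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return manifest
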