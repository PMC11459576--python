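"""Reading and writing on-disk artifacts of a targeted expression panel.

Handles NanoString-style RCC lane files, plain gene × sample count tables,
panel definitions (gene → code class), sample sheets, paired IHC H-score
tables and RNA-Seq TPM tables, plus deterministic TSV result reports.

The in-memory entry point of the pipeline is :class:`CountMatrix`: raw
integer probe counts together with the panel definition and per-sample
metadata. All invariants (unique identifiers, one universal-reference
sample per batch, non-negative integer counts) are enforced at
construction time so downstream modules can assume a valid cohort.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

CODE_CLASSES = ("Endogenous", "Housekeeping", "Positive", "Negative")
HISTOLOGIES = ("SCLC", "LUAD", "SqCC", "Other")

#: Fixed float formatting used by :func:`write_report`.
RATIO_DECIMALS = 4
PERCENT_DECIMALS = 1


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelDefinition:
    """Probe annotation: gene → code class, plus positive-control ladder.

    Parameters
    ----------
    table
        DataFrame indexed by gene with columns ``code_class`` and
        ``nominal_conc`` (fM; NaN except for Positive probes).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if not t.index.is_unique:
            dupes = t.index[t.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene identifiers in panel: {dupes}")
        bad = set(t["code_class"]) - set(CODE_CLASSES)
        if bad:
            raise ValidationError(f"unknown code classes: {sorted(bad)}")
        for cls in ("Housekeeping", "Positive", "Negative"):
            if not (t["code_class"] == cls).any():
                raise ValidationError(f"panel has no {cls} probes")
        pos = t.loc[t["code_class"] == "Positive", "nominal_conc"]
        if pos.isna().any() or (pos <= 0).any():
            raise ValidationError("Positive probes need strictly positive nominal_conc")
        if pos.duplicated().any():
            raise ValidationError("Positive nominal_conc values must be distinct")

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str] | tuple[str, str, float]],
    ) -> "PanelDefinition":
        """Build from ``(gene, code_class[, nominal_conc])`` tuples."""
        rows = []
        for rec in records:
            gene, code_class = rec[0], rec[1]
            conc = float(rec[2]) if len(rec) > 2 and rec[2] is not None else math.nan
            rows.append((gene, code_class, conc))
        df = pd.DataFrame(rows, columns=["gene", "code_class", "nominal_conc"])
        return cls(df.set_index("gene"))

    def genes_of_class(self, code_class: str) -> list[str]:
        return self.table.index[self.table["code_class"] == code_class].tolist()

    @property
    def genes(self) -> list[str]:
        return self.table.index.tolist()

    @property
    def positive_ladder(self) -> pd.Series:
        """Nominal concentrations (fM) of the positive probes, descending."""
        pos = self.table.loc[self.table["code_class"] == "Positive", "nominal_conc"]
        return pos.sort_values(ascending=False)


@dataclass(frozen=True)
class CountMatrix:
    """Raw digital probe counts with panel annotation and sample metadata.

    ``counts`` is genes × samples (integers ≥ 0); ``samples`` is indexed by
    sample_id with columns batch_id, patient_id, tissue_site, histology,
    is_reference, tumor_pct. Every batch must contain exactly one sample
    flagged as the universal mRNA reference.
    """

    counts: pd.DataFrame
    panel: PanelDefinition
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts.index.name = "gene"
        self.counts.columns.name = None
        self.samples.index.name = "sample_id"
        if not self.samples.index.is_unique:
            raise ValidationError("duplicate sample_ids in sample sheet")
        unknown = set(self.counts.index) - set(self.panel.genes)
        if unknown:
            raise SchemaError(f"genes absent from panel: {sorted(unknown)[:5]}")
        missing_meta = set(self.counts.columns) - set(self.samples.index)
        if missing_meta:
            raise SchemaError(f"samples missing from sheet: {sorted(missing_meta)[:5]}")
        if self.counts.isna().any().any():
            raise ValidationError("count matrix has missing cells")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValidationError("negative counts are not allowed")
        if not np.allclose(vals, np.round(vals)):
            raise ValidationError("counts must be integers")
        for batch, grp in self.samples.loc[self.counts.columns].groupby("batch_id"):
            n_ref = int(grp["is_reference"].sum())
            if n_ref != 1:
                raise ValidationError(
                    f"batch {batch!r} has {n_ref} reference samples (expected 1)"
                )
        tp = self.samples.get("tumor_pct")
        if tp is not None and ((tp.dropna() < 0) | (tp.dropna() > 100)).any():
            raise ValidationError("tumor_pct must lie in [0, 100]")

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def genes(self) -> list[str]:
        return self.counts.index.tolist()

    def genes_of_class(self, code_class: str) -> list[str]:
        return [g for g in self.panel.genes_of_class(code_class) if g in self.counts.index]

    def reference_map(self) -> dict[str, str]:
        """batch_id → sample_id of the universal reference run in that batch."""
        meta = self.samples.loc[self.counts.columns]
        refs = meta[meta["is_reference"].astype(bool)]
        return {str(row["batch_id"]): str(sid) for sid, row in refs.iterrows()}

    def batch_of(self, sample_id: str) -> str:
        return str(self.samples.at[sample_id, "batch_id"])


@dataclass(frozen=True)
class RccLane:
    """One parsed RCC file: a single lane / sample."""

    counts: pd.Series               # probe name → integer count
    code_classes: pd.Series         # probe name → code class
    attributes: dict[str, dict[str, str]] = field(default_factory=dict)

    @property
    def sample_id(self) -> str | None:
        for section in ("Sample_Attributes", "Lane_Attributes"):
            sid = self.attributes.get(section, {}).get("ID")
            if sid:
                return sid
        return None


# ---------------------------------------------------------------------------
# RCC container
# ---------------------------------------------------------------------------

def _split_fields(line: str) -> list[str]:
    # vendor exports vary between comma- and tab-delimited sections
    if "\t" in line:
        return [f.strip() for f in line.split("\t")]
    return [f.strip() for f in line.split(",")]


def read_rcc(path: str | Path) -> RccLane:
    """Parse a Reporter Code Count file (one lane) into counts + attributes.

    Section order is irrelevant; both comma- and tab-delimited Code_Summary
    sections are accepted; BOM and CRLF line endings are stripped.
    """
    text = Path(path).read_text(encoding="utf-8-sig")
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for raw in text.splitlines():
        line = raw.rstrip("\r").strip()
        if not line:
            continue
        if line.startswith("<") and line.endswith(">"):
            name = line.strip("<>")
            if name.startswith("/"):
                current = None
            else:
                current = name
                sections.setdefault(current, [])
            continue
        if current is not None:
            sections[current].append(line)

    if "Code_Summary" not in sections:
        raise FormatError(f"{path}: missing Code_Summary section")

    body = sections["Code_Summary"]
    header = _split_fields(body[0])
    try:
        i_class = header.index("CodeClass")
        i_name = header.index("Name")
        i_count = header.index("Count")
    except ValueError as exc:
        raise FormatError(f"{path}: Code_Summary header lacks {exc}") from None

    names, classes, counts = [], [], []
    for row in body[1:]:
        fields = _split_fields(row)
        if len(fields) <= max(i_class, i_name, i_count):
            raise FormatError(f"{path}: malformed Code_Summary row: {row!r}")
        raw_count = fields[i_count]
        try:
            count = int(raw_count)
        except ValueError:
            raise ValueError(
                f"{path}: non-integer Count {raw_count!r} in row {row!r}"
            ) from None
        names.append(fields[i_name])
        classes.append(fields[i_class])
        counts.append(count)

    attributes = {
        sec: dict(_split_fields(line)[:2] for line in lines if len(_split_fields(line)) >= 2)
        for sec, lines in sections.items()
        if sec != "Code_Summary"
    }
    return RccLane(
        counts=pd.Series(counts, index=pd.Index(names, name="gene"), name="Count"),
        code_classes=pd.Series(classes, index=pd.Index(names, name="gene")),
        attributes=attributes,
    )


def write_rcc(
    path: str | Path,
    sample_id: str,
    counts: Mapping[str, int] | pd.Series,
    code_classes: Mapping[str, str] | pd.Series,
    *,
    lane_id: int = 1,
    accession: Mapping[str, str] | None = None,
) -> None:
    """Write one lane of counts as a canonical comma-delimited RCC file."""
    counts = pd.Series(counts)
    code_classes = pd.Series(code_classes)
    buf = io.StringIO()
    buf.write("<Header>\nFileVersion,1.7\nSoftwareVersion,4.0.0\n</Header>\n")
    buf.write(f"<Sample_Attributes>\nID,{sample_id}\nOwner,\nDate,\n</Sample_Attributes>\n")
    buf.write(f"<Lane_Attributes>\nID,{lane_id}\n</Lane_Attributes>\n")
    buf.write("<Code_Summary>\nCodeClass,Name,Accession,Count\n")
    for gene, count in counts.items():
        acc = accession.get(gene, "NA") if accession else "NA"
        buf.write(f"{code_classes[gene]},{gene},{acc},{int(count)}\n")
    buf.write("</Code_Summary>\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_rcc_dir(
    directory: str | Path,
    panel: PanelDefinition,
    samples: pd.DataFrame,
) -> CountMatrix:
    """Assemble a :class:`CountMatrix` from a directory of per-sample RCC files.

    Each file is one lane = one sample, matched to the sheet via the RCC
    sample attribute ``ID``.
    """
    lanes = {}
    for path in sorted(Path(directory).glob("*.RCC")) + sorted(Path(directory).glob("*.rcc")):
        lane = read_rcc(path)
        sid = lane.sample_id or path.stem
        lanes[sid] = lane.counts
    if not lanes:
        raise FormatError(f"no RCC files found under {directory}")
    counts = pd.DataFrame(lanes).loc[:, list(samples.index.intersection(lanes))]
    counts = counts.reindex(columns=[s for s in samples.index if s in lanes])
    return CountMatrix(counts=counts.astype(int), panel=panel, samples=samples)


# ---------------------------------------------------------------------------
# Plain tables
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, **kwargs)


def read_panel(path: str | Path) -> PanelDefinition:
    """Read a TSV/CSV panel definition (columns: gene, code_class, nominal_conc)."""
    df = _read_table(path)
    required = {"gene", "code_class"}
    if not required.issubset(df.columns):
        raise SchemaError(f"panel file needs columns {sorted(required)}")
    if "nominal_conc" not in df.columns:
        df["nominal_conc"] = math.nan
    df["gene"] = df["gene"].astype(str).str.strip()
    df["code_class"] = df["code_class"].astype(str).str.strip()
    return PanelDefinition(df.set_index("gene")[["code_class", "nominal_conc"]])


_TRUE = {"true", "1", "yes", "y", "t"}


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet; returns a DataFrame indexed by sample_id."""
    df = _read_table(path, dtype=str).fillna("")
    required = {"sample_id", "batch_id", "is_reference"}
    if not required.issubset(df.columns):
        raise SchemaError(f"sample sheet needs columns {sorted(required)}")
    df["sample_id"] = df["sample_id"].str.strip()
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_ids in sample sheet")
    df["is_reference"] = df["is_reference"].str.strip().str.lower().isin(_TRUE)
    for col in ("patient_id", "tissue_site", "histology"):
        if col not in df.columns:
            df[col] = ""
    bad_hist = set(df["histology"]) - set(HISTOLOGIES) - {""}
    if bad_hist:
        raise ValidationError(f"unknown histology labels: {sorted(bad_hist)}")
    if "tumor_pct" in df.columns:
        df["tumor_pct"] = pd.to_numeric(df["tumor_pct"].mask(df["tumor_pct"] == ""))
    else:
        df["tumor_pct"] = np.nan
    return df.set_index("sample_id")


def read_count_table(
    path: str | Path,
    panel_path: str | Path,
    sheet_path: str | Path,
) -> CountMatrix:
    """Read a gene × sample count table with its panel and sample sheet."""
    panel = read_panel(panel_path)
    samples = read_sample_sheet(sheet_path)
    raw = _read_table(path, index_col=0)
    raw.index = raw.index.astype(str).str.strip()
    vals = raw.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise ValueError(f"{path}: non-numeric counts present")
    if not np.allclose(vals, np.round(vals)) or (vals < 0).any():
        raise ValueError(f"{path}: counts must be non-negative integers")
    return CountMatrix(counts=raw.astype(int), panel=panel, samples=samples)


def write_count_table(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.rename_axis("gene").to_csv(path, sep="\t")


def write_panel(panel: PanelDefinition, path: str | Path) -> None:
    panel.table.rename_axis("gene").to_csv(path, sep="\t")


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    out = samples.copy()
    out["is_reference"] = out["is_reference"].map({True: "true", False: "false"})
    out.rename_axis("sample_id").to_csv(path, sep="\t")


def read_ihc(path: str | Path) -> pd.DataFrame:
    """Read an IHC table (sample_id, marker, h_score); validates H-score range."""
    df = _read_table(path)
    required = {"sample_id", "marker", "h_score"}
    if not required.issubset(df.columns):
        raise SchemaError(f"IHC table needs columns {sorted(required)}")
    if df.duplicated(["sample_id", "marker"]).any():
        raise ValidationError("duplicate (sample_id, marker) rows in IHC table")
    h = df["h_score"]
    if ((h < 0) | (h > 300)).any():
        raise ValidationError("H-scores must lie in [0, 300]")
    return df


def read_tpm(path: str | Path) -> pd.DataFrame:
    """Read a gene × sample TPM table (non-negative reals)."""
    df = _read_table(path, index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValidationError("TPM values must be non-negative")
    return df


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _format_cell(value, column: str) -> str:
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        if column.endswith("_pct") or column in {
            "PPA", "NPA", "PPV", "NPV", "OPA",
        } or column.endswith(("_lo", "_hi")):
            return f"{value:.{PERCENT_DECIMALS}f}"
        return f"{value:.{RATIO_DECIMALS}f}"
    if value is None:
        return "NA"
    if isinstance(value, (bool, np.bool_)):
        return "true" if value else "false"
    return str(value)


def write_report(results: pd.DataFrame, path: str | Path) -> None:
    """Write a deterministic TSV report.

    Column order follows the input frame; floats are formatted to 4 decimals
    (ratios) or 1 decimal (percentage columns: names ending in ``_pct``,
    ``_lo``/``_hi``, or the agreement metric names); identical inputs give
    byte-identical files.
    """
    lines = ["\t".join(map(str, results.columns))]
    for _, row in results.iterrows():
        lines.append("\t".join(_format_cell(row[c], str(c)) for c in results.columns))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
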