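"""Reading and writing expression tables, NanoString RCC files, models and call tables.

Expression data travels as :class:`ExpressionMatrix`, a dense gene-by-sample
table of non-negative values with a platform tag.  All file formats are plain
text: TSV/CSV for matrices and calls, the RCC bracketed-section dialect for
NanoString lane files, and versioned JSON for serialized models.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MODEL_SCHEMA_VERSION = 1


class Platform(str, enum.Enum):
    """Origin of the expression values; only the scale differs, never the ranks."""

    nanostring_counts = "nanostring_counts"
    rnaseq_fpkm = "rnaseq_fpkm"
    microarray_intensity = "microarray_intensity"
    unknown = "unknown"


class ProbeClass(str, enum.Enum):
    """NanoString CodeClass of a probe."""

    Endogenous = "Endogenous"
    Negative = "Negative"
    Positive = "Positive"
    Housekeeping = "Housekeeping"


@dataclass
class ExpressionMatrix:
    """Dense gene x sample matrix of non-negative expression values.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as the index and sample identifiers
        as columns.  Every cell must be present, numeric and >= 0.
    platform
        Data-generation platform; NanoString counts are eligible for
        background correction, FPKM/microarray values are used as-is.
    """

    values: pd.DataFrame
    platform: Platform = Platform.unknown

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame (genes x samples)")
        self.platform = Platform(self.platform)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        try:
            arr = self.values.to_numpy(dtype=float)
        except (TypeError, ValueError):
            bad = _first_non_numeric(self.values)
            raise ValueError(f"non-numeric expression value at gene {bad[0]!r}, sample {bad[1]!r}") from None
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise ValueError(
                f"missing value at gene {self.values.index[g]!r}, sample {self.values.columns[s]!r}"
            )
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative expression value {arr[g, s]} at gene "
                f"{self.values.index[g]!r}, sample {self.values.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)].copy(), self.platform)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.platform)


def _first_non_numeric(df: pd.DataFrame) -> tuple[str, str]:
    for s in df.columns:
        col = pd.to_numeric(df[s], errors="coerce")
        if col.isna().any():
            g = df.index[col.isna().to_numpy().nonzero()[0][0]]
            return str(g), str(s)
    return "?", "?"


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_table(
    path: str | Path,
    orientation: str = "genes_in_rows",
    platform: Platform | str = Platform.unknown,
) -> ExpressionMatrix:
    """Read a delimited expression table into an :class:`ExpressionMatrix`.

    TSV by default, CSV when the extension is ``.csv``.  ``orientation``
    says whether rows are genes (``genes_in_rows``) or samples
    (``samples_in_rows``); the returned matrix is always genes x samples.
    Non-numeric or negative cells are hard errors naming the offending cell.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression table not found: {path}")
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    if df.index.isna().any() or any(df.isna().any()):
        raise ValueError(f"ragged or incomplete table: {path}")
    if orientation == "samples_in_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        numeric = df.apply(pd.to_numeric)
    except (TypeError, ValueError):
        g, s = _first_non_numeric(df)
        raise ValueError(f"non-numeric expression value at gene {g!r}, sample {s!r}") from None
    if numeric.isna().any().any():
        g, s = _first_non_numeric(df)
        raise ValueError(f"non-numeric expression value at gene {g!r}, sample {s!r}")
    return ExpressionMatrix(numeric.astype(float), Platform(platform))


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write genes-in-rows TSV/CSV (delimiter chosen by extension)."""
    path = Path(path)
    matrix.values.to_csv(path, sep=_sep_for(path), index_label="gene")


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column sample_id / label table (TSV or CSV by extension)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"labels file not found: {path}")
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"labels file needs sample_id and label columns: {path}")
    ser = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].astype(str), name="label")
    if ser.index.has_duplicates:
        raise ValueError(f"duplicate sample ids in labels file: {path}")
    return ser


def write_labels(labels: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample_id": labels.index.astype(str), "label": labels.values}).to_csv(
        Path(path), sep=_sep_for(Path(path)), index=False
    )


# ---------------------------------------------------------------------------
# NanoString RCC lane files
# ---------------------------------------------------------------------------

_SECTION_RE = re.compile(r"^<\s*(/?)([A-Za-z_]+)\s*>\s*$")


def _parse_rcc_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for raw in text.replace("\r\n", "\n").replace("\r", "\n").split("\n"):
        line = raw.rstrip()
        m = _SECTION_RE.match(line)
        if m:
            closing, name = m.groups()
            current = None if closing else name
            if current is not None:
                sections.setdefault(current, [])
            continue
        if current is not None and line != "":
            sections[current].append(line)
    return sections


def read_rcc_batch(
    paths: Iterable[str | Path],
) -> tuple[ExpressionMatrix, dict[str, ProbeClass]]:
    """Read single-sample NanoString RCC files into one count matrix.

    Each file contributes one sample column; the sample id comes from the
    ``ID`` row of ``Sample_Attributes``, falling back to the file stem, and
    a collision across files is resolved by suffixing the file stem.
    Returns the matrix (platform ``nanostring_counts``) and a map from probe
    name to its CodeClass, needed later for background correction and QC.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no RCC files given")
    columns: dict[str, pd.Series] = {}
    probe_class: dict[str, ProbeClass] = {}
    for path in paths:
        if not path.exists():
            raise FileNotFoundError(f"RCC file not found: {path}")
        sections = _parse_rcc_sections(path.read_text())
        if "Code_Summary" not in sections or not sections["Code_Summary"]:
            raise ValueError(f"missing Code_Summary section in {path}")
        sample_id = path.stem
        for line in sections.get("Sample_Attributes", []):
            parts = line.split(",")
            if parts and parts[0] == "ID" and len(parts) > 1 and parts[1].strip():
                sample_id = parts[1].strip()
                break
        rows = sections["Code_Summary"]
        header = [h.strip() for h in rows[0].split(",")]
        try:
            i_class = header.index("CodeClass")
            i_name = header.index("Name")
            i_count = header.index("Count")
        except ValueError:
            raise ValueError(f"Code_Summary header lacks CodeClass/Name/Count in {path}") from None
        counts: dict[str, int] = {}
        for row in rows[1:]:
            parts = [p.strip() for p in row.split(",")]
            if len(parts) <= max(i_class, i_name, i_count):
                raise ValueError(f"ragged Code_Summary row in {path}: {row!r}")
            name, raw_count = parts[i_name], parts[i_count]
            try:
                count = int(raw_count)
            except ValueError:
                raise ValueError(
                    f"non-integer Count {raw_count!r} for probe {name!r} in {path}"
                ) from None
            if name in counts:
                raise ValueError(f"duplicate probe Name {name!r} in {path}")
            counts[name] = count
            probe_class[name] = ProbeClass(parts[i_class])
        if sample_id in columns:
            sample_id = f"{sample_id}_{path.stem}"
        columns[sample_id] = pd.Series(counts, name=sample_id)
    df = pd.DataFrame(columns).astype(float)
    if df.isna().any().any():
        raise ValueError("RCC files disagree on probe content; cannot form a dense matrix")
    return ExpressionMatrix(df, Platform.nanostring_counts), probe_class


# ---------------------------------------------------------------------------
# Model serialization (versioned JSON)
# ---------------------------------------------------------------------------

def save_model(model, path: str | Path) -> None:
    """Serialize an SSPModel to versioned, human-readable JSON."""
    payload = {"schema_version": MODEL_SCHEMA_VERSION, "model": model.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_model(path: str | Path):
    """Load an SSPModel written by :func:`save_model`."""
    from .ssp_core import SSPModel

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file not found: {path}")
    payload = json.loads(path.read_text())
    if "schema_version" not in payload:
        raise ValueError(f"model file lacks schema_version: {path}")
    if payload["schema_version"] != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported model schema_version {payload['schema_version']} "
            f"(expected {MODEL_SCHEMA_VERSION}): {path}"
        )
    if "model" not in payload:
        raise ValueError(f"model file lacks model payload: {path}")
    return SSPModel.from_dict(payload["model"])


# ---------------------------------------------------------------------------
# Calls / predictions tables
# ---------------------------------------------------------------------------

def write_calls_table(records: Sequence, path: str | Path) -> None:
    """Write predictions or fusion calls as a TSV with a stable column order.

    Prediction rows get one ``posterior_<class>`` column per class; fusion
    call rows carry status, best_variant, imbalance_ratio, junction count and
    the QC flag.  Mixing record types is an error.
    """
    from .fusion_caller import FusionCall
    from .ssp_core import Prediction

    records = list(records)
    if not records:
        raise ValueError("refusing to write an empty calls table")
    kinds = {type(r) for r in records}
    if len(kinds) > 1:
        raise ValueError(f"mixed record types in calls table: {sorted(k.__name__ for k in kinds)}")
    path = Path(path)
    if isinstance(records[0], Prediction):
        classes = list(records[0].posterior)
        rows = []
        for r in records:
            row = {"sample_id": r.sample_id, "predicted_class": r.predicted_class}
            for c in classes:
                row[f"posterior_{c}"] = f"{r.posterior[c]:.10g}"
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    elif isinstance(records[0], FusionCall):
        rows = [
            {
                "sample_id": r.sample_id,
                "gene": r.gene,
                "status": r.status,
                "best_variant": r.best_variant if r.best_variant is not None else "",
                "imbalance_ratio": f"{r.imbalance_ratio:.10g}",
                "max_junction_count": f"{r.max_junction_count:.10g}",
                "qc_flag": r.qc_flag,
            }
            for r in records
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise TypeError(f"unsupported record type {type(records[0]).__name__}")


def read_calls_table(path: str | Path) -> pd.DataFrame:
    """Read back a calls/predictions TSV as a DataFrame."""
    return pd.read_csv(Path(path), sep="\t")
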