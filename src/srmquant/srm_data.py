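"""Domain types and readers/writers for SRM/MRM transition-level data.

The atomic observation in a targeted-proteomics experiment is one
chromatographic peak area for one (run, peptide, charge, fragment, label)
cell — a *transition measurement*.  Tables of these, plus per-run metadata
describing each run's experimental role (blank, calibration point,
replicate-design cell, or clinical sample), are the inputs to every
downstream stage.

All tabular I/O is long/tidy CSV with fixed column names matching a Skyline
custom-report export.  Missing peak areas are encoded as empty fields, never
as zero: zero is a legal measured area for a blank.  Identifiers are
case-sensitive throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRANSITION_COLUMNS",
    "METADATA_COLUMNS",
    "AMINO_ACIDS",
    "TransitionReportError",
    "ValidationError",
    "AssayReport",
    "ClassificationReport",
    "ProteinAbundanceMatrix",
    "read_transition_report",
    "write_transition_report",
    "read_run_metadata",
    "write_run_metadata",
    "write_report",
    "read_assay_report",
    "read_classification_report",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

TRANSITION_COLUMNS = [
    "run_id",
    "protein",
    "peptide",
    "precursor_charge",
    "fragment",
    "label",
    "rt_min",
    "area",
]

METADATA_COLUMNS = [
    "run_id",
    "run_type",
    "spike_fmol",
    "counterpart_fmol",
    "replicate_index",
    "day_index",
    "sample_id",
    "condition",
]

RUN_TYPES = {"blank", "calibration", "replicate_design", "clinical"}
CONDITIONS = {"control", "cirrhosis", "HCC"}
LABELS = {"light", "heavy"}


class TransitionReportError(ValueError):
    """Malformed transition report (missing columns, unparseable file)."""


class ValidationError(ValueError):
    """A row violates a domain invariant (bad residue, negative area, ...)."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TransitionReportError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )


def read_transition_report(path) -> pd.DataFrame:
    """Read a tidy transition-level peak-area report.

    Parameters
    ----------
    path : str or Path
        CSV with columns ``run_id, protein, peptide, precursor_charge,
        fragment, label, rt_min, area``.  Empty ``area`` fields are
        preserved as missing (NaN), never coerced to zero.

    Returns
    -------
    pandas.DataFrame
        One validated row per transition measurement.

    Raises
    ------
    TransitionReportError
        If the header is malformed.
    ValidationError
        Citing the offending line number for a negative area, an invalid
        peptide sequence, an unknown label, or a duplicated key.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"run_id": str, "protein": str, "peptide": str,
                                  "fragment": str, "label": str})
    _require_columns(df, TRANSITION_COLUMNS, path)
    df = df[TRANSITION_COLUMNS].copy()
    df["area"] = pd.to_numeric(df["area"], errors="coerce")
    df["rt_min"] = pd.to_numeric(df["rt_min"], errors="coerce")
    df["precursor_charge"] = df["precursor_charge"].astype(int)

    # data rows start at line 2 (line 1 is the header)
    for idx, row in df.iterrows():
        line = idx + 2
        pep = row["peptide"]
        if not pep or not set(pep) <= AMINO_ACIDS:
            raise ValidationError(
                f"{path} line {line}: invalid peptide sequence {pep!r}"
            )
        if row["label"] not in LABELS:
            raise ValidationError(
                f"{path} line {line}: label must be 'light' or 'heavy', got "
                f"{row['label']!r}"
            )
        if not np.isnan(row["area"]) and row["area"] < 0:
            raise ValidationError(
                f"{path} line {line}: negative peak area {row['area']}"
            )
        if row["precursor_charge"] <= 0:
            raise ValidationError(
                f"{path} line {line}: precursor charge must be positive"
            )
    key = ["run_id", "peptide", "precursor_charge", "fragment", "label"]
    dup = df.duplicated(subset=key)
    if dup.any():
        line = int(dup.idxmax()) + 2
        raise ValidationError(
            f"{path} line {line}: duplicate (run, peptide, charge, fragment, "
            f"label) key"
        )
    return df


def write_transition_report(df: pd.DataFrame, path) -> None:
    """Write a transition table back to tidy CSV (missing areas as empty)."""
    df[TRANSITION_COLUMNS].to_csv(path, index=False)


def read_run_metadata(path) -> pd.DataFrame:
    """Read per-run metadata (run role, spike level, design indices, labels)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"run_id": str, "run_type": str,
                                  "sample_id": str, "condition": str})
    _require_columns(df, ["run_id", "run_type"], path)
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    bad = ~df["run_type"].isin(RUN_TYPES)
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise ValidationError(
            f"{path} line {line}: unknown run_type {df.loc[bad.idxmax(), 'run_type']!r}"
        )
    clinical = df["run_type"] == "clinical"
    badcond = clinical & ~df["condition"].isin(CONDITIONS)
    if badcond.any():
        line = int(badcond.idxmax()) + 2
        raise ValidationError(f"{path} line {line}: clinical run needs a valid condition")
    blanks = df["run_type"] == "blank"
    nonzero = blanks & pd.to_numeric(df["spike_fmol"], errors="coerce").fillna(0).ne(0)
    if nonzero.any():
        line = int(nonzero.idxmax()) + 2
        raise ValidationError(f"{path} line {line}: blank run must have spike_fmol = 0")
    return df[METADATA_COLUMNS]


def write_run_metadata(df: pd.DataFrame, path) -> None:
    cols = [c for c in METADATA_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Result-report containers


@dataclass
class AssayReport:
    """Assay figures of merit.

    ``peptides`` has one row per peptide: protein, peptide, llod_fmol,
    lloq_fmol, r_squared, accepted, lloq_below_llod, and per-spike-level CV
    columns ``intra_cv_<level>``, ``inter_cv_<level>``, ``total_cv_<level>``
    (percent).  ``proteins`` has one row per protein: protein,
    protein_r_squared, and ``protein_total_cv_<level>`` columns.
    """

    peptides: pd.DataFrame
    proteins: pd.DataFrame

    def write(self, path_prefix) -> None:
        """Write ``<prefix>_peptides.csv`` and ``<prefix>_proteins.csv``."""
        prefix = str(path_prefix)
        self.peptides.to_csv(prefix + "_peptides.csv", index=False)
        self.proteins.to_csv(prefix + "_proteins.csv", index=False)


def read_assay_report(path_prefix) -> AssayReport:
    prefix = str(path_prefix)
    return AssayReport(
        peptides=pd.read_csv(prefix + "_peptides.csv"),
        proteins=pd.read_csv(prefix + "_proteins.csv"),
    )


@dataclass
class ClassificationReport:
    """Panel-classification results.

    accuracy_grid: DataFrame indexed by panel size with one column per
    algorithm, entries are out-of-sample (LOOCV) accuracy in percent.
    confusion: 3x3 integer matrix, true condition x predicted.
    auc: per-class one-vs-rest AUC from held-out LOOCV probabilities.
    """

    selected_panel: list[str]
    algorithm: str
    in_sample_accuracy: float
    out_of_sample_accuracy: float
    confusion: pd.DataFrame
    auc: dict[str, float]
    accuracy_grid: pd.DataFrame | None = None
    roc_curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "selected_panel": list(self.selected_panel),
            "algorithm": self.algorithm,
            "in_sample_accuracy": self.in_sample_accuracy,
            "out_of_sample_accuracy": self.out_of_sample_accuracy,
            "confusion": {
                "classes": list(self.confusion.index),
                "matrix": [[int(v) for v in row] for row in self.confusion.values],
            },
            "auc": {k: float(v) for k, v in self.auc.items()},
            "warnings": list(self.warnings),
        }
        if self.accuracy_grid is not None:
            d["accuracy_grid"] = {
                "panel_sizes": [int(k) for k in self.accuracy_grid.index],
                "algorithms": list(self.accuracy_grid.columns),
                "accuracy_percent": self.accuracy_grid.values.tolist(),
            }
        return d


def read_classification_report(path) -> ClassificationReport:
    with open(path) as fh:
        d = json.load(fh)
    classes = d["confusion"]["classes"]
    confusion = pd.DataFrame(d["confusion"]["matrix"], index=classes, columns=classes)
    grid = None
    if "accuracy_grid" in d:
        g = d["accuracy_grid"]
        grid = pd.DataFrame(
            g["accuracy_percent"], index=g["panel_sizes"], columns=g["algorithms"]
        )
    return ClassificationReport(
        selected_panel=d["selected_panel"],
        algorithm=d["algorithm"],
        in_sample_accuracy=d["in_sample_accuracy"],
        out_of_sample_accuracy=d["out_of_sample_accuracy"],
        confusion=confusion,
        auc=d["auc"],
        accuracy_grid=grid,
        warnings=d.get("warnings", []),
    )


def write_report(report, path) -> None:
    """Write an AssayReport (CSV pair) or ClassificationReport (JSON).

    Round-trips at full floating-point precision:
    ``read(write(x)) == x`` for all numeric fields.
    """
    if isinstance(report, AssayReport):
        prefix = str(path)
        if prefix.endswith(".csv"):
            prefix = prefix[:-4]
        report.write(prefix)
    elif isinstance(report, ClassificationReport):
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
    else:
        raise TypeError(f"unsupported report type {type(report).__name__}")


@dataclass
class ProteinAbundanceMatrix:
    """Samples x proteins matrix of log2 abundance estimators.

    ``values`` is a DataFrame with sample_ids as the index and proteins as
    columns; cells may be missing.  ``provenance`` maps each protein to the
    peptides that contributed and their rollup weights (summing to 1 over
    non-missing peptides per sample; the stored weights are the full-data
    weights).
    """

    values: pd.DataFrame
    provenance: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate protein ids")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def proteins(self) -> list[str]:
        return list(self.values.columns)

    def write(self, path) -> None:
        self.values.to_csv(path, index_label="sample_id")

    @classmethod
    def read(cls, path) -> "ProteinAbundanceMatrix":
        return cls(values=pd.read_csv(path, index_col="sample_id"))
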