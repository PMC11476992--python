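"""Data model and readers/writers for quantitative proteomics tables.

The package works with three plain-text table dialects modeled on the
vendor exports that label-free DIA/targeted workflows produce:

* **transition TSV** — long format, one row per fragment-ion peak area per
  injection (columns :data:`TRANSITION_COLUMNS`).  The ``snr`` column may
  be empty for the DIA arm, where signal-to-noise is not exported.
* **protein-wide CSV** — one row per protein, one column per injection,
  with a sample-sheet TSV sidecar describing each injection and an
  optional peptide-count sidecar.
* **ion-library TSV** — protein/peptide identifications with a search
  confidence in [0, 1] and the source injection that produced them.

Missing measurements are encoded as an *empty field*, never ``0``: a zero
area is a real (if unusual) measurement, whereas an empty cell means the
signal was not extracted at all.  In memory the missing marker is NaN.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Eye",
    "Cohort",
    "Direction",
    "SampleDescriptor",
    "TransitionQuant",
    "IonLibraryEntry",
    "QuantMatrix",
    "DepRecord",
    "FilterConfig",
    "QuantFormatError",
    "QuantValidationError",
    "TRANSITION_COLUMNS",
    "LIBRARY_COLUMNS",
    "SAMPLE_COLUMNS",
    "read_quant_table",
    "write_quant_table",
    "read_ion_library",
    "write_ion_library",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_matrix",
    "write_matrix",
    "transitions_to_records",
    "records_to_frame",
]


class QuantFormatError(ValueError):
    """A file does not match the documented column set for its dialect."""


class QuantValidationError(ValueError):
    """A structurally valid file contains an invalid value."""


class Eye(str, enum.Enum):
    OD = "OD"  # right eye
    OS = "OS"  # left eye


class Cohort(str, enum.Enum):
    SWATH = "SWATH"  # pooled-eye DIA arm, technical replicates
    MRMHR = "MRMHR"  # individual-animal targeted arm


class Direction(str, enum.Enum):
    UP = "UP"
    DOWN = "DOWN"
    NONE = "NONE"


VALID_DAYS = (4, 7, 14, 21, 28)

TRANSITION_COLUMNS = [
    "sample_id", "eye", "day", "replicate", "cohort",
    "protein", "peptide", "precursor_charge", "fragment_label",
    "area", "snr",
]
LIBRARY_COLUMNS = ["protein", "peptide", "confidence", "source_injection"]
SAMPLE_COLUMNS = ["sample_id", "eye", "day", "replicate", "cohort"]


@dataclass(frozen=True)
class SampleDescriptor:
    """One injection: which eye pool / animal, day, replicate and arm."""

    sample_id: str
    eye: Eye
    day: int
    replicate: int
    cohort: Cohort

    def __post_init__(self) -> None:
        if self.day not in VALID_DAYS:
            raise QuantValidationError(
                f"day must be one of {VALID_DAYS}, got {self.day!r}")
        if self.replicate < 1:
            raise QuantValidationError("replicate index must be >= 1")


@dataclass(frozen=True)
class TransitionQuant:
    """One measured fragment-ion peak area for one injection."""

    sample_id: str
    protein: str
    peptide: str
    precursor_charge: int
    fragment_label: str
    area: float
    snr: float | None = None

    def __post_init__(self) -> None:
        if self.area < 0:
            raise QuantValidationError(f"area must be >= 0, got {self.area}")
        if self.precursor_charge not in (2, 3):
            raise QuantValidationError(
                f"precursor charge must be 2 or 3, got {self.precursor_charge}")
        if not self.fragment_label or self.fragment_label[0] not in "yb":
            raise QuantValidationError(
                f"fragment ion type must be y or b, got {self.fragment_label!r}")


@dataclass(frozen=True)
class IonLibraryEntry:
    """One protein<->peptide identification with its search confidence."""

    protein: str
    peptide: str
    confidence: float
    source_injection: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise QuantValidationError(
                f"confidence must be in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class DepRecord:
    """Per-eye fold changes for one protein at one day-vs-reference contrast.

    ``ave_fc`` is the arithmetic mean of the two eye fold changes and
    ``sd_fc`` their two-value sample standard deviation |a - b| / sqrt(2).
    """

    protein: str
    day: int
    reference_day: int
    fc_od: float
    fc_os: float
    ave_fc: float
    sd_fc: float
    direction: Direction
    n_peptides: int


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the bilateral-concordance differential-expression filter."""

    up_cutoff: float = 1.5
    down_cutoff: float = 0.7
    min_peptides: int = 2
    min_confidence: float = 0.90

    def __post_init__(self) -> None:
        if not self.up_cutoff > 1:
            raise QuantValidationError("up_cutoff must exceed 1")
        if not 0 < self.down_cutoff < 1:
            raise QuantValidationError("down_cutoff must lie in (0, 1)")
        if self.min_peptides < 1:
            raise QuantValidationError("min_peptides must be >= 1")


@dataclass
class QuantMatrix:
    """Protein x injection area matrix with sample metadata.

    ``data`` is a float DataFrame indexed by protein accession with one
    column per sample_id; NaN marks a missing (not zero) measurement.
    ``samples`` is a DataFrame indexed by sample_id with columns eye, day,
    replicate, cohort, ordered like the columns of ``data``.
    ``peptide_counts`` gives, per protein, the number of quantified
    peptides supporting its values (minimum across injections where the
    protein is observed).
    """

    data: pd.DataFrame
    samples: pd.DataFrame
    peptide_counts: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(self.samples.index):
            raise QuantValidationError(
                "matrix columns and sample sheet are not aligned")
        if self.samples.index.has_duplicates:
            raise QuantValidationError("duplicate sample_id in sample sheet")
        key = self.samples[["eye", "day", "replicate", "cohort"]]
        if key.duplicated().any():
            raise QuantValidationError(
                "duplicate (eye, day, replicate, cohort) in sample sheet")
        if self.peptide_counts is None:
            self.peptide_counts = pd.Series(1, index=self.data.index)
        observed = self.data.notna().any(axis=1)
        counts = self.peptide_counts.reindex(self.data.index)
        if (counts[observed] < 1).any():
            raise QuantValidationError(
                "peptide_counts must be >= 1 for observed proteins")

    @property
    def proteins(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def columns_for(self, day: int, eye: str | Eye | None = None) -> list[str]:
        """Sample ids of all injections at ``day`` (optionally one eye)."""
        mask = self.samples["day"] == day
        if eye is not None:
            mask &= self.samples["eye"] == str(getattr(eye, "value", eye))
        return list(self.samples.index[mask])

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(self.data.copy(), self.samples.copy(),
                           self.peptide_counts.copy())


# ---------------------------------------------------------------------------
# transition tables


def _require_columns(frame: pd.DataFrame, required: Sequence[str],
                     path: Path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise QuantFormatError(
            f"{path}: missing mandatory column(s) {', '.join(missing)}")


def _validate_transitions(frame: pd.DataFrame, path: Path) -> pd.DataFrame:
    # data row i sits on file line i + 2 (header is line 1)
    bad = frame.index[frame["area"] < 0]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:5])
        raise QuantValidationError(
            f"{path}: negative area on row(s) at line {lines}")
    bad = frame.index[~frame["precursor_charge"].isin([2, 3])]
    if len(bad):
        raise QuantValidationError(
            f"{path}: precursor charge outside {{2,3}} at line {bad[0] + 2}")
    ion_type = frame["fragment_label"].astype(str).str[:1]
    bad = frame.index[~ion_type.isin(["y", "b"])]
    if len(bad):
        raise QuantValidationError(
            f"{path}: fragment ion type not y/b at line {bad[0] + 2}")
    return frame


def read_quant_table(path: str | Path, dialect: str = "transition",
                     sample_sheet: str | Path | None = None,
                     peptide_counts: str | Path | None = None):
    """Read a quant table.

    ``dialect='transition'`` returns a validated long-format DataFrame with
    columns :data:`TRANSITION_COLUMNS`.  ``dialect='protein_wide'`` reads a
    protein-wide CSV plus its sample-sheet sidecar and returns a
    :class:`QuantMatrix`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "transition":
        frame = pd.read_csv(path, sep="\t", dtype={
            "sample_id": str, "eye": str, "cohort": str,
            "protein": str, "peptide": str, "fragment_label": str})
        _require_columns(frame, TRANSITION_COLUMNS, path)
        frame = frame[TRANSITION_COLUMNS]
        if len(frame):
            frame["day"] = frame["day"].astype(int)
            frame["replicate"] = frame["replicate"].astype(int)
            frame["precursor_charge"] = frame["precursor_charge"].astype(int)
            frame["area"] = frame["area"].astype(float)
            frame["snr"] = frame["snr"].astype(float)
            _validate_transitions(frame, path)
        return frame
    if dialect == "protein_wide":
        if sample_sheet is None:
            raise QuantFormatError(
                "protein_wide dialect requires a sample-sheet sidecar")
        return read_matrix(path, sample_sheet, peptide_counts)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_quant_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a transition table in canonical (byte-reproducible) order.

    Rows are sorted by (sample_id, protein, peptide, fragment_label) and
    columns by the documented order, so two writes of the same records are
    byte-identical.
    """
    path = Path(path)
    out = pd.DataFrame(frame, columns=TRANSITION_COLUMNS)
    out = out.sort_values(
        ["sample_id", "protein", "peptide", "fragment_label"],
        kind="mergesort").reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False, na_rep="")


def transitions_to_records(frame: pd.DataFrame) -> list[TransitionQuant]:
    """Convert a transition DataFrame to validated dataclass records."""
    records = []
    for row in frame.itertuples(index=False):
        snr = None if pd.isna(row.snr) else float(row.snr)
        records.append(TransitionQuant(
            sample_id=row.sample_id, protein=row.protein, peptide=row.peptide,
            precursor_charge=int(row.precursor_charge),
            fragment_label=row.fragment_label, area=float(row.area), snr=snr))
    return records


def records_to_frame(records: Iterable[TransitionQuant],
                     samples: pd.DataFrame) -> pd.DataFrame:
    """Assemble a transition DataFrame from records plus sample metadata."""
    rows = [{
        "sample_id": r.sample_id,
        "protein": r.protein, "peptide": r.peptide,
        "precursor_charge": r.precursor_charge,
        "fragment_label": r.fragment_label,
        "area": r.area, "snr": np.nan if r.snr is None else r.snr,
    } for r in records]
    frame = pd.DataFrame(rows)
    meta = samples.reset_index() if samples.index.name == "sample_id" else samples
    frame = frame.merge(meta[SAMPLE_COLUMNS], on="sample_id", how="left")
    return frame[TRANSITION_COLUMNS]


# ---------------------------------------------------------------------------
# ion libraries


def read_ion_library(path: str | Path) -> pd.DataFrame:
    """Read an ion-library TSV, collapsing duplicate (protein, peptide,
    source) rows to the maximum confidence."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={
        "protein": str, "peptide": str, "source_injection": str})
    _require_columns(frame, LIBRARY_COLUMNS, path)
    frame = frame[LIBRARY_COLUMNS]
    frame["confidence"] = frame["confidence"].astype(float)
    bad = frame.index[(frame["confidence"] < 0) | (frame["confidence"] > 1)]
    if len(bad):
        raise QuantValidationError(
            f"{path}: confidence outside [0, 1] at line {bad[0] + 2}")
    frame = (frame.sort_values("confidence")
                  .drop_duplicates(["protein", "peptide", "source_injection"],
                                   keep="last")
                  .sort_values(["protein", "peptide", "source_injection"],
                               kind="mergesort")
                  .reset_index(drop=True))
    return frame


def write_ion_library(library: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(library, columns=LIBRARY_COLUMNS)
    out = out.sort_values(["protein", "peptide", "source_injection"],
                          kind="mergesort").reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sample sheets and protein-wide matrices


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={
        "sample_id": str, "eye": str, "cohort": str})
    _require_columns(frame, SAMPLE_COLUMNS, path)
    frame["day"] = frame["day"].astype(int)
    frame["replicate"] = frame["replicate"].astype(int)
    for row in frame.itertuples(index=False):
        SampleDescriptor(row.sample_id, Eye(row.eye), int(row.day),
                         int(row.replicate), Cohort(row.cohort))
    if frame["sample_id"].duplicated().any():
        raise QuantValidationError(f"{path}: duplicate sample_id")
    return frame.set_index("sample_id")


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    out = samples.reset_index() if samples.index.name == "sample_id" else samples
    out = pd.DataFrame(out, columns=SAMPLE_COLUMNS)
    out.to_csv(path, sep="\t", index=False)


def read_matrix(csv_path: str | Path, sample_sheet: str | Path,
                counts_path: str | Path | None = None) -> QuantMatrix:
    """Read a protein-wide CSV (+ sample sheet, optional peptide counts)."""
    frame = pd.read_csv(csv_path, index_col="protein")
    samples = read_sample_sheet(sample_sheet)
    counts = None
    if counts_path is not None:
        counts = pd.read_csv(counts_path, sep="\t",
                             index_col="protein")["n_peptides"]
    frame = frame[list(samples.index)]
    return QuantMatrix(frame.astype(float), samples, counts)


def write_matrix(matrix: QuantMatrix, csv_path: str | Path,
                 sample_sheet: str | Path,
                 counts_path: str | Path | None = None) -> None:
    out = matrix.data.copy()
    out.index.name = "protein"
    out.to_csv(csv_path, na_rep="")
    write_sample_sheet(matrix.samples, sample_sheet)
    if counts_path is not None:
        counts = matrix.peptide_counts.rename("n_peptides").to_frame()
        counts.index.name = "protein"
        counts.to_csv(counts_path, sep="\t")
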