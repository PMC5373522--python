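"""Reading and validating 12-lead ECGs and per-patient cohort tables.

The canonical in-memory unit is the millivolt. Readers convert from
microvolts when asked (``units="uV"``). ECG files are plain CSV (comma
separated, one header row naming the leads, UTF-8); WFDB records are
supported when the optional ``wfdb`` package is installed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import CohortError, EcgParseError, LeadError

#: Canonical 12-lead order.
LEADS_12 = ("I", "II", "III", "aVR", "aVL", "aVF",
            "V1", "V2", "V3", "V4", "V5", "V6")

#: The 8 linearly independent leads (the rest follow from Einthoven/Goldberger).
LEADS_8 = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

_LEAD_ALIASES = {lead.upper(): lead for lead in LEADS_12}


@dataclass
class EcgRecord:
    """A raw multi-lead ECG in millivolts.

    ``samples`` is ``[n_samples, 12]`` in the canonical lead order
    :data:`LEADS_12`; ``sampling_rate`` is in Hz.
    """

    samples: np.ndarray
    sampling_rate: float
    lead_names: tuple[str, ...] = LEADS_12
    subject_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 12:
            raise LeadError(
                f"expected a [n_samples, 12] matrix, got shape {self.samples.shape}")
        if tuple(self.lead_names) != LEADS_12:
            raise LeadError(f"leads must be in canonical order {LEADS_12}")
        if not self.sampling_rate > 0:
            raise EcgParseError("sampling_rate must be positive")
        if not np.isfinite(self.samples).all():
            raise EcgParseError("non-finite sample values")
        self.lead_names = LEADS_12

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.sampling_rate

    def lead(self, name: str) -> np.ndarray:
        return self.samples[:, LEADS_12.index(name)]

    def independent_leads(self) -> np.ndarray:
        """The ``[n_samples, 8]`` submatrix (I, II, V1-V6) used by the Kors transform."""
        idx = [LEADS_12.index(l) for l in LEADS_8]
        return self.samples[:, idx]


def complete_limb_leads(eight: np.ndarray) -> np.ndarray:
    """Expand an ``[n, 8]`` (I, II, V1-V6) matrix to the full 12 leads.

    Uses the Einthoven/Goldberger identities::

        III = II - I,  aVR = -(I + II)/2,  aVL = I - II/2,  aVF = II - I/2
    """
    eight = np.asarray(eight, dtype=float)
    if eight.ndim != 2 or eight.shape[1] != 8:
        raise LeadError(f"expected 8 independent leads, got shape {eight.shape}")
    lead_i, lead_ii = eight[:, 0], eight[:, 1]
    out = np.empty((eight.shape[0], 12))
    out[:, 0] = lead_i
    out[:, 1] = lead_ii
    out[:, 2] = lead_ii - lead_i
    out[:, 3] = -(lead_i + lead_ii) / 2.0
    out[:, 4] = lead_i - lead_ii / 2.0
    out[:, 5] = lead_ii - lead_i / 2.0
    out[:, 6:] = eight[:, 2:]
    return out


def read_ecg(path, format: str = "csv", sampling_rate: float | None = None,
             units: str = "mV", subject_id: str | None = None) -> EcgRecord:
    """Read a 12-lead ECG file into an :class:`EcgRecord`.

    CSV files must carry one header row naming the leads; either all 12
    leads or the 8 independent leads (I, II, V1-V6) may be present, in any
    column order. With 8 leads the limb leads are reconstructed. CSV carries
    no sampling rate, so ``sampling_rate`` is required for ``format="csv"``.
    """
    path = Path(path)
    if subject_id is None:
        subject_id = path.stem
    if format == "wfdb":
        return _read_wfdb(path, subject_id)
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    if sampling_rate is None:
        raise EcgParseError("sampling_rate is required for CSV input")
    try:
        frame = pd.read_csv(path)
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise EcgParseError(str(exc)) from exc
    frame.columns = [str(c).strip() for c in frame.columns]
    unknown = [c for c in frame.columns if c.upper() not in _LEAD_ALIASES]
    if unknown:
        raise LeadError(f"unknown lead label(s): {unknown}")
    have = {_LEAD_ALIASES[c.upper()]: c for c in frame.columns}
    if len(have) != len(frame.columns):
        raise LeadError("duplicate lead columns")
    values = frame.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        raise EcgParseError(f"non-numeric cells in {path.name}")
    if set(have) == set(LEADS_12):
        samples = np.column_stack([values[have[l]].to_numpy() for l in LEADS_12])
    elif set(have) == set(LEADS_8):
        eight = np.column_stack([values[have[l]].to_numpy() for l in LEADS_8])
        samples = complete_limb_leads(eight)
    else:
        missing = sorted(set(LEADS_8) - set(have))
        raise LeadError(f"need all 12 leads or the 8 independent leads; missing {missing}")
    if units == "uV":
        samples = samples / 1000.0
    elif units != "mV":
        raise EcgParseError(f"unknown units {units!r}")
    return EcgRecord(samples, float(sampling_rate), subject_id=subject_id)


def _read_wfdb(path: Path, subject_id: str) -> EcgRecord:
    try:
        import wfdb  # optional dependency
    except ImportError as exc:
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package "
            "(pip install aecg[wfdb]); CSV input needs no extra dependency") from exc
    rec = wfdb.rdrecord(str(path.with_suffix("")))
    names = [str(n).strip() for n in rec.sig_name]
    unknown = [n for n in names if n.upper() not in _LEAD_ALIASES]
    if unknown:
        raise LeadError(f"unknown lead label(s) in WFDB record: {unknown}")
    frame = pd.DataFrame(rec.p_signal, columns=[_LEAD_ALIASES[n.upper()] for n in names])
    if set(frame.columns) == set(LEADS_12):
        samples = frame[list(LEADS_12)].to_numpy()
    elif set(frame.columns) >= set(LEADS_8):
        samples = complete_limb_leads(frame[list(LEADS_8)].to_numpy())
    else:
        raise LeadError("WFDB record lacks the 8 independent leads")
    if str(getattr(rec, "units", ["mV"])[0]).lower() in ("uv", "microvolt", "microvolts"):
        samples = samples / 1000.0
    return EcgRecord(samples, float(rec.fs), subject_id=subject_id)


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Per-patient feature/outcome table.

    ``data`` is indexed by subject id; numeric analysis columns are floats
    with missing values as NaN (never silently zero). ``excluded`` maps
    column name -> reason for columns flagged out during feature selection
    (all-NULL, text, or low-count columns).
    """

    data: pd.DataFrame
    excluded: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise CohortError(f"duplicate patient ids: {dupes}")
        for col in ("event", "hf_event"):
            if col in self.data.columns:
                vals = self.data[col].dropna().unique()
                if not set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}:
                    raise CohortError(f"{col} must be binary 0/1")
        for col in self.data.columns:
            if "time" in col and pd.api.types.is_numeric_dtype(self.data[col]):
                if (self.data[col].dropna() < 0).any():
                    raise CohortError(f"negative times in column {col}")

    @property
    def n_patients(self) -> int:
        return len(self.data)

    def numeric_columns(self) -> list[str]:
        """Analysis-eligible numeric columns (excluded columns filtered out)."""
        return [c for c in self.data.columns
                if c not in self.excluded
                and pd.api.types.is_numeric_dtype(self.data[c])]


def read_cohort(path, id_column: str | None = None,
                min_count: int = 10) -> CohortTable:
    """Read a per-patient CSV/XLSX metadata table.

    Applies the feature-selection rule used throughout the cohort analyses:
    all-NULL columns, non-numeric (text) columns and columns with fewer than
    ``min_count`` non-missing values are retained but flagged in
    ``CohortTable.excluded`` rather than silently dropped.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        frame = pd.read_excel(path)
    else:
        frame = pd.read_csv(path)
    if id_column is None:
        id_column = frame.columns[0] if "subject_id" not in frame.columns else "subject_id"
    if frame[id_column].duplicated().any():
        raise CohortError(
            f"duplicate patient ids: {frame[id_column][frame[id_column].duplicated()].tolist()}")
    frame = frame.set_index(id_column)
    excluded: dict[str, str] = {}
    for col in frame.columns:
        series = frame[col]
        if series.isna().all():
            excluded[col] = "all-NULL"
            continue
        numeric = pd.to_numeric(series, errors="coerce")
        if numeric.isna().sum() > series.isna().sum():
            excluded[col] = "text"
            continue
        frame[col] = numeric
        if numeric.notna().sum() < min_count:
            excluded[col] = "low-count"
    return CohortTable(frame, excluded)


def write_features(table: CohortTable, path) -> None:
    """Write a cohort/feature table to CSV with stable column order and full float precision."""
    if table.n_patients == 0:
        raise CohortError("refusing to write an empty table")
    path = Path(path)
    try:
        table.data.to_csv(path, index=True, index_label=table.data.index.name or "subject_id",
                          float_format="%.17g")
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def write_ecg_csv(record: EcgRecord, path) -> None:
    """Write an :class:`EcgRecord` as a 12-column CSV (header = lead names, mV)."""
    frame = pd.DataFrame(record.samples, columns=list(LEADS_12))
    frame.to_csv(Path(path), index=False, float_format="%.9g")


def roundtrip_equal(a: CohortTable, b: CohortTable, rtol: float = 1e-12) -> bool:
    """True when two tables agree up to float representation."""
    if list(a.data.columns) != list(b.data.columns):
        return False
    if list(a.data.index) != list(b.data.index):
        return False
    for col in a.data.columns:
        x, y = a.data[col], b.data[col]
        if pd.api.types.is_numeric_dtype(x) and pd.api.types.is_numeric_dtype(y):
            if not np.allclose(x.fillna(np.nan), y.fillna(np.nan),
                               rtol=rtol, equal_nan=True):
                return False
        elif not (x.fillna("") == y.fillna("")).all():
            return False
    return True
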