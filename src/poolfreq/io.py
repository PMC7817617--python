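"""Core data containers and text I/O.

The quantitative measurement throughout the package is the fluorescence
intensity ratio (FIR) of a two-colour SNP-array spot, ``y / (x + y)``, where
``x`` is the allele-A channel intensity and ``y`` the allele-B channel
intensity.  All matrices are SNP-major (rows = SNPs, columns = samples);
missing values are ``NaN`` internally and the token ``NA`` on disk, because
``0`` is a legal intensity and a legal frequency.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "DuplicateRecordError",
    "FinalReportDialect",
    "IntensityRecord",
    "FIRMatrix",
    "GenotypeCallMatrix",
    "FrequencyMatrix",
    "SOURCE_FIXED",
    "SOURCE_LOGISTIC",
    "SOURCE_AMBIGUOUS",
    "SOURCE_MISSING",
    "GENOTYPE_CODES",
    "read_final_report",
    "build_fir_matrix",
    "read_fir_matrix",
    "write_fir_matrix",
    "read_genotype_calls",
    "write_genotype_calls",
    "read_frequency_matrix",
    "write_frequency_matrix",
    "sources_path",
]

NA_TOKEN = "NA"

SOURCE_FIXED = "FIXED_BY_TEST"
SOURCE_LOGISTIC = "LOGISTIC"
SOURCE_AMBIGUOUS = "AMBIGUOUS"
SOURCE_MISSING = "MISSING"
_SOURCE_CODES = {SOURCE_FIXED, SOURCE_LOGISTIC, SOURCE_AMBIGUOUS, SOURCE_MISSING}

GENOTYPE_CODES = ("AA", "AB", "BB")


class FormatError(ValueError):
    """An input file does not match the expected layout."""


class DuplicateRecordError(ValueError):
    """The same (SNP, sample) pair occurs more than once in an input file."""


@dataclass(frozen=True)
class FinalReportDialect:
    """Column-name map for a GenomeStudio-style final report.

    Export layouts vary between GenomeStudio versions and site conventions,
    so the four required column labels are configurable.
    """

    snp_col: str = "SNP Name"
    sample_col: str = "Sample ID"
    x_col: str = "X"
    y_col: str = "Y"

    def required(self) -> tuple[str, str, str, str]:
        return (self.snp_col, self.sample_col, self.x_col, self.y_col)


@dataclass(frozen=True)
class IntensityRecord:
    """Normalized two-channel intensities for one SNP in one sample.

    ``x`` is the allele-A channel and ``y`` the allele-B channel.  A record
    is missing when either channel is absent (NaN) or both are zero: no
    signal carries no frequency information.
    """

    snp_id: str
    sample_id: str
    x: float
    y: float

    @property
    def is_missing(self) -> bool:
        if np.isnan(self.x) or np.isnan(self.y):
            return True
        return self.x + self.y == 0.0

    @property
    def fir(self) -> float:
        """B-channel share of total signal, ``y/(x+y)``; NaN when missing."""
        if self.is_missing:
            return float("nan")
        return self.y / (self.x + self.y)


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} ids")


@dataclass
class FIRMatrix:
    """SNP x sample matrix of fluorescence intensity ratios in [0, 1]."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.values.index), "SNP")
        _check_unique(list(self.values.columns), "sample")
        v = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (v < 0) | (v > 1)
        if np.any(bad & ~np.isnan(v)):
            raise ValueError("FIR values must lie in [0, 1] or be missing")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GenotypeCallMatrix:
    """SNP x sample matrix of diploid calls in {AA, AB, BB} or missing (NaN)."""

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.calls.index), "SNP")
        _check_unique(list(self.calls.columns), "sample")
        seen = set(self.calls.to_numpy().ravel().tolist())
        allowed = set(GENOTYPE_CODES)
        for v in seen:
            if isinstance(v, float) and np.isnan(v):
                continue
            if v not in allowed:
                raise ValueError(f"invalid genotype call {v!r}")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.columns)


@dataclass
class FrequencyMatrix:
    """Estimated allele-B frequencies per SNP x population, with provenance.

    ``source`` records per cell how the estimate was obtained: a fixation
    test (frequency exactly 0 or 1), the logistic calibration curve
    (frequency strictly inside (0, 1)), an ambiguous fixation call, or a
    missing observation (both carry NaN frequency).
    """

    values: pd.DataFrame
    source: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.source is None:
            src = np.where(np.isnan(self.values.to_numpy(dtype=float)),
                           SOURCE_MISSING, SOURCE_LOGISTIC)
            fixed = np.isin(self.values.to_numpy(dtype=float), (0.0, 1.0))
            src = np.where(fixed, SOURCE_FIXED, src)
            self.source = pd.DataFrame(src, index=self.values.index,
                                       columns=self.values.columns)
        _check_unique(list(self.values.index), "SNP")
        _check_unique(list(self.values.columns), "population")
        if not (self.source.index.equals(self.values.index)
                and self.source.columns.equals(self.values.columns)):
            raise ValueError("source matrix must mirror the value matrix")
        v = self.values.to_numpy(dtype=float)
        s = self.source.to_numpy()
        bad_codes = set(s.ravel().tolist()) - _SOURCE_CODES
        if bad_codes:
            raise ValueError(f"invalid source codes {bad_codes}")
        with np.errstate(invalid="ignore"):
            if np.any(((v < 0) | (v > 1)) & ~np.isnan(v)):
                raise ValueError("frequencies must lie in [0, 1] or be missing")
        fixed = s == SOURCE_FIXED
        if np.any(fixed & ~np.isin(v, (0.0, 1.0))):
            raise ValueError("fixation-test frequencies must be exactly 0 or 1")
        logi = s == SOURCE_LOGISTIC
        with np.errstate(invalid="ignore"):
            if np.any(logi & (np.isnan(v) | (v <= 0.0) | (v >= 1.0))):
                raise ValueError("logistic frequencies must be strictly in (0, 1)")
        absent = (s == SOURCE_AMBIGUOUS) | (s == SOURCE_MISSING)
        if np.any(absent & ~np.isnan(v)):
            raise ValueError("ambiguous/missing cells must carry NaN frequency")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def population_ids(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# final-report reader


def read_final_report(path, dialect: FinalReportDialect | None = None
                      ) -> list[IntensityRecord]:
    """Parse a tab-delimited GenomeStudio-final-report-like file.

    An optional ``[Header]`` block terminated by a ``[Data]`` line precedes
    the data table.  Malformed or negative channel values become missing;
    a repeated (SNP, sample) pair is an error.
    """
    dialect = dialect or FinalReportDialect()
    text = Path(path).read_text()
    lines = text.splitlines()
    start = 0
    for i, line in enumerate(lines):
        if line.strip() == "[Data]":
            start = i + 1
            break
    table = pd.read_csv(_stdio.StringIO("\n".join(lines[start:])), sep="\t",
                        dtype=str, keep_default_na=False)
    for col in dialect.required():
        if col not in table.columns:
            raise FormatError(f"missing required column {col!r}")
    x = pd.to_numeric(table[dialect.x_col], errors="coerce")
    y = pd.to_numeric(table[dialect.y_col], errors="coerce")
    # negative intensity is physically invalid -> treat the channel as absent
    x = x.where(x >= 0)
    y = y.where(y >= 0)
    keys = list(zip(table[dialect.snp_col], table[dialect.sample_col]))
    if len(set(keys)) != len(keys):
        seen: set[tuple[str, str]] = set()
        for k in keys:
            if k in seen:
                raise DuplicateRecordError(
                    f"duplicate record for SNP {k[0]!r}, sample {k[1]!r}")
            seen.add(k)
    return [
        IntensityRecord(snp, sample, float(xi), float(yi))
        for (snp, sample), xi, yi in zip(keys, x.fillna(np.nan), y.fillna(np.nan))
    ]


def build_fir_matrix(records: Iterable[IntensityRecord]) -> FIRMatrix:
    """Assemble per-record FIR values into a SNP x sample matrix.

    Row and column order follow first appearance in the record stream.
    """
    records = list(records)
    if not records:
        raise ValueError("no intensity records")
    snp_order: dict[str, int] = {}
    sample_order: dict[str, int] = {}
    for r in records:
        snp_order.setdefault(r.snp_id, len(snp_order))
        sample_order.setdefault(r.sample_id, len(sample_order))
    mat = np.full((len(snp_order), len(sample_order)), np.nan)
    for r in records:
        mat[snp_order[r.snp_id], sample_order[r.sample_id]] = r.fir
    return FIRMatrix(pd.DataFrame(mat, index=list(snp_order),
                                  columns=list(sample_order)))


# ---------------------------------------------------------------------------
# matrix TSV round trips


def _write_matrix(df: pd.DataFrame, path, float_format: str | None) -> None:
    df.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format=float_format,
              index_label="snp_id")


def _read_matrix(path, numeric: bool) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN],
                     keep_default_na=False, dtype=None if numeric else str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if numeric:
        df = df.astype(float)
    return df


def write_fir_matrix(fm: FIRMatrix, path) -> None:
    _write_matrix(fm.values, path, "%.6f")


def read_fir_matrix(path) -> FIRMatrix:
    return FIRMatrix(_read_matrix(path, numeric=True))


def write_genotype_calls(gm: GenotypeCallMatrix, path) -> None:
    _write_matrix(gm.calls, path, None)


def read_genotype_calls(path) -> GenotypeCallMatrix:
    df = _read_matrix(path, numeric=False)
    return GenotypeCallMatrix(df.where(df.notna(), np.nan))


def sources_path(path) -> Path:
    """Sibling file carrying per-cell provenance codes for a frequency TSV."""
    p = Path(path)
    return p.with_name(p.stem + ".sources" + (p.suffix or ".tsv"))


def write_frequency_matrix(fm: FrequencyMatrix, path) -> None:
    """Write frequencies (6 decimals, NA for missing) plus a sources sibling."""
    _write_matrix(fm.values, path, "%.6f")
    _write_matrix(fm.source, sources_path(path), None)


def read_frequency_matrix(path) -> FrequencyMatrix:
    values = _read_matrix(path, numeric=True)
    sp = sources_path(path)
    if sp.exists():
        source = _read_matrix(sp, numeric=False)
    else:
        source = None
    return FrequencyMatrix(values, source)
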