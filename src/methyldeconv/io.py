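"""Readers and writers for beta matrices, sample sheets and result tables.

All interchange files are plain TSV/CSV. Beta matrices are probe-major
(rows = probes, header row = sample IDs, first column = probe IDs). Lines
starting with '#' are provenance comments and are skipped on read. Floats
are written with 17 significant digits so write -> read round-trips exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "read_annotation",
    "write_table",
]

_NA_SENTINELS = {"", "NA", "NaN", "nan"}


def _sep_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_beta_matrix(
    path: str | Path, delimiter: str | None = None
) -> pd.DataFrame:
    """Read a probe x sample beta matrix.

    "NA" and empty cells become NaN; any other non-numeric cell raises with
    the probe/sample it occurred at. Duplicate probe or sample IDs are
    errors.
    """
    path = Path(path)
    sep = _sep_for(path, delimiter)
    # check the raw header first: pandas silently mangles duplicate names
    with open(path) as handle:
        header = ""
        for line in handle:
            if not line.startswith("#"):
                header = line.rstrip("\n")
                break
    sample_ids = header.split(sep)[1:]
    dup_samples = {s for s in sample_ids if sample_ids.count(s) > 1}
    if dup_samples:
        raise ValueError(
            f"{path}: duplicate sample IDs: {sorted(dup_samples)[:5]}"
        )
    raw = pd.read_csv(
        path, sep=sep, index_col=0, comment="#", dtype=str,
        keep_default_na=False,
    )
    if not raw.index.is_unique:
        dups = raw.index[raw.index.duplicated()].unique()
        raise ValueError(f"{path}: duplicate probe IDs: {list(dups[:5])}")
    out = pd.DataFrame(
        np.nan, index=raw.index, columns=raw.columns, dtype=float
    )
    for col in raw.columns:
        cells = raw[col].str.strip()
        is_na = cells.isin(_NA_SENTINELS)
        numeric = pd.to_numeric(cells.where(~is_na), errors="coerce")
        bad = ~is_na & numeric.isna()
        if bad.any():
            probe = raw.index[bad.to_numpy()][0]
            raise ValueError(
                f"{path}: non-numeric value {cells[bad].iloc[0]!r} at "
                f"probe {probe!r}, sample {col!r}"
            )
        # float() is correctly rounded; pandas' fast parser is not
        values = np.full(len(cells), np.nan)
        present = (~is_na).to_numpy()
        values[present] = [float(v) for v in cells.to_numpy()[present]]
        out[col] = values
    out.index.name = "probe"
    return out


def write_beta_matrix(
    betas: pd.DataFrame,
    path: str | Path,
    delimiter: str | None = None,
    provenance: dict | None = None,
) -> None:
    path = Path(path)
    sep = _sep_for(path, delimiter)
    with open(path, "w") as handle:
        _write_provenance(handle, provenance)
        betas.to_csv(
            handle, sep=sep, index_label="probe", float_format="%.17g"
        )


def read_sample_sheet(path: str | Path, delimiter: str | None = None) -> pd.Series:
    """Two-column sheet (sample ID, cell-type label) with a header row."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path, delimiter), comment="#",
                        dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample, cell type)")
    series = pd.Series(
        frame.iloc[:, 1].to_numpy(), index=frame.iloc[:, 0], name="cell_type"
    )
    if not series.index.is_unique:
        dups = series.index[series.index.duplicated()].unique()
        raise ValueError(f"{path}: duplicate sample IDs: {list(dups[:5])}")
    return series


def read_annotation(path: str | Path, delimiter: str | None = None) -> pd.Series:
    """Two-column annotation (probe ID, chromosome) with a header row."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path, delimiter), comment="#",
                        dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (probe, chromosome)")
    series = pd.Series(
        frame.iloc[:, 1].to_numpy(), index=frame.iloc[:, 0], name="chromosome"
    )
    if not series.index.is_unique:
        dups = series.index[series.index.duplicated()].unique()
        raise ValueError(f"{path}: duplicate probe IDs: {list(dups[:5])}")
    return series


def _write_provenance(handle, provenance: dict | None) -> None:
    if provenance:
        for key, value in provenance.items():
            handle.write(f"# {key}: {value}\n")


def write_table(
    table: pd.DataFrame,
    path: str | Path,
    delimiter: str | None = None,
    provenance: dict | None = None,
    index: bool = False,
) -> None:
    """Write a tidy result table with optional '#'-prefixed provenance lines."""
    path = Path(path)
    sep = _sep_for(path, delimiter)
    with open(path, "w") as handle:
        _write_provenance(handle, provenance)
        table.to_csv(handle, sep=sep, index=index, float_format="%.17g")
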