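"""Readers and writers for the delimited-text tables the pipeline exchanges.

Three table kinds are supported:

* beta matrices — CpG loci × samples methylation levels in [0, 1],
  tab-delimited with a ``locus_id`` header column and one column per sample;
  missing cells are serialised as ``NA`` and held in memory as NaN;
* per-probe intensity tables — methylated (M) / unmethylated (U) signals
  with a 0/1 flag marking background-control probes;
* per-site WGBS methylation tables in the 6-column methcounts convention
  (chrom, 0-based position, strand, context, level, coverage), whitespace
  delimited, no header.

All readers validate on load and raise :class:`TableFormatError` with the
offending row/column named; no silent coercion is performed. Writers emit
files that the corresponding reader parses back to an identical object
(floats are written as their shortest exact decimal representation).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TableFormatError",
    "BetaMatrix",
    "IntensityTable",
    "WGBSSiteTable",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_intensity_table",
    "write_intensity_table",
    "read_wgbs_sites",
    "write_wgbs_sites",
]

def _fmt_float(value: float) -> str:
    """Shortest decimal string that parses back to the identical float."""
    return repr(float(value))


class TableFormatError(ValueError):
    """Raised when an on-disk table violates the format contract."""


@dataclass
class BetaMatrix:
    """Loci × samples matrix of methylation levels (fraction methylated).

    ``values[i, j]`` is the level of locus ``locus_ids[i]`` in sample
    ``sample_ids[j]``; NaN marks a missing measurement. Values must lie in
    [0, 1]; identifiers must be unique.
    """

    locus_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.locus_ids = [str(x) for x in self.locus_ids]
        self.sample_ids = [str(x) for x in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.locus_ids), len(self.sample_ids)):
            raise TableFormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.locus_ids)} loci x {len(self.sample_ids)} samples"
            )
        _require_unique(self.locus_ids, "locus_id")
        _require_unique(self.sample_ids, "sample_id")
        bad = np.argwhere(
            ~np.isnan(self.values) & ((self.values < 0) | (self.values > 1))
        )
        if bad.size:
            i, j = bad[0]
            raise TableFormatError(
                f"beta value {self.values[i, j]!r} outside [0, 1] at locus "
                f"{self.locus_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.locus_ids, name="locus_id"),
            columns=list(self.sample_ids),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BetaMatrix":
        return cls(
            locus_ids=[str(x) for x in frame.index],
            sample_ids=[str(x) for x in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    def sample(self, sample_id: str) -> pd.Series:
        """One sample's levels as a Series indexed by locus."""
        j = self.sample_ids.index(sample_id)
        return pd.Series(self.values[:, j], index=self.locus_ids, name=sample_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BetaMatrix):
            return NotImplemented
        return (
            self.locus_ids == other.locus_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


@dataclass
class IntensityTable:
    """Per-probe methylated/unmethylated fluorescence signals for one sample.

    Rows flagged ``is_background_control`` carry draws from the array's
    background-fluorescence distribution in both channels and anchor the
    detection p-value model; all intensities are non-negative.
    """

    frame: pd.DataFrame = field(repr=False)

    REQUIRED = ("probe_id", "M", "U", "is_background_control")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise TableFormatError(f"intensity table missing columns {missing}")
        f = self.frame.reset_index(drop=True).copy()
        f["probe_id"] = f["probe_id"].astype(str)
        f["M"] = f["M"].astype(float)
        f["U"] = f["U"].astype(float)
        f["is_background_control"] = f["is_background_control"].astype(bool)
        for col in ("M", "U"):
            neg = f.index[f[col] < 0]
            if len(neg):
                row = f.loc[neg[0]]
                raise TableFormatError(
                    f"negative {col} intensity {row[col]!r} for probe "
                    f"{row['probe_id']!r}"
                )
        _require_unique(list(f["probe_id"]), "probe_id")
        self.frame = f[list(self.REQUIRED)]

    @property
    def probes(self) -> pd.DataFrame:
        """Non-control rows, indexed by probe_id."""
        f = self.frame
        return f[~f["is_background_control"]].set_index("probe_id")

    @property
    def controls(self) -> pd.DataFrame:
        """Background-control rows, indexed by probe_id."""
        f = self.frame
        return f[f["is_background_control"]].set_index("probe_id")

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntensityTable):
            return NotImplemented
        return self.frame.equals(other.frame)


@dataclass
class WGBSSiteTable:
    """Per-CpG methylation levels and read coverage from WGBS.

    Columns: chrom, pos (0-based), strand (+/−), context, level in [0, 1],
    coverage (non-negative integer). (chrom, pos, strand) triples are unique.
    """

    frame: pd.DataFrame = field(repr=False)

    COLUMNS = ("chrom", "pos", "strand", "context", "level", "coverage")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise TableFormatError(f"WGBS table missing columns {missing}")
        f = self.frame.reset_index(drop=True).copy()
        f["chrom"] = f["chrom"].astype(str)
        f["pos"] = _int_column(f["pos"], "pos", minimum=0)
        f["strand"] = f["strand"].astype(str)
        bad_strand = f.index[~f["strand"].isin(["+", "-"])]
        if len(bad_strand):
            raise TableFormatError(
                f"strand must be '+' or '-', got "
                f"{f.loc[bad_strand[0], 'strand']!r} on line {bad_strand[0] + 1}"
            )
        f["context"] = f["context"].astype(str)
        f["level"] = f["level"].astype(float)
        bad = f.index[(f["level"] < 0) | (f["level"] > 1) | f["level"].isna()]
        if len(bad):
            raise TableFormatError(
                f"methylation level {f.loc[bad[0], 'level']!r} outside [0, 1] "
                f"on line {bad[0] + 1}"
            )
        f["coverage"] = _int_column(f["coverage"], "coverage", minimum=0)
        dup = f.duplicated(subset=["chrom", "pos", "strand"])
        if dup.any():
            k = int(np.flatnonzero(dup)[0])
            raise TableFormatError(
                f"duplicate site ({f.loc[k, 'chrom']}, {f.loc[k, 'pos']}, "
                f"{f.loc[k, 'strand']}) on line {k + 1}"
            )
        self.frame = f[list(self.COLUMNS)]

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WGBSSiteTable):
            return NotImplemented
        return self.frame.equals(other.frame)


def _require_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise TableFormatError(f"duplicate {what} {x!r}")
        seen.add(x)


def _int_column(col: pd.Series, name: str, minimum: int) -> pd.Series:
    as_float = col.astype(float)
    if not np.all(as_float == np.floor(as_float)):
        k = int(np.flatnonzero(as_float != np.floor(as_float))[0])
        raise TableFormatError(f"{name} {col.iloc[k]!r} is not an integer")
    out = as_float.astype(int)
    low = out.index[out < minimum]
    if len(low):
        raise TableFormatError(
            f"{name} {out.loc[low[0]]!r} below {minimum} on line {low[0] + 1}"
        )
    return out


# ---------------------------------------------------------------------------
# beta matrices


def read_beta_matrix(path) -> BetaMatrix:
    """Read a tab-delimited beta matrix (header row of sample ids, first
    column locus ids, ``NA`` for missing)."""
    with open(path) as handle:
        header = handle.readline().rstrip("\n")
    fields = header.split("\t")
    if not fields or fields[0] != "locus_id":
        raise TableFormatError(
            f"beta matrix header must start with 'locus_id', got "
            f"{fields[0] if fields else ''!r}"
        )
    _require_unique(fields[1:], "sample_id")  # before pandas mangles duplicates
    try:
        frame = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            na_values=["NA"],
            keep_default_na=False,
            dtype=str,
        )
    except Exception as exc:  # malformed file structure
        raise TableFormatError(f"cannot parse beta matrix {path}: {exc}") from exc
    try:
        # astype goes through exact per-element strtod, unlike to_numeric
        numeric = frame.astype(float)
    except (ValueError, TypeError):
        coerced = frame.apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna() & frame.notna()
        i, j = np.argwhere(bad.to_numpy())[0]
        raise TableFormatError(
            f"non-numeric value {frame.iat[i, j]!r} at locus "
            f"{frame.index[i]!r}, sample {frame.columns[j]!r}"
        ) from None
    return BetaMatrix(
        locus_ids=[str(x) for x in frame.index],
        sample_ids=[str(c) for c in frame.columns],
        values=numeric.to_numpy(dtype=float),
    )


def write_beta_matrix(matrix: BetaMatrix, path) -> None:
    """Write a beta matrix in the format read by :func:`read_beta_matrix`."""
    matrix.to_frame().to_csv(
        path, sep="\t", na_rep="NA", float_format=_fmt_float
    )


# ---------------------------------------------------------------------------
# intensity tables


def read_intensity_table(path) -> IntensityTable:
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise TableFormatError(f"cannot parse intensity table {path}: {exc}") from exc
    missing = [c for c in IntensityTable.REQUIRED if c not in frame.columns]
    if missing:
        raise TableFormatError(f"intensity table missing columns {missing}")
    try:
        frame["M"] = frame["M"].astype(float)
        frame["U"] = frame["U"].astype(float)
    except ValueError as exc:
        raise TableFormatError(f"non-numeric intensity in {path}: {exc}") from exc
    flags = frame["is_background_control"]
    if not flags.isin(["0", "1"]).all():
        bad = flags[~flags.isin(["0", "1"])].iloc[0]
        raise TableFormatError(
            f"is_background_control must be 0/1, got {bad!r}"
        )
    frame["is_background_control"] = flags == "1"
    return IntensityTable(frame)


def write_intensity_table(table: IntensityTable, path) -> None:
    out = table.frame.copy()
    out["is_background_control"] = out["is_background_control"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format=_fmt_float)


# ---------------------------------------------------------------------------
# WGBS site tables


def read_wgbs_sites(path) -> WGBSSiteTable:
    """Read a 6-column methcounts-style per-site methylation file."""
    rows = []
    handle = open(path) if not isinstance(path, io.TextIOBase) else path
    try:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6:
                raise TableFormatError(
                    f"line {lineno}: expected 6 whitespace-delimited columns, "
                    f"got {len(parts)}"
                )
            rows.append(parts)
    finally:
        if handle is not path:
            handle.close()
    if not rows:
        frame = pd.DataFrame(columns=list(WGBSSiteTable.COLUMNS))
        return WGBSSiteTable(frame)
    frame = pd.DataFrame(rows, columns=list(WGBSSiteTable.COLUMNS))
    try:
        frame["pos"] = frame["pos"].astype(int)
        frame["level"] = frame["level"].astype(float)
        frame["coverage"] = frame["coverage"].astype(int)
    except ValueError as exc:
        raise TableFormatError(f"non-numeric field in {path}: {exc}") from exc
    return WGBSSiteTable(frame)


def write_wgbs_sites(table: WGBSSiteTable, path) -> None:
    with open(path, "w") as handle:
        for row in table.frame.itertuples(index=False):
            handle.write(
                f"{row.chrom}\t{row.pos}\t{row.strand}\t{row.context}\t"
                f"{_fmt_float(row.level)}\t{row.coverage}\n"
            )
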