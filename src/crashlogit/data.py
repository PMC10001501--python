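"""Binary-coded crash tables: loading, validation, descriptives, collinearity screen.

A crash table has one row per crash, a 0/1 outcome column (1 = the rider was
killed, 0 = any lesser injury), 0/1 indicator covariates (rider, manoeuvre,
temporal/environmental and road characteristics), and an integer year label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CrashTable",
    "DescriptiveSummary",
    "CodingError",
    "load_crash_table",
    "descriptive_summary",
    "correlation_screen",
]


class CodingError(ValueError):
    """A coded column holds something other than 0/1, or a value is missing."""


@dataclass(frozen=True)
class CrashTable:
    """Validated crash records.

    Attributes
    ----------
    frame : pandas.DataFrame
        One row per crash; contains ``outcome_col``, ``year_col`` and the
        indicator covariates, all integer 0/1 (year excepted).
    outcome_col, year_col : str
        Column roles.
    """

    frame: pd.DataFrame
    outcome_col: str = "fatal"
    year_col: str = "year"

    def __post_init__(self) -> None:
        _validate(self.frame, self.outcome_col, self.year_col)

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.frame.columns if c not in (self.outcome_col, self.year_col)]

    @property
    def years(self) -> list[int]:
        return sorted(self.frame[self.year_col].unique().tolist())

    @property
    def n(self) -> int:
        return len(self.frame)

    def outcome(self) -> np.ndarray:
        return self.frame[self.outcome_col].to_numpy(dtype=np.int64)

    def subset_year(self, year: int) -> "CrashTable":
        sub = self.frame[self.frame[self.year_col] == year].reset_index(drop=True)
        if sub.empty:
            raise ValueError(f"no records for year {year}")
        return CrashTable(sub, self.outcome_col, self.year_col)

    def design(self, columns: list[str]) -> np.ndarray:
        """Covariate block as a float matrix in the given column order."""
        missing = [c for c in columns if c not in self.frame.columns]
        if missing:
            raise KeyError(f"unknown covariate(s): {missing}")
        return self.frame[columns].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _validate(frame: pd.DataFrame, outcome_col: str, year_col: str) -> None:
    for col in (outcome_col, year_col):
        if col not in frame.columns:
            raise KeyError(f"required column {col!r} not in table")
    if frame.isna().any().any():
        bad = frame.columns[frame.isna().any()].tolist()
        raise CodingError(f"missing values in column(s) {bad}")
    coded = [c for c in frame.columns if c != year_col]
    for col in coded:
        vals = frame[col].to_numpy()
        offenders = ~np.isin(vals, (0, 1))
        if offenders.any():
            row = int(np.flatnonzero(offenders)[0])
            raise CodingError(
                f"column {col!r} is not binary coded: value {vals[row]!r} at row {row}"
            )


def load_crash_table(path, outcome_col: str = "fatal", year_col: str = "year") -> CrashTable:
    """Read a crash CSV (header row required) and validate the binary coding.

    Row order is preserved.  Any non-0/1 value in a coded column, or any
    missing cell, raises :class:`CodingError` naming the column and row.
    """
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"empty crash table at {path}")
    return CrashTable(frame, outcome_col=outcome_col, year_col=year_col)


@dataclass
class DescriptiveSummary:
    """Per-year fatal/non-fatal counts and per-indicator means/SDs."""

    counts: pd.DataFrame  # index year, columns fatal / non_fatal / n
    moments: pd.DataFrame  # MultiIndex columns (year, mean|sd), index covariate
    table: pd.DataFrame = field(default=None)  # long-form convenience view

    def __post_init__(self):
        if self.table is None:
            self.table = self.moments.copy()


def descriptive_summary(table: CrashTable) -> DescriptiveSummary:
    """Counts and sample moments per year.

    SDs use the (n-1) denominator, so an indicator column with mean ``p`` over
    ``n`` rows has SD ``sqrt(p*(1-p)*n/(n-1))``.
    """
    if table.n == 0:
        raise ValueError("empty crash table")
    f = table.frame
    rows = []
    for year, sub in f.groupby(table.year_col, sort=True):
        y = sub[table.outcome_col]
        rows.append(
            {"year": int(year), "fatal": int(y.sum()), "non_fatal": int((1 - y).sum()), "n": len(sub)}
        )
    counts = pd.DataFrame(rows).set_index("year")

    blocks = {}
    for year, sub in f.groupby(table.year_col, sort=True):
        cov = sub[table.covariates]
        blocks[(int(year), "mean")] = cov.mean()
        blocks[(int(year), "sd")] = cov.std(ddof=1).fillna(0.0)
    moments = pd.DataFrame(blocks)
    moments.columns = pd.MultiIndex.from_tuples(moments.columns, names=["year", "stat"])
    return DescriptiveSummary(counts=counts, moments=moments)


def correlation_screen(
    table: CrashTable, threshold: float = 0.7
) -> list[tuple[str, str, float]]:
    """Pairwise Pearson screen for multicollinearity among the indicators.

    Returns every unordered covariate pair with ``|r| >= threshold`` (the
    conventional 0.7 cut used to declare multicollinearity absent when no pair
    reaches it).  A zero-variance column cannot enter a correlation and raises.
    """
    cols = table.covariates
    if len(cols) < 2:
        raise ValueError("need at least two covariates to screen")
    if table.n < 3:
        raise ValueError("need at least three rows to screen")
    X = table.design(cols)
    sd = X.std(axis=0, ddof=1)
    dead = [c for c, s in zip(cols, sd) if s == 0.0]
    if dead:
        raise ValueError(f"zero-variance column(s): {dead}")
    R = np.corrcoef(X, rowvar=False)
    flagged = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = float(R[i, j])
            if abs(r) >= threshold:
                flagged.append((cols[i], cols[j], r))
    return flagged
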