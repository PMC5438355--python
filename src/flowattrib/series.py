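"""Core containers: the yearly catchment record and analysis-period bounds.

A :class:`CatchmentSeries` holds one aligned growing-season record per
calendar year: precipitation ``P``, mean air temperature ``T``, potential
evapotranspiration ``ETp``, actual evapotranspiration ``ET`` and streamflow
depth ``Q`` (all water fluxes in mm per growing season, temperature in
degrees Celsius). Missing values are carried explicitly as NaN and are never
imputed; operations that need complete data call
:meth:`CatchmentSeries.require_complete` and fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError

#: Canonical column order for tables and frames.
COLUMNS = ("year", "P", "T", "ETp", "ET", "Q")

#: Flux columns that must be nonnegative wherever observed.
_NONNEGATIVE = ("P", "ETp", "ET", "Q")


@dataclass(frozen=True, eq=False)
class CatchmentSeries:
    """Aligned yearly growing-season hydro-meteorological record.

    Invariants (enforced on construction): all columns share one length,
    years are strictly increasing integers with no duplicates, and the water
    fluxes are nonnegative wherever they are not NaN.
    """

    year: np.ndarray
    P: np.ndarray
    T: np.ndarray
    ETp: np.ndarray
    ET: np.ndarray
    Q: np.ndarray

    def __post_init__(self) -> None:
        year = np.asarray(self.year)
        if year.size and not np.issubdtype(year.dtype, np.integer):
            as_float = np.asarray(year, dtype=float)
            if not np.all(as_float == np.round(as_float)):
                raise ValidationError("years must be integer calendar years")
            year = as_float.astype(int)
        else:
            year = year.astype(int)
        object.__setattr__(self, "year", year)
        n = year.size
        for name in COLUMNS[1:]:
            col = np.asarray(getattr(self, name), dtype=float)
            if col.size != n:
                raise ValidationError(
                    f"column {name!r} has length {col.size}, expected {n}"
                )
            object.__setattr__(self, name, col)
        if n == 0:
            raise ValidationError("empty series")
        diffs = np.diff(year)
        if np.any(diffs == 0):
            dup = int(year[:-1][diffs == 0][0])
            raise ValidationError(f"duplicate year {dup}")
        if np.any(diffs < 0):
            raise ValidationError("years must be strictly increasing")
        for name in _NONNEGATIVE:
            col = getattr(self, name)
            bad = col < 0
            if np.any(bad & ~np.isnan(col)):
                y = int(year[np.flatnonzero(bad)[0]])
                raise ValidationError(f"negative {name} in year {y}")

    def __len__(self) -> int:
        return self.year.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CatchmentSeries):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, f.name), getattr(other, f.name), equal_nan=True)
            for f in fields(self)
        )

    def to_frame(self) -> pd.DataFrame:
        """Return a copy of the record as a DataFrame in canonical column order."""
        return pd.DataFrame({name: getattr(self, name).copy() for name in COLUMNS})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, sort: bool = True) -> "CatchmentSeries":
        """Build a series from a DataFrame with the canonical columns.

        Rows are sorted by year first when ``sort`` is true; invariants are
        then enforced by the constructor.
        """
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"missing columns: {', '.join(missing)}")
        if sort:
            frame = frame.sort_values("year", kind="stable")
        return cls(*(frame[name].to_numpy() for name in COLUMNS))

    def period(self, start: int, end: int) -> "CatchmentSeries":
        """Subset to years in the closed interval [start, end]."""
        mask = (self.year >= start) & (self.year <= end)
        if not mask.any():
            raise DataError(f"no years in [{start}, {end}]")
        return CatchmentSeries(*(getattr(self, name)[mask] for name in COLUMNS))

    def has_missing(self, columns: tuple[str, ...] = COLUMNS[1:]) -> bool:
        return any(np.isnan(getattr(self, name)).any() for name in columns)

    def require_complete(
        self, columns: tuple[str, ...] = COLUMNS[1:], context: str = "operation"
    ) -> None:
        """Raise :class:`DataError` naming the offending column/years if any
        requested column contains NaN. Years are never dropped silently."""
        for name in columns:
            nan_mask = np.isnan(getattr(self, name))
            if nan_mask.any():
                years = ", ".join(str(int(y)) for y in self.year[nan_mask][:5])
                raise DataError(
                    f"{context} requires complete {name}; missing in years {years}"
                )


@dataclass(frozen=True)
class PeriodDefinition:
    """Pre- and post-restoration analysis periods in calendar years.

    The default periods follow the common split for Tibetan Plateau
    restoration studies: 1982-1999 before large-scale grassland
    rehabilitation, 2000-2012 after.
    """

    pre_start: int = 1982
    pre_end: int = 1999
    post_start: int = 2000
    post_end: int = 2012

    def __post_init__(self) -> None:
        if not (self.pre_start <= self.pre_end):
            raise ValidationError("pre_start must not exceed pre_end")
        if not (self.post_start <= self.post_end):
            raise ValidationError("post_start must not exceed post_end")
        if not (self.pre_end < self.post_start):
            raise ValidationError("pre period must end before post period starts")

    def split(self, series: CatchmentSeries) -> tuple[CatchmentSeries, CatchmentSeries]:
        """Return (pre, post) sub-series; each must contain >= 3 years."""
        pre = series.period(self.pre_start, self.pre_end)
        post = series.period(self.post_start, self.post_end)
        if len(pre) < 3:
            raise DataError(f"pre period has only {len(pre)} years (< 3)")
        if len(post) < 3:
            raise DataError(f"post period has only {len(post)} years (< 3)")
        return pre, post

    def to_dict(self) -> dict:
        return {
            "pre_start": self.pre_start,
            "pre_end": self.pre_end,
            "post_start": self.post_start,
            "post_end": self.post_end,
        }
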