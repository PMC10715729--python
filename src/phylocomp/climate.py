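"""Brumation-period estimation from daily temperatures, plus climate summaries.

A species' brumation (cold-season dormancy) period in a calendar year is
defined operationally from its experimentally determined activity
threshold: the active period starts on the first day of the first run of at
least `persistence` consecutive days with mean temperature above the
emergence threshold, and ends on the last day before the terminal run of
days below the entry threshold that lasts to the end of the year.
Brumation days = days in the year minus the active-period length.

Days exactly at the threshold count as inactive ("below"); this is
configurable via `at_threshold`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureSeries",
    "ActivityThresholds",
    "BrumationEstimate",
    "annual_brumation_days",
    "buffered_days",
    "estimate_brumation",
    "classify_brumation",
    "climate_cv",
    "dry_season_p2t",
]

NON_BRUMATING_MAX_DAYS = 27  # species at or below this are "non-brumating"


@dataclass
class TemperatureSeries:
    """Daily mean temperatures (deg C) at one site."""

    site_id: str
    dates: np.ndarray  # datetime64[D]
    temps: np.ndarray

    def __post_init__(self) -> None:
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        self.temps = np.asarray(self.temps, dtype=float)
        if self.dates.size != self.temps.size:
            raise ValueError("dates and temps differ in length")
        if self.dates.size > 1 and not np.all(np.diff(self.dates).astype(int) > 0):
            raise ValueError("dates must be strictly increasing")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, site_id: str | None = None) -> "TemperatureSeries":
        """Build from a `site,date,temp_c` table (one site)."""
        if site_id is not None:
            df = df[df["site"] == site_id]
        elif "site" in df.columns:
            sites = df["site"].unique()
            if len(sites) != 1:
                raise ValueError(f"multiple sites present: {list(sites)}")
            site_id = sites[0]
        df = df.sort_values("date")
        return cls(
            site_id=str(site_id),
            dates=pd.to_datetime(df["date"]).to_numpy().astype("datetime64[D]"),
            temps=df["temp_c"].to_numpy(dtype=float),
        )

    def year_slice(self, year: int) -> np.ndarray:
        """Temperatures for every day of `year`; errors list any gaps."""
        start = np.datetime64(f"{year}-01-01", "D")
        stop = np.datetime64(f"{year + 1}-01-01", "D")
        expected = np.arange(start, stop)
        mask = (self.dates >= start) & (self.dates < stop)
        have = self.dates[mask]
        missing = np.setdiff1d(expected, have)
        if missing.size:
            head = ", ".join(str(d) for d in missing[:5])
            more = f" (+{missing.size - 5} more)" if missing.size > 5 else ""
            raise ValueError(f"missing days in {year}: {head}{more}")
        order = np.argsort(have)
        return self.temps[mask][order]


@dataclass
class ActivityThresholds:
    """Experimentally determined activity thresholds for one species.

    The emergence temperature opens the active period in spring; the entry
    temperature closes it in autumn.  When only one threshold was measured,
    pass it as `entry_c` and emergence defaults to it.
    """

    species: str
    entry_c: float
    emergence_c: float | None = None
    buffer: float = 0.0

    def __post_init__(self) -> None:
        if self.emergence_c is None:
            self.emergence_c = self.entry_c
        if self.buffer not in (0, 2, 4):
            raise ValueError(f"buffer must be 0, 2 or 4 deg C, got {self.buffer}")


@dataclass
class BrumationEstimate:
    species: str
    per_year_days: dict[int, int]
    mean_days: float = field(init=False)
    status: str = field(init=False)

    def __post_init__(self) -> None:
        self.mean_days = float(np.mean(list(self.per_year_days.values())))
        self.status = classify_brumation(self.mean_days)


def _runs_above(active: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) half-open index pairs."""
    padded = np.concatenate(([False], active, [False])).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def annual_brumation_days(
    series: TemperatureSeries,
    thr: ActivityThresholds,
    year: int,
    persistence: int = 5,
    at_threshold: str = "inactive",
) -> int:
    """Days of brumation in one calendar year under the run rules.

    Returns the full year length when no qualifying active run exists.
    """
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    if at_threshold not in ("inactive", "active"):
        raise ValueError("at_threshold must be 'inactive' or 'active'")
    temps = series.year_slice(year)
    ndays = temps.size
    emerge = thr.emergence_c - thr.buffer
    entry = thr.entry_c - thr.buffer
    if at_threshold == "inactive":
        above_emerge = temps > emerge
        below_entry = temps <= entry
    else:
        above_emerge = temps >= emerge
        below_entry = temps < entry
    start = None
    for s, e in _runs_above(above_emerge):
        if e - s >= persistence:
            start = s
            break
    if start is None:
        return ndays
    # terminal run below the entry threshold reaching the year end
    end = ndays - 1
    while end >= 0 and below_entry[end]:
        end -= 1
    if end < start:
        return ndays
    active = end - start + 1
    return ndays - active


def buffered_days(
    series: TemperatureSeries,
    thr: ActivityThresholds,
    year: int,
    buffer: float,
    persistence: int = 5,
) -> int:
    """Brumation days with thresholds lowered by a 2 or 4 deg C buffer,
    emulating thermal buffering of the ground microclimate."""
    if buffer not in (2, 4):
        raise ValueError("buffer must be 2 or 4")
    shifted = ActivityThresholds(
        thr.species, thr.entry_c, thr.emergence_c, buffer=buffer
    )
    return annual_brumation_days(series, shifted, year, persistence=persistence)


def estimate_brumation(
    series: TemperatureSeries,
    thr: ActivityThresholds,
    years: list[int],
    persistence: int = 5,
) -> BrumationEstimate:
    """Species-level estimate: arithmetic mean of per-year brumation days."""
    per_year = {
        y: annual_brumation_days(series, thr, y, persistence=persistence)
        for y in years
    }
    return BrumationEstimate(thr.species, per_year)


def classify_brumation(mean_days: float) -> str:
    """Species with <= 27 mean days below threshold are unlikely to show
    sustained brumation and are classified non-brumating."""
    return "non-brumating" if mean_days <= NON_BRUMATING_MAX_DAYS else "brumating"


def climate_cv(values) -> float:
    """Coefficient of variation: sample SD / mean of monthly values."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for a CV")
    m = v.mean()
    if m <= 0:
        warnings.warn(
            "mean <= 0: CV of a Celsius series crossing zero is ill-defined",
            stacklevel=2,
        )
    return float(v.std(ddof=1) / m)


def dry_season_p2t(monthly_precip, monthly_temp) -> int:
    """Months in which total precipitation (mm) < 2 x mean temperature (C)."""
    p = np.asarray(monthly_precip, dtype=float)
    t = np.asarray(monthly_temp, dtype=float)
    if p.size != 12 or t.size != 12:
        raise ValueError("need 12 monthly values of precipitation and temperature")
    return int(np.sum(p < 2.0 * t))
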