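"""Exposure schedules: per-day (concentration, duration) records.

Airborne exposure is scored as a time-concentration product: the gas-phase
concentration in ppm multiplied by the exposure duration in hours, summed
over days, giving a cumulative dose in ppm·h.  A schedule is the ground
truth against which simulated patches are generated and estimates scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

CSV_COLUMNS = ("day", "concentration_ppm", "duration_h")


@dataclass(frozen=True)
class ExposureRecord:
    """A single day of exposure: `concentration_ppm` for `duration_h` hours."""

    day: int
    concentration_ppm: float
    duration_h: float

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValueError(f"day index must be >= 1, got {self.day}")
        if self.concentration_ppm < 0:
            raise ValueError(
                f"concentration must be >= 0 ppm, got {self.concentration_ppm}"
            )
        if self.duration_h < 0:
            raise ValueError(f"duration must be >= 0 h, got {self.duration_h}")

    @property
    def dose(self) -> float:
        """Daily dose contribution, ppm·h."""
        return self.concentration_ppm * self.duration_h


@dataclass(frozen=True)
class ExposureSchedule:
    """An ordered sequence of daily exposure records.

    Day indices must be strictly increasing (missing days mean no exposure).
    Cumulative dose over any prefix is non-negative and non-decreasing.
    """

    records: tuple[ExposureRecord, ...]

    def __post_init__(self) -> None:
        days = [r.day for r in self.records]
        for a, b in zip(days, days[1:]):
            if b <= a:
                raise ValueError(
                    f"day indices must be strictly increasing, got {a} then {b}"
                )

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[int, float, float]]
    ) -> "ExposureSchedule":
        return cls(tuple(ExposureRecord(*r) for r in records))

    @classmethod
    def constant(
        cls, concentration_ppm: float, n_days: int, hours_per_day: float = 8.0
    ) -> "ExposureSchedule":
        """The standard trial pattern: a fixed concentration for a fixed
        number of hours on each of ``n_days`` consecutive days."""
        return cls.from_records(
            (d, concentration_ppm, hours_per_day) for d in range(1, n_days + 1)
        )

    @property
    def last_day(self) -> int:
        return self.records[-1].day if self.records else 0

    def cumulative_dose(self, upto_day: int | None = None) -> float:
        """Total dose in ppm·h over all records with day <= ``upto_day``."""
        return sum(
            r.dose for r in self.records if upto_day is None or r.day <= upto_day
        )

    def cumulative_hours(self, upto_day: int | None = None) -> float:
        return sum(
            r.duration_h
            for r in self.records
            if upto_day is None or r.day <= upto_day
        )

    def concentrations(self) -> Sequence[float]:
        return [r.concentration_ppm for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.day, r.concentration_ppm, r.duration_h) for r in self.records],
            columns=list(CSV_COLUMNS),
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExposureSchedule":
        df = pd.read_csv(path)
        missing = set(CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"schedule CSV missing columns: {sorted(missing)}")
        return cls.from_records(
            (int(r.day), float(r.concentration_ppm), float(r.duration_h))
            for r in df.itertuples()
        )
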