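"""Reading locomotor time-series tables and experiment-design configurations.

A photolocomotor behavioral response (PBR) experiment records one swim-speed
value per subject per minute while the lighting alternates between light and
dark periods.  This module holds the two objects everything downstream
consumes: the validated raw table of per-subject series (:class:`RawSeriesTable`)
and the experiment design (:class:`ExperimentDesign`) that defines the time
domain, the optional acclimation window and the light/dark period layout from
which analysis regions are derived.

Balanced designs are required throughout (equal group sizes, one shared time
grid); unbalanced input is rejected at load time rather than silently
reweighted, because the downstream sums-of-squares formulas assume n_i = n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RawSeriesTable",
    "Region",
    "Period",
    "ExperimentDesign",
    "read_series",
    "write_series",
    "load_design",
    "DataFormatError",
    "BalanceError",
    "DesignError",
]


class DataFormatError(ValueError):
    """A required column or key is missing or malformed."""


class BalanceError(ValueError):
    """The data violate the balanced-design requirements."""


class DesignError(ValueError):
    """The experiment design is internally inconsistent."""


@dataclass(frozen=True)
class Region:
    """Half-open analysis window [start, end) in minutes."""

    name: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise DesignError(
                f"region {self.name!r} is empty: [{self.start}, {self.end})"
            )

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class Period:
    """One lighting period with its condition."""

    start: float
    end: float
    condition: Literal["light", "dark"]


@dataclass
class RawSeriesTable:
    """Long-format per-subject locomotor series on a shared time grid.

    Attributes
    ----------
    data
        DataFrame with columns ``subject``, ``group``, ``time``, ``value``,
        sorted by subject then time.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        df = self.data
        for col in ("subject", "group", "time", "value"):
            if col not in df.columns:
                raise DataFormatError(f"missing required column {col!r}")
        dup = df.duplicated(subset=["subject", "time"])
        if dup.any():
            pairs = df.loc[dup, ["subject", "time"]].head(5).to_dict("records")
            raise DataFormatError(f"duplicated (subject, time) pairs, e.g. {pairs}")
        ngroups = df.groupby("subject", observed=True)["group"].nunique()
        multi = ngroups[ngroups > 1]
        if len(multi):
            raise BalanceError(
                f"subjects assigned to more than one group: {list(multi.index)}"
            )
        grids = df.groupby("subject", observed=True)["time"].apply(
            lambda s: tuple(np.sort(s.to_numpy()))
        )
        if any(len(g) < 2 for g in grids):
            bad = [s for s, g in grids.items() if len(g) < 2]
            raise BalanceError(f"subjects with fewer than 2 time points: {bad}")
        ref = grids.iloc[0]
        off = [s for s, g in grids.items() if g != ref]
        if off:
            raise BalanceError(f"subjects not on the shared time grid: {off}")
        self.data = df.sort_values(["subject", "time"], kind="stable").reset_index(
            drop=True
        )

    @property
    def subjects(self) -> list:
        return list(dict.fromkeys(self.data["subject"]))

    @property
    def grid(self) -> np.ndarray:
        """The shared observation times, ascending."""
        first = self.subjects[0]
        return np.sort(
            self.data.loc[self.data["subject"] == first, "time"].to_numpy(float)
        )

    @property
    def groups(self) -> pd.Series:
        """Group label per subject, indexed by subject id."""
        return self.data.groupby("subject", observed=True, sort=False)["group"].first()

    def to_matrix(self) -> tuple[np.ndarray, np.ndarray, list]:
        """Return (values: subjects x times, group labels, subject ids)."""
        wide = self.data.pivot(index="subject", columns="time", values="value")
        wide = wide.loc[self.subjects, np.sort(wide.columns)]
        labels = self.groups.loc[wide.index].to_numpy()
        return wide.to_numpy(float), labels, list(wide.index)


@dataclass
class ExperimentDesign:
    """Domain, acclimation window and light/dark period layout of an assay.

    Regions are derived automatically: one per period (named L1, D1, ... by
    condition and occurrence order) plus the full non-acclimation window
    (named e.g. ``L1-D2``).  All intervals are half-open ``[start, end)``.
    """

    domain: tuple[float, float]
    periods: list[Period]
    acclimation: tuple[float, float] | None = None
    regions: dict[str, Region] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if not hi > lo:
            raise DesignError(f"empty domain [{lo}, {hi}]")
        if not self.periods:
            raise DesignError("at least one period is required")
        pts = sorted(self.periods, key=lambda p: p.start)
        start = self.acclimation[1] if self.acclimation else lo
        if self.acclimation:
            a0, a1 = self.acclimation
            if not (a0 == lo and a1 > a0):
                raise DesignError(
                    "acclimation must begin at the domain start and precede analysis"
                )
        cursor = start
        for p in pts:
            if not np.isclose(p.start, cursor):
                raise DesignError(
                    f"periods must tile the domain contiguously; gap or overlap at t={p.start}"
                )
            if p.condition not in ("light", "dark"):
                raise DesignError(f"unknown condition {p.condition!r}")
            cursor = p.end
        if cursor > hi + 1e-9:
            raise DesignError("periods extend past the domain")
        self.periods = pts
        self.regions = self._derive_regions()

    def _derive_regions(self) -> dict[str, Region]:
        regions: dict[str, Region] = {}
        counts = {"light": 0, "dark": 0}
        names = []
        for p in self.periods:
            counts[p.condition] += 1
            name = f"{'L' if p.condition == 'light' else 'D'}{counts[p.condition]}"
            regions[name] = Region(name, p.start, p.end)
            names.append(name)
        full_name = f"{names[0]}-{names[-1]}" if len(names) > 1 else "full"
        regions[full_name] = Region(full_name, self.periods[0].start, self.periods[-1].end)
        return regions

    @property
    def full_region(self) -> Region:
        """The union of all non-acclimation periods."""
        key = [k for k in self.regions if "-" in k or k == "full"][0]
        return self.regions[key]


def read_series(path: str | Path, dialect: Literal["long", "wide"] = "long") -> RawSeriesTable:
    """Read a locomotor series table from CSV.

    Long dialect: columns ``subject,group,time,value``.  Wide dialect: one row
    per subject with columns ``subject,group,t<minutes>,...``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if dialect == "long":
        return RawSeriesTable(df)
    if dialect == "wide":
        for col in ("subject", "group"):
            if col not in df.columns:
                raise DataFormatError(f"missing required column {col!r}")
        tcols = [c for c in df.columns if c not in ("subject", "group")]
        if not tcols:
            raise DataFormatError("wide file has no time columns")
        try:
            times = {c: float(c.lstrip("t")) for c in tcols}
        except ValueError as exc:
            raise DataFormatError(f"unparseable time column among {tcols}") from exc
        long = df.melt(
            id_vars=["subject", "group"], value_vars=tcols,
            var_name="time", value_name="value",
        )
        long["time"] = long["time"].map(times)
        return RawSeriesTable(long)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_series(table: RawSeriesTable, path: str | Path) -> None:
    """Write a table in the long CSV dialect."""
    table.data.to_csv(path, index=False)


def load_design(path: str | Path) -> ExperimentDesign:
    """Load an experiment design from a YAML/JSON config file.

    Expected keys: ``domain: [lo, hi]``, optional ``acclimation: [lo, hi]``,
    ``periods: [{start, end, condition}, ...]``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    for key in ("domain", "periods"):
        if key not in cfg:
            raise DataFormatError(f"design config missing key {key!r}")
    periods = [
        Period(float(p["start"]), float(p["end"]), p["condition"])
        for p in cfg["periods"]
    ]
    accl = tuple(map(float, cfg["acclimation"])) if cfg.get("acclimation") else None
    return ExperimentDesign(
        domain=tuple(map(float, cfg["domain"])), periods=periods, acclimation=accl
    )
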