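"""Tabular plate-reader / cytometry I/O.

Three long-format CSV dialects are consumed (UTF-8, "." decimal separator):

* ``timeseries.csv`` — columns ``well,time_h,od600``; one row per OD600
  reading, times in decimal hours.
* ``layout.csv`` — columns ``well,kind,strain_a,strain_b,species_a,
  species_b,replicate,run``; maps each well to its culture descriptor.
* ``cytometry.csv`` — columns ``culture_id,timepoint,gate,events``; already
  gated event counts per fluorescence gate at T0 and T24.

Lines starting with ``#`` are treated as comments (the pipeline embeds its
configuration hash that way).  No blank/background correction is applied at
read time; an optional constant offset is handled downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

log = logging.getLogger(__name__)

TIMEPOINTS = ("T0", "T24")
KINDS = ("monoculture", "coculture")


@dataclass(frozen=True)
class GrowthCurve:
    """One well's OD600 time series (times in hours, strictly increasing)."""

    culture_id: str
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "od", od)
        if times.ndim != 1 or od.ndim != 1 or len(times) != len(od):
            raise InputError(f"curve {self.culture_id!r}: times and od must be 1-D and equal length")
        if len(times) < 4:
            raise InputError(f"curve {self.culture_id!r}: need at least 4 timepoints, got {len(times)}")
        if not np.all(np.diff(times) > 0):
            raise InputError(f"curve {self.culture_id!r}: times must be strictly increasing")
        if not np.all(np.isfinite(od)) or np.any(od < 0):
            raise InputError(f"curve {self.culture_id!r}: OD readings must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class CultureDescriptor:
    """What was inoculated in one well."""

    culture_id: str
    kind: str
    strain_a: str
    strain_b: str
    species_a: str
    species_b: str
    replicate: int
    run: str

    def __post_init__(self):
        if self.kind not in KINDS:
            raise InputError(f"well {self.culture_id!r}: unknown kind {self.kind!r}")
        if self.kind == "monoculture" and self.strain_a != self.strain_b:
            raise InputError(
                f"well {self.culture_id!r}: monoculture with two different strains "
                f"({self.strain_a!r}, {self.strain_b!r})"
            )
        if self.kind == "coculture" and self.strain_a == self.strain_b:
            raise InputError(f"well {self.culture_id!r}: coculture with identical strains {self.strain_a!r}")
        if self.replicate < 1:
            raise InputError(f"well {self.culture_id!r}: replicate must be a positive integer")

    @property
    def strain_pair(self) -> tuple[str, str]:
        return tuple(sorted((self.strain_a, self.strain_b)))


@dataclass
class PlateLayout:
    """Mapping from well/culture id to :class:`CultureDescriptor`."""

    wells: dict[str, CultureDescriptor] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.wells)

    def __getitem__(self, well: str) -> CultureDescriptor:
        return self.wells[well]

    def __iter__(self):
        return iter(self.wells.values())

    def strains(self) -> list[str]:
        out: set[str] = set()
        for d in self:
            out.update((d.strain_a, d.strain_b))
        return sorted(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    well=d.culture_id, kind=d.kind, strain_a=d.strain_a, strain_b=d.strain_b,
                    species_a=d.species_a, species_b=d.species_b, replicate=d.replicate, run=d.run,
                )
                for d in self
            ]
        )


@dataclass(frozen=True)
class CytometrySample:
    """Gated event counts for one culture at one timepoint."""

    culture_id: str
    timepoint: str
    counts: Mapping[str, int]

    def __post_init__(self):
        if self.timepoint not in TIMEPOINTS:
            raise InputError(f"sample {self.culture_id!r}: timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}")
        for gate, n in self.counts.items():
            if n < 0 or int(n) != n:
                raise InputError(f"sample {self.culture_id!r}: negative/non-integer event count for gate {gate!r}")
        if self.total_events <= 0:
            raise InputError(f"sample {self.culture_id!r}: zero total events")

    @property
    def total_events(self) -> int:
        return int(sum(self.counts.values()))


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise InputError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    return df


def read_timeseries(path) -> list[GrowthCurve]:
    """Read a long-format OD600 time-series CSV into one curve per well."""
    df = _read_csv(path, ["well", "time_h", "od600"])
    for col in ("time_h", "od600"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.loc[vals.isna(), "well"].iloc[0]
            raise InputError(f"{path}: non-numeric {col} value in well {bad!r}")
        df[col] = vals
    dup = df.duplicated(subset=["well", "time_h"])
    if dup.any():
        bad = df.loc[dup, "well"].iloc[0]
        raise InputError(f"{path}: duplicated (well, time) row for well {bad!r}")
    curves = []
    for well, grp in df.groupby("well", sort=True):
        grp = grp.sort_values("time_h")
        curves.append(GrowthCurve(str(well), grp["time_h"].to_numpy(), grp["od600"].to_numpy()))
    return curves


def read_layout(path) -> PlateLayout:
    """Read and validate a plate-layout CSV."""
    df = _read_csv(path, ["well", "kind", "strain_a", "strain_b", "species_a", "species_b", "replicate", "run"])
    layout = PlateLayout()
    for _, row in df.iterrows():
        well = str(row["well"])
        if well in layout.wells:
            raise InputError(f"{path}: duplicate well id {well!r}")
        layout.wells[well] = CultureDescriptor(
            culture_id=well,
            kind=str(row["kind"]),
            strain_a=str(row["strain_a"]),
            strain_b=str(row["strain_b"]),
            species_a=str(row["species_a"]),
            species_b=str(row["species_b"]),
            replicate=int(row["replicate"]),
            run=str(row["run"]),
        )
    return layout


def read_cytometry(path) -> list[CytometrySample]:
    """Read gated cytometry counts, one sample per (culture_id, timepoint)."""
    df = _read_csv(path, ["culture_id", "timepoint", "gate", "events"])
    events = pd.to_numeric(df["events"], errors="coerce")
    if events.isna().any():
        raise InputError(f"{path}: non-numeric event count")
    df["events"] = events.astype(int)
    samples = []
    for (cid, tp), grp in df.groupby(["culture_id", "timepoint"], sort=True):
        counts = dict(zip(grp["gate"].astype(str), grp["events"].astype(int)))
        samples.append(CytometrySample(str(cid), str(tp), counts))
    return samples


def join(curves: Iterable[GrowthCurve], layout: PlateLayout) -> list[tuple[CultureDescriptor, GrowthCurve]]:
    """1:1 join of curves to layout descriptors.

    Layout wells with no curve are an error; curves with no layout entry are
    logged and dropped.
    """
    by_id = {c.culture_id: c for c in curves}
    missing = [w for w in layout.wells if w not in by_id]
    if missing:
        raise InputError(f"layout wells without a growth curve: {missing[:10]}{'...' if len(missing) > 10 else ''}")
    unmatched = sorted(set(by_id) - set(layout.wells))
    if unmatched:
        log.info("%d curves have no layout entry and are ignored: %s", len(unmatched), unmatched[:10])
    return [(layout[w], by_id[w]) for w in layout.wells]


def write_timeseries(curves: Iterable[GrowthCurve], path, header: str | None = None) -> None:
    rows = [
        {"well": c.culture_id, "time_h": t, "od600": od}
        for c in curves
        for t, od in zip(c.times, c.od)
    ]
    _write_frame(pd.DataFrame(rows, columns=["well", "time_h", "od600"]), path, header)


def write_layout(layout: PlateLayout, path, header: str | None = None) -> None:
    _write_frame(layout.to_frame(), path, header)


def write_cytometry(samples: Iterable[CytometrySample], path, header: str | None = None) -> None:
    rows = [
        {"culture_id": s.culture_id, "timepoint": s.timepoint, "gate": g, "events": n}
        for s in samples
        for g, n in s.counts.items()
    ]
    _write_frame(pd.DataFrame(rows, columns=["culture_id", "timepoint", "gate", "events"]), path, header)


def _write_frame(df: pd.DataFrame, path, header: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.12g")
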