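"""Time-series containers and their delimited-text representations.

The central container is :class:`AbundanceSeries`, a species-by-time matrix of
non-negative abundances on an explicit, strictly increasing time grid.  Field
data arrive as catch-per-unit-effort from several fishing gears
(:class:`GearCatchTable`); synthetic data come straight from the simulator.
All matrices are species-major and carry an explicit species-order manifest so
rows are never silently permuted between pipeline stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A table violated the declared layout (duplicate species, bad cells...)."""


def _validate_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if times.size >= 2 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    if not np.all(np.isfinite(times)):
        raise ValueError("times must be finite")
    return times


@dataclass(frozen=True)
class AbundanceSeries:
    """Species x time matrix of non-negative abundances.

    Parameters
    ----------
    species_ids : sequence of str
        Row labels, unique and ordered.
    times : array-like of float
        Strictly increasing observation times (calendar years for field data,
        abstract units for synthetic data).
    values : ndarray of shape (n_species, n_times)
        Non-negative abundances (relative-abundance units for standardized
        field data, arbitrary units otherwise).
    site_label : str, optional
    """

    species_ids: tuple[str, ...]
    times: np.ndarray
    values: np.ndarray
    site_label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "species_ids", tuple(str(s) for s in self.species_ids))
        times = _validate_times(self.times)
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, m = values.shape
        if n != len(self.species_ids):
            raise ValueError(
                f"values has {n} rows but {len(self.species_ids)} species ids"
            )
        if m != times.size:
            raise ValueError(f"values has {m} columns but {times.size} time points")
        if len(set(self.species_ids)) != n:
            dupes = sorted({s for s in self.species_ids if self.species_ids.count(s) > 1})
            raise SchemaError(f"duplicate species ids: {dupes}")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        if np.any(values < 0):
            raise ValueError("abundances must be non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_times(self) -> int:
        return self.times.size

    def with_values(self, values: np.ndarray) -> "AbundanceSeries":
        return replace(self, values=np.asarray(values, dtype=float))

    def subset_times(self, keep: np.ndarray) -> "AbundanceSeries":
        """Return the series restricted to a boolean/index mask over time."""
        keep = np.asarray(keep)
        return replace(self, times=self.times[keep], values=self.values[:, keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.species_ids), columns=self.times)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, site_label: str | None = None) -> "AbundanceSeries":
        return cls(
            species_ids=tuple(str(i) for i in frame.index),
            times=np.asarray(frame.columns, dtype=float),
            values=frame.to_numpy(dtype=float),
            site_label=site_label,
        )


@dataclass(frozen=True)
class ExogenousSeries:
    """Abundance of an external perturbing species (e.g. an invader).

    Evaluated between samples by monotone piecewise-cubic interpolation and by
    constant extrapolation outside the observed window.
    """

    times: np.ndarray
    values: np.ndarray
    interpolation_rule: str = "pchip"

    def __post_init__(self) -> None:
        times = _validate_times(self.times)
        values = np.asarray(self.values, dtype=float)
        if values.shape != times.shape:
            raise ValueError("values and times must have the same length")
        if np.any(values < 0):
            raise ValueError("exogenous abundances must be non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def interpolator(self):
        """Return a callable t -> abundance honouring the declared rule."""
        from scipy.interpolate import PchipInterpolator

        if self.times.size == 1:
            v = float(self.values[0])
            return lambda t: np.full_like(np.asarray(t, dtype=float), v)
        if self.interpolation_rule != "pchip":
            raise ValueError(f"unknown interpolation rule {self.interpolation_rule!r}")
        inner = PchipInterpolator(self.times, self.values, extrapolate=False)
        lo, hi = self.values[0], self.values[-1]
        t0, t1 = self.times[0], self.times[-1]

        def evaluate(t):
            t = np.asarray(t, dtype=float)
            out = inner(t)
            out = np.where(t < t0, lo, out)
            out = np.where(t > t1, hi, out)
            return out

        return evaluate


@dataclass(frozen=True)
class GearCatchTable:
    """Raw catch-per-unit-effort counts, one species x time matrix per gear."""

    gear_ids: tuple[str, ...]
    species_ids: tuple[str, ...]
    times: np.ndarray
    counts: Mapping[str, np.ndarray] = field(default_factory=dict)
    site_label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "gear_ids", tuple(self.gear_ids))
        object.__setattr__(self, "species_ids", tuple(str(s) for s in self.species_ids))
        times = _validate_times(self.times)
        counts = {}
        for gear in self.gear_ids:
            if gear not in self.counts:
                raise ValueError(f"missing counts for gear {gear!r}")
            mat = np.asarray(self.counts[gear], dtype=float)
            if mat.shape != (len(self.species_ids), times.size):
                raise ValueError(
                    f"gear {gear!r}: counts shape {mat.shape} does not match "
                    f"({len(self.species_ids)}, {times.size})"
                )
            if np.any(mat < 0) or not np.all(np.isfinite(mat)):
                raise ValueError(f"gear {gear!r}: counts must be finite and >= 0")
            counts[gear] = mat
        object.__setattr__(self, "counts", counts)


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def write_abundance_table(series: AbundanceSeries, path: str | Path, sep: str = "\t") -> None:
    """Write an :class:`AbundanceSeries` as wide delimited text.

    First column holds species ids; header row holds the time points.
    """
    frame = series.to_frame()
    frame.index.name = "species"
    frame.to_csv(path, sep=sep)


def read_abundance_table(
    path: str | Path,
    dialect: str = "wide",
    sep: str = "\t",
    site_label: str | None = None,
) -> AbundanceSeries | GearCatchTable:
    """Read a delimited abundance table.

    ``dialect='wide'`` expects species x time (first column species id, header
    row of time points) and returns an :class:`AbundanceSeries`.
    ``dialect='long'`` expects columns (site, gear, species, year, cpue) and
    returns a :class:`GearCatchTable`.
    Schema violations raise :class:`SchemaError` with coordinates.
    """
    path = Path(path)
    if dialect == "wide":
        frame = pd.read_csv(path, sep=sep, index_col=0)
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        if dupes:
            raise SchemaError(f"{path}: duplicated species rows: {dupes}")
        try:
            times = frame.columns.astype(float)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: non-numeric time header: {list(frame.columns)}") from exc
        for col in frame.columns:
            bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()].tolist()
            if bad:
                raise SchemaError(f"{path}: non-numeric cells at column {col!r}, rows {bad}")
        return AbundanceSeries(
            species_ids=tuple(str(i) for i in frame.index),
            times=np.asarray(times, dtype=float),
            values=frame.to_numpy(dtype=float),
            site_label=site_label,
        )
    if dialect == "long":
        frame = pd.read_csv(path, sep=sep)
        required = {"gear", "species", "year", "cpue"}
        missing = required - set(frame.columns)
        if missing:
            raise SchemaError(f"{path}: long format missing columns {sorted(missing)}")
        if site_label is not None and "site" in frame.columns:
            frame = frame[frame["site"] == site_label]
        dup = frame.duplicated(subset=["gear", "species", "year"])
        if dup.any():
            rows = frame.loc[dup, ["gear", "species", "year"]].to_dict("records")
            raise SchemaError(f"{path}: duplicated (gear, species, year) entries: {rows}")
        species = tuple(sorted(frame["species"].astype(str).unique()))
        years = np.asarray(sorted(frame["year"].unique()), dtype=float)
        gears = tuple(sorted(frame["gear"].astype(str).unique()))
        counts = {}
        for gear in gears:
            sub = frame[frame["gear"].astype(str) == gear]
            mat = (
                sub.pivot_table(index="species", columns="year", values="cpue", fill_value=0.0)
                .reindex(index=list(species), columns=list(years), fill_value=0.0)
                .to_numpy(dtype=float)
            )
            counts[gear] = mat
        return GearCatchTable(
            gear_ids=gears, species_ids=species, times=years, counts=counts,
            site_label=site_label,
        )
    raise ValueError(f"unknown dialect {dialect!r}")
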