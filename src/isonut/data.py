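"""Core data objects and delimited-text I/O.

The exchange object between every pipeline stage is :class:`IsotopeDataset`:
a flat table of samples with a geographical-origin label, a harvest year and
eight isotope markers (all in per-mil, ‰):

* ``d18O_bulk`` — bulk oxygen-18 of the homogenised kernel,
* ``d13C_16_0 .. d13C_18_2`` — carbon-13 of the palmitic, stearic, oleic and
  linoleic fatty acid methyl esters,
* ``d2H_16_0, d2H_18_1, d2H_18_2`` — deuterium of the palmitic, oleic and
  linoleic esters.

Missing marker values are rejected on read: the modelling stages assume a
complete matrix and no imputation is offered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical marker schema, fixed across the whole pipeline.
MARKER_NAMES: tuple[str, ...] = (
    "d18O_bulk",
    "d13C_16_0",
    "d13C_18_0",
    "d13C_18_1",
    "d13C_18_2",
    "d2H_16_0",
    "d2H_18_1",
    "d2H_18_2",
)

#: Label used for samples rejected by every per-class decision threshold.
NO_CLASS = "NO_CLASS"

_META_COLUMNS = ("sample_id", "origin", "harvest_year")


class SchemaError(ValueError):
    """A required column is absent from an input file."""


class ParseError(ValueError):
    """A cell could not be parsed (non-numeric or empty marker value)."""


@dataclass(frozen=True)
class IsotopeSample:
    """One hazelnut sample: identity, origin, harvest year, 8 marker values."""

    sample_id: str
    origin: str
    harvest_year: int
    markers: np.ndarray  # shape (8,), order = MARKER_NAMES

    def __post_init__(self) -> None:
        m = np.asarray(self.markers, dtype=float)
        if m.shape != (len(MARKER_NAMES),):
            raise ValueError(
                f"sample {self.sample_id!r}: expected {len(MARKER_NAMES)} "
                f"marker values, got shape {m.shape}"
            )
        if not np.all(np.isfinite(m)):
            raise ValueError(f"sample {self.sample_id!r}: non-finite marker value")
        object.__setattr__(self, "markers", m)


@dataclass
class IsotopeDataset:
    """An ordered collection of samples sharing the canonical marker schema.

    Internally column-major: parallel arrays for ids, origins, years and an
    ``(n, 8)`` marker matrix ``X``.  Row order is meaningful (file order /
    generation order) and preserved by all transformations.
    """

    sample_ids: np.ndarray  # (n,) object
    origins: np.ndarray  # (n,) object
    harvest_years: np.ndarray  # (n,) int
    X: np.ndarray  # (n, 8) float
    marker_names: tuple[str, ...] = field(default=MARKER_NAMES)

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.origins = np.asarray(self.origins, dtype=object)
        self.harvest_years = np.asarray(self.harvest_years, dtype=int)
        self.X = np.asarray(self.X, dtype=float)
        n = len(self.sample_ids)
        if not (len(self.origins) == len(self.harvest_years) == self.X.shape[0] == n):
            raise ValueError("inconsistent column lengths")
        if self.X.shape[1] != len(self.marker_names):
            raise ValueError(
                f"marker matrix has {self.X.shape[1]} columns, "
                f"schema has {len(self.marker_names)}"
            )
        if n and not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite marker values in dataset")
        ids = set()
        for sid in self.sample_ids:
            if sid in ids:
                raise ValueError(f"duplicate sample_id {sid!r}")
            ids.add(sid)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.sample_ids)

    def __iter__(self) -> Iterable[IsotopeSample]:
        for i in range(len(self)):
            yield IsotopeSample(
                str(self.sample_ids[i]),
                str(self.origins[i]),
                int(self.harvest_years[i]),
                self.X[i].copy(),
            )

    @property
    def n_samples(self) -> int:
        return len(self)

    @property
    def class_labels(self) -> tuple[str, ...]:
        """Distinct origin labels, sorted for a stable class order."""
        return tuple(sorted({str(o) for o in self.origins}))

    def subset(self, indices: Sequence[int] | np.ndarray) -> "IsotopeDataset":
        idx = np.asarray(indices, dtype=int)
        return IsotopeDataset(
            self.sample_ids[idx],
            self.origins[idx],
            self.harvest_years[idx],
            self.X[idx],
            self.marker_names,
        )

    @classmethod
    def from_samples(cls, samples: Sequence[IsotopeSample]) -> "IsotopeDataset":
        return cls(
            np.array([s.sample_id for s in samples], dtype=object),
            np.array([s.origin for s in samples], dtype=object),
            np.array([s.harvest_year for s in samples], dtype=int),
            np.vstack([s.markers for s in samples])
            if samples
            else np.empty((0, len(MARKER_NAMES))),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "origin": self.origins,
                "harvest_year": self.harvest_years,
            }
        )
        for j, name in enumerate(self.marker_names):
            df[name] = self.X[:, j] if len(self) else np.array([], dtype=float)
        return df


def read_dataset(
    path, schema: Sequence[str] = MARKER_NAMES
) -> IsotopeDataset:
    """Read an IsotopeDataset from a comma-separated UTF-8 file.

    The header must contain ``sample_id``, ``origin``, ``harvest_year`` and
    every marker in *schema*, in any column order.  Surplus columns are
    ignored with a logged warning.  Non-numeric or empty marker cells raise
    :class:`ParseError` naming the offending row (1-based, excluding the
    header) and column.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = list(_META_COLUMNS) + list(schema)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    surplus = [c for c in df.columns if c not in required]
    if surplus:
        logger.warning("ignoring surplus columns: %s", ", ".join(surplus))

    n = len(df)
    X = np.empty((n, len(schema)))
    for j, name in enumerate(schema):
        for i, cell in enumerate(df[name].to_numpy()):
            try:
                val = float(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"row {i + 1}, column {name!r}: cannot parse {cell!r}"
                ) from None
            if not np.isfinite(val):
                raise ParseError(f"row {i + 1}, column {name!r}: non-finite value")
            X[i, j] = val
    years = np.empty(n, dtype=int)
    for i, cell in enumerate(df["harvest_year"].to_numpy()):
        try:
            years[i] = int(cell)
        except (TypeError, ValueError):
            raise ParseError(
                f"row {i + 1}, column 'harvest_year': cannot parse {cell!r}"
            ) from None
    return IsotopeDataset(
        df["sample_id"].to_numpy(dtype=object),
        df["origin"].to_numpy(dtype=object),
        years,
        X,
        tuple(schema),
    )


def write_dataset(dataset: IsotopeDataset, path) -> None:
    """Write a dataset as CSV with full float precision (round-trip safe)."""
    df = dataset.to_frame()
    # repr() of a float round-trips exactly in Python 3
    for name in dataset.marker_names:
        df[name] = [repr(float(v)) for v in df[name]]
    df.to_csv(path, index=False, encoding="utf-8")


@dataclass
class MarkerStatsTable:
    """Per (origin, marker) sample mean, sample SD (n-1) and count."""

    table: pd.DataFrame  # columns: origin, marker, mean, sd, n

    def lookup(self, origin: str, marker: str) -> tuple[float, float, int]:
        row = self.table[
            (self.table["origin"] == origin) & (self.table["marker"] == marker)
        ]
        if row.empty:
            raise KeyError((origin, marker))
        r = row.iloc[0]
        return float(r["mean"]), float(r["sd"]), int(r["n"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def summarize(dataset: IsotopeDataset) -> MarkerStatsTable:
    """Per-origin, per-marker mean and sample SD (n-1 denominator).

    SD is reported as 0 for groups of size 1.  Raises on an empty dataset.
    """
    if len(dataset) == 0:
        raise ValueError("cannot summarize an empty dataset")
    rows = []
    for origin in dataset.class_labels:
        mask = dataset.origins == origin
        sub = dataset.X[mask]
        n = int(mask.sum())
        means = sub.mean(axis=0)
        sds = sub.std(axis=0, ddof=1) if n > 1 else np.zeros(sub.shape[1])
        for j, marker in enumerate(dataset.marker_names):
            rows.append(
                {
                    "origin": origin,
                    "marker": marker,
                    "mean": means[j],
                    "sd": sds[j],
                    "n": n,
                }
            )
    return MarkerStatsTable(pd.DataFrame(rows))
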