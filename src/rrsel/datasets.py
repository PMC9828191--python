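"""Per-individual phenotype/fitness datasets.

A :class:`SelectionDataset` holds one population-year of observations: a
block of "standard" traits (morphology, phenology) that enter a selection
analysis as ordinary covariates, a block of many correlated composite-trait
measurements (volatile emission rates) that will be reduced to one or a few
learned axes, and absolute fitness (typically fruit count), from which
relative fitness is derived by dividing by the population mean.

Loading is schema-driven: the caller names the fitness column and assigns
every other column a role (standard trait, volatile, identifier, ignore),
either explicitly or by column-name prefix. Cleaning is listwise deletion of
incomplete rows plus removal of zero-variance volatile columns; both are
recorded in a :class:`CleaningLog`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DataError,
    DegenerateFitnessError,
    InsufficientDataError,
    SchemaError,
)

_log = logging.getLogger(__name__)

#: Minimum surplus of rows over standard-trait columns required for a fit.
_MIN_ROW_SURPLUS = 3


def relative_fitness(absolute_fitness) -> np.ndarray:
    """Divide absolute fitness by its mean so the result has mean 1.

    Parameters
    ----------
    absolute_fitness
        Nonnegative vector (fruit counts or any fitness proxy).

    Returns
    -------
    numpy.ndarray
        Element-wise ``absolute / mean(absolute)``.

    Raises
    ------
    DataError
        If the vector is empty, non-finite, or contains negative values.
    DegenerateFitnessError
        If every value is zero (mean fitness is zero).
    """
    w = np.asarray(absolute_fitness, dtype=float)
    if w.size == 0:
        raise DataError("absolute fitness vector is empty")
    if not np.all(np.isfinite(w)):
        raise DataError("absolute fitness contains non-finite values")
    if np.any(w < 0):
        raise DataError("absolute fitness contains negative values")
    mean = w.mean()
    if mean <= 0:
        raise DegenerateFitnessError("mean absolute fitness is zero")
    return w / mean


@dataclass
class CleaningLog:
    """Record of what was removed while validating a dataset."""

    n_rows_in: int = 0
    n_rows_dropped: int = 0
    dropped_columns: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_rows_in": self.n_rows_in,
            "n_rows_dropped": self.n_rows_dropped,
            "dropped_columns": list(self.dropped_columns),
        }


@dataclass
class Schema:
    """Column-role mapping for :func:`load_dataset`.

    Roles may be given as explicit column lists (``standard``, ``volatiles``)
    or by name prefix (``standard_prefix``, ``volatile_prefix``); explicit
    lists take precedence. Columns matching neither a role nor ``ignore``
    are ignored with a warning.
    """

    fitness: str
    identifier: str | None = None
    standard: list[str] | None = None
    volatiles: list[str] | None = None
    standard_prefix: str | None = None
    volatile_prefix: str | None = None
    ignore: list[str] = field(default_factory=list)

    @classmethod
    def from_dict(cls, d: dict) -> "Schema":
        if "fitness" not in d:
            raise SchemaError("schema must name a fitness column")
        known = {
            "fitness",
            "identifier",
            "standard",
            "volatiles",
            "standard_prefix",
            "volatile_prefix",
            "ignore",
        }
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown schema keys: {sorted(unknown)}")
        return cls(**d)

    def assign_roles(self, columns: list[str]) -> dict[str, str]:
        """Map every column name to one of fitness/identifier/standard/volatile/ignore."""
        if self.fitness not in columns:
            raise SchemaError(f"fitness column {self.fitness!r} not found in file")
        for role, cols in (("standard", self.standard), ("volatiles", self.volatiles)):
            for c in cols or []:
                if c not in columns:
                    raise SchemaError(f"{role} column {c!r} not found in file")
        roles: dict[str, str] = {}
        for c in columns:
            if c == self.fitness:
                roles[c] = "fitness"
            elif self.identifier is not None and c == self.identifier:
                roles[c] = "identifier"
            elif self.standard and c in self.standard:
                roles[c] = "standard"
            elif self.volatiles and c in self.volatiles:
                roles[c] = "volatile"
            elif c in self.ignore:
                roles[c] = "ignore"
            elif self.standard_prefix and c.startswith(self.standard_prefix):
                roles[c] = "standard"
            elif self.volatile_prefix and c.startswith(self.volatile_prefix):
                roles[c] = "volatile"
            else:
                _log.warning("column %r matches no schema role; ignoring", c)
                roles[c] = "ignore"
        if not any(r == "volatile" for r in roles.values()):
            raise SchemaError("schema assigns no volatile columns")
        return roles


def default_schema() -> Schema:
    """Schema matching the files written by :mod:`rrsel.simulate`."""
    return Schema(
        fitness="fitness",
        identifier="id",
        standard_prefix="trait_",
        volatile_prefix="vol_",
    )


@dataclass
class SelectionDataset:
    """One population-year of individuals with traits and fitness.

    Attributes
    ----------
    dataset_id
        Free-form label (e.g. ``"Remigen:2010"``).
    standard_traits
        ``n x p`` DataFrame of standard covariates on their original
        measurement scale.
    volatiles
        ``n x q`` DataFrame of composite-trait measurements (emission rate
        per flower or plant), original scale.
    absolute_fitness
        Nonnegative length-``n`` Series.
    relative_fitness
        Length-``n`` Series with mean 1; derived from ``absolute_fitness``
        when not supplied.
    cleaning
        Log of rows/columns removed during loading (empty for in-memory
        construction).
    """

    dataset_id: str
    standard_traits: pd.DataFrame
    volatiles: pd.DataFrame
    absolute_fitness: pd.Series
    relative_fitness: pd.Series | None = None
    cleaning: CleaningLog = field(default_factory=CleaningLog)

    def __post_init__(self):
        if self.relative_fitness is None:
            self.relative_fitness = pd.Series(
                relative_fitness(self.absolute_fitness.to_numpy()),
                index=self.absolute_fitness.index,
                name="relative_fitness",
            )
        self.validate()

    # -- derived sizes -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.absolute_fitness)

    @property
    def n_standard(self) -> int:
        return self.standard_traits.shape[1]

    @property
    def n_volatiles(self) -> int:
        return self.volatiles.shape[1]

    @property
    def standard_names(self) -> list[str]:
        return list(self.standard_traits.columns)

    @property
    def volatile_names(self) -> list[str]:
        return list(self.volatiles.columns)

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        n = self.n
        if len(self.standard_traits) != n or len(self.volatiles) != n:
            raise DataError("trait blocks and fitness have differing row counts")
        if self.n_volatiles < 1:
            raise DataError("dataset has no volatile columns")
        for name, block in (
            ("standard_traits", self.standard_traits),
            ("volatiles", self.volatiles),
        ):
            arr = block.to_numpy(dtype=float)
            if arr.size and not np.all(np.isfinite(arr)):
                raise DataError(f"{name} contains missing or non-finite values")
        w = self.absolute_fitness.to_numpy(dtype=float)
        if np.any(w < 0):
            raise DataError("absolute fitness contains negative values")
        if n < self.n_standard + _MIN_ROW_SURPLUS:
            raise InsufficientDataError(
                f"need at least {self.n_standard + _MIN_ROW_SURPLUS} complete rows, "
                f"got {n}"
            )
        v = self.volatiles.to_numpy(dtype=float)
        var = v.var(axis=0, ddof=1) if n > 1 else np.zeros(self.n_volatiles)
        if np.any(var <= 0):
            bad = [c for c, ok in zip(self.volatile_names, var > 0) if not ok]
            raise DataError(f"zero-variance volatile columns: {bad}")
        rel = self.relative_fitness.to_numpy(dtype=float)
        if abs(rel.mean() - 1.0) > 1e-12:
            raise DataError("relative fitness does not have mean 1")


def load_dataset(path, schema: Schema | dict, dataset_id: str | None = None) -> SelectionDataset:
    """Read a delimited-text file and return a validated dataset.

    The delimiter (comma or tab) is autodetected; the file must have one
    header row. Rows with any missing value in a used column are dropped;
    volatile columns with zero variance after row cleaning are dropped; both
    actions are recorded in the returned dataset's cleaning log.

    Raises
    ------
    SchemaError
        If the fitness column (or an explicitly listed column) is absent.
    DataError
        If fitness values are negative.
    InsufficientDataError
        If fewer than ``p + 3`` complete rows remain.
    """
    if isinstance(schema, dict):
        schema = Schema.from_dict(schema)
    raw = pd.read_csv(path, sep=None, engine="python")
    roles = schema.assign_roles(list(raw.columns))
    std_cols = [c for c in raw.columns if roles[c] == "standard"]
    vol_cols = [c for c in raw.columns if roles[c] == "volatile"]
    used = std_cols + vol_cols + [schema.fitness]

    log = CleaningLog(n_rows_in=len(raw))
    complete = raw[used].notna().all(axis=1)
    log.n_rows_dropped = int((~complete).sum())
    if log.n_rows_dropped:
        _log.info(
            "dropped %d incomplete rows from %s", log.n_rows_dropped, path
        )
    data = raw.loc[complete].reset_index(drop=True)

    fitness = pd.to_numeric(data[schema.fitness], errors="coerce")
    if fitness.isna().any() or not np.all(np.isfinite(fitness)):
        raise DataError("fitness column contains non-numeric values")
    if (fitness < 0).any():
        raise DataError("negative fitness values in input file")

    vols = data[vol_cols].astype(float)
    if len(vols) > 1:
        variances = vols.var(axis=0, ddof=1)
    else:
        variances = pd.Series(0.0, index=vol_cols)
    keep = [c for c in vol_cols if variances[c] > 0]
    dropped = [c for c in vol_cols if c not in keep]
    if dropped:
        _log.warning("dropping zero-variance volatile columns: %s", dropped)
        log.dropped_columns.extend(dropped)
    if not keep:
        raise DataError("all volatile columns have zero variance")

    n_needed = len(std_cols) + _MIN_ROW_SURPLUS
    if len(data) < n_needed:
        raise InsufficientDataError(
            f"{len(data)} complete rows remain; need at least {n_needed}"
        )

    return SelectionDataset(
        dataset_id=dataset_id or str(path),
        standard_traits=data[std_cols].astype(float),
        volatiles=vols[keep],
        absolute_fitness=fitness.astype(float).rename("absolute_fitness"),
        cleaning=log,
    )
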