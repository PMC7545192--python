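"""Region tables and density matrices.

The pipeline's sole external input is a *region table*: one row per
administrative region with its land area (hectares), resident population and
one non-negative count per indicator (crimes, property transactions, deaths,
age-group populations).  All densities are *derived* from counts and areas —
never read from a file — so that every downstream quantity traces back to the
raw table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default column-name schema for region-table CSVs
DEFAULT_SCHEMA = {"id": "region_id", "area": "area", "population": "population"}


class SchemaError(ValueError):
    """A required column is missing or the schema is malformed."""


class ValidationError(ValueError):
    """A cell violates a region-table invariant (names row and column)."""


@dataclass
class RegionTable:
    """Per-region land area, resident population and indicator counts.

    Parameters
    ----------
    region_id : sequence of str
        Unique region labels.
    area : array-like
        Land area in hectares; strictly positive.
    population : array-like
        Resident population; non-negative.
    counts : pandas.DataFrame
        Regions x indicators matrix of non-negative counts, indexed to match
        ``region_id``.
    """

    region_id: pd.Index
    area: np.ndarray
    population: np.ndarray
    counts: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.region_id = pd.Index([str(r) for r in self.region_id], name="region_id")
        self.area = np.asarray(self.area, dtype=float)
        self.population = np.asarray(self.population, dtype=float)
        if self.counts is None or len(self.counts) == 0:
            self.counts = pd.DataFrame(index=self.region_id)
        else:
            self.counts = pd.DataFrame(self.counts)
            self.counts.index = self.region_id
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n = len(self.region_id)
        if self.region_id.has_duplicates:
            dupes = self.region_id[self.region_id.duplicated()].tolist()
            raise ValidationError(f"duplicate region_id values: {dupes[:5]}")
        if len(self.area) != n or len(self.population) != n:
            raise ValidationError("area/population length does not match region_id")
        for name, vals, cond in (
            ("area", self.area, lambda v: v > 0),
            ("population", self.population, lambda v: v >= 0),
        ):
            bad = ~(np.isfinite(vals) & cond(vals))
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"invalid {name} in row {row} "
                    f"(region {self.region_id[row]!r}): {vals[row]!r}"
                )
        cvals = self.counts.to_numpy(dtype=float) if self.counts.shape[1] else None
        if cvals is not None:
            bad = ~(np.isfinite(cvals) & (cvals >= 0))
            if bad.any():
                r, c = map(int, np.argwhere(bad)[0])
                raise ValidationError(
                    f"invalid count in row {r} (region {self.region_id[r]!r}), "
                    f"column {self.counts.columns[c]!r}: {cvals[r, c]!r}"
                )

    # -- convenience --------------------------------------------------------
    @property
    def n_regions(self) -> int:
        return len(self.region_id)

    @property
    def indicators(self) -> list[str]:
        return list(self.counts.columns)

    def zero_cell_counts(self) -> pd.Series:
        """Number of zero-valued cells per indicator (anonymised zeros included)."""
        return (self.counts == 0).sum(axis=0)

    def to_frame(self, schema: dict | None = None) -> pd.DataFrame:
        schema = {**DEFAULT_SCHEMA, **(schema or {})}
        df = pd.DataFrame(
            {
                schema["id"]: self.region_id,
                schema["area"]: self.area,
                schema["population"]: self.population,
            }
        )
        return pd.concat([df, self.counts.reset_index(drop=True)], axis=1)

    def write_csv(self, path: str | Path, schema: dict | None = None) -> None:
        self.to_frame(schema).to_csv(path, index=False)


def read_region_table(path: str | Path, schema: dict | None = None) -> RegionTable:
    """Read and validate a region table from a CSV file.

    ``schema`` maps the roles ``id``, ``area``, ``population`` to column
    names; every remaining column is treated as an indicator.  Zero-cell
    counts per indicator are logged (anonymised sources concentrate zeros at
    the rural end).
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path)
    missing = [schema[k] for k in ("id", "area", "population") if schema[k] not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s) {missing} in {path}")
    reserved = {schema["id"], schema["area"], schema["population"]}
    ind_cols = [c for c in df.columns if c not in reserved]
    for col in [schema["area"], schema["population"], *ind_cols]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().all():
            row = int(coerced.isna().idxmax())
            raise ValidationError(f"non-numeric value in row {row}, column {col!r}")
        df[col] = coerced
    table = RegionTable(
        region_id=df[schema["id"]].astype(str),
        area=df[schema["area"]].to_numpy(),
        population=df[schema["population"]].to_numpy(),
        counts=df[ind_cols],
    )
    zeros = table.zero_cell_counts()
    if len(zeros):
        logger.info("zero-valued cells per indicator: %s", zeros.to_dict())
    return table


@dataclass
class DensityMatrix:
    """Population density and indicator densities per region.

    ``d = population / area`` (people per hectare) and ``y = count / area``
    per indicator.  Base-10 logs are attached; log cells whose underlying
    value is zero are missing (NaN), never ``-inf`` — zero counts carry no
    information about the scaling exponent and are excluded from fits.
    """

    region_id: pd.Index
    d: pd.Series
    y: pd.DataFrame
    log_d: pd.Series
    log_y: pd.DataFrame

    @property
    def indicators(self) -> list[str]:
        return list(self.y.columns)

    def write_csv(self, path: str | Path) -> None:
        out = pd.concat([self.d.rename("population_density"), self.y], axis=1)
        out.index.name = "region_id"
        out.to_csv(path)


def compute_density_matrix(
    table: RegionTable,
    verify_densities: pd.DataFrame | None = None,
    rtol: float = 1e-9,
) -> DensityMatrix:
    """Derive the density matrix ``(d, y)`` from a region table.

    When ``verify_densities`` is given (a region x indicator density table,
    e.g. a published densities file), the derived values are cross-checked
    against it to relative tolerance ``rtol`` and a mismatch raises
    :class:`ValidationError`; the supplied values are never used directly.
    """
    idx = table.region_id
    d = pd.Series(table.population / table.area, index=idx, name="d")
    y = table.counts.div(pd.Series(table.area, index=idx), axis=0)
    with np.errstate(divide="ignore"):
        log_d = pd.Series(np.where(d > 0, np.log10(d.where(d > 0, 1.0)), np.nan), index=idx)
        log_y = pd.DataFrame(
            np.where(y > 0, np.log10(y.where(y > 0, 1.0)), np.nan),
            index=idx,
            columns=y.columns,
        )
    if verify_densities is not None:
        common = [c for c in y.columns if c in verify_densities.columns]
        ref = verify_densities.loc[idx, common]
        if not np.allclose(y[common], ref, rtol=rtol, equal_nan=True):
            raise ValidationError("supplied densities disagree with derived counts/area")
    return DensityMatrix(region_id=idx, d=d, y=y, log_d=log_d, log_y=log_y)


def apply_anonymisation(count):
    """Disclosure-control distortion used by the mortality source.

    Counts of 2 or less are reported as 0; counts of 3 and 4 are reported
    as 5; larger counts pass through.  Accepts a scalar or array; idempotent.
    """
    arr = np.asarray(count)
    if np.any(arr < 0):
        raise ValidationError("anonymisation requires non-negative counts")
    out = np.where(arr <= 2, 0, np.where(arr <= 4, 5, arr))
    if np.isscalar(count) or arr.ndim == 0:
        return out.item()
    return out
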