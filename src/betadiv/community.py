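"""Hierarchical community incidence data: types, validation and CSV I/O.

The atom of every diversity computation here is the :class:`IncidenceMatrix`,
a binary replicate x taxon table whose rows are keyed by the nested sampling
hierarchy (estuary > site > replicate).  Two plain-text layouts are supported:

* *long* — one row per (estuary, site, replicate, taxon) occurrence, with an
  optional ``value`` column (any value > 0 is coerced to presence);
* *wide* — one row per replicate, the three hierarchy columns followed by one
  column per taxon.

Loads are order-independent: permuting the input rows yields an identical
matrix.  Taxa observed nowhere are retained (and flagged in the validation
report) but never contribute to richness, which is computed on observed taxa.
All-zero replicates are legal — an empty core is a real observation — and
count toward sample totals in rarefaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CommunityDataError",
    "IncidenceMatrix",
    "ValidationReport",
    "SiteEnvironment",
    "EstuaryEnvironment",
    "read_community",
    "write_community",
    "pool_site",
    "read_site_environment",
    "read_estuary_environment",
]

HIERARCHY = ("estuary", "site", "replicate")

SHELL_CLASSES = ("none", "rare", "present")


class CommunityDataError(ValueError):
    """Raised when an input table violates the incidence-data contract."""


@dataclass(frozen=True)
class ValidationReport:
    """Summary of structural checks on a loaded incidence matrix."""

    n_replicates: int
    n_taxa: int
    n_sites: int
    n_estuaries: int
    absent_taxa: tuple[str, ...]
    empty_replicates: tuple[tuple[str, str, str], ...]


class IncidenceMatrix:
    """Binary presence/absence matrix over a nested sampling hierarchy.

    Parameters
    ----------
    data
        DataFrame with a three-level MultiIndex (estuary, site, replicate)
        and one column per taxon; entries are 0/1.

    Notes
    -----
    Site identifiers are scoped to their estuary: the pair (estuary, site)
    names a site, so the same site label may recur in different estuaries.
    """

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data.index, pd.MultiIndex) or data.index.nlevels != 3:
            raise CommunityDataError(
                "incidence data needs a (estuary, site, replicate) MultiIndex"
            )
        data = data.copy()
        data.index = data.index.set_names(HIERARCHY)
        if data.shape[0] < 1 or data.shape[1] < 1:
            raise CommunityDataError("need at least one replicate and one taxon")
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise CommunityDataError(f"duplicate replicate key {dup!r}")
        if data.columns.has_duplicates:
            raise CommunityDataError("taxon labels must be unique")
        values = data.to_numpy()
        if np.isnan(values.astype(float)).any():
            raise CommunityDataError("missing cells are not allowed (absent = 0)")
        if (values.astype(float) < 0).any():
            raise CommunityDataError("negative abundances are invalid")
        self._data = (data > 0).astype(np.int8).sort_index()

    # ------------------------------------------------------------------ views
    @property
    def data(self) -> pd.DataFrame:
        """The underlying binary DataFrame (rows sorted by hierarchy key)."""
        return self._data

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self._data.columns)

    @property
    def n_replicates(self) -> int:
        return self._data.shape[0]

    def estuaries(self) -> tuple[str, ...]:
        return tuple(self._data.index.unique("estuary"))

    def sites(self, estuary: str | None = None) -> tuple[tuple[str, str], ...]:
        """All (estuary, site) pairs, optionally restricted to one estuary."""
        pairs = self._data.index.droplevel("replicate").unique()
        if estuary is not None:
            pairs = [p for p in pairs if p[0] == estuary]
        return tuple(pairs)

    # -------------------------------------------------------------- selection
    def site_incidence(self, site_key: tuple[str, str]) -> pd.DataFrame:
        """Replicate x taxon sub-table for one site."""
        estuary, site = site_key
        try:
            sub = self._data.xs((estuary, site), level=("estuary", "site"))
        except KeyError:
            raise KeyError(f"unknown site {site_key!r}") from None
        if sub.shape[0] == 0:
            raise KeyError(f"unknown site {site_key!r}")
        return sub

    def estuary_incidence(self, estuary: str) -> pd.DataFrame:
        try:
            sub = self._data.xs(estuary, level="estuary")
        except KeyError:
            raise KeyError(f"unknown estuary {estuary!r}") from None
        return sub

    def pool_site(self, site_key: tuple[str, str]) -> frozenset[str]:
        """Taxa present in at least one replicate of the site (the union pool)."""
        sub = self.site_incidence(site_key)
        present = sub.to_numpy().any(axis=0)
        return frozenset(np.asarray(sub.columns)[present])

    def pool_estuary(self, estuary: str) -> frozenset[str]:
        """Taxa present in at least one sample anywhere in the estuary."""
        sub = self.estuary_incidence(estuary)
        present = sub.to_numpy().any(axis=0)
        return frozenset(np.asarray(sub.columns)[present])

    def replicate_richness(self, site_key: tuple[str, str]) -> np.ndarray:
        """Per-replicate species richness within one site."""
        return self.site_incidence(site_key).to_numpy().sum(axis=1)

    # ------------------------------------------------------------- validation
    def validation_report(self) -> ValidationReport:
        values = self._data.to_numpy()
        absent = tuple(self._data.columns[values.sum(axis=0) == 0])
        empty = tuple(self._data.index[values.sum(axis=1) == 0])
        return ValidationReport(
            n_replicates=self._data.shape[0],
            n_taxa=self._data.shape[1],
            n_sites=len(self.sites()),
            n_estuaries=len(self.estuaries()),
            absent_taxa=absent,
            empty_replicates=empty,
        )

    # ------------------------------------------------------------ conversions
    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "IncidenceMatrix":
        missing = [c for c in (*HIERARCHY, "taxon") if c not in df.columns]
        if missing:
            raise CommunityDataError(f"long format missing columns {missing}")
        df = df.copy()
        if "value" not in df.columns:
            df["value"] = 1
        df["value"] = pd.to_numeric(df["value"], errors="raise")
        if (df["value"] < 0).any():
            raise CommunityDataError("negative abundances are invalid")
        key = [*HIERARCHY, "taxon"]
        presence = df.assign(value=(df["value"] > 0).astype(int))
        per_cell = presence.groupby(key)["value"].agg(["min", "max"])
        conflict = per_cell["min"] != per_cell["max"]
        if conflict.any():
            bad = per_cell.index[conflict][0]
            raise CommunityDataError(
                f"conflicting duplicate rows for {bad!r} (presence differs)"
            )
        wide = (
            per_cell["max"]
            .unstack("taxon", fill_value=0)
            .sort_index(axis=1)
        )
        return cls(wide)

    @classmethod
    def from_wide(cls, df: pd.DataFrame) -> "IncidenceMatrix":
        missing = [c for c in HIERARCHY if c not in df.columns]
        if missing:
            raise CommunityDataError(f"wide format missing columns {missing}")
        df = df.set_index(list(HIERARCHY))
        return cls(df)

    def to_long(self) -> pd.DataFrame:
        long = (
            self._data.stack()
            .rename("value")
            .reset_index()
            .rename(columns={"level_3": "taxon"})
        )
        long.columns = [*HIERARCHY, "taxon", "value"]
        return long[long["value"] > 0].reset_index(drop=True)

    def to_wide(self) -> pd.DataFrame:
        return self._data.reset_index()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IncidenceMatrix):
            return NotImplemented
        return self._data.sort_index(axis=1).equals(other._data.sort_index(axis=1))

    def __repr__(self) -> str:
        r = self.validation_report()
        return (
            f"IncidenceMatrix({r.n_replicates} replicates, {r.n_taxa} taxa, "
            f"{r.n_sites} sites, {r.n_estuaries} estuaries)"
        )


def pool_site(m: IncidenceMatrix, site_key: tuple[str, str]) -> frozenset[str]:
    """Union of taxa over a site's replicates (module-level convenience)."""
    return m.pool_site(site_key)


def read_community(path: str | Path, format: str | None = None) -> IncidenceMatrix:
    """Read a community CSV in long or wide layout.

    ``format`` is ``"long"``, ``"wide"`` or None to auto-detect (a ``taxon``
    column implies long layout).
    """
    df = pd.read_csv(path)
    if format is None:
        format = "long" if "taxon" in df.columns else "wide"
    if format == "long":
        return IncidenceMatrix.from_long(df)
    if format == "wide":
        return IncidenceMatrix.from_wide(df)
    raise ValueError(f"unknown community format {format!r}")


def write_community(
    m: IncidenceMatrix, path: str | Path, format: str = "wide"
) -> None:
    if format == "long":
        m.to_long().to_csv(path, index=False)
    elif format == "wide":
        m.to_wide().to_csv(path, index=False)
    else:
        raise ValueError(f"unknown community format {format!r}")


# --------------------------------------------------------------------------
# Environment tables
# --------------------------------------------------------------------------

_PERCENT_BOUNDS = (0.0, 100.0)


@dataclass(frozen=True)
class SiteEnvironment:
    """Site-scale environment table keyed by (estuary, site).

    Numeric columns are sediment fractions and related local covariates in
    percent, chlorophyll a in ug/g, and distance to the estuary mouth in km;
    ``shell_hash`` is the categorical three-class cover score.  Missing values
    are permitted and recorded in ``missing``.
    """

    table: pd.DataFrame
    missing: tuple[tuple[tuple[str, str], str], ...] = field(default=())

    def variables(self) -> pd.DataFrame:
        """Numeric variables only (categorical shell class excluded)."""
        return self.table.select_dtypes("number")


@dataclass(frozen=True)
class EstuaryEnvironment:
    """Estuary/catchment characteristics table keyed by estuary id."""

    table: pd.DataFrame

    def variables(self) -> pd.DataFrame:
        return self.table.select_dtypes("number")


def _check_percentages(df: pd.DataFrame, cols: Iterable[str], where: str) -> None:
    for col in cols:
        if col not in df.columns:
            continue
        vals = df[col].dropna()
        lo, hi = _PERCENT_BOUNDS
        if ((vals < lo) | (vals > hi)).any():
            raise CommunityDataError(f"{where}: column {col!r} outside [0, 100]")


def read_site_environment(
    path: str | Path,
    percent_columns: Iterable[str] = ("mud", "coarse", "medium_sand", "fine_sand", "organic"),
) -> SiteEnvironment:
    df = pd.read_csv(path)
    for col in ("estuary", "site"):
        if col not in df.columns:
            raise CommunityDataError(f"site environment table needs a {col!r} column")
    df = df.set_index(["estuary", "site"])
    _check_percentages(df, percent_columns, "site environment")
    if "shell_hash" in df.columns:
        bad = set(df["shell_hash"].dropna()) - set(SHELL_CLASSES)
        if bad:
            raise CommunityDataError(f"unknown shell-hash classes {sorted(bad)}")
    missing = tuple(
        (idx, col)
        for col in df.columns
        for idx in df.index[df[col].isna()]
    )
    if missing:
        warnings.warn(
            f"site environment has {len(missing)} missing cells", stacklevel=2
        )
    return SiteEnvironment(table=df, missing=missing)


def read_estuary_environment(
    path: str | Path,
    percent_columns: Iterable[str] = ("intertidal_pct", "natural_pct", "pastoral_pct", "urban_pct", "exotic_pct"),
) -> EstuaryEnvironment:
    df = pd.read_csv(path)
    if "estuary" not in df.columns:
        raise CommunityDataError("estuary environment table needs an 'estuary' column")
    df = df.set_index("estuary")
    _check_percentages(df, percent_columns, "estuary environment")
    for col in df.select_dtypes("number").columns:
        if col.endswith(("_km2", "_km")) and (df[col].dropna() <= 0).any():
            raise CommunityDataError(f"estuary environment: {col!r} must be > 0")
    return EstuaryEnvironment(table=df)
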