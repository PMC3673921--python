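"""Dissimilarity and distance matrices, plus estuary geometry helpers.

All matrices are returned as :class:`skbio.DistanceMatrix` — a labeled,
validated (symmetric, zero-diagonal) container — with unit ids either estuary
labels or ``"estuary/site"`` composites.

Community dissimilarity is Jaccard on presence/absence: a unit's composition
is the union of its member samples' taxa, the same pooling that defines
γ-site and γ-estuary (an alternative frequency-threshold composition —
presence in at least a given fraction of members — is available behind a
flag).  Environmental distance is Euclidean on (by default) z-scored
variables; spatial distance is planar Euclidean or great-circle haversine.

The two estuary geometry indices summarise shoreline shape: shore complexity
compares the shoreline to the circumference of an equal-area circle (1 =
circular/simple, small values = convoluted), and the closure index is mouth
width over shoreline length (large = open mouth, small = nearly closed).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .community import IncidenceMatrix

__all__ = [
    "site_label",
    "jaccard_dissimilarity",
    "pairwise_jaccard",
    "within_estuary_jaccard",
    "environmental_distance",
    "spatial_distance",
    "value_difference_matrix",
    "shore_complexity",
    "closure_index",
    "shell_class",
    "write_distance_matrix",
    "read_distance_matrix",
]

EARTH_RADIUS_KM = 6371.0


def site_label(estuary: str, site: str) -> str:
    """Composite unit id for a site, unique across estuaries."""
    return f"{estuary}/{site}"


def jaccard_dissimilarity(a: frozenset | set, b: frozenset | set) -> float:
    """1 − |a ∩ b| / |a ∪ b| on two taxon sets; undefined for two empty sets."""
    union = len(a | b)
    if union == 0:
        raise ValueError("Jaccard dissimilarity is undefined for two empty sets")
    return 1.0 - len(a & b) / union


def _unit_pools(
    m: IncidenceMatrix, level: str, frequency_threshold: float | None
) -> tuple[list[str], np.ndarray]:
    """Binary unit x taxon composition matrix at site or estuary level."""
    if level == "site":
        units = [site_label(*k) for k in m.sites()]
        members = [m.site_incidence(k) for k in m.sites()]
    elif level == "estuary":
        units = list(m.estuaries())
        if frequency_threshold is None:
            members = [m.estuary_incidence(e) for e in m.estuaries()]
        else:
            # estuary members are its site pools, not raw replicates
            members = []
            for e in m.estuaries():
                pools = np.stack(
                    [
                        m.site_incidence(k).to_numpy().any(axis=0)
                        for k in m.sites(e)
                    ]
                )
                members.append(pd.DataFrame(pools, columns=m.taxa))
    else:
        raise ValueError(f"unknown level {level!r}")
    comps = []
    for sub in members:
        x = sub.to_numpy() > 0
        if frequency_threshold is None:
            comps.append(x.any(axis=0))
        else:
            comps.append(x.mean(axis=0) >= frequency_threshold)
    return units, np.stack(comps)


def pairwise_jaccard(
    m: IncidenceMatrix,
    level: str = "site",
    frequency_threshold: float | None = None,
) -> DistanceMatrix:
    """Jaccard dissimilarity between all units at the requested level.

    ``frequency_threshold`` switches the unit composition from the union of
    member samples to taxa present in at least that fraction of members.
    """
    units, comp = _unit_pools(m, level, frequency_threshold)
    if len(units) < 2:
        raise ValueError(f"need >= 2 units at level {level!r}")
    empties = [u for u, row in zip(units, comp) if not row.any()]
    if empties:
        raise ValueError(f"unit(s) with empty composition: {empties}")
    inter = (comp.astype(int) @ comp.astype(int).T).astype(float)
    sizes = comp.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    d = 1.0 - inter / union
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix((d + d.T) / 2.0, ids=units)


def within_estuary_jaccard(
    m: IncidenceMatrix, frequency_threshold: float | None = None
) -> dict[str, DistanceMatrix]:
    """One between-site Jaccard matrix per estuary with >= 2 sites."""
    full = pairwise_jaccard(m, level="site", frequency_threshold=frequency_threshold)
    out: dict[str, DistanceMatrix] = {}
    for e in m.estuaries():
        ids = [site_label(*k) for k in m.sites(e)]
        if len(ids) >= 2:
            out[e] = full.filter(ids)
    return out


def environmental_distance(
    table: pd.DataFrame,
    standardize: bool = True,
    missing: str = "strict",
) -> DistanceMatrix:
    """Euclidean distance between units over environmental variables.

    Parameters
    ----------
    table
        Units in rows (index = unit ids), numeric variables in columns.
    standardize
        z-score each column (population SD) before computing distances;
        recommended whenever variables are on different scales.
    missing
        ``"strict"`` drops any column containing a missing value (warning);
        ``"pairwise"`` computes each pair's distance over its complete
        variables, rescaled by sqrt(p / p_complete) to stay comparable.
    """
    if table.shape[0] < 2:
        raise ValueError("need >= 2 units")
    X = table.select_dtypes("number").astype(float)
    if missing == "strict":
        bad = [c for c in X.columns if X[c].isna().any()]
        if bad:
            warnings.warn(f"dropping columns with missing values: {bad}", stacklevel=2)
            X = X.drop(columns=bad)
    elif missing != "pairwise":
        raise ValueError(f"unknown missing policy {missing!r}")
    if standardize:
        const = [c for c in X.columns if np.nanstd(X[c].to_numpy()) == 0]
        if const:
            warnings.warn(f"dropping zero-variance columns: {const}", stacklevel=2)
            X = X.drop(columns=const)
        if X.shape[1] == 0:
            raise ValueError("no variable with nonzero variance to standardize")
        X = (X - X.mean()) / X.std(ddof=0)
    if X.shape[1] == 0:
        raise ValueError("no usable variables")
    ids = [str(i) for i in X.index]
    vals = X.to_numpy()
    if missing == "pairwise" and np.isnan(vals).any():
        n, p = vals.shape
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ok = ~(np.isnan(vals[i]) | np.isnan(vals[j]))
                if not ok.any():
                    raise ValueError(
                        f"units {ids[i]!r} and {ids[j]!r} share no complete variable"
                    )
                diff = vals[i, ok] - vals[j, ok]
                d[i, j] = d[j, i] = np.sqrt((diff**2).sum() * p / ok.sum())
        return DistanceMatrix(d, ids=ids)
    return DistanceMatrix(squareform(pdist(vals, metric="euclidean")), ids=ids)


def _haversine_km(coords: np.ndarray) -> np.ndarray:
    lon = np.radians(coords[:, 0])
    lat = np.radians(coords[:, 1])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = (
        np.sin(dlat / 2.0) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def spatial_distance(coords: pd.DataFrame, mode: str = "euclidean") -> DistanceMatrix:
    """Pairwise spatial distance between units.

    ``coords`` is indexed by unit id with two columns: (x, y) in planar units
    for ``mode="euclidean"``, or (lon, lat) in decimal degrees for
    ``mode="haversine"`` (great-circle km, Earth radius 6371 km).
    """
    if coords.isna().any().any():
        raise ValueError("coordinates must be present for all units")
    vals = coords.to_numpy(dtype=float)
    if vals.shape[1] != 2:
        raise ValueError("coordinates need exactly two columns")
    ids = [str(i) for i in coords.index]
    if mode == "euclidean":
        d = squareform(pdist(vals, metric="euclidean"))
    elif mode == "haversine":
        lat = vals[:, 1]
        if (np.abs(lat) > 90).any():
            raise ValueError("latitude outside [-90, 90]")
        d = _haversine_km(vals)
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return DistanceMatrix(d, ids=ids)


def value_difference_matrix(values: pd.Series) -> DistanceMatrix:
    """|v_i − v_j| between units of a per-unit scalar (e.g. β-conn)."""
    v = values.astype(float)
    if v.isna().any():
        dropped = list(v.index[v.isna()])
        warnings.warn(f"excluding units with missing values: {dropped}", stacklevel=2)
        v = v.dropna()
    if v.shape[0] < 2:
        raise ValueError("need >= 2 units with values")
    arr = v.to_numpy()
    d = np.abs(arr[:, None] - arr[None, :])
    return DistanceMatrix(d, ids=[str(i) for i in v.index])


def shore_complexity(area_km2: float, perimeter_km: float) -> float:
    """Equal-area-circle circumference over shoreline length, in (0, 1].

    1 for a circular (simple) shoreline, small values for convoluted shores;
    by the isoperimetric inequality the ratio cannot exceed 1 for a closed
    shoreline enclosing the given area.
    """
    if area_km2 <= 0 or perimeter_km <= 0:
        raise ValueError("area and perimeter must be > 0")
    return 2.0 * np.sqrt(np.pi * area_km2) / perimeter_km


def closure_index(mouth_width_km: float, perimeter_km: float) -> float:
    """Estuary mouth width over shoreline length (large = open mouth)."""
    if perimeter_km <= 0:
        raise ValueError("perimeter must be > 0")
    if mouth_width_km < 0:
        raise ValueError("mouth width must be >= 0")
    return mouth_width_km / perimeter_km


def shell_class(cover_percent: float) -> str:
    """Three-class shell-hash score from % quadrat cover.

    0% -> "none"; up to 5% -> "rare"; above 5% -> "present".
    """
    if not 0 <= cover_percent <= 100:
        raise ValueError("cover must be in [0, 100]")
    if cover_percent == 0:
        return "none"
    if cover_percent <= 5:
        return "rare"
    return "present"


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    """Square labeled CSV (header row + label column)."""
    dm.to_data_frame().to_csv(path)


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return DistanceMatrix(df.to_numpy(dtype=float), ids=list(df.index))
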