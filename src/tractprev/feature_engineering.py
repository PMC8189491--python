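"""Per-tract feature construction.

Query features are normalized keyword counts S_i(k): the fraction of tract
i's queries whose token set contains keyword k, optionally averaged over
the m nearest tracts (self included) to counter sparsity and geolocation
error.  Land-cover features are per-sub-class area proportions plus three
pixel-adjacency statistics; census features are the 20 demographic
proportions, passed through unsmoothed (demographics are defined strictly
within tract boundaries).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from shapely import STRtree
from shapely.geometry import Point

from .errors import (
    AlignmentError,
    InconsistentIndexError,
    InvalidParameterError,
    MissingDataError,
    SchemaError,
)
from .synthetic_city import (
    CENSUS_COLUMNS,
    FOREST_CODES,
    HIGH_DEVELOPED_CODES,
    LANDCOVER_CLASSES,
    CensusTable,
    LandCoverRaster,
    QueryLog,
    TractSet,
)

logger = logging.getLogger(__name__)

ADJACENCY_COLUMNS = ("highdev_adj_highdev", "highdev_adj_forest", "forest_adj_forest")


@dataclass
class FeatureTable:
    """Tract x feature matrix with provenance and smoothing metadata.

    ``m`` records the neighbor-smoothing applied (1 = raw values);
    ``provenance`` labels every column as query / landcover / census /
    state; ``flags`` collects per-tract data-sparsity warnings (tracts with
    zero query events or zero attributed raster cells).
    """

    data: pd.DataFrame  # index tract_id
    provenance: dict[str, str] = field(default_factory=dict)
    m: int = 1
    flags: dict[str, list[str]] = field(default_factory=dict)
    state_code_map: dict[str, int] | None = None

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if len(set(cols)) != len(cols):
            raise SchemaError("duplicate feature column names")
        for c in cols:
            self.provenance.setdefault(c, "unknown")

    @property
    def tract_ids(self) -> list[str]:
        return list(self.data.index)

    def columns_from(self, source: str) -> list[str]:
        return [c for c in self.data.columns if self.provenance.get(c) == source]


# ---------------------------------------------------------------------------
# Spatial assignment
# ---------------------------------------------------------------------------

def assign_points_to_tracts(
    points: Sequence[tuple[float, float]] | np.ndarray,
    tracts: TractSet,
) -> list[str | None]:
    """Map each planar point to the tract whose polygon covers it.

    Points on a shared boundary go to the lexicographically smallest
    tract_id; points outside every tract map to ``None`` (counted and
    logged, not fatal).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidParameterError("points must be an (n, 2) array-like")
    polys = [t.polygon for t in tracts.tracts]
    ids = np.asarray(tracts.ids, dtype=object)
    tree = STRtree(polys)
    geoms = [Point(x, y) for x, y in pts]
    pt_idx, poly_idx = tree.query(geoms, predicate="covered_by")

    result: list[str | None] = [None] * len(geoms)
    if pt_idx.size:
        pairs = pd.DataFrame({"pt": pt_idx, "tract": ids[poly_idx]})
        best = pairs.groupby("pt")["tract"].min()
        for p, t in best.items():
            result[int(p)] = t
    n_out = sum(1 for r in result if r is None)
    if n_out:
        logger.warning("%d of %d points fell outside every tract", n_out, len(geoms))
    return result


# ---------------------------------------------------------------------------
# Query features
# ---------------------------------------------------------------------------

def normalized_counts(
    log: QueryLog,
    keywords: Mapping[str, str],
    tracts: TractSet,
) -> FeatureTable:
    """Compute S_i(k) = |{queries in tract i containing k}| / |queries in tract i|.

    Keyword matching is exact token membership in the query's token set
    (not substring).  Tracts with no query events get 0 for every keyword
    and are flagged under ``flags['zero_event_tracts']``.
    """
    tract_ids = tracts.ids
    pos = {t: i for i, t in enumerate(tract_ids)}
    unknown = set(log.tract_ids) - set(pos)
    if unknown:
        raise MissingDataError(f"query events reference unknown tracts: {sorted(unknown)[:5]}")

    kw_list = sorted(keywords)
    kw_col = {k: j for j, k in enumerate(kw_list)}

    ev_tract = np.fromiter((pos[t] for t in log.tract_ids), dtype=np.int64, count=len(log))
    totals = np.bincount(ev_tract, minlength=len(tract_ids)).astype(float)

    counts = np.zeros((len(tract_ids), len(kw_list)))
    if len(log):
        lengths = np.fromiter((len(t) for t in log.tokens), dtype=np.int64, count=len(log))
        flat_tokens = np.array([tok for toks in log.tokens for tok in toks], dtype=object)
        flat_event = np.repeat(np.arange(len(log)), lengths)
        is_kw = pd.Series(flat_tokens).isin(kw_col).to_numpy()
        if is_kw.any():
            ev = flat_event[is_kw]
            cols = np.fromiter((kw_col[t] for t in flat_tokens[is_kw]),
                               dtype=np.int64, count=int(is_kw.sum()))
            # One query counts once per keyword no matter how often it repeats it.
            uniq = np.unique(np.stack([ev, cols], axis=1), axis=0)
            np.add.at(counts, (ev_tract[uniq[:, 0]], uniq[:, 1]), 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(totals[:, None] > 0, counts / np.maximum(totals, 1)[:, None], 0.0)

    df = pd.DataFrame(rates, index=pd.Index(tract_ids, name="tract_id"), columns=kw_list)
    zero = [tract_ids[i] for i in range(len(tract_ids)) if totals[i] == 0]
    if zero:
        logger.warning("%d tracts have zero query events", len(zero))
    return FeatureTable(
        data=df,
        provenance={c: "query" for c in kw_list},
        m=1,
        flags={"zero_event_tracts": zero},
    )


def category_sums(table: FeatureTable, keywords: Mapping[str, str]) -> FeatureTable:
    """Append sum_symptoms / sum_diseases / sum_medications columns.

    Each is the row-wise sum of the member keyword columns; an empty
    category yields a zero column.  Original columns are retained.
    """
    df = table.data.copy()
    prov = dict(table.provenance)
    for cat, col in (("symptom", "sum_symptoms"),
                     ("disease", "sum_diseases"),
                     ("medication", "sum_medications")):
        members = [k for k, c in keywords.items() if c == cat and k in df.columns]
        df[col] = df[list(members)].sum(axis=1) if members else 0.0
        prov[col] = "query"
    return FeatureTable(df, provenance=prov, m=table.m, flags=dict(table.flags))


# ---------------------------------------------------------------------------
# Neighbor smoothing
# ---------------------------------------------------------------------------

@dataclass
class NeighborIndex:
    """tract_id -> ordered list of m tract_ids (self first, then nearest)."""

    index: dict[str, list[str]]
    m: int

    def __post_init__(self) -> None:
        for t, lst in self.index.items():
            if len(lst) != self.m or len(set(lst)) != self.m:
                raise InvalidParameterError(f"neighbor list for {t} must hold m distinct entries")
            if t not in lst:
                raise InvalidParameterError(f"neighbor list for {t} must include itself")


def nearest_neighbors(tracts: TractSet, m: int) -> NeighborIndex:
    """For each tract: itself plus its m-1 nearest others by centroid distance.

    Euclidean distance between centroids; distance ties broken by
    lexicographic tract_id for determinism.
    """
    n = len(tracts)
    if m < 1 or m > n:
        raise InvalidParameterError(f"m must lie in [1, {n}], got {m}")
    ids = np.asarray(tracts.ids)
    dists = cdist(tracts.centroids, tracts.centroids)
    index: dict[str, list[str]] = {}
    for i in range(n):
        order = np.lexsort((ids, dists[i]))
        order = order[order != i]  # self goes first regardless of coincident centroids
        index[str(ids[i])] = [str(ids[i])] + [str(ids[j]) for j in order[: m - 1]]
    return NeighborIndex(index=index, m=m)


def neighbor_smooth(table: FeatureTable, index: NeighborIndex) -> FeatureTable:
    """Replace every cell by the unweighted mean over the row's m neighbors.

    A convex combination, so values stay within the column's range; m=1
    is the identity.
    """
    ids = table.tract_ids
    missing = [t for t in ids if t not in index.index]
    if missing:
        raise InconsistentIndexError(f"tracts missing from neighbor index: {missing[:5]}")
    pos = {t: i for i, t in enumerate(ids)}
    nbr = np.empty((len(ids), index.m), dtype=np.int64)
    for i, t in enumerate(ids):
        for j, nb in enumerate(index.index[t]):
            if nb not in pos:
                raise InconsistentIndexError(f"neighbor {nb} of {t} not in feature table")
            nbr[i, j] = pos[nb]
    vals = table.data.to_numpy(dtype=float)
    smoothed = vals[nbr].mean(axis=1)
    df = pd.DataFrame(smoothed, index=table.data.index, columns=table.data.columns)
    return FeatureTable(df, provenance=dict(table.provenance), m=index.m,
                        flags=dict(table.flags), state_code_map=table.state_code_map)


# ---------------------------------------------------------------------------
# Land-cover features
# ---------------------------------------------------------------------------

def _cell_tract_assignment(raster: LandCoverRaster, tracts: TractSet) -> np.ndarray:
    """Tract row index per raster cell (-1 where no tract covers the center)."""
    assigned = assign_points_to_tracts(raster.cell_centers(), tracts)
    pos = {t: i for i, t in enumerate(tracts.ids)}
    return np.fromiter((pos.get(a, -1) if a is not None else -1 for a in assigned),
                       dtype=np.int64, count=len(assigned))


def landcover_column(code: int) -> str:
    return f"landcover_{LANDCOVER_CLASSES.get(code, f'class_{code}')}"


def landcover_proportions(raster: LandCoverRaster, tracts: TractSet) -> FeatureTable:
    """Proportion of each tract's area covered by each land-cover sub-class.

    Cells are attributed to tracts by cell-center containment (zonal
    statistics convention); per-tract proportions over attributed cells sum
    to 1.  A tract with zero attributed cells is flagged degenerate and
    receives the region-wide mean proportions.
    """
    cell_tract = _cell_tract_assignment(raster, tracts)
    flat = raster.grid.ravel()
    codes = sorted(set(LANDCOVER_CLASSES) | set(np.unique(flat).tolist()))
    code_pos = {c: j for j, c in enumerate(codes)}
    n = len(tracts)

    counts = np.zeros((n, len(codes)))
    inside = cell_tract >= 0
    cls = np.fromiter((code_pos[c] for c in flat[inside]), dtype=np.int64,
                      count=int(inside.sum()))
    np.add.at(counts, (cell_tract[inside], cls), 1.0)

    totals = counts.sum(axis=1)
    region = counts.sum(axis=0)
    region = region / region.sum() if region.sum() > 0 else np.full(len(codes), 1 / len(codes))
    props = np.empty_like(counts)
    degenerate = []
    for i in range(n):
        if totals[i] > 0:
            props[i] = counts[i] / totals[i]
        else:
            props[i] = region
            degenerate.append(tracts.ids[i])
    if degenerate:
        logger.warning("%d tracts have zero attributed raster cells", len(degenerate))

    cols = [landcover_column(c) for c in codes]
    df = pd.DataFrame(props, index=pd.Index(tracts.ids, name="tract_id"), columns=cols)
    return FeatureTable(df, provenance={c: "landcover" for c in cols}, m=1,
                        flags={"degenerate_tracts": degenerate})


def adjacency_features(
    raster: LandCoverRaster,
    tracts: TractSet,
    high_developed: frozenset[int] = HIGH_DEVELOPED_CODES,
    forest: frozenset[int] = FOREST_CODES,
    neighborhood: int = 4,
) -> FeatureTable:
    """Pixel-adjacency statistics capturing the spatial arrangement of land cover.

    For each tract, three features: the proportion of its high-developed
    pixels with at least one high-developed neighbor, the proportion of its
    high-developed pixels with at least one forest neighbor, and the
    proportion of its forest pixels with at least one forest neighbor.
    Neighbors are the 4-neighborhood by default (8 available); neighbors
    may lie outside the tract but not outside the raster.  Tracts with no
    focal pixels score 0.
    """
    if neighborhood not in (4, 8):
        raise InvalidParameterError("neighborhood must be 4 or 8")
    grid = raster.grid
    is_hd = np.isin(grid, list(high_developed))
    is_fo = np.isin(grid, list(forest))

    def has_neighbor(mask: np.ndarray) -> np.ndarray:
        out = np.zeros_like(mask)
        out[:-1, :] |= mask[1:, :]
        out[1:, :] |= mask[:-1, :]
        out[:, :-1] |= mask[:, 1:]
        out[:, 1:] |= mask[:, :-1]
        if neighborhood == 8:
            out[:-1, :-1] |= mask[1:, 1:]
            out[:-1, 1:] |= mask[1:, :-1]
            out[1:, :-1] |= mask[:-1, 1:]
            out[1:, 1:] |= mask[:-1, :-1]
        return out

    near_hd = has_neighbor(is_hd)
    near_fo = has_neighbor(is_fo)

    cell_tract = _cell_tract_assignment(raster, tracts)
    n = len(tracts)

    def tract_ratio(focal: np.ndarray, qualifying: np.ndarray) -> np.ndarray:
        f = focal.ravel()
        q = (focal & qualifying).ravel()
        inside = cell_tract >= 0
        nf = np.bincount(cell_tract[inside], weights=f[inside], minlength=n)
        nq = np.bincount(cell_tract[inside], weights=q[inside], minlength=n)
        return np.where(nf > 0, nq / np.maximum(nf, 1), 0.0)

    df = pd.DataFrame(
        {
            "highdev_adj_highdev": tract_ratio(is_hd, near_hd),
            "highdev_adj_forest": tract_ratio(is_hd, near_fo),
            "forest_adj_forest": tract_ratio(is_fo, near_fo),
        },
        index=pd.Index(tracts.ids, name="tract_id"),
    )
    return FeatureTable(df, provenance={c: "landcover" for c in ADJACENCY_COLUMNS}, m=1)


# ---------------------------------------------------------------------------
# Census features and merging
# ---------------------------------------------------------------------------

def census_features(census: CensusTable, tracts: TractSet | None = None) -> FeatureTable:
    """Pass the 20 demographic proportions through as features (never smoothed)."""
    df = census.data
    if tracts is not None:
        missing = [t for t in tracts.ids if t not in df.index]
        if missing:
            raise MissingDataError(f"census rows missing for tracts: {missing[:10]}")
        df = df.loc[tracts.ids]
    census_check = CensusTable(df)  # re-validate block sums on the selected rows
    return FeatureTable(census_check.data.copy(),
                        provenance={c: "census" for c in CENSUS_COLUMNS}, m=1)


def merge_features(
    parts: Sequence[FeatureTable],
    state_feature: bool = False,
    tracts: TractSet | None = None,
) -> FeatureTable:
    """Column-concatenate feature tables over an identical tract row set.

    With ``state_feature`` on, appends one integer-coded categorical state
    column (codes assigned by sorted state label; the code map is persisted
    on the result so it can be re-applied to new regions).
    """
    if not parts:
        raise InvalidParameterError("merge_features needs at least one part")
    row_sets = [tuple(p.tract_ids) for p in parts]
    if any(set(rs) != set(row_sets[0]) for rs in row_sets[1:]):
        raise AlignmentError("feature tables cover different tract sets")
    order = list(row_sets[0])

    seen: set[str] = set()
    for p in parts:
        dup = seen & set(p.data.columns)
        if dup:
            raise SchemaError(f"duplicate feature columns across parts: {sorted(dup)[:5]}")
        seen |= set(p.data.columns)

    df = pd.concat([p.data.loc[order] for p in parts], axis=1)
    prov: dict[str, str] = {}
    flags: dict[str, list[str]] = {}
    for p in parts:
        prov.update(p.provenance)
        for k, v in p.flags.items():
            flags.setdefault(k, []).extend(v)

    code_map = None
    if state_feature:
        if tracts is None:
            raise InvalidParameterError("state_feature requires the TractSet")
        if "state" in df.columns:
            raise SchemaError("a 'state' column already exists")
        states = {t.tract_id: t.state_code for t in tracts.tracts}
        missing = [t for t in order if t not in states]
        if missing:
            raise AlignmentError(f"tracts absent from TractSet: {missing[:5]}")
        code_map = {s: i for i, s in enumerate(sorted(set(states.values())))}
        df["state"] = [code_map[states[t]] for t in order]
        prov["state"] = "state"

    ms = {p.m for p in parts}
    return FeatureTable(df, provenance=prov, m=max(ms), flags=flags, state_code_map=code_map)
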