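"""Plain-text readers and writers for every pipeline artifact.

Formats: tracts as GeoJSON FeatureCollection; census, prevalence, feature
tables, keyword sets, rankings and neighbor indices as CSV; query logs as
JSON-lines; land-cover rasters as ESRI ASCII grid (the header carries the
georeference: lower-left origin and cell size).  All writers emit
deterministic byte streams for identical inputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping, shape

from .errors import InvalidInputError
from .feature_engineering import FeatureTable, NeighborIndex
from .keyword_selection import KeywordSet, RankedTerms
from .synthetic_city import (
    CensusTable,
    LandCoverRaster,
    PrevalenceTable,
    QueryLog,
    Tract,
    TractSet,
)

_FLOAT_FMT = "%.10g"


# -- tracts ------------------------------------------------------------------

def write_tracts_geojson(tracts: TractSet, path: str | Path) -> None:
    features = []
    for t in tracts.tracts:
        features.append({
            "type": "Feature",
            "geometry": mapping(t.polygon),
            "properties": {
                "tract_id": t.tract_id,
                "state_code": t.state_code,
                "population": t.population,
                "area_km2": round(t.area, 10),
            },
        })
    doc = {
        "type": "FeatureCollection",
        "bbox": list(tracts.region_bounds),
        "features": features,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, separators=(",", ":")) + "\n")


def read_tracts_geojson(path: str | Path) -> TractSet:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise InvalidInputError(f"{path}: not a GeoJSON FeatureCollection")
    tracts = []
    for feat in doc["features"]:
        props = feat["properties"]
        geom = shape(feat["geometry"])
        if not isinstance(geom, Polygon):
            raise InvalidInputError(f"tract {props.get('tract_id')}: geometry is not a Polygon")
        tracts.append(Tract(
            tract_id=str(props["tract_id"]),
            state_code=str(props["state_code"]),
            polygon=geom,
            population=int(props["population"]),
        ))
    bbox = doc.get("bbox")
    if bbox is None:
        xs = [t.polygon.bounds for t in tracts]
        bbox = [min(b[0] for b in xs), min(b[1] for b in xs),
                max(b[2] for b in xs), max(b[3] for b in xs)]
    return TractSet(tracts, tuple(float(v) for v in bbox))


# -- tabular -----------------------------------------------------------------

def write_census_csv(census: CensusTable, path: str | Path) -> None:
    census.data.to_csv(path, float_format=_FLOAT_FMT)


def read_census_csv(path: str | Path) -> CensusTable:
    return CensusTable(pd.read_csv(path, index_col="tract_id"))


def write_prevalence_csv(prev: PrevalenceTable, path: str | Path) -> None:
    prev.data.to_csv(path, float_format=_FLOAT_FMT)


def read_prevalence_csv(path: str | Path) -> PrevalenceTable:
    return PrevalenceTable(pd.read_csv(path, index_col="tract_id"))


def write_features_csv(table: FeatureTable, path: str | Path) -> None:
    out = table.data.copy()
    out.index.name = "tract_id"
    out.to_csv(path, float_format=_FLOAT_FMT)


def read_features_csv(path: str | Path, provenance: Mapping[str, str] | None = None,
                      m: int = 1) -> FeatureTable:
    df = pd.read_csv(path, index_col="tract_id")
    df.index = df.index.astype(str)
    return FeatureTable(df, provenance=dict(provenance or {}), m=m)


# -- query log ---------------------------------------------------------------

def write_querylog_jsonl(log: QueryLog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, t, toks in zip(log.user_ids, log.tract_ids, log.tokens):
            fh.write(json.dumps({"user_id": u, "tract_id": t, "tokens": list(toks)},
                                sort_keys=True, separators=(",", ":")) + "\n")


def read_querylog_jsonl(path: str | Path) -> QueryLog:
    users, tracts_, tokens = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            users.append(rec["user_id"])
            tracts_.append(rec["tract_id"])
            tokens.append(tuple(rec["tokens"]))
    return QueryLog(users, tracts_, tokens)


# -- raster (ESRI ASCII grid) ------------------------------------------------

def write_raster_asc(raster: LandCoverRaster, path: str | Path) -> None:
    nrows, ncols = raster.grid.shape
    x0, y0 = raster.origin
    lines = [
        f"ncols {ncols}",
        f"nrows {nrows}",
        f"xllcorner {x0:.10g}",
        f"yllcorner {y0:.10g}",
        f"cellsize {raster.cell_km:.10g}",
        "NODATA_value -9999",
    ]
    # ASCII grid rows run north to south; our row 0 is the southernmost.
    for r in range(nrows - 1, -1, -1):
        lines.append(" ".join(str(int(v)) for v in raster.grid[r]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_raster_asc(path: str | Path) -> LandCoverRaster:
    text = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    row_lines: list[str] = []
    for line in text:
        parts = line.split()
        if not parts:
            continue
        if parts[0].lower() in {"ncols", "nrows", "xllcorner", "yllcorner",
                                "cellsize", "nodata_value"}:
            header[parts[0].lower()] = float(parts[1])
        else:
            row_lines.append(line)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    grid = np.array([[int(v) for v in line.split()] for line in row_lines], dtype=np.int32)
    if grid.shape != (nrows, ncols):
        raise InvalidInputError(f"{path}: grid shape {grid.shape} disagrees with header")
    return LandCoverRaster(
        grid=grid[::-1],  # back to south-up row order
        cell_km=float(header["cellsize"]),
        origin=(float(header["xllcorner"]), float(header["yllcorner"])),
    )


# -- keywords and rankings ---------------------------------------------------

def write_keywords_csv(keywords: Mapping[str, str], path: str | Path) -> None:
    df = pd.DataFrame(sorted(keywords.items()), columns=["keyword", "category"])
    df.to_csv(path, index=False)


def read_keywords_csv(path: str | Path) -> KeywordSet:
    df = pd.read_csv(path)
    return KeywordSet(dict(zip(df["keyword"], df["category"])))


def write_ranked_terms_csv(ranked: RankedTerms, path: str | Path) -> None:
    rows = [{"rank": i + 1, "term": t, "score": s} for i, (t, s) in enumerate(ranked.terms)]
    pd.DataFrame(rows, columns=["rank", "term", "score"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT)


def read_ranked_terms_csv(path: str | Path, seed_terms: tuple[str, ...] = ()) -> RankedTerms:
    df = pd.read_csv(path).sort_values("rank")
    return RankedTerms([(str(t), float(s)) for t, s in zip(df["term"], df["score"])],
                       seed_terms)


# -- neighbor index ----------------------------------------------------------

def write_neighbor_index_csv(index: NeighborIndex, path: str | Path) -> None:
    rows = []
    for t in sorted(index.index):
        for rank, nb in enumerate(index.index[t], start=1):
            rows.append({"tract_id": t, "rank": rank, "neighbor_id": nb})
    pd.DataFrame(rows, columns=["tract_id", "rank", "neighbor_id"]).to_csv(path, index=False)


def read_neighbor_index_csv(path: str | Path) -> NeighborIndex:
    df = pd.read_csv(path, dtype={"tract_id": str, "neighbor_id": str})
    idx: dict[str, list[str]] = {}
    for t, group in df.sort_values(["tract_id", "rank"]).groupby("tract_id", sort=True):
        idx[str(t)] = [str(n) for n in group["neighbor_id"]]
    ms = {len(v) for v in idx.values()}
    if len(ms) != 1:
        raise InvalidInputError("neighbor lists have inconsistent lengths")
    return NeighborIndex(index=idx, m=ms.pop())
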