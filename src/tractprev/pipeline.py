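"""End-to-end experiment orchestration.

Runs the full study design on one region: tract filtering (data
completeness, then a privacy floor on distinct users), feature
construction for the four model variants (search; search + state;
search + land; search + land + census + state), m-nearest-tract
smoothing with a single shared neighbor index per m, the m-sweep
diagnostic, cross-validated evaluation, and deterministic report files.

Two evaluation modes are deliberately kept apart and labeled: the m-sweep
reports training-data correlation (a smoothing diagnostic), while variant
comparisons always use held-out cross-validation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as tpio
from .errors import EmptyResultError, InvalidParameterError
from .estimation import CVResult, FittedModel, ModelConfig, cross_validate, fit_forest, pearson_correlation
from .feature_engineering import (
    FeatureTable,
    NeighborIndex,
    adjacency_features,
    category_sums,
    census_features,
    landcover_proportions,
    merge_features,
    nearest_neighbors,
    neighbor_smooth,
    normalized_counts,
)
from .keyword_selection import KeywordSet
from .synthetic_city import (
    CensusTable,
    LandCoverRaster,
    PrevalenceTable,
    QueryLog,
    TractSet,
)
from .vocab import DEFAULT_KEYWORDS

logger = logging.getLogger(__name__)

VARIANTS = ("search", "search_state", "search_land", "search_land_census")
EXCLUSION_REASONS = ("missing_census", "missing_landcover", "under_privacy_threshold")
DEFAULT_M = 8
DEFAULT_M_SWEEP = (1, 4, 8, 16, 32)
DEFAULT_PRIVACY_THRESHOLD = 50


@dataclass
class ExperimentConfig:
    """File-based experiment description (YAML-loadable)."""

    tracts: str
    queries: str
    census: str
    raster: str
    prevalence: str
    keywords: str | None = None
    out_dir: str = "experiment_out"
    m: int = DEFAULT_M
    m_values: tuple[int, ...] = DEFAULT_M_SWEEP
    variants: tuple[str, ...] = VARIANTS
    outcomes: tuple[str, ...] | None = None
    privacy_threshold: int = DEFAULT_PRIVACY_THRESHOLD
    seed: int = 0
    n_trees: int = 500
    min_leaf: int = 5
    k_folds: int = 5
    run_sweep: bool = False

    def __post_init__(self) -> None:
        bad = [v for v in self.variants if v not in VARIANTS]
        if bad:
            raise InvalidParameterError(f"unknown variants: {bad}")
        if self.privacy_threshold < 1:
            raise InvalidParameterError("privacy_threshold must be at least 1")
        if any(m < 1 for m in self.m_values) or self.m < 1:
            raise InvalidParameterError("m values must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("m_values", "variants", "outcomes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def canonical_json(self) -> str:
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        return json.dumps(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]

    def model_config(self, seed_offset: int = 0) -> ModelConfig:
        return ModelConfig(n_trees=self.n_trees, min_leaf=self.min_leaf,
                           seed=self.seed + seed_offset, k_folds=self.k_folds)


@dataclass
class ExperimentReport:
    """Per-variant metrics, m-sweep table, exclusion ledger, importances."""

    variant_metrics: pd.DataFrame          # variant, outcome, correlation, mae
    exclusions: pd.DataFrame               # tract_id, reason
    n_retained: int
    importances: dict[tuple[str, str], pd.Series]
    cv_results: dict[tuple[str, str], CVResult]
    m_sweep: pd.DataFrame | None = None    # m, outcome, source, correlation
    config_hash: str | None = None


# ---------------------------------------------------------------------------
# Tract filtering
# ---------------------------------------------------------------------------

def filter_tracts(
    tracts: TractSet,
    log: QueryLog,
    census: CensusTable,
    raster: LandCoverRaster,
    threshold: int = DEFAULT_PRIVACY_THRESHOLD,
) -> tuple[TractSet, pd.DataFrame]:
    """Retain tracts with complete data and enough distinct users.

    A tract is kept when it has a complete census row, at least one
    attributed raster cell, and a distinct-user count >= ``threshold``.
    Each excluded tract gets its first matching reason in the order:
    missing_census, missing_landcover, under_privacy_threshold.  Retained
    set and ledger partition the input tract set.
    """
    if threshold < 1:
        raise InvalidParameterError("threshold must be at least 1")

    census_ok = {
        t for t in census.data.index
        if not census.data.loc[t].isna().any()
    }
    from .feature_engineering import _cell_tract_assignment
    cell_tract = _cell_tract_assignment(raster, tracts)
    covered = {tracts.ids[i] for i in np.unique(cell_tract[cell_tract >= 0])}
    users = log.unique_user_counts()

    retained_ids = []
    rows = []
    for t in tracts.ids:
        if t not in census_ok:
            rows.append({"tract_id": t, "reason": "missing_census"})
        elif t not in covered:
            rows.append({"tract_id": t, "reason": "missing_landcover"})
        elif int(users.get(t, 0)) < threshold:
            rows.append({"tract_id": t, "reason": "under_privacy_threshold"})
        else:
            retained_ids.append(t)

    ledger = pd.DataFrame(rows, columns=["tract_id", "reason"])
    logger.info("filter_tracts: retained %d of %d tracts (%d excluded)",
                len(retained_ids), len(tracts), len(ledger))
    return tracts.subset(retained_ids), ledger


def _subset_log(log: QueryLog, tracts: TractSet) -> QueryLog:
    keep = set(tracts.ids)
    mask = np.fromiter((t in keep for t in log.tract_ids), dtype=bool, count=len(log))
    idx = np.nonzero(mask)[0]
    return QueryLog(log.user_ids[idx], log.tract_ids[idx],
                    [log.tokens[i] for i in idx])


# ---------------------------------------------------------------------------
# Variant feature assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureBundle:
    """Raw per-source feature tables for one retained tract set."""

    query_raw: FeatureTable
    landcover_raw: FeatureTable | None
    census: FeatureTable | None
    tracts: TractSet

    def smoothed(self, index: NeighborIndex | None):
        q = neighbor_smooth(self.query_raw, index) if index else self.query_raw
        lc = (neighbor_smooth(self.landcover_raw, index)
              if (index and self.landcover_raw is not None) else self.landcover_raw)
        return q, lc


def build_feature_bundle(
    tracts: TractSet,
    log: QueryLog,
    keywords: Mapping[str, str],
    raster: LandCoverRaster | None = None,
    census: CensusTable | None = None,
) -> FeatureBundle:
    """Compute raw (unsmoothed) feature tables for every source once."""
    q = category_sums(normalized_counts(log, keywords, tracts), keywords)
    lc = None
    if raster is not None:
        lc = merge_features([landcover_proportions(raster, tracts),
                             adjacency_features(raster, tracts)])
    cen = census_features(census, tracts) if census is not None else None
    return FeatureBundle(q, lc, cen, tracts)


def variant_features(
    bundle: FeatureBundle,
    variant: str,
    index: NeighborIndex | None,
) -> FeatureTable:
    """Assemble the design matrix for one model variant.

    Query and land-cover features are smoothed with the shared neighbor
    index; census features never are.
    """
    if variant not in VARIANTS:
        raise InvalidParameterError(f"unknown variant {variant!r}")
    q, lc = bundle.smoothed(index)
    parts: list[FeatureTable] = [q]
    state = variant in ("search_state", "search_land_census")
    if variant in ("search_land", "search_land_census"):
        if lc is None:
            raise InvalidParameterError(f"variant {variant!r} needs a land-cover raster")
        parts.append(lc)
    if variant == "search_land_census":
        if bundle.census is None:
            raise InvalidParameterError("variant 'search_land_census' needs census data")
        parts.append(bundle.census)
    return merge_features(parts, state_feature=state, tracts=bundle.tracts)


# ---------------------------------------------------------------------------
# m-sweep (training-data correlation diagnostic)
# ---------------------------------------------------------------------------

def sweep_m(
    bundle: FeatureBundle,
    prevalence: PrevalenceTable,
    outcomes: Sequence[str],
    m_values: Sequence[int] = DEFAULT_M_SWEEP,
    source: str = "search",
    model_config: ModelConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Training-data correlation for each smoothing radius m.

    Fits on all retained tracts and correlates in-sample predictions with
    the target — a smoothing diagnostic, not a generalization estimate
    (variant comparison uses cross-validation instead).  Returns the sweep
    table and the argmax m per outcome.
    """
    if source not in ("search", "land"):
        raise InvalidParameterError("source must be 'search' or 'land'")
    if source == "land" and bundle.landcover_raw is None:
        raise InvalidParameterError("land sweep needs a land-cover raster")
    n = len(bundle.tracts)
    if any(m > n for m in m_values):
        raise InvalidParameterError(f"m values must not exceed the tract count {n}")
    model_config = model_config or ModelConfig()

    prev = PrevalenceTable(prevalence.data.loc[bundle.tracts.ids])
    rows = []
    for m in m_values:
        index = nearest_neighbors(bundle.tracts, m)
        q, lc = bundle.smoothed(index)
        table = q if source == "search" else lc
        for outcome in outcomes:
            model = fit_forest(table, prev, outcome, model_config)
            pred = model.predict(table)
            r = pearson_correlation(pred.to_numpy(),
                                    prev.data.loc[table.tract_ids, outcome].to_numpy())
            rows.append({"m": m, "outcome": outcome, "source": source, "correlation": r})
    sweep = pd.DataFrame(rows, columns=["m", "outcome", "source", "correlation"])
    best = {
        o: int(sweep[sweep.outcome == o].sort_values(["correlation", "m"],
                                                     ascending=[False, True]).iloc[0]["m"])
        for o in outcomes
    }
    return sweep, best


# ---------------------------------------------------------------------------
# Full experiment
# ---------------------------------------------------------------------------

def run_variants(
    tracts: TractSet,
    log: QueryLog,
    census: CensusTable,
    raster: LandCoverRaster,
    prevalence: PrevalenceTable,
    keywords: Mapping[str, str] | None = None,
    variants: Sequence[str] = VARIANTS,
    outcomes: Sequence[str] | None = None,
    m: int = DEFAULT_M,
    privacy_threshold: int = DEFAULT_PRIVACY_THRESHOLD,
    model_config: ModelConfig | None = None,
    m_values: Sequence[int] | None = None,
) -> ExperimentReport:
    """Filter, featurize and cross-validate every variant x outcome.

    The in-memory core of ``run_experiment``; the file-based entry point
    wraps it with I/O.
    """
    keywords = KeywordSet(keywords if keywords is not None else DEFAULT_KEYWORDS)
    outcomes = tuple(outcomes if outcomes is not None else prevalence.outcomes)
    model_config = model_config or ModelConfig()

    retained, ledger = filter_tracts(tracts, log, census, raster, privacy_threshold)
    if len(retained) == 0:
        raise EmptyResultError("no tracts survive filtering")
    if m > len(retained):
        raise InvalidParameterError(f"m={m} exceeds retained tract count {len(retained)}")

    log_r = _subset_log(log, retained)
    prev_r = PrevalenceTable(prevalence.data.loc[retained.ids])
    bundle = build_feature_bundle(retained, log_r, keywords, raster, census)
    index = nearest_neighbors(retained, m)

    rows = []
    importances: dict[tuple[str, str], pd.Series] = {}
    cv_results: dict[tuple[str, str], CVResult] = {}
    for variant in variants:
        table = variant_features(bundle, variant, index)
        for outcome in outcomes:
            cv = cross_validate(table, prev_r, outcome, model_config)
            rows.append({"variant": variant, "outcome": outcome,
                         "correlation": cv.correlation, "mae": cv.mae})
            importances[(variant, outcome)] = cv.importances
            cv_results[(variant, outcome)] = cv
            logger.info("variant=%s outcome=%s r=%.3f mae=%.3f",
                        variant, outcome, cv.correlation, cv.mae)

    sweep_table = None
    if m_values:
        sweep_table, _ = sweep_m(bundle, prev_r, outcomes, m_values,
                                 source="search", model_config=model_config)

    return ExperimentReport(
        variant_metrics=pd.DataFrame(rows, columns=["variant", "outcome", "correlation", "mae"]),
        exclusions=ledger,
        n_retained=len(retained),
        importances=importances,
        cv_results=cv_results,
        m_sweep=sweep_table,
    )


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """File-based experiment: read inputs, run all variants, write reports.

    Outputs under ``config.out_dir``: report.json (metrics, sweep,
    exclusion counts, config hash), exclusions.csv, and per variant x
    outcome a predictions CSV (tract_id, fold, actual, predicted) and an
    importances CSV (rank, feature, importance).  Reruns with identical
    config and inputs produce byte-identical files.
    """
    for name in ("tracts", "queries", "census", "raster", "prevalence"):
        p = Path(getattr(config, name))
        if not p.exists():
            raise FileNotFoundError(f"input file for {name!r} not readable: {p}")

    tracts = tpio.read_tracts_geojson(config.tracts)
    log = tpio.read_querylog_jsonl(config.queries)
    census = tpio.read_census_csv(config.census)
    raster = tpio.read_raster_asc(config.raster)
    prevalence = tpio.read_prevalence_csv(config.prevalence)
    keywords = (tpio.read_keywords_csv(config.keywords)
                if config.keywords else KeywordSet(DEFAULT_KEYWORDS))

    logger.info("run_experiment: seed=%d config_hash=%s", config.seed, config.config_hash())
    report = run_variants(
        tracts, log, census, raster, prevalence,
        keywords=keywords,
        variants=config.variants,
        outcomes=config.outcomes,
        m=config.m,
        privacy_threshold=config.privacy_threshold,
        model_config=config.model_config(),
        m_values=config.m_values if config.run_sweep else None,
    )
    report.config_hash = config.config_hash()
    write_report(report, config.out_dir)
    return report


def write_report(report: ExperimentReport, out_dir: str | Path) -> None:
    """Persist an ExperimentReport as deterministic JSON and CSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    doc = {
        "config_hash": report.config_hash,
        "n_retained": report.n_retained,
        "n_excluded": int(len(report.exclusions)),
        "exclusion_counts": {
            r: int((report.exclusions["reason"] == r).sum()) for r in EXCLUSION_REASONS
        },
        "metrics": [
            {k: (round(v, 12) if isinstance(v, float) else v) for k, v in row.items()}
            for row in report.variant_metrics.to_dict("records")
        ],
        "m_sweep": (
            [{k: (round(v, 12) if isinstance(v, float) else v) for k, v in row.items()}
             for row in report.m_sweep.to_dict("records")]
            if report.m_sweep is not None else None
        ),
    }
    (out / "report.json").write_text(json.dumps(doc, sort_keys=True, indent=2) + "\n")
    report.exclusions.to_csv(out / "exclusions.csv", index=False)
    report.variant_metrics.to_csv(out / "metrics.csv", index=False, float_format="%.12g")

    for (variant, outcome), cv in report.cv_results.items():
        cv.predictions_frame().to_csv(
            out / f"predictions_{variant}_{outcome}.csv", index=False, float_format="%.12g")
        imp = report.importances[(variant, outcome)]
        imp_df = pd.DataFrame({
            "rank": np.arange(1, len(imp) + 1),
            "feature": imp.index,
            "importance": imp.to_numpy(),
        })
        imp_df.to_csv(out / f"importances_{variant}_{outcome}.csv",
                      index=False, float_format="%.12g")
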