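"""Synthetic study region generator.

Builds a desk-scale stand-in for the real study inputs: a tiling of a
planar region into census-tract-like polygons, per-tract demographic
proportion tables, a categorical land-cover raster, per-tract ground-truth
prevalence percentages for asthma and COPD, and a geo-assigned,
user-attributed search-query log whose keyword rates carry a tunable
prevalence signal.

Coordinates are planar kilometres (not lon/lat): synthetic regions are
small, and every downstream distance computation is Euclidean.  Defaults
approximate the real-data scale of the study setting: median tract area
about 2.45 km2 and median population 3652.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon

from .errors import InvalidInputError, InvalidParameterError
from .vocab import BACKGROUND_VOCAB, DEFAULT_KEYWORDS, SEED_TERMS

# ---------------------------------------------------------------------------
# Land-cover class codes (NLCD-style: 8 main classes, 20 sub-classes)
# ---------------------------------------------------------------------------

LANDCOVER_CLASSES: dict[int, str] = {
    11: "open_water",
    12: "perennial_ice_snow",
    21: "developed_open",
    22: "developed_low",
    23: "developed_medium",
    24: "developed_high",
    31: "barren",
    41: "forest_deciduous",
    42: "forest_evergreen",
    43: "forest_mixed",
    51: "shrub_dwarf",
    52: "shrub",
    71: "grassland",
    72: "sedge",
    73: "lichens",
    74: "moss",
    81: "pasture_hay",
    82: "cultivated_crops",
    90: "wetlands_woody",
    95: "wetlands_herbaceous",
}

HIGH_DEVELOPED_CODES: frozenset[int] = frozenset({24})
FOREST_CODES: frozenset[int] = frozenset({41, 42, 43})

#: Urban-leaning default mixture over the 20 sub-classes.
DEFAULT_CLASS_WEIGHTS: dict[int, float] = {
    11: 0.03, 12: 0.001, 21: 0.12, 22: 0.14, 23: 0.12, 24: 0.10,
    31: 0.02, 41: 0.08, 42: 0.05, 43: 0.04, 51: 0.01, 52: 0.03,
    71: 0.06, 72: 0.005, 73: 0.002, 74: 0.002, 81: 0.08, 82: 0.08,
    90: 0.03, 95: 0.02,
}

# ---------------------------------------------------------------------------
# Census indicator schema: 20 proportions in four blocks
# ---------------------------------------------------------------------------

AGE_COLUMNS: tuple[str, ...] = (
    "age_under5", "age_5_17", "age_18_24", "age_25_34", "age_35_44",
    "age_45_54", "age_55_64", "age_65_74", "age_75_plus",
)
GENDER_COLUMNS: tuple[str, ...] = ("gender_male", "gender_female")
RACE_COLUMNS: tuple[str, ...] = (
    "race_white", "race_black", "race_native", "race_asian",
    "race_pacific", "race_other", "race_two_plus", "race_hispanic",
)
POVERTY_COLUMN: str = "poverty"
CENSUS_COLUMNS: tuple[str, ...] = (
    AGE_COLUMNS + GENDER_COLUMNS + RACE_COLUMNS + (POVERTY_COLUMN,)
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Tract:
    """One spatial unit: a simple polygon with population and state label."""

    tract_id: str
    state_code: str
    polygon: Polygon
    population: int

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return (c.x, c.y)

    @property
    def area(self) -> float:
        return self.polygon.area


class TractSet:
    """Ordered collection of tracts tiling a rectangular region."""

    def __init__(self, tracts: Sequence[Tract], region_bounds: tuple[float, float, float, float]):
        ids = [t.tract_id for t in tracts]
        if len(set(ids)) != len(ids):
            raise InvalidInputError("tract_ids must be unique within a TractSet")
        self.tracts: list[Tract] = list(tracts)
        self.region_bounds = region_bounds  # (xmin, ymin, xmax, ymax)
        self._by_id = {t.tract_id: t for t in self.tracts}

    def __len__(self) -> int:
        return len(self.tracts)

    def __iter__(self) -> Iterator[Tract]:
        return iter(self.tracts)

    def __getitem__(self, tract_id: str) -> Tract:
        return self._by_id[tract_id]

    def __contains__(self, tract_id: str) -> bool:
        return tract_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [t.tract_id for t in self.tracts]

    @property
    def centroids(self) -> np.ndarray:
        """(n, 2) array of tract centroids in km."""
        return np.array([t.centroid for t in self.tracts])

    @property
    def populations(self) -> np.ndarray:
        return np.array([t.population for t in self.tracts])

    @property
    def state_codes(self) -> list[str]:
        return [t.state_code for t in self.tracts]

    def subset(self, keep_ids: Iterable[str]) -> "TractSet":
        keep = set(keep_ids)
        return TractSet([t for t in self.tracts if t.tract_id in keep], self.region_bounds)


@dataclass(frozen=True)
class QueryEvent:
    """A single search query: who issued it, from which tract, which tokens."""

    user_id: str
    tract_id: str
    tokens: tuple[str, ...]


class QueryLog:
    """Columnar store of query events with a per-tract index.

    Kept columnar (parallel arrays plus a list of token tuples) so that
    desk-scale logs with millions of events stay cheap to aggregate.
    """

    def __init__(self, user_ids: Sequence[str], tract_ids: Sequence[str],
                 tokens: Sequence[tuple[str, ...]]):
        if not (len(user_ids) == len(tract_ids) == len(tokens)):
            raise InvalidInputError("user_ids, tract_ids and tokens must be parallel")
        for toks in tokens:
            if len(toks) == 0:
                raise InvalidInputError("every query must have at least one token")
        self.user_ids = np.asarray(user_ids, dtype=object)
        self.tract_ids = np.asarray(tract_ids, dtype=object)
        self.tokens: list[tuple[str, ...]] = [tuple(t) for t in tokens]

    def __len__(self) -> int:
        return len(self.tokens)

    def events(self) -> Iterator[QueryEvent]:
        for u, t, toks in zip(self.user_ids, self.tract_ids, self.tokens):
            yield QueryEvent(u, t, toks)

    def event_counts(self) -> pd.Series:
        """Number of query events per tract."""
        return pd.Series(self.tract_ids).value_counts().sort_index()

    def unique_user_counts(self) -> pd.Series:
        """Number of distinct users per tract (the privacy-filter quantity)."""
        df = pd.DataFrame({"tract": self.tract_ids, "user": self.user_ids})
        return df.groupby("tract")["user"].nunique().sort_index()

    def sentences(self) -> list[tuple[str, ...]]:
        """Token sequences only, for embedding training."""
        return self.tokens


@dataclass
class CensusTable:
    """Per-tract demographic proportions: 9 age, 2 gender, 8 race, 1 poverty.

    Each block of proportions sums to 1 per tract; poverty is a single
    proportion in [0, 1].
    """

    data: pd.DataFrame  # index tract_id, columns CENSUS_COLUMNS

    def __post_init__(self) -> None:
        missing = [c for c in CENSUS_COLUMNS if c not in self.data.columns]
        if missing:
            raise InvalidInputError(f"census table missing columns: {missing}")
        self.validate()

    def validate(self) -> None:
        for cols in (AGE_COLUMNS, GENDER_COLUMNS, RACE_COLUMNS):
            sums = self.data[list(cols)].sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise InvalidInputError(f"block {cols[0]}.. does not sum to 1")
        pov = self.data[POVERTY_COLUMN]
        if ((pov < 0) | (pov > 1)).any():
            raise InvalidInputError("poverty proportion outside [0, 1]")


@dataclass
class PrevalenceTable:
    """Per-tract outcome prevalences in percent, one column per outcome."""

    data: pd.DataFrame  # index tract_id, columns outcome names, percent

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if ((vals < 0) | (vals > 100)).any():
            raise InvalidInputError("prevalence values must lie in [0, 100]")

    @property
    def outcomes(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class LandCoverRaster:
    """Categorical land-cover grid aligned to the tract plane.

    ``grid[r, c]`` holds an integer class code; row 0 is the southernmost
    row.  ``origin`` is the (x, y) of the grid's lower-left corner in km and
    ``cell_km`` the square cell edge.
    """

    grid: np.ndarray  # (nrows, ncols) int
    cell_km: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int32)
        if self.grid.ndim != 2:
            raise InvalidInputError("raster grid must be 2-D")
        if self.cell_km <= 0:
            raise InvalidParameterError("cell_km must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def cell_centers(self) -> np.ndarray:
        """(nrows*ncols, 2) array of cell-center coordinates in km."""
        nrows, ncols = self.grid.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncols) + 0.5) * self.cell_km
        ys = y0 + (np.arange(nrows) + 0.5) * self.cell_km
        xx, yy = np.meshgrid(xs, ys)
        return np.column_stack([xx.ravel(), yy.ravel()])


@dataclass
class GenerativeTruth:
    """The coefficients a prevalence table was generated from, for recovery tests."""

    base: dict[str, float]
    coefficients: dict[str, dict[str, float]]
    state_offsets: dict[str, dict[str, float]]
    noise_sd: float


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

#: Median tract area (km2) and population matched to the real-data scale.
DEFAULT_MEDIAN_AREA_KM2 = 2.45
DEFAULT_MEDIAN_POPULATION = 3652


def generate_tracts(
    n_tracts: int,
    region_size: float | None = None,
    jitter: float = 0.25,
    seed: int = 0,
    n_states: int = 4,
    population_median: int = DEFAULT_MEDIAN_POPULATION,
    population_sigma: float = 0.55,
) -> TractSet:
    """Tile a square region into ``n_tracts`` jittered rectangular tracts.

    The region is cut into rows of near-equal height and each row into
    cells; interior cut positions are perturbed by ``jitter`` (a fraction
    of the unperturbed cell size, in [0, 0.5)), so the polygons remain a
    tiling by construction.  State codes are assigned in contiguous
    row-major blocks so that the state label carries a learnable spatial
    baseline.  Populations are log-normal around ``population_median``.

    With ``region_size`` omitted, the region edge is chosen so the mean
    tract area equals the real-data median of 2.45 km2.
    """
    if n_tracts < 2:
        raise InvalidParameterError("n_tracts must be at least 2")
    if region_size is None:
        region_size = math.sqrt(n_tracts * DEFAULT_MEDIAN_AREA_KM2)
    if region_size <= 0:
        raise InvalidParameterError("region_size must be positive")
    if not (0.0 <= jitter < 0.5):
        raise InvalidParameterError("jitter must lie in [0, 0.5)")
    if n_states < 1:
        raise InvalidParameterError("n_states must be at least 1")

    rng = np.random.default_rng(seed)
    size = float(region_size)

    n_rows = max(1, round(math.sqrt(n_tracts)))
    # Distribute tract counts over rows as evenly as possible.
    base_count, extra = divmod(n_tracts, n_rows)
    row_counts = [base_count + (1 if r < extra else 0) for r in range(n_rows)]

    # Row boundaries: equal heights with jittered interior cuts.
    y_cuts = np.linspace(0.0, size, n_rows + 1)
    row_h = size / n_rows
    y_cuts[1:-1] += rng.uniform(-jitter, jitter, size=max(0, n_rows - 1)) * row_h

    tracts: list[Tract] = []
    width = len(str(n_tracts))
    idx = 0
    for r in range(n_rows):
        c_r = row_counts[r]
        x_cuts = np.linspace(0.0, size, c_r + 1)
        cell_w = size / c_r
        x_cuts[1:-1] += rng.uniform(-jitter, jitter, size=max(0, c_r - 1)) * cell_w
        for c in range(c_r):
            poly = Polygon([
                (x_cuts[c], y_cuts[r]),
                (x_cuts[c + 1], y_cuts[r]),
                (x_cuts[c + 1], y_cuts[r + 1]),
                (x_cuts[c], y_cuts[r + 1]),
            ])
            tracts.append(Tract(
                tract_id=f"T{idx:0{width}d}",
                state_code="",  # assigned below
                polygon=poly,
                population=0,
            ))
            idx += 1

    # Contiguous state blocks over the row-major order.
    state_blocks = np.array_split(np.arange(n_tracts), n_states)
    state_of = {}
    for s, block in enumerate(state_blocks):
        for i in block:
            state_of[i] = f"S{s:02d}"

    pops = np.exp(rng.normal(math.log(population_median), population_sigma, size=n_tracts))
    pops = np.maximum(50, np.round(pops)).astype(int)

    finished = [
        Tract(t.tract_id, state_of[i], t.polygon, int(pops[i]))
        for i, t in enumerate(tracts)
    ]
    return TractSet(finished, (0.0, 0.0, size, size))


def generate_census(
    tracts: TractSet,
    concentration: float = 5.0,
    poverty_range: tuple[float, float] = (0.05, 0.35),
    seed: int = 0,
) -> CensusTable:
    """Draw per-tract demographic proportions.

    Each block (age, gender, race) is an independent symmetric Dirichlet
    with the given concentration per component; large concentrations pull
    every block toward its uniform vector.  Poverty is uniform on
    ``poverty_range``.
    """
    if len(tracts) == 0:
        raise InvalidInputError("TractSet is empty")
    if concentration <= 0:
        raise InvalidParameterError("concentration must be positive")
    lo, hi = poverty_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise InvalidParameterError("poverty_range must be an interval within [0, 1]")

    rng = np.random.default_rng(seed)
    n = len(tracts)
    blocks = {}
    for cols in (AGE_COLUMNS, GENDER_COLUMNS, RACE_COLUMNS):
        draw = rng.dirichlet(np.full(len(cols), concentration), size=n)
        for j, c in enumerate(cols):
            blocks[c] = draw[:, j]
    blocks[POVERTY_COLUMN] = rng.uniform(lo, hi, size=n)
    df = pd.DataFrame(blocks, index=pd.Index(tracts.ids, name="tract_id"))
    return CensusTable(df[list(CENSUS_COLUMNS)])


def generate_landcover(
    tracts: TractSet,
    cell_km: float = 0.25,
    class_weights: Mapping[int, float] | None = None,
    clumping: float = 2.0,
    seed: int = 0,
) -> LandCoverRaster:
    """Generate a categorical land-cover raster covering the region.

    ``clumping = 0`` draws cells i.i.d. from the weight mixture.  For
    ``clumping > 0`` each class gets a Gaussian-smoothed noise field
    (sigma = clumping, in cells) offset by its log weight, and each cell
    takes the argmax class, which produces spatially coherent patches
    whose typical size grows with ``clumping``.
    """
    if len(tracts) == 0:
        raise InvalidInputError("TractSet is empty")
    if cell_km <= 0:
        raise InvalidParameterError("cell_km must be positive")
    if clumping < 0:
        raise InvalidParameterError("clumping must be non-negative")
    if class_weights is None:
        class_weights = DEFAULT_CLASS_WEIGHTS
    codes = np.array(sorted(class_weights), dtype=np.int32)
    weights = np.array([float(class_weights[int(c)]) for c in codes])
    if (weights < 0).any():
        raise InvalidParameterError("class weights must be non-negative")
    positive = weights > 0
    if not positive.any():
        raise InvalidParameterError("at least one class weight must be positive")
    codes, weights = codes[positive], weights[positive]
    probs = weights / weights.sum()

    xmin, ymin, xmax, ymax = tracts.region_bounds
    ncols = max(1, math.ceil((xmax - xmin) / cell_km))
    nrows = max(1, math.ceil((ymax - ymin) / cell_km))

    rng = np.random.default_rng(seed)
    if len(codes) == 1:
        grid = np.full((nrows, ncols), codes[0], dtype=np.int32)
    elif clumping == 0:
        grid = rng.choice(codes, size=(nrows, ncols), p=probs)
    else:
        score = np.empty((len(codes), nrows, ncols))
        for j in range(len(codes)):
            f = gaussian_filter(rng.standard_normal((nrows, ncols)), sigma=clumping, mode="wrap")
            f /= max(f.std(), 1e-12)  # renormalise: smoothing shrinks variance
            score[j] = f + np.log(probs[j])
        grid = codes[np.argmax(score, axis=0)]

    return LandCoverRaster(grid=grid.astype(np.int32), cell_km=cell_km, origin=(xmin, ymin))


def default_coefficients() -> dict[str, dict[str, float]]:
    """Default generative effect sizes linking features to prevalence.

    Asthma loads on poverty, dense development (pollution proxy) and
    forest cover (pollen proxy); COPD on poverty, development and older
    age.  Units: percentage points of prevalence per unit of the feature
    (features are proportions in [0, 1]).
    """
    return {
        "asthma": {
            "poverty": 22.0,
            "landcover_developed_high": 8.0,
            "landcover_forest_deciduous": 5.0,
            "age_under5": 10.0,
        },
        "copd": {
            "poverty": 18.0,
            "landcover_developed_high": 7.0,
            "age_65_74": 14.0,
            "age_75_plus": 14.0,
        },
    }


DEFAULT_BASE = {"asthma": 9.783, "copd": 6.416}


def generate_prevalence(
    tracts: TractSet,
    census: CensusTable,
    landcover: LandCoverRaster | None = None,
    coefficients: Mapping[str, Mapping[str, float]] | None = None,
    noise_sd: float = 1.0,
    base: Mapping[str, float] | float | None = None,
    state_offset_sd: float = 2.5,
    state_offsets: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
) -> tuple[PrevalenceTable, GenerativeTruth]:
    """Generate ground-truth prevalence percentages per tract and outcome.

    For each outcome, prevalence_i = clip(base + sum_f coef[f] * feature_f(i)
    + state_offset(state_i) + Normal(0, noise_sd), 0, 100).  Features may be
    census proportions or land-cover sub-class area proportions (prefixed
    ``landcover_``).  Returns the table together with the generating truth
    so that recovery tests can compare against it.
    """
    if coefficients is None:
        coefficients = default_coefficients()
    if base is None:
        base = {o: DEFAULT_BASE.get(o, 5.0) for o in coefficients}
    if isinstance(base, (int, float)):
        base = {o: float(base) for o in coefficients}
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be non-negative")

    features = census.data.copy()
    if landcover is not None:
        from .feature_engineering import landcover_proportions  # local: avoids cycle
        lc = landcover_proportions(landcover, tracts)
        features = features.join(lc.data)

    for outcome, coefs in coefficients.items():
        unknown = [f for f in coefs if f not in features.columns]
        if unknown:
            raise InvalidParameterError(
                f"unknown coefficient feature(s) for {outcome!r}: {unknown}"
            )

    rng = np.random.default_rng(seed)
    states = sorted(set(tracts.state_codes))
    state_arr = np.array(tracts.state_codes)
    features = features.loc[tracts.ids]

    out = {}
    truth_offsets: dict[str, dict[str, float]] = {}
    for outcome in coefficients:
        coefs = coefficients[outcome]
        if state_offsets is not None and outcome in state_offsets:
            offsets = dict(state_offsets[outcome])
        else:
            draws = rng.normal(0.0, state_offset_sd, size=len(states))
            offsets = {s: float(d) for s, d in zip(states, draws)}
        truth_offsets[outcome] = offsets
        lin = np.full(len(tracts), float(base[outcome]))
        for f, b in coefs.items():
            lin += b * features[f].to_numpy()
        lin += np.array([offsets[s] for s in state_arr])
        lin += rng.normal(0.0, noise_sd, size=len(tracts))
        out[outcome] = np.clip(lin, 0.0, 100.0)

    table = PrevalenceTable(pd.DataFrame(out, index=pd.Index(tracts.ids, name="tract_id")))
    truth = GenerativeTruth(
        base={o: float(base[o]) for o in coefficients},
        coefficients={o: dict(c) for o, c in coefficients.items()},
        state_offsets=truth_offsets,
        noise_sd=noise_sd,
    )
    return table, truth


def generate_queries(
    tracts: TractSet,
    prevalence: PrevalenceTable,
    vocab: Mapping[str, str] | None = None,
    background_vocab: Sequence[str] | None = None,
    users_per_capita: float = 0.05,
    queries_per_user: float = 20.0,
    signal_strength: float = 2.0,
    base_rate: float = 0.05,
    category_mix: Mapping[str, float] | None = None,
    topic_coherence: float = 0.5,
    mean_extra_tokens: float = 3.0,
    seed: int = 0,
) -> QueryLog:
    """Simulate a geo-assigned query log carrying a prevalence signal.

    Each tract gets ``max(1, round(users_per_capita * population))`` users;
    each user issues a Poisson(``queries_per_user``) number of queries.  A
    query is a bag of background tokens, except that with probability
    ``p_i = base_rate * (1 + signal_strength * prevalence_i / 100)`` (capped
    at 1) a disease keyword, drawn by category mix then uniformly within
    category, is inserted — so the expected keyword rate is monotone
    increasing in prevalence when ``signal_strength > 0``.  Prevalence is
    averaged across the table's outcomes (both illnesses share one keyword
    dictionary).  Disease queries additionally receive extra disease-topic
    tokens with probability ``topic_coherence`` each, giving the corpus the
    co-occurrence structure a word embedding can exploit.
    """
    if vocab is None:
        vocab = DEFAULT_KEYWORDS
    if background_vocab is None:
        background_vocab = BACKGROUND_VOCAB
    overlap = set(vocab) & set(background_vocab)
    if overlap:
        raise InvalidParameterError(f"vocab and background_vocab overlap: {sorted(overlap)[:5]}")
    if signal_strength < 0:
        raise InvalidParameterError("signal_strength must be non-negative")
    if not (0 < base_rate <= 1):
        raise InvalidParameterError("base_rate must lie in (0, 1]")
    if category_mix is None:
        category_mix = {"symptom": 0.35, "disease": 0.30, "medication": 0.20, "smoking": 0.15}

    rng = np.random.default_rng(seed)
    keywords = sorted(vocab)
    categories = sorted({vocab[k] for k in keywords})
    kw_probs = np.zeros(len(keywords))
    for cat in categories:
        members = [i for i, k in enumerate(keywords) if vocab[k] == cat]
        w = float(category_mix.get(cat, 0.0))
        if members and w > 0:
            kw_probs[members] = w / len(members)
    if kw_probs.sum() <= 0:
        raise InvalidParameterError("category_mix gives zero mass to every vocab category")
    kw_probs /= kw_probs.sum()

    prev = prevalence.data.loc[tracts.ids].mean(axis=1).to_numpy()
    p_insert = np.clip(base_rate * (1.0 + signal_strength * prev / 100.0), 0.0, 1.0)

    background = np.asarray(list(background_vocab), dtype=object)
    # Zipf-ish background frequencies: realistic head-heavy token usage.
    bg_probs = 1.0 / (np.arange(len(background)) + 2.0)
    bg_probs /= bg_probs.sum()
    kw_arr = np.asarray(keywords, dtype=object)

    n_users = np.maximum(1, np.round(users_per_capita * tracts.populations)).astype(int)
    user_tract_idx = np.repeat(np.arange(len(tracts)), n_users)
    n_queries = rng.poisson(queries_per_user, size=user_tract_idx.size)
    ev_user = np.repeat(np.arange(user_tract_idx.size), n_queries)
    ev_tract_idx = user_tract_idx[ev_user]
    n_events = ev_user.size

    # Per-user serials within tract, vectorised.
    user_serial = np.concatenate([np.arange(k) for k in n_users]) if n_users.size else np.array([], int)
    tract_ids_arr = np.asarray(tracts.ids, dtype=object)
    user_labels = np.array(
        [f"u{tract_ids_arr[t]}_{s}" for t, s in zip(user_tract_idx, user_serial)],
        dtype=object,
    )

    n_bg = 1 + rng.poisson(mean_extra_tokens, size=n_events)
    insert = rng.random(n_events) < p_insert[ev_tract_idx]
    kw_choice = rng.choice(len(kw_arr), size=n_events, p=kw_probs)
    n_extra = np.where(insert, rng.binomial(2, topic_coherence, size=n_events), 0)
    topic_pool = np.asarray(sorted(set(keywords) | set(SEED_TERMS)), dtype=object)
    total_bg = int(n_bg.sum())
    bg_draws = rng.choice(len(background), size=total_bg, p=bg_probs)
    extra_draws = rng.choice(len(topic_pool), size=int(n_extra.sum()))

    tokens: list[tuple[str, ...]] = []
    bg_pos = 0
    ex_pos = 0
    for e in range(n_events):
        toks = list(background[bg_draws[bg_pos:bg_pos + n_bg[e]]])
        bg_pos += n_bg[e]
        if insert[e]:
            toks.append(kw_arr[kw_choice[e]])
            k = n_extra[e]
            toks.extend(topic_pool[extra_draws[ex_pos:ex_pos + k]])
            ex_pos += k
        tokens.append(tuple(toks))

    return QueryLog(
        user_ids=user_labels[ev_user],
        tract_ids=tract_ids_arr[ev_tract_idx],
        tokens=tokens,
    )


def planted_synonym_corpus(
    n_queries: int = 2000,
    related_terms: Sequence[str] | None = None,
    seeds: Sequence[str] = SEED_TERMS,
    background_vocab: Sequence[str] | None = None,
    topic_rate: float = 0.5,
    tokens_per_query: int = 6,
    seed: int = 0,
) -> tuple[list[tuple[str, ...]], list[str]]:
    """Build a corpus with planted disease-related terms for embedding tests.

    A fraction ``topic_rate`` of queries is drawn from a disease topic
    (seed terms plus the planted related terms), the rest from background
    vocabulary, so related terms share contexts with the seeds and should
    dominate a cosine-similarity ranking.  Returns (sentences, planted terms).
    """
    if related_terms is None:
        related_terms = [
            "cough", "wheezing", "inhaler", "bronchitis", "nicotine",
            "emphysema", "nebulizer", "phlegm", "cigarette", "dyspnea",
        ]
    if background_vocab is None:
        background_vocab = BACKGROUND_VOCAB
    topic_pool = np.asarray(sorted(set(seeds) | set(related_terms)), dtype=object)
    bg_pool = np.asarray([w for w in background_vocab if w not in set(topic_pool)], dtype=object)
    rng = np.random.default_rng(seed)
    sentences: list[tuple[str, ...]] = []
    for _ in range(n_queries):
        if rng.random() < topic_rate:
            toks = rng.choice(topic_pool, size=tokens_per_query, replace=True)
        else:
            toks = rng.choice(bg_pool, size=tokens_per_query, replace=True)
        sentences.append(tuple(toks))
    return sentences, list(related_terms)


@dataclass
class SyntheticCity:
    """One fully simulated study region, bundling every generated input."""

    tracts: TractSet
    census: CensusTable
    landcover: LandCoverRaster
    prevalence: PrevalenceTable
    truth: GenerativeTruth
    queries: QueryLog


def simulate_city(
    n_tracts: int = 500,
    seed: int = 0,
    n_states: int = 4,
    users_per_capita: float = 0.05,
    queries_per_user: float = 20.0,
    signal_strength: float = 2.0,
    noise_sd: float = 1.0,
    coefficients: Mapping[str, Mapping[str, float]] | None = None,
    base: Mapping[str, float] | float | None = None,
    state_offset_sd: float = 2.5,
    cell_km: float = 0.25,
    clumping: float = 2.0,
    jitter: float = 0.25,
) -> SyntheticCity:
    """Run the full generator chain under one master seed.

    Sub-seeds are derived deterministically from ``seed`` so that each
    stage is independently reproducible.
    """
    ss = np.random.SeedSequence(seed).spawn(5)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    tracts = generate_tracts(n_tracts, jitter=jitter, seed=sub[0], n_states=n_states)
    census = generate_census(tracts, seed=sub[1])
    landcover = generate_landcover(tracts, cell_km=cell_km, clumping=clumping, seed=sub[2])
    prevalence, truth = generate_prevalence(
        tracts, census, landcover,
        coefficients=coefficients, noise_sd=noise_sd, base=base,
        state_offset_sd=state_offset_sd, seed=sub[3],
    )
    queries = generate_queries(
        tracts, prevalence,
        users_per_capita=users_per_capita,
        queries_per_user=queries_per_user,
        signal_strength=signal_strength,
        seed=sub[4],
    )
    return SyntheticCity(tracts, census, landcover, prevalence, truth, queries)
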