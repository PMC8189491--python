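"""Generator correctness: tiling geometry, proportion invariants, seeded
reproducibility, and the prevalence-to-query signal chain."""

import numpy as np
import pytest

import tractprev as tp
from tractprev.errors import InvalidInputError, InvalidParameterError
from tractprev.synthetic_city import (
    AGE_COLUMNS,
    GENDER_COLUMNS,
    RACE_COLUMNS,
    generate_census,
    generate_landcover,
    generate_prevalence,
    generate_queries,
    generate_tracts,
)


class TestGenerateTracts:
    def test_zero_jitter_2x2_tiling_is_exact(self):
        ts = generate_tracts(4, region_size=4.0, jitter=0.0, seed=1)
        assert len(ts) == 4
        assert [round(t.area, 9) for t in ts.tracts] == [4.0] * 4
        centroids = sorted(tuple(np.round(t.centroid, 9)) for t in ts.tracts)
        assert centroids == [(1.0, 1.0), (1.0, 3.0), (3.0, 1.0), (3.0, 3.0)]

    def test_tiling_conservation_and_disjointness(self):
        ts = generate_tracts(500, seed=7)
        assert len(ts) == 500
        areas = np.array([t.area for t in ts.tracts])
        assert (areas > 0).all()
        xmin, ymin, xmax, ymax = ts.region_bounds
        region_area = (xmax - xmin) * (ymax - ymin)
        assert areas.sum() == pytest.approx(region_area, rel=1e-6)
        # Brute-force pairwise interior-disjointness on a 20-tract subsample.
        sample = ts.tracts[::25][:20]
        for i, a in enumerate(sample):
            for b in sample[i + 1:]:
                inter = a.polygon.intersection(b.polygon)
                assert inter.area == pytest.approx(0.0, abs=1e-9)

    def test_centroid_inside_and_invariants(self):
        ts = generate_tracts(50, jitter=0.45, seed=3)
        assert len(set(ts.ids)) == 50
        for t in ts.tracts:
            assert t.polygon.is_simple and t.polygon.is_valid
            assert t.polygon.covers(t.polygon.centroid)
            assert t.population >= 50

    def test_state_codes_are_contiguous_blocks(self):
        ts = generate_tracts(40, seed=0, n_states=4)
        codes = ts.state_codes
        assert len(set(codes)) == 4
        # row-major order never revisits a state once left
        seen, last = [], None
        for c in codes:
            if c != last:
                assert c not in seen
                seen.append(c)
                last = c

    @pytest.mark.parametrize("kwargs", [
        dict(n_tracts=1), dict(n_tracts=0), dict(n_tracts=10, region_size=-1.0),
        dict(n_tracts=10, jitter=0.5), dict(n_tracts=10, jitter=-0.1),
    ])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(InvalidParameterError):
            generate_tracts(**{"seed": 0, **kwargs})

    def test_reproducibility(self):
        a = generate_tracts(30, seed=5)
        b = generate_tracts(30, seed=5)
        assert all(x.polygon.equals(y.polygon) and x.population == y.population
                   for x, y in zip(a.tracts, b.tracts))


class TestGenerateCensus:
    def test_block_sums(self, grid_tracts):
        census = generate_census(grid_tracts, seed=2)
        for cols in (AGE_COLUMNS, GENDER_COLUMNS, RACE_COLUMNS):
            np.testing.assert_allclose(census.data[list(cols)].sum(axis=1), 1.0, atol=1e-9)

    def test_large_concentration_approaches_uniform(self, grid_tracts):
        census = generate_census(grid_tracts, concentration=1e6, seed=0)
        np.testing.assert_allclose(census.data[list(AGE_COLUMNS)], 1 / 9, atol=1e-2)
        np.testing.assert_allclose(census.data[list(GENDER_COLUMNS)], 1 / 2, atol=1e-2)

    def test_degenerate_poverty_interval(self, grid_tracts):
        census = generate_census(grid_tracts, poverty_range=(0.3, 0.3), seed=0)
        np.testing.assert_allclose(census.data["poverty"], 0.3)

    def test_empty_tractset_rejected(self):
        empty = tp.TractSet([], (0, 0, 1, 1))
        with pytest.raises(InvalidInputError):
            generate_census(empty, seed=0)


class TestGenerateLandcover:
    def test_single_positive_class_uniform(self, grid_tracts):
        ras = generate_landcover(grid_tracts, cell_km=0.5,
                                 class_weights={24: 1.0, 41: 0.0}, seed=0)
        assert (ras.grid == 24).all()

    def test_iid_two_class_frequencies(self):
        ts = generate_tracts(4, region_size=30.0, jitter=0.0, seed=0)
        ras = generate_landcover(ts, cell_km=0.1, class_weights={24: 1.0, 41: 1.0},
                                 clumping=0.0, seed=5)
        assert ras.grid.shape == (300, 300)
        freq = (ras.grid == 24).mean()
        assert abs(freq - 0.5) < 0.02

    def test_clumping_grows_patches(self, grid_tracts):
        smooth = generate_landcover(grid_tracts, cell_km=0.1, clumping=4.0, seed=1)
        rough = generate_landcover(grid_tracts, cell_km=0.1, clumping=0.0, seed=1)
        # same-neighbor agreement is higher for the clumped field
        def agreement(g):
            return (g[:, 1:] == g[:, :-1]).mean()
        assert agreement(smooth.grid) > agreement(rough.grid) + 0.2

    def test_invalid_parameters(self, grid_tracts):
        with pytest.raises(InvalidParameterError):
            generate_landcover(grid_tracts, cell_km=0.0, seed=0)
        with pytest.raises(InvalidParameterError):
            generate_landcover(grid_tracts, class_weights={24: 0.0, 41: 0.0}, seed=0)


class TestGeneratePrevalence:
    def test_zero_effects_zero_noise_equals_base(self, grid_tracts):
        census = generate_census(grid_tracts, seed=0)
        prev, _ = generate_prevalence(
            grid_tracts, census, coefficients={"asthma": {}}, noise_sd=0.0,
            base={"asthma": 5.0}, state_offset_sd=0.0, seed=0)
        np.testing.assert_allclose(prev.data["asthma"], 5.0)

    def test_mean_matches_base_under_zero_effects(self):
        ts = generate_tracts(500, seed=4)
        census = generate_census(ts, seed=4)
        prev, _ = generate_prevalence(
            ts, census, coefficients={"asthma": {}}, noise_sd=1.0,
            base={"asthma": 9.783}, state_offset_sd=0.0, seed=4)
        assert prev.data["asthma"].mean() == pytest.approx(9.783, abs=0.2)

    def test_positive_poverty_effect_induces_correlation(self):
        ts = generate_tracts(500, seed=6)
        census = generate_census(ts, seed=6)
        prev, _ = generate_prevalence(
            ts, census, coefficients={"asthma": {"poverty": 20.0}},
            noise_sd=0.2, base={"asthma": 9.783}, state_offset_sd=0.0, seed=6)
        r = np.corrcoef(census.data["poverty"], prev.data["asthma"])[0, 1]
        assert r > 0.9

    def test_unknown_coefficient_rejected(self, grid_tracts):
        census = generate_census(grid_tracts, seed=0)
        with pytest.raises(InvalidParameterError):
            generate_prevalence(grid_tracts, census,
                                coefficients={"asthma": {"not_a_feature": 1.0}}, seed=0)

    def test_truth_is_returned(self, grid_tracts):
        census = generate_census(grid_tracts, seed=0)
        landcover = generate_landcover(grid_tracts, seed=0)
        prev, truth = generate_prevalence(grid_tracts, census, landcover, seed=0)
        assert set(truth.coefficients) == set(prev.outcomes)
        assert all(s in truth.state_offsets["asthma"] for s in set(grid_tracts.state_codes))


class TestGenerateQueries:
    def test_overlapping_vocabularies_rejected(self, grid_tracts):
        census = generate_census(grid_tracts, seed=0)
        prev, _ = generate_prevalence(grid_tracts, census,
                                      coefficients={"asthma": {"poverty": 10.0}}, seed=0)
        with pytest.raises(InvalidParameterError):
            generate_queries(grid_tracts, prev, vocab={"cough": "symptom"},
                             background_vocab=["cough", "weather"], seed=0)

    def test_user_counts_track_users_per_capita(self, grid_tracts):
        census = generate_census(grid_tracts, seed=0)
        prev, _ = generate_prevalence(grid_tracts, census,
                                      coefficients={"asthma": {"poverty": 10.0}}, seed=0)
        log = generate_queries(grid_tracts, prev, users_per_capita=0.01,
                               queries_per_user=5.0, seed=0)
        users = log.unique_user_counts()
        for t in grid_tracts.tracts:
            expected = max(1, round(0.01 * t.population))
            # every user issues >=0 queries, so observed distinct users <= expected
            assert users.get(t.tract_id, 0) <= expected

    def test_signal_strength_zero_decouples_rate_from_prevalence(self):
        city = tp.simulate_city(n_tracts=100, seed=9, users_per_capita=0.02,
                                queries_per_user=10, signal_strength=0.0)
        rate = _keyword_rate(city)
        r = np.corrcoef(rate, city.prevalence.data.mean(axis=1))[0, 1]
        assert abs(r) < 0.25

    def test_strong_signal_gives_high_rank_correlation(self):
        from scipy.stats import spearmanr
        city = tp.simulate_city(n_tracts=100, seed=9, users_per_capita=0.1,
                                queries_per_user=20, signal_strength=20.0, noise_sd=0.2)
        rate = _keyword_rate(city)
        rho = spearmanr(rate, city.prevalence.data.mean(axis=1)).statistic
        assert rho > 0.9

    def test_monotone_signal_over_replicates(self):
        """Keyword-rate/prevalence correlation is stronger with signal than without."""
        diffs = []
        for seed in range(20):
            tracts = generate_tracts(40, seed=seed)
            census = generate_census(tracts, seed=seed)
            prev, _ = generate_prevalence(tracts, census, coefficients={"asthma": {}},
                                          noise_sd=2.0, base={"asthma": 9.783},
                                          state_offset_sd=2.0, seed=seed)
            corrs = {}
            for sig in (0.0, 2.0):
                log = generate_queries(tracts, prev, users_per_capita=0.05,
                                       queries_per_user=10, signal_strength=sig,
                                       seed=1000 + seed)
                rate = _keyword_rate_from(log, tracts)
                corrs[sig] = abs(np.corrcoef(rate, prev.data["asthma"])[0, 1])
            diffs.append(corrs[2.0] - corrs[0.0])
        assert np.mean(diffs) > 0

    def test_reproducibility(self, grid_tracts):
        census = generate_census(grid_tracts, seed=0)
        prev, _ = generate_prevalence(grid_tracts, census,
                                      coefficients={"asthma": {"poverty": 10.0}}, seed=0)
        a = generate_queries(grid_tracts, prev, users_per_capita=0.01, seed=3)
        b = generate_queries(grid_tracts, prev, users_per_capita=0.01, seed=3)
        assert a.tokens == b.tokens and (a.user_ids == b.user_ids).all()


def _keyword_rate_from(log, tracts):
    from tractprev.vocab import DEFAULT_KEYWORDS
    kws = set(DEFAULT_KEYWORDS)
    import pandas as pd
    hit = [bool(kws & set(toks)) for toks in log.tokens]
    df = pd.DataFrame({"tract": log.tract_ids, "hit": hit})
    rate = df.groupby("tract")["hit"].mean()
    return rate.reindex(tracts.ids).fillna(0.0).to_numpy()


def _keyword_rate(city):
    return _keyword_rate_from(city.queries, city.tracts)
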