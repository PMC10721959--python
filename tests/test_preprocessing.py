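"""Filtering, floral-metric and standardization rules."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fireabund import preprocessing as prep
from fireabund.errors import ContractError, DegenerateInputError, InputError
from fireabund.preprocessing import (CountDataset, CovariateSet, ModelFlags,
                                     QuadratRecord, VisitationRecord,
                                     BUTTERFLY_FLAGS)


def _visits(counts: dict[str, int]) -> list[VisitationRecord]:
    return [
        VisitationRecord(plant, f"bee{i}", "p1", "v1")
        for plant, n in counts.items()
        for i in range(n)
    ]


class TestFrequentPlantFilter:
    @pytest.mark.parametrize("counts,min_visits,expected", [
        ({"A": 12, "B": 10, "C": 9}, 10, {"A", "B"}),
        ({"A": 1, "B": 1, "C": 1}, 10, set()),
        ({}, 10, set()),
        ({"A": 5}, 1, {"A"}),
    ])
    def test_threshold_boundary(self, counts, min_visits, expected):
        assert prep.filter_frequent_plants(_visits(counts), min_visits) == expected

    def test_survey_scale_partition(self):
        """147 plants: 63 never visited, 45 rarely (<5), 9 occasionally
        (5-9) and 30 frequently (>=10) -- only the 30 pass the filter."""
        counts = {}
        k = 0
        for n in [0] * 63 + [1, 2, 3, 4] * 11 + [3] + [5, 6, 7] * 3 + [10, 15, 40] * 10:
            counts[f"plant{k}"] = n
            k += 1
        assert len(counts) == 147
        kept = prep.filter_frequent_plants(_visits(counts), 10)
        assert len(kept) == 30
        assert all(counts[p] >= 10 for p in kept)

    @given(st.dictionaries(st.text(min_size=1, max_size=3),
                           st.integers(0, 30), max_size=20),
           st.integers(1, 15))
    @settings(derandomize=True, deadline=None, max_examples=50)
    def test_monotone_in_threshold(self, counts, min_visits):
        recs = _visits(counts)
        lo = prep.filter_frequent_plants(recs, min_visits)
        hi = prep.filter_frequent_plants(recs, min_visits + 1)
        assert hi <= lo


class TestFloralMetrics:
    def test_direct_sum(self):
        quads = [
            QuadratRecord("p1", "v1", 1, "A", 3),
            QuadratRecord("p1", "v1", 2, "A", 2),
            QuadratRecord("p1", "v1", 3, "B", 1),
            QuadratRecord("p1", "v1", 4, "C", 5),
        ]
        out = prep.compute_floral_metrics(quads, {"A", "B"}, [("p1", "v1")])
        assert out[("p1", "v1")] == (6, 2)

    def test_empty_frequent_set(self):
        quads = [QuadratRecord("p1", "v1", 1, "A", 3)]
        out = prep.compute_floral_metrics(quads, set(), [("p1", "v1"), ("p2", "v1")])
        assert out == {("p1", "v1"): (0, 0), ("p2", "v1"): (0, 0)}

    def test_species_spread_over_all_quadrats(self):
        quads = [QuadratRecord("p1", "v1", q, "A", 1) for q in range(1, 9)]
        out = prep.compute_floral_metrics(quads, {"A"}, [("p1", "v1")])
        assert out[("p1", "v1")] == (8, 1)

    def test_unknown_plot_visit_rejected(self):
        with pytest.raises(InputError):
            prep.compute_floral_metrics(
                [QuadratRecord("p9", "v9", 1, "A", 1)], {"A"}, [("p1", "v1")])

    def test_species_outside_master_list_rejected(self):
        with pytest.raises(InputError):
            prep.compute_floral_metrics(
                [QuadratRecord("p1", "v1", 1, "X", 1)], {"A"},
                [("p1", "v1")], master_plants={"A", "B"})

    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(1, 8),
                              st.integers(0, 2), st.integers(0, 9)),
                    max_size=40))
    @settings(derandomize=True, deadline=None, max_examples=50)
    def test_matches_naive_loop(self, raw):
        plants = ["A", "B", "C"]
        frequent = {"A", "B"}
        pv = [("p1", "v1"), ("p1", "v2"), ("p2", "v1"), ("p2", "v2")]
        quads = [QuadratRecord(*pv[i], q, plants[s], n) for i, q, s, n in raw]
        out = prep.compute_floral_metrics(quads, frequent, pv)
        for key in pv:
            ab = sum(r.open_inflorescences for r in quads
                     if (r.plot_id, r.visit_id) == key
                     and r.plant_species in frequent)
            ri = len({r.plant_species for r in quads
                      if (r.plot_id, r.visit_id) == key
                      and r.plant_species in frequent
                      and r.open_inflorescences > 0})
            assert out[key] == (ab, ri)


class TestSnowmelt:
    @pytest.mark.parametrize("visit,melt,expected", [
        (dt.date(2016, 6, 16), dt.date(2016, 6, 6), 10),
        (dt.date(2017, 6, 18), dt.date(2017, 6, 18), 0),
        (dt.date(2017, 9, 1), dt.date(2017, 6, 18), 75),
    ])
    def test_day_differences(self, visit, melt, expected):
        assert prep.days_since_snowmelt(visit, melt) == expected

    def test_visit_before_snowmelt_rejected(self):
        with pytest.raises(InputError):
            prep.days_since_snowmelt(dt.date(2016, 6, 1), dt.date(2016, 6, 6))


class TestStandardization:
    def test_simple_vector(self):
        z, m, s = prep.standardize_global([1.0, 2.0, 3.0])
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])
        assert (m, s) == (2.0, 1.0)

    def test_two_points(self):
        z, m, s = prep.standardize_global([10.0, 30.0])
        np.testing.assert_allclose(z, [-0.7071, 0.7071], atol=1e-4)
        np.testing.assert_allclose(s, 14.1421, atol=1e-4)

    def test_idempotent(self, rng):
        x = rng.normal(size=50)
        z1, _, _ = prep.standardize_global(x)
        z2, _, _ = prep.standardize_global(z1)
        np.testing.assert_allclose(z1, z2, atol=1e-12)

    def test_round_trip(self, rng):
        x = rng.normal(3.0, 7.0, size=80)
        z, m, s = prep.standardize_global(x)
        np.testing.assert_allclose(z * s + m, x, atol=1e-10)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            prep.standardize_global([4.0, 4.0, 4.0])

    def test_within_habitat_strata(self):
        vals = np.array([2.0, 4.0, 10.0, 30.0])
        hab = np.array(["meadow", "meadow", "upland", "upland"], dtype=object)
        z, stats = prep.standardize_within_habitat(vals, hab)
        np.testing.assert_allclose(z, [-0.7071, 0.7071, -0.7071, 0.7071],
                                   atol=1e-4)
        assert set(stats) == {"meadow", "upland"}

    def test_single_stratum_reduces_to_global(self, rng):
        x = rng.normal(size=30)
        hab = np.array(["upland"] * 30, dtype=object)
        z, _ = prep.standardize_within_habitat(x, hab)
        zg, _, _ = prep.standardize_global(x)
        np.testing.assert_allclose(z, zg, atol=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(derandomize=True, deadline=None, max_examples=25)
    def test_matches_stratum_loop(self, seed):
        r = np.random.default_rng(seed)
        n = 40
        x = r.normal(5, 3, size=n)
        hab = np.where(r.random(n) < 0.5, "meadow", "upland").astype(object)
        if min((hab == "meadow").sum(), (hab == "upland").sum()) < 2:
            return
        z, _ = prep.standardize_within_habitat(x, hab)
        for level in ("meadow", "upland"):
            mask = hab == level
            expect = (x[mask] - x[mask].mean()) / x[mask].std(ddof=1)
            np.testing.assert_allclose(z[mask], expect, atol=1e-12)
            assert abs(z[mask].mean()) < 1e-10
            assert abs(z[mask].std(ddof=1) - 1.0) < 1e-10

    def test_constant_stratum_rejected(self):
        with pytest.raises(DegenerateInputError):
            prep.standardize_within_habitat(
                np.array([1.0, 1.0, 2.0, 3.0]),
                np.array(["meadow", "meadow", "upland", "upland"], dtype=object))


class TestPooling:
    def test_elementwise_sum_and_symmetry(self, rng):
        a = rng.integers(0, 10, size=(3, 4))
        b = rng.integers(0, 10, size=(3, 4))
        np.testing.assert_array_equal(prep.pool_double_surveys(a, b), a + b)
        np.testing.assert_array_equal(prep.pool_double_surveys(a, b),
                                      prep.pool_double_surveys(b, a))
        np.testing.assert_array_equal(
            prep.pool_double_surveys(a, np.zeros_like(a)), a)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            prep.pool_double_surveys(np.zeros((2, 2)), np.zeros((3, 2)))


def _dataset(counts, n_plots=4, n_visits=2):
    counts = np.asarray(counts)
    S = counts.shape[0]
    return CountDataset(
        species_ids=[f"sp{i}" for i in range(S)],
        counts=counts,
        observed=np.ones((n_plots, n_visits), dtype=bool),
        plot_ids=[f"p{j}" for j in range(n_plots)],
        visit_ids=[f"v{k}" for k in range(n_visits)],
        plot_to_site={f"p{j}": f"s{j // 2}" for j in range(n_plots)},
        years=np.full((n_plots, n_visits), 2016),
    )


class TestCommunitySpeciesFilter:
    def test_boundary_and_concentration(self):
        counts = np.zeros((2, 4, 2), dtype=int)
        counts[0, 0, 0] = counts[0, 1, 0] = counts[0, 2, 1] = 1  # 3 plots
        counts[1, 0, :] = 100                                    # 1 plot
        with pytest.warns(UserWarning):
            out = prep.filter_community_species(_dataset(counts), 3)
        assert out.species_ids == ["sp0"]

    def test_matches_recount_oracle(self, rng):
        counts = (rng.random((10, 6, 3)) < 0.25) * rng.integers(1, 5, (10, 6, 3))
        ds = _dataset(counts, n_plots=6, n_visits=3)
        out = prep.filter_community_species(ds, 3)
        expected = []
        for i, sp in enumerate(ds.species_ids):
            occupied = {j for j in range(6) for k in range(3)
                        if counts[i, j, k] > 0}
            if len(occupied) >= 3:
                expected.append(sp)
        assert out.species_ids == expected

    def test_monotone_in_threshold(self, rng):
        counts = (rng.random((8, 5, 2)) < 0.4) * 1
        ds = _dataset(counts, n_plots=5, n_visits=2)
        prev = None
        for m in range(1, 6):
            kept = set(prep.filter_community_species(ds, m).species_ids) \
                if m < 5 else set()
            if prev is not None and m < 5:
                assert kept <= prev
            if m < 5:
                prev = kept


def _covariates(n_plots=4, n_visits=2, habitat=("meadow", "meadow",
                                                "upland", "upland")):
    rng = np.random.default_rng(7)
    return CovariateSet(
        burn=np.array([100.0, 900.0, 200.0, 800.0]),
        habitat=np.array(habitat, dtype=object),
        elevation=rng.uniform(1300, 1800, n_plots),
        snowmelt=rng.integers(5, 60, (n_plots, n_visits)).astype(float),
        richness=rng.integers(0, 10, (n_plots, n_visits)).astype(float),
        inflor=rng.integers(0, 200, (n_plots, n_visits)).astype(float),
        year=np.tile([2016, 2017], (n_plots, 1)),
    )


class TestBuildDesign:
    def _prepped(self, flags=ModelFlags()):
        counts = np.arange(2 * 4 * 2).reshape(2, 4, 2)
        ds = _dataset(counts)
        ds.years = np.tile([2016, 2017], (4, 1))
        cov = prep.standardize_covariates(_covariates(), ds.observed)
        return ds, cov, prep.build_design(ds, cov, flags)

    def test_requires_standardized_covariates(self):
        ds = _dataset(np.zeros((2, 4, 2), dtype=int))
        with pytest.raises(ContractError):
            prep.build_design(ds, _covariates(), ModelFlags())

    def test_meadow_quadratic_column_is_zero(self):
        ds, cov, data = self._prepped()
        q = data.column_names.index("burn2_upland")
        meadow_rows = cov.habitat[data.plot_index] == "meadow"
        assert np.all(data.X[meadow_rows, q] == 0.0)
        # upland rows carry the square of the standardized burn value
        up = ~meadow_rows
        b = data.column_names.index("burn")
        np.testing.assert_allclose(data.X[up, q], data.X[up, b] ** 2)

    def test_upland_interaction_and_indicator(self):
        ds, cov, data = self._prepped()
        b = data.column_names.index("burn")
        for name, expect in [("burn_x_upland", data.X[:, b]),
                             ("upland", np.ones(data.n_obs))]:
            c = data.column_names.index(name)
            up = cov.habitat[data.plot_index] == "upland"
            np.testing.assert_allclose(data.X[up, c],
                                       expect[up] if name != "upland" else 1.0)
            assert np.all(data.X[~up, c] == 0.0)

    def test_butterfly_variant_drops_year_and_quadratic(self):
        _, _, data = self._prepped(BUTTERFLY_FLAGS)
        assert "year" not in data.column_names
        assert "burn2_upland" not in data.column_names
        assert "burn" in data.column_names

    def test_year_indicator_reference_2016(self):
        ds, cov, data = self._prepped()
        y = data.column_names.index("year")
        assert data.year_reference == 2016
        assert set(data.X[:, y]) == {0.0, 1.0}

    def test_counts_aligned_species_major(self):
        ds, cov, data = self._prepped()
        obs = np.argwhere(ds.observed)
        for r_ix, (j, k) in enumerate(obs):
            np.testing.assert_array_equal(data.y[:, r_ix], ds.counts[:, j, k])

    def test_mask_excludes_cells(self):
        counts = np.zeros((2, 4, 2), dtype=int)
        ds = _dataset(counts)
        ds.observed[1, 1] = False
        cov = prep.standardize_covariates(_covariates(), ds.observed)
        data = prep.build_design(ds, cov, ModelFlags(include_year=False))
        assert data.n_obs == 7
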