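"""Filtering boundaries, winsorization, compositional transform,
outcome transforms, and standardization invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dustdab import FilterSpec, transform_feno
from dustdab.preprocess import (EmptyResultError, aggregate_rank,
                                build_covariates, filter_table, standardize,
                                to_relative_abundance, winsorize_counts)

from conftest import make_metadata, make_table


class TestFilterTable:
    def test_sample_boundary_is_strict(self):
        t = make_table(np.diag([999, 1000, 5000]))
        out = filter_table(t, FilterSpec(min_sample_reads=1000,
                                         min_taxon_fraction=0.0))
        assert out.sample_ids == ["S1", "S2"]

    def test_taxon_boundary_strict_at_exact_fraction(self):
        # grand total 1e6; 0.0005% = 5 reads: 4 dropped, 5 retained
        counts = np.zeros((2, 3), dtype=int)
        counts[0] = [999_991 - 4 - 5, 4, 5]
        counts[1] = [0, 0, 9]
        t = make_table(counts)
        assert t.counts.sum() == 1_000_000  # grand total as constructed
        out = filter_table(t, FilterSpec(min_sample_reads=0,
                                         min_taxon_fraction=5e-6))
        assert "G1" not in out.taxon_ids  # 4 reads < 5
        assert "G2" in out.taxon_ids      # 14 reads >= 5

    def test_zero_thresholds_identity(self, toy_table):
        out = filter_table(toy_table, FilterSpec(0, 0.0, ()))
        assert np.array_equal(out.counts, toy_table.counts)

    def test_excluded_kingdom_dropped(self):
        t = make_table([[5, 5]], lineages=[
            "k__Bacteria;p__A;c__;o__;f__;g__G0",
            "k__Eukaryota;p__B;c__;o__;f__;g__G1"])
        out = filter_table(t, FilterSpec(0, 0.0))
        assert out.taxon_ids == ["G0"]

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(0)
        t = make_table(rng.integers(0, 2000, size=(12, 8)))
        kept = []
        for depth in (0, 500, 1500, 4000):
            try:
                out = filter_table(t, FilterSpec(depth, 0.0, ()))
                kept.append(out.n_samples)
            except EmptyResultError:
                kept.append(0)
        assert kept == sorted(kept, reverse=True)

    def test_exact_removal_count(self):
        totals = [500, 800, 1200, 3000]
        t = make_table(np.diag(totals))
        out = filter_table(t, FilterSpec(1000, 0.0, ()))
        assert out.n_samples == 2

    def test_all_samples_removed_errors(self):
        t = make_table([[1, 1]])
        with pytest.raises(EmptyResultError):
            filter_table(t, FilterSpec(min_sample_reads=10))


class TestWinsorize:
    def test_worked_example_top5_to_sixth(self):
        col = np.array([[10], [9], [8], [7], [6], [5], [4]])
        t = make_table(col)
        out = winsorize_counts(t, k_top=5)
        assert out.counts[:, 0].tolist() == [5, 5, 5, 5, 5, 5, 4]

    def test_all_equal_column_unchanged(self):
        t = make_table(np.full((7, 1), 3))
        assert np.array_equal(winsorize_counts(t).counts, t.counts)

    def test_too_few_samples_errors(self):
        t = make_table(np.ones((6, 1), dtype=int))
        with pytest.raises(ValueError, match="more than 6 samples"):
            winsorize_counts(t, k_top=5)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.integers(0, 10_000), min_size=8, max_size=40))
    def test_idempotent_and_never_increases(self, values):
        t = make_table(np.array(values)[:, None])
        once = winsorize_counts(t)
        twice = winsorize_counts(once)
        assert np.array_equal(once.counts, twice.counts)
        assert np.all(once.counts <= t.counts)

    def test_ranks_preserved_outside_top_k(self):
        vals = np.array([100, 90, 80, 70, 60, 50, 40, 30, 20, 10])
        t = make_table(vals[:, None])
        out = winsorize_counts(t).counts[:, 0]
        below = vals <= 50  # at or below the 6th largest
        assert np.array_equal(out[below], vals[below])


class TestRelativeAbundance:
    def test_simple_proportions(self):
        rel = to_relative_abundance(make_table([[2, 3, 5]]))
        assert np.allclose(rel, [[0.2, 0.3, 0.5]])

    def test_single_taxon_all_ones(self):
        rel = to_relative_abundance(make_table([[7], [1], [100]]))
        assert np.allclose(rel, 1.0)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        t = make_table(rng.integers(1, 500, size=(20, 15)))
        rel = to_relative_abundance(t)
        assert np.all(np.abs(rel.sum(axis=1) - 1.0) < 1e-12)

    def test_zero_total_sample_named(self):
        t = make_table([[0, 0], [1, 2]])
        with pytest.raises(ZeroDivisionError, match="S0"):
            to_relative_abundance(t)


class TestTransformFeno:
    def test_below_lod_imputed_at_3_5(self):
        out = transform_feno(np.array([np.nan]), below_lod=np.array([True]))
        assert np.isclose(out[0], np.log(3.5))

    def test_at_lod_untouched(self):
        out = transform_feno(np.array([5.0]))
        assert np.isclose(out[0], np.log(5.0))

    def test_below_lod_entries_identical(self):
        out = transform_feno(np.array([0.0, 0.0]),
                             below_lod=np.array([True, True]))
        assert out[0] == out[1]

    def test_negative_measurement_errors(self):
        with pytest.raises(ValueError, match="negative"):
            transform_feno(np.array([-1.0]))


class TestStandardize:
    def _std(self, X, y=None):
        n, p = X.shape
        y = np.arange(n, dtype=float) if y is None else y
        Z = pd.DataFrame(index=range(n))
        return standardize(X, y, Z, [f"G{j}" for j in range(p)],
                           [f"S{i}" for i in range(n)])

    def test_simple_column(self):
        d = self._std(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(d.X[:, 0], np.array([-1, 0, 1]))  # sd(1,2,3)=1

    def test_columns_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(2)
        d = self._std(rng.gamma(2, 3, size=(40, 6)))
        assert np.all(np.abs(d.X.mean(axis=0)) < 1e-10)
        assert np.all(np.abs(d.X.std(axis=0, ddof=1) - 1) < 1e-10)
        assert abs(d.y.mean()) < 1e-10 and abs(d.y.std(ddof=1) - 1) < 1e-10

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(3)
        d = self._std(rng.normal(size=(30, 4)))
        d2 = self._std(d.X, y=d.y)
        assert np.allclose(d2.X, d.X, atol=1e-12)

    def test_constant_column_dropped(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        d = self._std(X)
        assert d.dropped_taxa == ["G0"] and d.taxon_ids == ["G1"]

    def test_zero_variance_outcome_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            self._std(np.random.default_rng(0).normal(size=(10, 2)),
                      y=np.ones(10))

    def test_missing_values_rejected(self):
        X = np.array([[1.0], [np.nan], [3.0]])
        with pytest.raises(ValueError, match="complete cases"):
            self._std(X)


class TestBuildCovariates:
    def test_fvc_adds_weight_only(self, meta50):
        z_fev1 = build_covariates(meta50, "fev1")
        z_fvc = build_covariates(meta50, "fvc")
        assert set(z_fvc.columns) - set(z_fev1.columns) == {"weight"}
        assert z_fvc.shape[1] == z_fev1.shape[1] + 1

    def test_feno_drops_quadratics(self, meta50):
        z = build_covariates(meta50, "feno")
        assert "age2" not in z.columns and "height2" not in z.columns
        assert "age" in z.columns and "height" in z.columns
        assert "weight" not in z.columns

    def test_season_sensitivity_adds_one_column(self, meta50):
        z0 = build_covariates(meta50, "fev1")
        z1 = build_covariates(meta50, "fev1", season_sensitivity=True)
        assert set(z1.columns) - set(z0.columns) == {"season_winter"}

    def test_reference_levels(self, meta50):
        z = build_covariates(meta50, "fev1")
        never = meta50.data["smoking"] == "never"
        assert (z.loc[never, ["smoking_former", "smoking_current"]] == 0).all().all()

    def test_unknown_outcome(self, meta50):
        with pytest.raises(ValueError, match="unknown outcome"):
            build_covariates(meta50, "dlco")


class TestAggregateRank:
    def test_species_sum_to_genus(self):
        lineages = [
            "k__B;p__P;c__C;o__O;f__F;g__Gen1;s__sp1",
            "k__B;p__P;c__C;o__O;f__F;g__Gen1;s__sp2",
            "k__B;p__P;c__C;o__O;f__F;g__Gen2;s__sp3",
        ]
        t = make_table([[1, 2, 4], [10, 20, 40]],
                       taxon_ids=["t1", "t2", "t3"], lineages=lineages)
        out = aggregate_rank(t, "genus")
        assert out.n_taxa == 2
        assert out.counts.tolist() == [[3, 4], [30, 40]]

    def test_unknown_rank(self, toy_table):
        with pytest.raises(ValueError, match="rank"):
            aggregate_rank(toy_table, "strain")
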