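import numpy as np
import pandas as pd
import pytest

from vistl.catalogue import Group, default_catalogue
from vistl.encode import (
    HourlyGrid,
    TimelineImage,
    apply_normalizer,
    block_hourly,
    encode_admission,
    encode_cohort,
    fit_imputation_stats,
    fit_normalizer,
    fit_ordering,
    impute_missing,
    native_hourly_grid,
    read_png,
    reorder,
    write_png,
)
from vistl.simulate import CohortConfig, generate_cohort


def _obs(rows):
    return pd.DataFrame(rows, columns=["variable", "time_h", "value"])


def brute_force_locf(obs_rows, n_hours=48):
    """Scalar re-implementation of hourly blocking + LOCF for one variable:
    for each hour take the last observation at time < h+1, if any."""
    out = [np.nan] * n_hours
    for h in range(n_hours):
        best_t, best_i, val = -1.0, -1, np.nan
        for i, (t, v) in enumerate(obs_rows):
            if t < h + 1 and (t, i) >= (best_t, best_i):
                best_t, best_i, val = t, i, v
        out[h] = val
    return np.array(out)


class TestBlockHourly:
    def test_locf_carries_most_recent_observation(self, demo_catalogue):
        grid = block_hourly(_obs([("heart_rate", 0.5, 80.0),
                                  ("heart_rate", 2.2, 120.0)]), demo_catalogue)
        row = grid.values[demo_catalogue.index("heart_rate")]
        assert np.allclose(row[:2], 80.0)
        assert np.allclose(row[2:], 120.0)

    def test_later_timestamp_wins_within_hour(self, demo_catalogue):
        grid = block_hourly(_obs([("heart_rate", 3.2, 70.0),
                                  ("heart_rate", 3.8, 95.0),
                                  ("heart_rate", 3.5, 80.0)]), demo_catalogue)
        assert grid.values[demo_catalogue.index("heart_rate"), 3] == 95.0

    def test_equal_timestamps_resolved_by_input_order(self, demo_catalogue):
        grid = block_hourly(_obs([("heart_rate", 3.5, 70.0),
                                  ("heart_rate", 3.5, 95.0)]), demo_catalogue)
        assert grid.values[demo_catalogue.index("heart_rate"), 3] == 95.0

    def test_unobserved_variable_row_is_missing(self, demo_catalogue):
        grid = block_hourly(_obs([("heart_rate", 0.5, 80.0)]), demo_catalogue)
        assert np.isnan(grid.values[demo_catalogue.index("lactate")]).all()
        assert not grid.observed_mask[demo_catalogue.index("lactate")].any()

    def test_out_of_window_observation_dropped_with_count(self, demo_catalogue):
        with pytest.warns(UserWarning, match="dropped 1"):
            grid = block_hourly(_obs([("heart_rate", 0.5, 80.0),
                                      ("heart_rate", 50.0, 99.0)]), demo_catalogue)
        assert grid.n_dropped == 1
        assert np.allclose(grid.values[demo_catalogue.index("heart_rate")], 80.0)

    def test_unknown_variable_rejected(self, demo_catalogue):
        with pytest.raises(ValueError, match="unknown variable"):
            block_hourly(_obs([("mystery", 0.5, 1.0)]), demo_catalogue)

    def test_agrees_with_brute_force_on_random_sparse_records(self, demo_catalogue, rng):
        """Vectorized blocking equals the scalar LOCF re-implementation on 200
        random sparse observation sequences (a larger sweep runs in the
        acceptance suite)."""
        hr = demo_catalogue.index("heart_rate")
        for _ in range(200):
            k = rng.integers(0, 12)
            times = np.round(rng.uniform(0, 48, size=k), 3)
            vals = rng.normal(80, 20, size=k).round(1)
            grid = block_hourly(_obs([("heart_rate", t, v)
                                      for t, v in zip(times, vals)]), demo_catalogue)
            expect = brute_force_locf(list(zip(times, vals)))
            np.testing.assert_array_equal(grid.values[hr], expect)


class TestImputation:
    def test_location_median_definition(self, small_cohort):
        stats = fit_imputation_stats(small_cohort)
        cat = small_cohort.catalogue
        obs = small_cohort.observations
        adm = small_cohort.admissions
        icu_ids = set(adm.loc[adm["admission_location"] == "ICU", "id"])
        sel = obs[(obs["variable"] == "heart_rate") & obs["id"].isin(icu_ids)]
        expect = sel["value"].median()
        got = stats.value_for(cat.index("heart_rate"), "ICU")
        assert got == pytest.approx(expect, abs=1e-5)

    def test_fallback_chain(self, demo_catalogue):
        cohort = generate_cohort(CohortConfig(n_admissions=20, seed=3))
        stats = fit_imputation_stats(cohort)
        # a variable never observed anywhere falls back to the range midpoint
        i = cohort.catalogue.index("heart_rate")
        stats.location_medians[i, :] = np.nan
        stats.global_medians[i] = np.nan
        assert stats.value_for(i, "ward") == demo_catalogue["heart_rate"].midpoint

    def test_binary_fallback_is_absence(self, small_cohort):
        stats = fit_imputation_stats(small_cohort)
        cat = small_cohort.catalogue
        i = cat.index("med_vasopressor")
        stats.location_medians[i, :] = np.nan
        stats.global_medians[i] = np.nan
        assert stats.value_for(i, "ward") == 0.0

    def test_empty_cohort_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="empty"):
            fit_imputation_stats(small_cohort, ids=[])

    def test_observed_cells_untouched(self, demo_catalogue, imputation_stats):
        grid = block_hourly(_obs([("heart_rate", 0.2, 111.0)]), demo_catalogue,
                            admission_location="ICU")
        out = impute_missing(grid, imputation_stats)
        assert np.allclose(out.values[demo_catalogue.index("heart_rate")], 111.0)
        assert out.complete

    def test_locf_applies_before_imputation(self, demo_catalogue, imputation_stats):
        """Hour 0 of a variable first observed at hour 1 is imputed; later
        hours carry the observation forward."""
        grid = block_hourly(_obs([("lactate", 1.5, 6.0)]), demo_catalogue,
                            admission_location="ICU")
        out = impute_missing(grid, imputation_stats)
        i = demo_catalogue.index("lactate")
        assert out.values[i, 0] == imputation_stats.value_for(i, "ICU")
        assert np.allclose(out.values[i, 1:], 6.0)


class TestNormalizer:
    def test_percentile_bounds_on_uniform_values(self, demo_catalogue, rng):
        """Training cells uniform over the plausible range give bounds near
        the 1st/99th quantiles of that range."""
        V = len(demo_catalogue)
        grids = rng.random((20, V, 48))
        i = demo_catalogue.index("heart_rate")
        lo, hi = demo_catalogue["heart_rate"].plausible_range
        grids[:, i, :] = rng.uniform(lo, hi, size=(20, 48))
        stats = fit_normalizer(grids, "min_max", demo_catalogue)
        span = hi - lo
        assert stats.low[i] == pytest.approx(lo + 0.01 * span, rel=0.2)
        assert stats.high[i] == pytest.approx(hi - 0.01 * span, rel=0.2)

    def test_constant_variable_falls_back_to_plausible_range(self, demo_catalogue, rng):
        V = len(demo_catalogue)
        grids = rng.random((4, V, 48)) * 0.5 + 30
        i = demo_catalogue.index("heart_rate")
        grids[:, i, :] = 72.0
        with pytest.warns(UserWarning, match="constant"):
            stats = fit_normalizer(grids, "min_max", demo_catalogue)
        assert (stats.low[i], stats.high[i]) == demo_catalogue["heart_rate"].plausible_range

    def test_refit_is_deterministic(self, small_prep, small_cohort):
        again = fit_normalizer(small_prep.native_grids, "min_max",
                               small_cohort.catalogue)
        np.testing.assert_array_equal(again.low, np.minimum(again.low, again.high))

    def test_unknown_scheme_rejected(self, demo_catalogue, rng):
        with pytest.raises(ValueError, match="scheme"):
            fit_normalizer(rng.random((2, len(demo_catalogue), 48)), "zscore",
                           demo_catalogue)

    def _grid_with(self, catalogue, name, value, stats):
        fill = stats.fill_vector("ward")
        values = np.repeat(fill[:, None], 48, axis=1)
        values[catalogue.index(name)] = value
        return HourlyGrid(values, np.ones_like(values, dtype=bool), catalogue, "ward")

    def test_min_max_endpoints(self, demo_catalogue, imputation_stats, minmax_normalizer):
        i = demo_catalogue.index("heart_rate")
        lo, hi = minmax_normalizer.low[i], minmax_normalizer.high[i]
        img_lo = apply_normalizer(
            self._grid_with(demo_catalogue, "heart_rate", lo, imputation_stats),
            minmax_normalizer)
        img_hi = apply_normalizer(
            self._grid_with(demo_catalogue, "heart_rate", hi, imputation_stats),
            minmax_normalizer)
        assert np.allclose(img_lo.pixels[i], 0.0)
        assert np.allclose(img_hi.pixels[i], 1.0)

    def test_custom_inverts_lower_abnormal(self, demo_catalogue, imputation_stats,
                                           custom_normalizer):
        """Low urine output is abnormal: at its high bound the custom pixel is
        0 (normal), at its low bound 1 (abnormal)."""
        i = demo_catalogue.index("urine_output_rate")
        hi = custom_normalizer.high[i]
        lo = custom_normalizer.low[i]
        img_hi = apply_normalizer(
            self._grid_with(demo_catalogue, "urine_output_rate", hi, imputation_stats),
            custom_normalizer)
        img_lo = apply_normalizer(
            self._grid_with(demo_catalogue, "urine_output_rate", lo, imputation_stats),
            custom_normalizer)
        assert np.allclose(img_hi.pixels[i], 0.0)
        assert np.allclose(img_lo.pixels[i], 1.0)

    def test_custom_bidirectional_distance_from_mean(self, demo_catalogue,
                                                     imputation_stats,
                                                     custom_normalizer):
        i = demo_catalogue.index("heart_rate")
        m = custom_normalizer.mean[i]
        img_mean = apply_normalizer(
            self._grid_with(demo_catalogue, "heart_rate", m, imputation_stats),
            custom_normalizer)
        img_hi = apply_normalizer(
            self._grid_with(demo_catalogue, "heart_rate",
                            custom_normalizer.high[i], imputation_stats),
            custom_normalizer)
        assert np.allclose(img_mean.pixels[i], 0.0, atol=1e-6)
        assert img_hi.pixels[i].max() == pytest.approx(1.0)

    def test_binary_passthrough(self, demo_catalogue, imputation_stats,
                                custom_normalizer):
        i = demo_catalogue.index("med_vasopressor")
        img = apply_normalizer(
            self._grid_with(demo_catalogue, "med_vasopressor", 1.0, imputation_stats),
            custom_normalizer)
        assert np.allclose(img.pixels[i], 1.0)


class TestOrdering:
    def test_standard_is_identity(self, demo_catalogue):
        o = fit_ordering([], "standard", demo_catalogue)
        assert np.array_equal(o.permutation, np.arange(len(demo_catalogue)))

    @pytest.mark.parametrize("scheme", ["within_group", "across_group"])
    def test_cluster_orderings_are_permutations(self, scheme, small_prep, small_cohort):
        perm = small_prep.orderings[scheme].permutation
        assert sorted(perm.tolist()) == list(range(len(small_cohort.catalogue)))

    def test_within_group_preserves_group_blocks(self, small_prep, small_cohort):
        perm = small_prep.orderings["within_group"].permutation
        for g, sl in small_cohort.catalogue.group_slices().items():
            block = perm[sl]
            assert set(block) == set(range(sl.start, sl.stop)), g

    def test_duplicated_variables_become_adjacent(self, demo_catalogue, rng):
        """Two perfectly correlated variables in the same group end up on
        adjacent rows after within-group cluster ordering."""
        V = len(demo_catalogue)
        imgs = rng.random((6, V, 48))
        a, b = demo_catalogue.index("heart_rate"), demo_catalogue.index("temperature")
        imgs[:, b, :] = imgs[:, a, :]
        o = fit_ordering(imgs, "within_group", demo_catalogue)
        pos = {v: r for r, v in enumerate(o.permutation)}
        assert abs(pos[a] - pos[b]) == 1

    def test_single_training_image_rejected(self, demo_catalogue, rng):
        with pytest.raises(ValueError, match="at least 2"):
            fit_ordering(rng.random((1, len(demo_catalogue), 48)), "across_group",
                         demo_catalogue)


class TestEncodeAdmission:
    def test_full_preset_image_shape(self):
        cohort = generate_cohort(CohortConfig(n_admissions=12, seed=9,
                                              catalogue_preset="full"))
        from vistl.models import make_split
        from vistl.pipeline import prepare_cohort
        split = make_split(list(cohort.ids), 1)
        prep = prepare_cohort(cohort, split)
        img = encode_admission(cohort[0], cohort.catalogue, prep.imputation,
                               prep.normalizers["min_max"])
        assert img.pixels.shape == (156, 48)

    def test_pixels_bounded(self, small_cohort, imputation_stats, minmax_normalizer):
        img = encode_admission(small_cohort[5], small_cohort.catalogue,
                               imputation_stats, minmax_normalizer)
        assert img.pixels.min() >= 0 and img.pixels.max() <= 1

    def test_observation_order_does_not_matter(self, small_cohort, imputation_stats,
                                               minmax_normalizer, rng):
        rec = small_cohort[3]
        img1 = encode_admission(rec, small_cohort.catalogue, imputation_stats,
                                minmax_normalizer)
        shuffled = rec.observations.sample(frac=1.0, random_state=5)
        # stable tie-break uses input order only for exactly equal timestamps,
        # which are almost surely absent in the generated data
        rec2 = type(rec)(**{**rec.__dict__, "observations": shuffled})
        img2 = encode_admission(rec2, small_cohort.catalogue, imputation_stats,
                                minmax_normalizer)
        np.testing.assert_allclose(img1.pixels, img2.pixels)

    def test_static_rows_constant_and_correct(self, small_cohort, imputation_stats,
                                              minmax_normalizer):
        rec = small_cohort[7]
        cat = small_cohort.catalogue
        grid = native_hourly_grid(rec, cat, imputation_stats)
        assert np.allclose(grid.values[cat.index("age_years")], rec.age)
        assert np.allclose(grid.values[cat.index("female")], rec.female)
        loc_row = {"ward": "loc_ward", "ED": "loc_ed", "ICU": "loc_icu",
                   "other": "loc_other"}[rec.admission_location]
        assert np.allclose(grid.values[cat.index(loc_row)], 1.0)

    def test_batch_encoding_equals_per_admission(self, small_cohort, small_prep,
                                                 imputation_stats, minmax_normalizer):
        images, ids, labels = encode_cohort(small_cohort, imputation_stats,
                                            minmax_normalizer)
        for i in (0, 17, 101):
            img = encode_admission(small_cohort.record(ids[i]),
                                   small_cohort.catalogue,
                                   imputation_stats, minmax_normalizer)
            np.testing.assert_allclose(images[i], img.pixels, atol=1e-6)

    def test_reorder_moves_rows_and_labels_together(self, small_cohort, small_prep,
                                                    imputation_stats,
                                                    minmax_normalizer):
        img = encode_admission(small_cohort[2], small_cohort.catalogue,
                               imputation_stats, minmax_normalizer)
        ordering = small_prep.orderings["across_group"]
        out = reorder(img, ordering)
        r = 5
        src = ordering.permutation[r]
        assert out.row_labels[r] == img.row_labels[src]
        np.testing.assert_array_equal(out.pixels[r], img.pixels[src])


class TestPng:
    def test_byte_mapping_and_orientation(self, tmp_path):
        px = np.zeros((156, 48))
        px[0, 0] = 1.0
        img = TimelineImage(px, [f"v{i}" for i in range(156)], "min_max", "standard")
        path = tmp_path / "img.png"
        write_png(img, path)
        from PIL import Image
        with Image.open(path) as im:
            assert im.size == (48, 156)  # width x height
            arr = np.asarray(im)
        assert arr[0, 0] == 255 and arr[1, 1] == 0

    def test_round_trip_within_quantization(self, tmp_path, rng):
        px = rng.random((20, 48))
        img = TimelineImage(px, [f"v{i}" for i in range(20)], "min_max", "standard")
        path = tmp_path / "img.png"
        write_png(img, path)
        back = read_png(path, img.row_labels)
        assert np.abs(back.pixels - px).max() <= 1 / 510 + 1e-9

    def test_pixel_range_enforced(self):
        with pytest.raises(ValueError, match="0, 1"):
            TimelineImage(np.full((3, 48), 1.5), ["a", "b", "c"], "min_max", "standard")
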