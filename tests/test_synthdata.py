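"""Generator realism: printed feature bands, determinism, recovery oracles."""

import numpy as np
import pytest

from belugabuzz.buzzfeatures import extract_features
from belugabuzz.errors import GenerationError
from belugabuzz.feedclassify import FEEDING, NOT_FEEDING, classify_stream, classify_train
from belugabuzz.synthdata import (
    FeedingBuzzParams,
    SocialBuzzParams,
    gen_buzz_dataset,
    gen_feeding_train,
    gen_mooring_stream,
    gen_social_buzz,
    gen_weir_season,
)


class TestFeedingTrains:
    def test_feature_bands_and_shape(self):
        rng = np.random.default_rng(61)
        params = FeedingBuzzParams()
        for i in range(100):
            train = gen_feeding_train(params, rng, train_id=f"f{i}")
            f = extract_features(train)
            assert 2.3 <= f.min_ici <= 8.92
            assert -8.82 <= f.ici_increment_range <= -0.42
            assert f.buzz_onset_index is not None
            # buzz section strictly decreasing: all increments negative
            ici = np.diff(train.click_times) * 1000
            section = ici[f.buzz_onset_index :]
            assert (np.diff(section) < 0).all()
            # pre-buzz mean two to five times the buzz mean
            ratio = ici[: f.buzz_onset_index].mean() / section.mean()
            assert 2.0 <= ratio <= 5.0

    def test_always_classified_feeding(self):
        rng = np.random.default_rng(67)
        for i in range(50):
            f = extract_features(gen_feeding_train(rng=rng), context="unknown")
            assert classify_train(f).verdict == FEEDING

    def test_degenerate_request_rejected(self):
        with pytest.raises(GenerationError):
            gen_feeding_train(rng=np.random.default_rng(0), n_clicks=2)


class TestSocialBuzzes:
    def test_feature_bands_and_irregularity(self):
        rng = np.random.default_rng(71)
        for i in range(100):
            train = gen_social_buzz(rng=rng, train_id=f"s{i}")
            f = extract_features(train)  # social context: whole train
            assert 9.03 <= f.min_ici <= 29.75
            assert 2.98 <= f.ici_increment_range <= 18.72
            increments = np.diff(np.diff(train.click_times) * 1000)
            assert (increments > 0).any() and (increments < 0).any()

    def test_never_classified_feeding(self):
        rng = np.random.default_rng(73)
        for i in range(50):
            f = extract_features(gen_social_buzz(rng=rng), context="unknown")
            assert classify_train(f).verdict == NOT_FEEDING

    def test_social_longer_than_feeding_on_average(self):
        rng = np.random.default_rng(79)
        nf = np.mean([gen_feeding_train(rng=rng).n_clicks for _ in range(30)])
        ns = np.mean([gen_social_buzz(rng=rng).n_clicks for _ in range(30)])
        assert ns > nf

    def test_fixed_seed_reproducible(self):
        a = gen_social_buzz(rng=np.random.default_rng(5))
        b = gen_social_buzz(rng=np.random.default_rng(5))
        np.testing.assert_array_equal(a.click_times, b.click_times)

    def test_invalid_params_rejected(self):
        with pytest.raises(GenerationError):
            SocialBuzzParams(min_ici=(5.0, 10.0))
        with pytest.raises(GenerationError):
            FeedingBuzzParams(buzz_min_ici=(2.3, 9.5))


class TestBuzzDataset:
    def test_study_sized_dataset(self, buzz_dataset):
        trains, features = buzz_dataset
        assert len(trains) == 37
        assert (features["context"] == "feeding").sum() == 18
        assert (features["context"] == "social").sum() == 19

    def test_single_class_dataset_allowed(self):
        trains, features = gen_buzz_dataset(
            n_feeding=0, n_social=4, rng=np.random.default_rng(83)
        )
        assert len(trains) == 4
        assert set(features["context"]) == {"social"}

    def test_empty_request_rejected(self):
        with pytest.raises(GenerationError):
            gen_buzz_dataset(n_feeding=0, n_social=0)


class TestMooringStream:
    def test_feeding_fraction_zero_yields_no_fpm(self):
        stream = gen_mooring_stream(
            days=3, feeding_fraction=0.0, rng=np.random.default_rng(89)
        )
        assert len(stream.planted_feeding_minutes) == 0

    def test_planted_minutes_recovered_by_classifier(self):
        stream = gen_mooring_stream(
            days=4, trains_per_day=15, feeding_fraction=0.4,
            rng=np.random.default_rng(97),
        )
        result = classify_stream(stream.trains)
        minutes = {
            v.first_click_time.floor("min")
            for v in result.verdicts
            if v.verdict == FEEDING
        }
        assert minutes == stream.planted_feeding_minutes

    def test_fixed_seed_reproducible(self):
        a = gen_mooring_stream(days=2, rng=np.random.default_rng(101))
        b = gen_mooring_stream(days=2, rng=np.random.default_rng(101))
        assert a.events.equals(b.events)
        assert len(a.trains) == len(b.trains)


class TestWeirSeason:
    def test_mass_conserved_between_site_and_weir(self):
        season = gen_weir_season(total_fish=500, rng=np.random.default_rng(103))
        assert season.weir.sum() == season.true_site.sum() == 500

    def test_point_mass_lag_is_exact_shift(self):
        from belugabuzz.salmonruns import predict_counts_at_site, travel_time_distribution

        season = gen_weir_season(
            total_fish=300, lag_samples=[3], rng=np.random.default_rng(107)
        )
        predicted = predict_counts_at_site(
            season.weir, travel_time_distribution(season.travel_time_samples)
        )
        aligned = predicted.reindex(season.true_site.index, fill_value=0.0)
        np.testing.assert_allclose(aligned.to_numpy(), season.true_site.to_numpy())

    def test_zero_fish_rejected(self):
        with pytest.raises(GenerationError):
            gen_weir_season(total_fish=0)
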