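import numpy as np
import pytest

from trbci.epochs import (
    Epoch,
    average_epochs,
    extract_features,
    feature_CNR,
    feature_r,
    feature_SM,
    feature_SS,
    model_epoch,
)
from trbci.protocol import build_protocol

PROTOCOL = build_protocol()
DT = PROTOCOL.frame_period_s


def make_epoch(values, dispersion=None):
    values = np.asarray(values, dtype=float)
    assert values.size == 200
    return Epoch(values, DT, 50, 150, 5, 1, "HbO2", dispersion)


class TestAverageEpochs:
    def test_constant_input_gives_zero_epoch(self):
        epoch = average_epochs([np.full(1100, 4.2)], PROTOCOL)
        np.testing.assert_allclose(epoch.values, 0.0, atol=1e-12)
        assert epoch.values.size == 200
        assert epoch.duration_s == pytest.approx(60.0)

    def test_identical_cycles_average_to_one_cycle(self, rng):
        cycle = rng.normal(0.0, 1.0, 200)
        run = np.concatenate([cycle[:50], np.tile(cycle[50:].repeat(1), 5), cycle[:50]])
        # build a run whose every epoch window sees the same 200 samples
        run = np.zeros(1100)
        template = rng.normal(0.0, 1.0, 200)
        for onset_s in PROTOCOL.answer_onsets_s:
            i = int(round(onset_s / DT))
            run[i - 50 : i + 150] = template
        epoch = average_epochs([run], PROTOCOL)
        expected = template - template[:50].mean()
        np.testing.assert_allclose(epoch.values, expected, atol=1e-10)

    def test_white_noise_averaging_shrinks_by_sqrt_n(self):
        """SD of the averaged epoch ~ single-cycle SD / sqrt(cycles*channels)
        within 15% over 10 seeds."""
        ratios = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            chans = [r.normal(0.0, 1.0, 1100) for _ in range(4)]
            epoch = average_epochs(chans, PROTOCOL)
            single = chans[0][50:250] - chans[0][50:100].mean()
            ratios.append(epoch.values.std() / single.std())
        expected = 1.0 / np.sqrt(5 * 4)
        assert np.mean(ratios) == pytest.approx(expected, rel=0.15)

    def test_cycle_count_bounds(self):
        with pytest.raises(ValueError):
            average_epochs([np.zeros(1100)], PROTOCOL, n_cycles=6)
        with pytest.raises(ValueError):
            average_epochs([np.zeros(1100)], PROTOCOL, n_cycles=0)

    def test_dispersion_is_standard_error_across_units(self, rng):
        chans = [rng.normal(0.0, 1.0, 1100) for _ in range(2)]
        epoch = average_epochs(chans, PROTOCOL)
        assert epoch.dispersion.shape == (200,)
        assert epoch.dispersion.mean() == pytest.approx(1.0 / np.sqrt(10), rel=0.25)


class TestFeatures:
    def test_sm_plateau_minus_rest(self):
        values = np.concatenate([np.full(50, 0.2), np.full(100, 1.0), np.full(50, 0.2)])
        assert feature_SM(make_epoch(values)) == pytest.approx(0.8)

    def test_sm_zero_epoch(self):
        assert feature_SM(make_epoch(np.zeros(200))) == 0.0

    def test_sm_on_a_ramp_matches_direct_median_evaluation(self):
        values = np.arange(200) * 0.01
        skip = int(np.ceil(10.0 / DT))
        expected = np.median(values[50 + skip : 150]) - np.median(values[:50])
        assert feature_SM(make_epoch(values)) == pytest.approx(expected, rel=1e-12)

    def test_ss_recovers_an_exact_ramp_slope(self):
        values = np.zeros(200)
        t_task = (np.arange(50, 150) - 50) * DT
        values[50:150] = 0.05 * t_task
        assert feature_SS(make_epoch(values)) == pytest.approx(0.05, rel=1e-9)

    def test_ss_flat_epoch_is_zero(self):
        assert feature_SS(make_epoch(np.ones(200))) == pytest.approx(0.0, abs=1e-12)

    def test_ss_matches_normal_equation_oracle(self, rng):
        values = rng.normal(0.0, 1.0, 200)
        n = int(round(16.0 / DT))
        y = values[50 : 50 + n]
        t = np.arange(n) * DT
        expected = ((t - t.mean()) * (y - y.mean())).sum() / ((t - t.mean()) ** 2).sum()
        assert feature_SS(make_epoch(values)) == pytest.approx(expected, rel=1e-9)

    def test_ss_window_cannot_exceed_task(self):
        with pytest.raises(ValueError):
            feature_SS(make_epoch(np.zeros(200)), slope_window_s=40.0)

    def test_cnr_simple_numbers(self):
        rest = np.zeros(50)
        rest[::2] = 1.0  # mean 0.5, sd ~0.505
        values = np.concatenate([rest, np.full(100, 1.5), np.zeros(50)])
        epoch = make_epoch(values)
        expected = (1.5 - 0.5) / np.std(rest, ddof=1)
        assert feature_CNR(epoch) == pytest.approx(expected, rel=1e-12)

    def test_cnr_task_equals_rest_statistics(self, rng):
        values = rng.normal(0.0, 1.0, 200)
        assert abs(feature_CNR(make_epoch(values))) < 1.0

    def test_cnr_matches_two_pass_oracle(self, rng):
        values = rng.normal(0.3, 0.7, 200)
        epoch = make_epoch(values)
        rest, task = values[:50], values[50:150]
        expected = (task.mean() - rest.mean()) / rest.std(ddof=1)
        assert feature_CNR(epoch) == pytest.approx(expected, rel=1e-12)

    def test_cnr_degenerate_rest_rejected(self):
        values = np.concatenate([np.zeros(50), np.ones(150)])
        with pytest.raises(ValueError, match="degenerate"):
            feature_CNR(make_epoch(values))

    def test_r_on_the_model_is_one(self):
        model = model_epoch(PROTOCOL)
        assert feature_r(model, model) == pytest.approx(1.0)
        negated = make_epoch(-model.values)
        assert feature_r(negated, model) == pytest.approx(-1.0)

    def test_r_matches_pearson_oracle(self, rng):
        values = rng.normal(0.0, 1.0, 200)
        epoch = make_epoch(values)
        model = model_epoch(PROTOCOL)
        x, y = values, model.values
        expected = (
            ((x - x.mean()) * (y - y.mean())).mean() / (x.std() * y.std())
        )
        assert feature_r(epoch, model) == pytest.approx(expected, rel=1e-12)

    def test_r_bounded_and_symmetric(self, rng):
        a = make_epoch(rng.normal(0.0, 1.0, 200))
        b = make_epoch(rng.normal(0.0, 1.0, 200))
        r_ab = feature_r(a, b)
        assert -1.0 <= r_ab <= 1.0
        assert feature_r(b, a) == pytest.approx(r_ab, rel=1e-12)


class TestFeatureInvariances:
    def test_amplitude_equivariance(self, rng):
        values = rng.normal(0.0, 1.0, 200)
        model = model_epoch(PROTOCOL)
        f1 = extract_features(make_epoch(values), model)
        f2 = extract_features(make_epoch(3.0 * values), model)
        assert f2.SM == pytest.approx(3.0 * f1.SM, rel=1e-9)
        assert f2.SS == pytest.approx(3.0 * f1.SS, rel=1e-9)
        assert f2.CNR == pytest.approx(f1.CNR, rel=1e-9)
        assert f2.r == pytest.approx(f1.r, rel=1e-9)

    def test_offset_invariance(self, rng):
        values = rng.normal(0.0, 1.0, 200)
        model = model_epoch(PROTOCOL)
        f1 = extract_features(make_epoch(values), model)
        f2 = extract_features(make_epoch(values + 17.0), model)
        assert f2.SM == pytest.approx(f1.SM, rel=1e-9)
        assert f2.SS == pytest.approx(f1.SS, rel=1e-9)
        assert f2.CNR == pytest.approx(f1.CNR, rel=1e-9)
        assert f2.r == pytest.approx(f1.r, rel=1e-9)

    def test_degenerate_noise_free_no_epoch_is_guarded(self):
        fv = extract_features(make_epoch(np.zeros(200)), model_epoch(PROTOCOL))
        assert fv.SM == 0.0 and fv.SS == 0.0
        assert np.isfinite(fv.CNR) and np.isfinite(fv.r)

    def test_model_shaped_epoch_has_unit_correlation(self):
        model = model_epoch(PROTOCOL)
        fv = extract_features(make_epoch(model.values.copy()), model)
        assert fv.r == pytest.approx(1.0)
        assert fv.SM > 0


def test_responder_features_separate_from_non_responders(default_study):
    """On the default synthetic cohort the responder 'yes' runs separate from
    all 'no'/non-responder runs by more than one pooled SD in r."""
    yes_resp = [
        rec.features.r
        for rec, e in zip(default_study.records, default_study.manifest.entries)
        if rec.truth == "yes" and e["responder"]
    ]
    rest = [
        rec.features.r
        for rec, e in zip(default_study.records, default_study.manifest.entries)
        if rec.truth == "no" or not e["responder"]
    ]
    pooled_sd = np.sqrt((np.var(yes_resp) + np.var(rest)) / 2)
    assert (np.mean(yes_resp) - np.mean(rest)) > 1.0 * pooled_sd
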