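import numpy as np
import pytest

from trbci.conversion import ExtinctionTable
from trbci.montecarlo import bin_photon_records
from trbci.mtof import windowed_moments
from trbci.protocol import build_protocol
from trbci.simulate import (
    AcquisitionConfig,
    CohortConfig,
    NoiseConfig,
    ParticipantProfile,
    draw_cohort,
    hemodynamic_timecourse,
    hrf_kernel,
    simulate_run,
)


@pytest.fixture(scope="module")
def table():
    return ExtinctionTable.default()


class TestHemodynamics:
    def test_no_answer_is_identically_zero(self):
        protocol = build_protocol()
        hbo2, hb = hemodynamic_timecourse(protocol, "no", ParticipantProfile("P"))
        assert not hbo2.any() and not hb.any()

    def test_long_block_plateaus_at_the_profile_amplitude(self):
        """Unit-area kernel convolved with a long boxcar approaches the step
        amplitude: 60-s blocks plateau at amp within 1%."""
        protocol = build_protocol(answer_s=60.0, rest_s=60.0, n_cycles=2)
        prof = ParticipantProfile("P", amp_hbo2=1.0, amp_hb=-0.3)
        hbo2, hb = hemodynamic_timecourse(protocol, "yes", prof)
        dt = protocol.frame_period_s
        # end of the first 60-s answer block
        i = int(round((30.0 + 60.0) / dt)) - 1
        assert hbo2[i] == pytest.approx(1.0, rel=0.01)
        assert hb[i] == pytest.approx(-0.3, rel=0.01)

    def test_response_correlates_perfectly_with_the_feature_model(self):
        """Same kernel in generation and feature model -> self-correlation 1."""
        from trbci.epochs import average_epochs, feature_r, model_epoch

        protocol = build_protocol()
        prof = ParticipantProfile("P", amp_hbo2=0.8, amp_hb=-0.2, hrf_peak_s=7.0)
        hbo2, _ = hemodynamic_timecourse(protocol, "yes", prof)
        epoch = average_epochs([hbo2], protocol)
        assert feature_r(epoch, model_epoch(protocol)) == pytest.approx(1.0, abs=1e-9)

    def test_non_responder_profile_forces_zero_amplitudes(self):
        prof = ParticipantProfile("P", responder=False, amp_hbo2=0.9, amp_hb=-0.2)
        assert prof.amp_hbo2 == 0.0 and prof.amp_hb == 0.0

    def test_kernel_peaks_at_the_stated_time(self):
        dt = 0.1
        k = hrf_kernel(dt, peak_s=7.0)
        assert np.argmax(k) * dt == pytest.approx(7.0, abs=2 * dt)
        assert k.sum() == pytest.approx(1.0)


@pytest.fixture(scope="module")
def binned(mc_records, medium):
    acq = AcquisitionConfig()
    return bin_photon_records(mc_records, acq.bin_edges_ps, medium.mu_a)


class TestSimulateRun:
    def test_noise_off_no_answer_gives_identical_frames(self, binned, medium, table):
        protocol = build_protocol()
        run = simulate_run(
            protocol, ParticipantProfile("P"), "no", binned, medium,
            AcquisitionConfig(), NoiseConfig.silent(), table, seed=5,
        )
        counts = run[(0, 830.0)]
        assert np.allclose(counts, counts[0][None, :])
        t_mean, _, _ = windowed_moments(counts, AcquisitionConfig().bin_edges_ps)
        np.testing.assert_allclose(t_mean - t_mean[0], 0.0, atol=1e-9)

    def test_same_seed_reproduces_identical_data(self, binned, medium, table):
        protocol = build_protocol()
        kwargs = dict(
            protocol=protocol, profile=ParticipantProfile("P", amp_hbo2=0.5, amp_hb=-0.15),
            truth="yes", records=binned, medium=medium,
            acquisition=AcquisitionConfig(), noise=NoiseConfig(), table=table,
        )
        a = simulate_run(seed=77, **kwargs)
        b = simulate_run(seed=77, **kwargs)
        for key in a:
            np.testing.assert_array_equal(a[key], b[key])

    def test_poisson_mean_time_variance_matches_counting_statistics(
        self, binned, medium, table
    ):
        """With Poisson noise only, Var(<t>) across frames ~ Var(t)/N within
        20% (checked on 200 identical-expectation frames)."""
        protocol = build_protocol(baseline_s=60.0, n_cycles=0, frame_period_ms=300.0)
        acq = AcquisitionConfig(n_channels=1, counts_per_frame=1e5)
        expected_run = simulate_run(
            protocol, ParticipantProfile("P"), "no", binned, medium, acq,
            NoiseConfig.silent(), table, seed=11,
        )[(0, 830.0)][0]
        from trbci.mtof import truncate_window

        window = truncate_window(expected_run)
        run = simulate_run(
            protocol, ParticipantProfile("P"), "no", binned, medium, acq,
            NoiseConfig(systemic=False, motion=False, drift=False, poisson=True),
            table, seed=11,
        )
        counts = run[(0, 830.0)].astype(float)
        t_mean, tot, _ = windowed_moments(counts, acq.bin_edges_ps, window=window)
        # predicted: variance of the truncated arrival-time distribution / N
        i0, i1 = window
        centers = 0.5 * (acq.bin_edges_ps[:-1] + acq.bin_edges_ps[1:])
        c = expected_run[i0 : i1 + 1]
        t = centers[i0 : i1 + 1]
        mu = (c * t).sum() / c.sum()
        var_t = (c * (t - mu) ** 2).sum() / c.sum()
        predicted = var_t / tot.mean()
        assert t_mean.var(ddof=1) == pytest.approx(predicted, rel=0.20)

    def test_motion_spikes_perturb_flagged_frames_only(self, binned, medium, table):
        protocol = build_protocol()
        noise = NoiseConfig(
            systemic=False, drift=False, poisson=False, motion=True, motion_rate_hz=0.02
        )
        run = simulate_run(
            protocol, ParticipantProfile("P"), "no", binned, medium,
            AcquisitionConfig(n_channels=1), noise, table, seed=21,
        )
        counts = run[(0, 830.0)]
        t_mean, _, _ = windowed_moments(counts, AcquisitionConfig().bin_edges_ps)
        dev = np.abs(t_mean - np.median(t_mean))
        assert (dev > 1.0).any()          # some frames were hit
        assert (dev < 1e-9).mean() > 0.8  # the rest are untouched


class TestDrawCohort:
    def test_manifest_is_deterministic_for_a_seed(self):
        cfg = CohortConfig()
        _, m1 = draw_cohort(cfg, 33)
        _, m2 = draw_cohort(cfg, 33)
        assert m1.to_json() == m2.to_json()

    def test_rows_are_participants_times_questions(self):
        cfg = CohortConfig(n_participants=7, n_questions=4)
        profiles, manifest = draw_cohort(cfg, 5)
        assert len(profiles) == 7
        assert len(manifest.entries) == 28
        for pid in {e["participant"] for e in manifest.entries}:
            rows = [e for e in manifest.entries if e["participant"] == pid]
            assert sorted(e["question_index"] for e in rows) == [1, 2, 3, 4]
            assert sum(e["truth"] == "yes" for e in rows) == cfg.yes_per_participant

    def test_non_responder_count_matches_identical_rng_stream(self):
        """Brute-force redraw with the same seed reproduces the realised
        non-responder count (~12% of 18 expected)."""
        cfg = CohortConfig()
        profiles, _ = draw_cohort(cfg, 99)
        realized = sum(not p.responder for p in profiles)
        rng = np.random.default_rng(99)
        expected = 0
        for _ in range(cfg.n_participants):
            responder = rng.random() >= cfg.non_responder_frac
            if responder:
                rng.normal(cfg.amp_hbo2_mean_um, cfg.amp_hbo2_sd_um)
            else:
                expected += 1
            rng.normal(cfg.hrf_peak_mean_s, cfg.hrf_peak_sd_s)
            rng.permutation(cfg.n_questions)
            rng.integers(0, 2**31, size=None)  # seed draws, one per question
            for _ in range(cfg.n_questions - 1):
                rng.integers(0, 2**31, size=None)
        assert realized == expected
        assert 0 <= realized <= cfg.n_participants

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            draw_cohort(CohortConfig(n_participants=1), 1)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            draw_cohort(CohortConfig(non_responder_frac=1.0), 1)
        with pytest.raises(ValueError):
            draw_cohort(CohortConfig(yes_per_participant=9), 1)
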