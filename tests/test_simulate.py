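import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from walkmort.signal_io import WALKING
from walkmort.simulate import (
    BoutLengthDist,
    HazardCoefs,
    SimConfig,
    _rng,
    _S_SIGNAL,
    _walking_magnitudes,
    simulate_cohort,
    simulate_ph_scenario,
    simulate_recording,
    simulate_survival,
)

SHORT_DAYS = 300.0 / 86400.0  # a 5-minute "week" for recording-level tests


def short_config(**kw):
    return SimConfig(n_participants=5, recording_days=SHORT_DAYS, **kw)


def profile(intensity=0.2):
    return {"age": 60.0, "sex": 1, "true_intensity": intensity}


def test_recording_length_and_epoch_count():
    cfg = short_config(seed=3)
    rec, labels = simulate_recording(profile(), cfg)
    assert rec.n_samples == int(SHORT_DAYS * 86400 * 100)  # days * 86400 s * rate
    assert len(labels) == cfg.n_epochs == 10


def test_week_yields_20160_epochs():
    assert SimConfig(recording_days=7, epoch_s=30).n_epochs == 20160


def test_stationary_device_magnitude_is_exactly_one_g():
    cfg = short_config(walk_noise_sd=0.0, rest_noise_sd=0.0, seed=1)
    rec, _ = simulate_recording(profile(intensity=0.0), cfg)
    mag = np.linalg.norm(rec.samples, axis=1)
    np.testing.assert_allclose(mag, 1.0, rtol=1e-12)
    # hence epoch ENMOtrunc is 0
    assert np.mean(np.maximum(mag - 1.0, 0.0)) == pytest.approx(0.0, abs=1e-12)


def test_recording_determinism_and_seed_sensitivity():
    rec1, lab1 = simulate_recording(profile(), short_config(seed=5))
    rec2, lab2 = simulate_recording(profile(), short_config(seed=5))
    rec3, _ = simulate_recording(profile(), short_config(seed=6))
    np.testing.assert_array_equal(rec1.samples, rec2.samples)
    assert lab1 == lab2
    assert not np.array_equal(rec1.samples, rec3.samples)


def test_invalid_durations_rejected():
    with pytest.raises(ValueError):
        SimConfig(recording_days=0)
    with pytest.raises(ValueError):
        SimConfig(sampling_rate_hz=-1)


def test_null_hazard_matches_exponential_cdf():
    # all betas zero: event proportion over horizon Y is 1 - exp(-h0*Y)
    n, h0, y = 10000, 0.05, 5.0
    cfg = SimConfig(
        n_participants=n,
        hazard_coefs=HazardCoefs(0.0, 0.0, 0.0),
        baseline_hazard=h0,
        dropout_fraction=0.0,
        seed=42,
    )
    profiles = pd.DataFrame(
        {"age": np.full(n, 60.0), "sex": np.zeros(n), "true_intensity": np.full(n, 0.2)}
    )
    surv = simulate_survival(profiles, cfg)
    expected = 1.0 - np.exp(-h0 * y)
    mc_sd = np.sqrt(expected * (1 - expected) / n)
    assert surv["event"].mean() == pytest.approx(expected, abs=4 * mc_sd)


def test_protective_intensity_gives_negative_rank_correlation():
    n = 8000
    rng = np.random.default_rng(0)
    profiles = pd.DataFrame(
        {
            "age": np.full(n, 62.0),  # age and sex held fixed
            "sex": np.zeros(n),
            "true_intensity": rng.uniform(0.05, 0.35, n),
        }
    )
    cfg = SimConfig(n_participants=n, dropout_fraction=0.0, event_rate_target=0.1, seed=9)
    assert cfg.hazard_coefs.beta_enmo < 0
    surv = simulate_survival(profiles, cfg)
    rho = spearmanr(profiles["true_intensity"], surv["event"]).statistic
    assert rho < 0


def test_zero_horizon_censors_everything_at_time_zero():
    profiles = pd.DataFrame({"age": [60.0], "sex": [0], "true_intensity": [0.2]})
    surv = simulate_survival(profiles, SimConfig(admin_censor_years=0.0, baseline_hazard=0.1))
    assert surv["time"].iloc[0] == 0.0 and surv["event"].iloc[0] == 0


def test_event_rate_calibration_across_seeds():
    rates = [
        simulate_cohort(SimConfig(n_participants=5000, seed=s), signals="none")
        .participants["event"]
        .mean()
        for s in range(10)
    ]
    assert abs(np.mean(rates) - 0.02) < 0.005


def test_cohort_determinism(default_cohort):
    again = simulate_cohort(SimConfig(n_participants=1500, seed=101))
    pd.testing.assert_frame_equal(default_cohort.participants, again.participants)
    pd.testing.assert_frame_equal(default_cohort.ground_truth, again.ground_truth)


def test_walking_enmo_monotone_in_intensity():
    cfg = SimConfig()
    lengths = np.array([20, 20, 20])
    means = []
    for intensity in (0.05, 0.1, 0.15, 0.2, 0.3):
        rng = _rng(7, _S_SIGNAL, 0)
        mags = _walking_magnitudes(rng, cfg, intensity, lengths)
        means.append(np.mean(np.maximum(mags - 1.0, 0.0)))
    assert all(a < b for a, b in zip(means, means[1:]))


def test_walking_epochs_exceed_rest_epochs_for_every_participant():
    cfg = short_config(seed=21, bouts_per_day=3000.0)  # force bouts into a short window
    for i in range(3):
        rec, labels = simulate_recording(profile(0.15), cfg, participant_index=i)
        mag = np.linalg.norm(rec.samples, axis=1).reshape(-1, 3000)[: len(labels)]
        enmo = np.maximum(mag - 1.0, 0.0).mean(axis=1)
        walking = np.array([l == WALKING for l in labels])
        if walking.any() and (~walking).any():
            assert enmo[walking].mean() > enmo[~walking].mean()


def test_bout_mixture_supports_inclusion_design(default_cohort):
    p = default_cohort.participants
    # ~90% of participants have at least one qualifying (>=12 epoch) run
    assert 0.82 <= p["included"].mean() <= 0.96
    lengths = BoutLengthDist().sample(np.random.default_rng(0), 20000)
    assert lengths.min() >= 1 and lengths.max() <= 40


def test_site_assignment_and_ground_truth_consistency(default_cohort):
    p = default_cohort.participants
    gt = default_cohort.ground_truth
    assert p["site"].between(0, 21).all()
    # observed time = min(event time, censor time); event iff the event time won
    t = np.minimum(gt["true_event_time"], gt["censor_time"])
    np.testing.assert_allclose(p["time"], t)
    np.testing.assert_array_equal(
        p["event"], (gt["true_event_time"] <= gt["censor_time"]).astype(int)
    )


def test_ph_scenario_is_proportional_when_betas_match():
    d1 = simulate_ph_scenario(500, beta_early=0.7, seed=3)
    d2 = simulate_ph_scenario(500, beta_early=0.7, beta_late=0.7, seed=3)
    pd.testing.assert_frame_equal(d1, d2)
    assert 0 < d1["event"].mean() < 1
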