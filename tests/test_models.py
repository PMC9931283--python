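import numpy as np
import pandas as pd
import pytest

from walkmort import models as M
from walkmort.simulate import SimConfig, simulate_cohort, simulate_ph_scenario

from oracles import concordance_oracle, grid_argmax_beta


def random_survival(rng, n, tie_times=False, tie_scores=False):
    times = rng.integers(1, 8, n).astype(float) if tie_times else rng.exponential(3.0, n)
    events = (rng.random(n) < 0.6).astype(int)
    scores = rng.integers(0, 4, n).astype(float) if tie_scores else rng.normal(size=n)
    return times, events, scores


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------


def test_perfect_ordering_and_inversion():
    t = np.array([1.0, 2.0, 3.0])
    e = np.ones(3, dtype=int)
    assert M.concordance_index(t, e, np.array([3.0, 2.0, 1.0])) == 1.0
    assert M.concordance_index(t, e, np.array([1.0, 2.0, 3.0])) == 0.0


def test_concordance_matches_brute_force_with_ties():
    rng = np.random.default_rng(0)
    for k in range(40):
        t, e, s = random_survival(rng, int(rng.integers(10, 60)),
                                  tie_times=k % 2 == 0, tie_scores=k % 3 == 0)
        if e.sum() == 0:
            continue
        assert M.concordance_index(t, e, s) == pytest.approx(
            concordance_oracle(t, e, s), abs=1e-14
        )


def test_concordance_antisymmetry_without_ties():
    rng = np.random.default_rng(1)
    t, e, s = random_survival(rng, 50)
    assert M.concordance_index(t, e, s) + M.concordance_index(t, e, -s) == pytest.approx(1.0)


def test_concordance_cross_checks_against_sksurv():
    from sksurv.metrics import concordance_index_censored

    rng = np.random.default_rng(2)
    t, e, s = random_survival(rng, 80)
    ours = M.concordance_index(t, e, s)
    theirs = concordance_index_censored(e.astype(bool), t, s)[0]
    assert ours == pytest.approx(theirs, abs=1e-12)


def test_no_comparable_pairs_is_an_error():
    with pytest.raises(ValueError, match="comparable"):
        M.concordance_index([1.0, 2.0], [0, 0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# stratified folds
# ---------------------------------------------------------------------------


def test_exactly_divisible_strata():
    e = np.array([1] * 20 + [0] * 80)
    folds = M.stratified_folds(e, k=10, seed=0)
    for f in range(10):
        assert (e[folds == f] == 1).sum() == 2
        assert (e[folds == f] == 0).sum() == 8


def test_remainder_spreads_by_at_most_one():
    e = np.array([1] * 21 + [0] * 80)
    folds = M.stratified_folds(e, k=10, seed=0)
    dead = [(e[folds == f] == 1).sum() for f in range(10)]
    assert set(dead) <= {2, 3} and sum(dead) == 21


def test_folds_partition_cohort_and_are_deterministic():
    rng = np.random.default_rng(3)
    for _ in range(5):
        n = int(rng.integers(60, 200))
        e = (rng.random(n) < 0.3).astype(int)
        if e.sum() < 10 or (1 - e).sum() < 10:
            continue
        f1 = M.stratified_folds(e, k=10, seed=7)
        f2 = M.stratified_folds(e, k=10, seed=7)
        np.testing.assert_array_equal(f1, f2)
        assert set(f1) == set(range(10))
        assert len(f1) == n


def test_too_few_events_for_folds():
    with pytest.raises(ValueError, match="events"):
        M.stratified_folds([1, 0, 0, 0, 0], k=2)
    # 1 event < 2 folds
    with pytest.raises(ValueError):
        M.stratified_folds([1] * 5, k=2)


# ---------------------------------------------------------------------------
# penalized Cox
# ---------------------------------------------------------------------------

HAND_DATA = pd.DataFrame(
    {
        "x": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
        "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        "event": [1, 1, 0, 1, 1, 0],
    }
)


def test_unpenalized_fit_matches_likelihood_grid_search():
    fit = M.fit_penalized_cox(HAND_DATA, ["x"], alpha=0.0, lam=0.0)
    beta_grid = grid_argmax_beta(
        HAND_DATA["x"].tolist(), HAND_DATA["time"].tolist(), HAND_DATA["event"].tolist()
    )
    assert fit.coef[0] == pytest.approx(beta_grid, abs=1e-4)


def test_lasso_zeroes_all_coefficients_above_lambda_max(model_table):
    preds = ["age", "sex", "ENMOtrunc"]
    lmax = M.lambda_max(model_table, preds, alpha=1.0)
    hi = M.fit_penalized_cox(model_table, preds, alpha=1.0, lam=lmax * 1.001)
    lo = M.fit_penalized_cox(model_table, preds, alpha=1.0, lam=lmax * 0.9)
    assert np.all(hi.coef == 0.0)
    assert np.any(lo.coef_std != 0.0)


def test_l1_norm_nonincreasing_along_path(model_table):
    preds = ["age", "sex", "race", "ENMOtrunc", "ENMOabs"]
    lmax = M.lambda_max(model_table, preds, alpha=1.0)
    grid = np.geomspace(lmax, 1e-3 * lmax, 12)
    norms = [
        np.abs(M.fit_penalized_cox(model_table, preds, alpha=1.0, lam=l).coef_std).sum()
        for l in grid
    ]
    # lambda decreasing -> L1 norm nondecreasing
    assert all(b >= a - 1e-8 for a, b in zip(norms, norms[1:]))


def test_no_events_is_an_error():
    df = HAND_DATA.assign(event=0)
    with pytest.raises(ValueError, match="events"):
        M.fit_penalized_cox(df, ["x"])


def test_confidence_interval_coverage_of_true_hazard_coefficients():
    """Unpenalized fits on the ground-truth covariates cover the generator's
    coefficients at roughly the nominal 95% rate."""
    from lifelines import CoxPHFitter

    truth = SimConfig().hazard_coefs
    true_beta = {"age": truth.beta_age, "sex": truth.beta_sex, "true_intensity": truth.beta_enmo}
    hits = {k: 0 for k in true_beta}
    n_rep = 12
    for s in range(n_rep):
        cohort = simulate_cohort(SimConfig(n_participants=2000, seed=600 + s), signals="none")
        p = cohort.participants
        df = p[["age", "sex", "true_intensity", "time", "event"]]
        cph = CoxPHFitter().fit(df, duration_col="time", event_col="event")
        ci = cph.confidence_intervals_
        for k in true_beta:
            lo, hi = ci.loc[k]
            hits[k] += int(lo <= true_beta[k] <= hi)
    for k, h in hits.items():
        assert h >= int(0.75 * n_rep), (k, h)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def test_pure_noise_feature_scores_near_half():
    cohort = simulate_cohort(SimConfig(n_participants=2000, seed=55), signals="none")
    df = cohort.participants[["time", "event"]].copy()
    df["noise"] = np.random.default_rng(5).normal(size=len(df))
    cv = M.cross_validate(df, ["noise"], penalty=None, k=10, seed=1)
    assert cv.mean_cindex == pytest.approx(0.5, abs=0.05)


def test_cross_validation_is_deterministic(model_table):
    cv1 = M.cross_validate(model_table, ["age", "sex"], horizon=5.0, k=10, seed=9)
    cv2 = M.cross_validate(model_table, ["age", "sex"], horizon=5.0, k=10, seed=9)
    np.testing.assert_array_equal(cv1.folds, cv2.folds)
    np.testing.assert_array_equal(cv1.fold_cindex, cv2.fold_cindex)


def test_penalty_grid_selection_reports_best_pair(model_table):
    spec = M.PenaltySpec(alphas=(0.5, 1.0), n_lambda=8)
    cv = M.cross_validate(model_table, ["age", "sex", "ENMOtrunc", "ENMOabs"],
                          penalty=spec, horizon=5.0, k=5, seed=2)
    assert cv.alpha in (0.5, 1.0)
    assert cv.grid is not None and len(cv.grid) == 16
    assert cv.mean_cindex == pytest.approx(cv.grid["mean_cindex"].max())


# ---------------------------------------------------------------------------
# stepwise and marginal
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def noisy_table():
    cohort = simulate_cohort(SimConfig(n_participants=1200, seed=88), signals="none")
    df = cohort.participants[["age", "sex", "time", "event"]].copy()
    rng = np.random.default_rng(6)
    for j in range(5):
        df[f"noise{j}"] = rng.normal(size=len(df))
    return df


def test_stepwise_picks_informative_feature_first(noisy_table):
    cands = tuple(["noise0", "noise1", "noise2", "age"])
    trace = M.stepwise_select(
        noisy_table, M.StepwiseConfig(candidates=cands, threshold=0.01, k=5), seed=3
    )
    assert trace.iloc[0]["name"] == "age"
    accepted = trace["increment"].dropna()
    assert (accepted >= 0.01).all()


def test_stepwise_stops_at_unachievable_threshold(noisy_table):
    trace = M.stepwise_select(
        noisy_table,
        M.StepwiseConfig(candidates=("noise0", "noise1"), threshold=0.45, base=("age",), k=5),
        seed=3,
    )
    assert trace["name"].tolist() == ["age"]


def test_marginal_ranking_finds_informative_feature(noisy_table):
    rank = M.marginal_feature_ranking(
        noisy_table, ["noise0", "age", "noise1", "noise2"], k=5, seed=4
    )
    assert rank.iloc[0]["feature"] == "age"
    # ranking invariant to candidate order
    rank2 = M.marginal_feature_ranking(
        noisy_table, ["noise2", "noise1", "noise0", "age"], k=5, seed=4
    )
    assert rank["feature"].tolist() == rank2["feature"].tolist()


def test_constant_feature_scores_exactly_half(noisy_table):
    df = noisy_table.assign(flat=1.0)
    rank = M.marginal_feature_ranking(df, ["flat"], k=5, seed=1)
    assert rank.iloc[0]["cindex"] == 0.5


# ---------------------------------------------------------------------------
# hierarchy
# ---------------------------------------------------------------------------


def test_duplicated_features_merge_at_height_zero():
    rng = np.random.default_rng(7)
    df = pd.DataFrame({"a": rng.normal(size=100)})
    df["b"] = df["a"]
    df["c"] = rng.normal(size=100)
    h = M.feature_hierarchy(df, ["a", "b", "c"])
    z = h["linkage"]
    assert z[0, 2] == pytest.approx(0.0, abs=1e-12)
    assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}


def test_enmo_variants_are_nearest_neighbours(model_table):
    h = M.feature_hierarchy(model_table, ["age", "ENMOtrunc", "ENMOabs", "sex"],
                            duration_col="time", event_col="event", k=5)
    z = h["linkage"]
    first = {int(z[0, 0]), int(z[0, 1])}
    assert first == {1, 2}  # the two ENMO variants merge first
    assert h["selected"] is not None and len(h["selected"]) == 4


# ---------------------------------------------------------------------------
# Schoenfeld diagnostics
# ---------------------------------------------------------------------------


def test_residuals_exist_only_at_event_times(model_table):
    summary, resid = M.schoenfeld_test(model_table, ["age", "sex", "ENMOtrunc"])
    assert len(resid) == int(model_table["event"].sum())
    assert set(summary["predictor"]) == {"age", "sex", "ENMOtrunc"}


def test_schoenfeld_needs_three_events():
    df = pd.DataFrame({"x": [1.0, 0.5, 0.2, 0.8], "time": [1, 2, 3, 4.0], "event": [1, 1, 0, 0]})
    with pytest.raises(ValueError, match="3 events"):
        M.schoenfeld_test(df, ["x"])


def test_strong_time_varying_effect_is_detected():
    d = simulate_ph_scenario(2000, beta_early=1.0, beta_late=-1.0, seed=11)
    summary, _ = M.schoenfeld_test(d, ["x"])
    assert not summary["pass_ph"].iloc[0]


# ---------------------------------------------------------------------------
# percentile survival curves
# ---------------------------------------------------------------------------


def test_percentile_one_returns_first_event_time():
    t, censored = M._km_crossing_time(
        np.array([2.0, 3.0, 5.0, 7.0]), np.array([1, 0, 1, 0]), percentile=1.0
    )
    assert t == 2.0 and not censored


def test_no_events_reports_horizon_with_censored_flag():
    t, censored = M._km_crossing_time(np.array([4.0, 5.0]), np.array([0, 0]), percentile=0.98)
    assert t == 5.0 and censored


def test_curves_cover_sex_by_tertile_strata(model_table):
    curves = M.percentile_survival_curves(model_table, "ENMOtrunc")
    assert set(curves["sex"]) == {0, 1}
    assert set(curves["tertile"]) == {1, 2, 3}
    assert (curves["crossing_time"] <= 5.0 + 1e-9).all()


# ---------------------------------------------------------------------------
# grouped concordance
# ---------------------------------------------------------------------------


def test_single_group_equals_global_cindex(model_table):
    fit = M.fit_penalized_cox(model_table, ["age", "sex", "ENMOtrunc"])
    df = model_table.assign(everyone="all")
    grouped = M.grouped_cindex(df, fit, "everyone")
    global_ci = M.concordance_index(
        model_table["time"], model_table["event"], fit.risk_scores(model_table)
    )
    assert grouped.loc[0, "cindex"] == pytest.approx(global_ci)


def test_zero_event_group_is_flagged():
    fit_df = pd.DataFrame(
        {"x": [1.0, 0.2, 0.5, 0.9, 0.1, 0.7], "time": [1, 2, 3, 4, 5, 6.0],
         "event": [1, 1, 0, 1, 0, 0], "g": ["a", "a", "a", "a", "b", "b"]}
    )
    fit = M.fit_penalized_cox(fit_df, ["x"])
    grouped = M.grouped_cindex(fit_df, fit, "g")
    row_b = grouped[grouped["group"] == "b"].iloc[0]
    assert bool(row_b["flagged"]) and np.isnan(row_b["cindex"])


def test_per_site_spread_shrinks_with_sample_size():
    def site_spread(n, seed):
        cohort = simulate_cohort(
            SimConfig(n_participants=n, site_count=4, event_rate_target=0.1, seed=seed),
            signals="none",
        )
        p = cohort.participants.copy()
        p["score"] = cohort.ground_truth["linear_predictor"]
        cis = [
            M.concordance_index(g["time"], g["event"], g["score"])
            for _, g in p.groupby("site")
        ]
        return np.std(cis)

    small = np.mean([site_spread(400, s) for s in (1, 2, 3)])
    large = np.mean([site_spread(4000, s) for s in (1, 2, 3)])
    assert large < small
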