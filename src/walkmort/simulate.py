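"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure of a national accelerometer sub-study:
week-long wrist recordings at 100 Hz with per-30-s walking / non-walking
labels, walking bouts of varying run length and intensity, demographics and
categorical health covariates, and survival outcomes (~2% events over 5
years) driven by a known proportional-hazards ground truth linking age, sex
and true walking intensity to mortality.

The signal model: non-walking epochs are low-amplitude noise around the
gravity vector (|a| ~ 1 g); walking epochs superimpose a quasi-periodic
component at a per-bout step frequency (1.5-2.2 Hz) whose amplitude is the
participant's true mean walking acceleration amplitude (g).  Axes decompose
the magnitude along a slowly drifting random gravity direction, so per-axis
and orientation features are non-degenerate.  This is a statistical stand-in,
not a biomechanical gait model.

All generation is a pure function of (SimConfig, seed): per-participant
streams are keyed by (seed, stream tag, participant index), so recordings can
be re-materialized lazily and bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import sessions as _sessions
from .features import extract_feature_table
from .registry import FEATURE_NAMES
from .signal_io import OTHER, WALKING, Epoch, RawRecording

__all__ = [
    "BoutLengthDist",
    "IntensityModel",
    "HazardCoefs",
    "SimConfig",
    "Cohort",
    "simulate_recording",
    "simulate_survival",
    "simulate_cohort",
    "simulate_ph_scenario",
    "ADC_COLUMNS",
    "MRF_COLUMNS",
    "DEMO_COLUMNS",
]

# stream tags for per-participant substreams
_S_BOUTS = 11
_S_SIGNAL = 12
_S_PLACE = 13
_S_PROFILE = 21
_S_SURVIVAL = 22
_S_COVARIATES = 23
_S_FRAILTY = 24

DEMO_COLUMNS = ["age", "sex", "race"]
ADC_COLUMNS = [
    "cardiovascular_disease",
    "pulmonary_disease",
    "cancer",
    "diabetes",
    "operation",
    "hospital_admissions",
    "falls",
]
MRF_COLUMNS = [
    "hypertension",
    "cholesterol",
    "obesity",
    "medications",
    "alcohol",
    "smoking",
    "stress",
    "health",
    "education",
    "income",
]


@dataclass(frozen=True)
class BoutLengthDist:
    """Mixture over walking-bout run lengths (in 30-s epochs).

    Short bouts (1-11 epochs) dominate; a small fraction are long steady
    sessions of 12-40 epochs with a geometric length tail, tuned so ~90% of
    participants record at least one qualifying (>=12) run over the week while
    only a minority accumulate half an hour of steady walking.
    """

    p_long: float = 0.065
    short_mean: float = 2.0  # short length = 1 + Poisson(short_mean), capped at 11
    long_min: int = 12
    long_max: int = 40
    long_tail: float = 0.25  # geometric continuation beyond long_min

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        is_long = rng.random(size) < self.p_long
        short = 1 + np.minimum(rng.poisson(self.short_mean, size), self.long_min - 2)
        long = np.minimum(
            self.long_min + rng.geometric(self.long_tail, size) - 1, self.long_max
        )
        return np.where(is_long, long, short)


@dataclass(frozen=True)
class IntensityModel:
    """True mean walking acceleration amplitude (g) as a function of age/sex."""

    base: float = 0.18  # amplitude at the reference age, female
    age_slope: float = -0.002  # g per year from the reference age
    sex_effect: float = 0.02  # additional amplitude for males
    sd: float = 0.06  # between-person spread
    floor: float = 0.02  # amplitudes are clipped to stay positive
    reference_age: float = 62.0

    def sample(self, rng: np.random.Generator, age: np.ndarray, sex: np.ndarray) -> np.ndarray:
        mu = self.base + self.age_slope * (np.asarray(age) - self.reference_age)
        mu = mu + self.sex_effect * np.asarray(sex)
        return np.maximum(mu + rng.normal(0.0, self.sd, size=np.shape(age)), self.floor)


@dataclass(frozen=True)
class HazardCoefs:
    """Log-hazard-ratio ground truth: h(t|x) = h0 * exp(lp)."""

    beta_age: float = 0.09  # per year
    beta_sex: float = 0.8  # male vs female
    beta_enmo: float = -12.0  # per g of true walking amplitude (protective)

    def linear_predictor(self, age, sex, intensity) -> np.ndarray:
        lp = (
            self.beta_age * np.asarray(age, dtype=float)
            + self.beta_sex * np.asarray(sex, dtype=float)
            + self.beta_enmo * np.asarray(intensity, dtype=float)
        )
        if not np.all(np.isfinite(lp)):
            raise ValueError("non-finite linear predictor; check hazard coefficients")
        return lp


@dataclass(frozen=True)
class SimConfig:
    n_participants: int = 500
    sampling_rate_hz: float = 100.0
    recording_days: float = 7.0
    epoch_s: float = 30.0
    age_range: tuple[float, float] = (45.0, 79.0)
    male_fraction: float = 0.5
    white_fraction: float = 0.94
    bouts_per_day: float = 5.0
    walking_bout_length_dist: BoutLengthDist = field(default_factory=BoutLengthDist)
    intensity_model: IntensityModel = field(default_factory=IntensityModel)
    hazard_coefs: HazardCoefs = field(default_factory=HazardCoefs)
    baseline_hazard: float | None = None  # events/year; None = calibrate to target
    admin_censor_years: float = 5.0
    event_rate_target: float = 0.02
    dropout_fraction: float = 0.05  # uniform dropout over (0, admin_censor_years]
    site_count: int = 22
    site_frailty_sd: float = 0.0  # per-site log-hazard multiplier; 0 = off
    walk_noise_sd: float = 0.03  # g, sample noise during walking epochs
    rest_noise_sd: float = 0.01  # g, sample noise during non-walking epochs
    gravity_drift: float = 0.002  # per-sample random-walk step of the gravity direction
    step_freq_range: tuple[float, float] = (1.5, 2.2)  # Hz
    min_run_epochs: int = 12
    seed: int = 45178

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.recording_days <= 0 or self.epoch_s <= 0:
            raise ValueError("recording duration and epoch length must be positive")
        if self.baseline_hazard is not None and self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.admin_censor_years < 0:
            raise ValueError("admin_censor_years must be >= 0")

    @property
    def n_epochs(self) -> int:
        return int(self.recording_days * 86400.0 / self.epoch_s)

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.sampling_rate_hz * self.epoch_s))


def _rng(seed: int, tag: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, tag, index])


# ---------------------------------------------------------------------------
# bout structure and labels
# ---------------------------------------------------------------------------


def _bout_lengths(config: SimConfig, participant_index: int) -> np.ndarray:
    rng = _rng(config.seed, _S_BOUTS, participant_index)
    n_bouts = rng.poisson(config.bouts_per_day * config.recording_days)
    lengths = config.walking_bout_length_dist.sample(rng, n_bouts)
    # keep bouts + one-epoch separating gaps within the week
    budget = config.n_epochs
    cum = np.cumsum(lengths + 1)
    lengths = lengths[cum <= budget]
    return lengths


def _materialize_labels(config: SimConfig, participant_index: int, lengths: np.ndarray) -> np.ndarray:
    """Boolean walking mask over the week, bouts separated by >= 1 gap epoch."""
    n_epochs = config.n_epochs
    mask = np.zeros(n_epochs, dtype=bool)
    b = len(lengths)
    if b == 0:
        return mask
    rng = _rng(config.seed, _S_PLACE, participant_index)
    free = n_epochs - int(np.sum(lengths)) - (b - 1)
    extra = rng.multinomial(free, np.full(b + 1, 1.0 / (b + 1)))
    pos = extra[0]
    for k, ln in enumerate(lengths):
        mask[pos : pos + ln] = True
        pos += int(ln)
        if k < b - 1:
            pos += 1 + int(extra[k + 1])
    return mask


def labels_from_mask(mask: np.ndarray) -> list[str]:
    return [WALKING if w else OTHER for w in mask]


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------


def _walking_magnitudes(
    rng: np.random.Generator, config: SimConfig, intensity: float, lengths: np.ndarray
) -> np.ndarray:
    """Magnitude series (n_epochs_total, samples_per_epoch) for walking bouts."""
    spe = config.samples_per_epoch
    total = int(np.sum(lengths))
    if total == 0:
        return np.empty((0, spe))
    t = np.arange(spe) / config.sampling_rate_hz
    freqs = rng.uniform(*config.step_freq_range, size=len(lengths))
    f_per_epoch = np.repeat(freqs, lengths)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=total)
    r = 1.0 + intensity * np.sin(
        2.0 * np.pi * f_per_epoch[:, None] * t[None, :] + phases[:, None]
    )
    if config.walk_noise_sd > 0:
        r = r + rng.normal(0.0, config.walk_noise_sd, size=r.shape)
    return r


def _gravity_directions(rng: np.random.Generator, n: int, drift: float) -> np.ndarray:
    """Slow random walk on the unit sphere, one direction per sample."""
    d0 = rng.normal(size=3)
    d0 /= np.linalg.norm(d0)
    if drift > 0:
        walk = d0 + np.cumsum(rng.normal(0.0, drift, size=(n, 3)), axis=0)
    else:
        walk = np.broadcast_to(d0, (n, 3)).copy()
    norms = np.linalg.norm(walk, axis=1, keepdims=True)
    return walk / norms


def _epoch_samples_from_magnitude(
    rng: np.random.Generator, config: SimConfig, magnitudes: np.ndarray
) -> np.ndarray:
    """Decompose epoch magnitude rows along a drifting gravity direction."""
    n_ep, spe = magnitudes.shape
    dirs = _gravity_directions(rng, n_ep * spe, config.gravity_drift).reshape(n_ep, spe, 3)
    return magnitudes[..., None] * dirs


def simulate_recording(profile, sim_config: SimConfig, participant_index: int = 0):
    """Full raw recording + epoch labels for one participant.

    ``profile`` needs ``age``, ``sex`` and a positive ``true_intensity``.
    Returns (RawRecording, labels) with ``recording_days * 86400 *
    sampling_rate_hz`` samples; the trailing partial epoch (if any) is
    background.  A week at 100 Hz is ~1.4 GB in memory — use short
    ``recording_days`` for tests and the cohort-level fast path for modelling.
    """
    intensity = float(profile["true_intensity"])
    if intensity < 0:
        raise ValueError("true_intensity must be >= 0")
    cfg = sim_config
    n_total = int(round(cfg.recording_days * 86400.0 * cfg.sampling_rate_hz))
    spe = cfg.samples_per_epoch
    n_epochs = cfg.n_epochs

    lengths = _bout_lengths(cfg, participant_index)
    mask = _materialize_labels(cfg, participant_index, lengths)

    rng = _rng(cfg.seed, _S_SIGNAL, participant_index)
    magnitudes = np.empty((n_epochs, spe))
    n_rest = int(np.count_nonzero(~mask))
    if cfg.rest_noise_sd > 0:
        magnitudes[~mask] = 1.0 + rng.normal(0.0, cfg.rest_noise_sd, size=(n_rest, spe))
    else:
        magnitudes[~mask] = 1.0
    walk_epoch_lengths = _run_lengths_from_mask(mask)
    magnitudes[mask] = _walking_magnitudes(rng, cfg, intensity, walk_epoch_lengths)

    samples = _epoch_samples_from_magnitude(rng, cfg, magnitudes).reshape(-1, 3)
    if n_total > samples.shape[0]:
        tail = n_total - samples.shape[0]
        tail_mag = np.ones((1, tail))
        if cfg.rest_noise_sd > 0:
            tail_mag += rng.normal(0.0, cfg.rest_noise_sd, size=(1, tail))
        samples = np.vstack([samples, _epoch_samples_from_magnitude(rng, cfg, tail_mag).reshape(-1, 3)])
    recording = RawRecording(samples=samples[:n_total], sampling_rate_hz=cfg.sampling_rate_hz)
    return recording, labels_from_mask(mask)


def _run_lengths_from_mask(mask: np.ndarray) -> np.ndarray:
    runs = _sessions.find_walking_runs(mask)
    return np.array([ln for _, ln in runs], dtype=int)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def _expected_event_fraction(h0: float, lp: np.ndarray, horizon: float, dropout: float) -> float:
    """Closed-form expected event proportion under exponential event times,
    administrative censoring at ``horizon`` and uniform dropout over (0, Y]."""
    rate = h0 * np.exp(lp)
    ry = rate * horizon
    p_admin = -np.expm1(-ry)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_drop = np.where(ry > 0, 1.0 - p_admin / np.where(ry > 0, ry, 1.0), 0.0)
    return float(np.mean((1.0 - dropout) * p_admin + dropout * p_drop))


def calibrate_baseline_hazard(lp: np.ndarray, config: SimConfig) -> float:
    """Solve for h0 so the expected event proportion equals event_rate_target."""
    y, d, target = config.admin_censor_years, config.dropout_fraction, config.event_rate_target
    if y <= 0:
        raise ValueError("cannot calibrate with a zero administrative horizon")

    def f(log_h0: float) -> float:
        return _expected_event_fraction(np.exp(log_h0), lp, y, d) - target

    return float(np.exp(brentq(f, -40.0, 10.0, xtol=1e-12)))


def simulate_survival(profiles: pd.DataFrame, sim_config: SimConfig) -> pd.DataFrame:
    """Survival outcomes + ground truth for a cohort of participant profiles.

    ``profiles`` needs columns age, sex, true_intensity (and site when per-site
    frailty is enabled).  Event times are exponential with hazard
    ``h0 * exp(beta_age*age + beta_sex*sex + beta_enmo*true_intensity)``;
    censoring is the minimum of uniform dropout and the administrative
    horizon.  Returns time, event, true_event_time, censor_time,
    linear_predictor; the realized baseline hazard is in ``attrs['h0']``.
    """
    cfg = sim_config
    n = len(profiles)
    lp = cfg.hazard_coefs.linear_predictor(
        profiles["age"].to_numpy(), profiles["sex"].to_numpy(), profiles["true_intensity"].to_numpy()
    )
    if cfg.site_frailty_sd > 0:
        frail_rng = _rng(cfg.seed, _S_FRAILTY)
        site_effect = frail_rng.normal(0.0, cfg.site_frailty_sd, size=cfg.site_count)
        lp = lp + site_effect[profiles["site"].to_numpy(dtype=int)]

    y = cfg.admin_censor_years
    rng = _rng(cfg.seed, _S_SURVIVAL)
    if y == 0:
        out = pd.DataFrame(
            {
                "time": np.zeros(n),
                "event": np.zeros(n, dtype=int),
                "true_event_time": np.full(n, np.inf),
                "censor_time": np.zeros(n),
                "linear_predictor": lp,
            },
            index=profiles.index,
        )
        out.attrs["h0"] = cfg.baseline_hazard or np.nan
        return out

    h0 = cfg.baseline_hazard if cfg.baseline_hazard is not None else calibrate_baseline_hazard(lp, cfg)
    rate = h0 * np.exp(lp)
    true_event_time = rng.exponential(1.0 / rate)
    dropout = rng.random(n) < cfg.dropout_fraction
    censor_time = np.where(dropout, rng.uniform(0.0, y, size=n), y)
    censor_time = np.minimum(censor_time, y)
    time = np.minimum(true_event_time, censor_time)
    event = (true_event_time <= censor_time).astype(int)
    out = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "true_event_time": true_event_time,
            "censor_time": censor_time,
            "linear_predictor": lp,
        },
        index=profiles.index,
    )
    out.attrs["h0"] = h0
    return out


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------


def _simulate_covariates(rng: np.random.Generator, age: np.ndarray) -> pd.DataFrame:
    """Categorical health features, encoded 1 = bad / 0 = good (ordinals kept
    ordinal, higher = worse except income/education where higher = better)."""
    n = len(age)
    z = (age - 62.0) / 10.0

    def binary(base_logit: float, age_coef: float = 0.5) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-(base_logit + age_coef * z)))
        return (rng.random(n) < p).astype(int)

    cols: dict[str, np.ndarray] = {}
    for name, logit in zip(ADC_COLUMNS, (-2.6, -3.0, -2.4, -2.7, -2.0, -2.2, -2.8)):
        cols[name] = binary(logit)
    cols["hypertension"] = binary(-1.2)
    cols["cholesterol"] = binary(-1.0)
    cols["obesity"] = binary(-1.3, 0.1)
    cols["medications"] = binary(-1.8)
    cols["alcohol"] = rng.integers(0, 6, size=n)
    cols["smoking"] = rng.choice(3, size=n, p=(0.6, 0.15, 0.25))
    cols["stress"] = rng.choice(3, size=n, p=(0.55, 0.25, 0.2))
    cols["health"] = rng.choice(4, size=n, p=(0.25, 0.45, 0.22, 0.08))
    cols["education"] = (rng.random(n) < 0.35).astype(int)
    cols["income"] = rng.integers(0, 5, size=n)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """A fully simulated cohort: tables plus hooks to re-materialize signals."""

    config: SimConfig
    participants: pd.DataFrame  # profile + sessions summary + sensor aggregate + outcome
    covariates: pd.DataFrame  # id + ADC + MRF columns
    ground_truth: pd.DataFrame  # id + true_* columns + linear predictor
    features: pd.DataFrame | None = None  # id + 76 aggregated sensor features
    baseline_hazard: float = np.nan

    def labels_for(self, participant_index: int) -> list[str]:
        lengths = _bout_lengths(self.config, participant_index)
        return labels_from_mask(_materialize_labels(self.config, participant_index, lengths))

    def recording_for(self, participant_index: int, recording_days: float | None = None):
        cfg = self.config
        if recording_days is not None:
            cfg = replace(cfg, recording_days=recording_days)
        row = self.participants.iloc[participant_index]
        return simulate_recording(
            {"age": row["age"], "sex": row["sex"], "true_intensity": row["true_intensity"]},
            cfg,
            participant_index=participant_index,
        )

    def modelling_table(self) -> tuple[pd.DataFrame, dict[str, str]]:
        """Included participants only: demographics + categoricals + sensor
        aggregates + outcome, with a column->group schema."""
        from .cohort import assemble_table

        inc = self.participants[self.participants["included"]]
        sensor_cols = ["id"] + (
            list(FEATURE_NAMES) if self.features is not None else ["ENMOtrunc", "ENMOabs"]
        )
        if self.features is not None:
            sensor = self.features[self.features["id"].isin(inc["id"])]
        else:
            sensor = inc[["id", "ENMOtrunc", "ENMOabs"]]
        covar = self.covariates.merge(
            inc[["id", "age", "sex", "race", "site"]], on="id"
        )
        outcomes = inc[["id", "time", "event"]]
        return assemble_table(sensor[sensor_cols], covar, outcomes)


def simulate_cohort(sim_config: SimConfig | None = None, signals: str = "enmo", seed: int | None = None) -> Cohort:
    """Generate a labeled cohort end to end.

    ``signals`` controls how much raw signal is synthesized:

    * ``"enmo"`` (default) — only the included walking epochs' magnitude
      series are generated, and ENMOtrunc/ENMOabs aggregates computed; fast
      enough for thousands of participants.
    * ``"full"`` — tri-axial samples for every included epoch and the full
      76-feature extraction + per-participant aggregation.
    * ``"none"`` — bout structure and outcomes only.
    """
    cfg = sim_config or SimConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    if signals not in {"enmo", "full", "none"}:
        raise ValueError(f"unknown signals mode {signals!r}")

    n = cfg.n_participants
    prof_rng = _rng(cfg.seed, _S_PROFILE)
    age = prof_rng.uniform(cfg.age_range[0], cfg.age_range[1], size=n)
    sex = (prof_rng.random(n) < cfg.male_fraction).astype(int)
    race = (prof_rng.random(n) < cfg.white_fraction).astype(int)
    site = prof_rng.integers(0, cfg.site_count, size=n)
    intensity = cfg.intensity_model.sample(prof_rng, age, sex)

    profiles = pd.DataFrame(
        {
            "id": np.arange(n),
            "age": age,
            "sex": sex,
            "race": race,
            "site": site,
            "true_intensity": intensity,
        }
    )

    surv = simulate_survival(profiles, cfg)
    covars = _simulate_covariates(_rng(cfg.seed, _S_COVARIATES), age)
    covars.insert(0, "id", profiles["id"].to_numpy())

    # bout structure, inclusion, and sensor aggregates
    criteria = _sessions.SessionCriteria(min_run_epochs=cfg.min_run_epochs, epoch_s=cfg.epoch_s)
    n_runs = np.zeros(n, dtype=int)
    n_sessions = np.zeros(n, dtype=int)
    included_epochs = np.zeros(n, dtype=int)
    enmo_trunc = np.full(n, np.nan)
    enmo_abs = np.full(n, np.nan)
    feature_rows: list[np.ndarray] = []
    feature_ids: list[int] = []

    for i in range(n):
        lengths = _bout_lengths(cfg, i)
        qualifying = lengths[lengths >= criteria.min_run_epochs]
        n_runs[i] = len(lengths)
        n_sessions[i] = len(qualifying)
        included_epochs[i] = int(qualifying.sum())
        if signals == "none" or len(qualifying) == 0:
            continue
        sig_rng = _rng(cfg.seed, _S_SIGNAL, i)
        magnitudes = _walking_magnitudes(sig_rng, cfg, float(intensity[i]), qualifying)
        if signals == "enmo":
            dev = magnitudes - 1.0
            enmo_trunc[i] = float(np.mean(np.maximum(dev, 0.0)))
            enmo_abs[i] = float(np.mean(np.abs(dev)))
        else:  # full
            samples = _epoch_samples_from_magnitude(sig_rng, cfg, magnitudes)
            epochs = [
                Epoch(index=j, samples=samples[j], label=WALKING, duration_s=cfg.epoch_s)
                for j in range(samples.shape[0])
            ]
            table = extract_feature_table(epochs, duration_s=cfg.epoch_s)
            agg = table.mean(axis=0)
            feature_rows.append(agg)
            feature_ids.append(i)
            names = list(FEATURE_NAMES)
            enmo_trunc[i] = agg[names.index("ENMOtrunc")]
            enmo_abs[i] = agg[names.index("ENMOabs")]

    included = n_sessions > 0
    reason = np.where(included, _sessions.REASON_OK, _sessions.REASON_WALKING)

    participants = profiles.copy()
    participants["n_runs"] = n_runs
    participants["n_sessions"] = n_sessions
    participants["included_epochs"] = included_epochs
    participants["walking_minutes"] = included_epochs * cfg.epoch_s / 60.0
    participants["included"] = included
    participants["exclusion_reason"] = reason
    participants["ENMOtrunc"] = enmo_trunc
    participants["ENMOabs"] = enmo_abs
    participants["time"] = surv["time"].to_numpy()
    participants["event"] = surv["event"].to_numpy()

    ground_truth = pd.DataFrame(
        {
            "id": profiles["id"],
            "true_intensity": intensity,
            "linear_predictor": surv["linear_predictor"].to_numpy(),
            "true_event_time": surv["true_event_time"].to_numpy(),
            "censor_time": surv["censor_time"].to_numpy(),
            "site": site,
        }
    )

    features = None
    if signals == "full":
        features = pd.DataFrame(
            np.vstack(feature_rows) if feature_rows else np.empty((0, len(FEATURE_NAMES))),
            columns=list(FEATURE_NAMES),
        )
        features.insert(0, "id", np.array(feature_ids, dtype=int))

    return Cohort(
        config=cfg,
        participants=participants,
        covariates=covars,
        ground_truth=ground_truth,
        features=features,
        baseline_hazard=float(surv.attrs.get("h0", np.nan)),
    )


# ---------------------------------------------------------------------------
# proportional-hazards diagnostic scenarios
# ---------------------------------------------------------------------------


def simulate_ph_scenario(
    n: int,
    beta_early: float,
    beta_late: float | None = None,
    t_switch: float = 2.5,
    baseline_hazard: float = 0.1,
    horizon: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Single-covariate survival data with an optionally time-varying effect.

    With ``beta_late`` omitted (or equal to ``beta_early``) the proportional
    hazards assumption holds exactly; otherwise the log hazard ratio switches
    from ``beta_early`` to ``beta_late`` at ``t_switch`` (piecewise
    exponential), giving a controlled PH violation for diagnostic power
    studies.
    """
    if beta_late is None:
        beta_late = beta_early
    rng = np.random.default_rng([seed, 31])
    x = rng.normal(size=n)
    rate1 = baseline_hazard * np.exp(beta_early * x)
    rate2 = baseline_hazard * np.exp(beta_late * x)
    e = rng.exponential(1.0, size=n)  # unit-exponential cumulative hazard
    t = np.where(e < rate1 * t_switch, e / rate1, t_switch + (e - rate1 * t_switch) / rate2)
    time = np.minimum(t, horizon)
    event = (t <= horizon).astype(int)
    return pd.DataFrame({"x": x, "time": time, "event": event})
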