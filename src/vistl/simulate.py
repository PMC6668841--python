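"""Synthetic inpatient cohort generator.

Real inpatient EHR extracts of this kind are not publicly shareable, so this
module generates admission cohorts whose admission-level marginals are
calibrated to a large single-center adult inpatient population:

* in-hospital mortality ~2.5%,
* ICU admission ~25% among deaths vs ~5% among survivors,
* mean age 63 (deaths) vs 55 (survivors),
* female 47% vs 57%,
* median length of stay 9 days (deaths) vs 5 (survivors),

while the timestamped observations are driven by a single latent severity
process so that downstream image classifiers have genuine spatio-temporal
signal to learn.

Generative model
----------------
Per admission: an admission location (ward/ED/ICU/other), age (truncated
normal on [18, 100]), sex, race and comorbidity flags are drawn first. A
latent severity trace ``s_t`` (one value per hour, 48 hours) follows a
discrete mean-reverting (Ornstein-Uhlenbeck-style) process around a
location-specific baseline plus a per-admission linear trend:

    s_0 = b_loc + init_sd * eps
    s_{t+1} = s_t + reversion * (b_loc + slope*(t+1) + drift*(t+1) - s_t)
              + noise_sd * eps_t

with ICU baseline > ED/ward baseline > other. The in-hospital death
probability is a logistic function of the *maximum* severity over the 48
hours, age and sex. Length of stay is outcome-conditional lognormal with a
two-day floor (the framework only considers admissions of >= 48 h, and by
construction deaths occur after hour 48).

Observations are emitted per variable from an hourly-modulated Poisson
process; continuous values are the variable's normal value plus a signed
severity link plus Gaussian noise, clipped to the plausible range; binary
values are Bernoulli with a logit linear in severity. Consciousness is
emitted as an ordinal AVPU level and a GCS band, both driven by severity
thresholds. A subset of channels has a zero severity link on purpose: they
are pure-noise rows against which interpretability methods can be checked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .catalogue import (
    Catalogue,
    Direction,
    Group,
    Kind,
    STATIC_GROUPS,
    default_catalogue,
)

LOCATIONS = ("ward", "ED", "ICU", "other")


class Observation(NamedTuple):
    variable: str
    time_h: float
    value: float


@dataclass
class AdmissionRecord:
    """One hospital admission with sparse timestamped observations."""

    id: str
    age: float
    female: int
    race_black: int
    admission_location: str
    comorbidity_flags: Dict[str, int]
    observations: pd.DataFrame  # columns: variable, time_h, value
    outcome: str  # "died" | "alive"
    los_days: float
    latent_trace: Optional[np.ndarray] = None  # per-hour severity, test-only

    def observation_list(self) -> List[Observation]:
        return [
            Observation(v, float(t), float(x))
            for v, t, x in self.observations[["variable", "time_h", "value"]].itertuples(index=False)
        ]


@dataclass(frozen=True)
class EmissionParams:
    """Per-variable observation emission parameters.

    ``mode`` is ``linear`` (normal value + link*relu(severity) + noise),
    ``binary`` (Bernoulli with logit ``base_logit + sev_logit*severity``),
    ``avpu`` (ordinal 0-3 via severity thresholds) or ``gcs`` (15 down to 3
    via severity bands).
    """

    rate_per_h: float
    mode: str = "linear"
    link: float = 0.0
    noise_sd: float = 0.0
    base_logit: float = -3.0
    sev_logit: float = 0.0


# Emission defaults for the named demo variables. Signs follow clinical
# direction (e.g. blood pressure falls and lactate rises with severity).
# Variables with link 0 / sev_logit 0 are deliberate null channels.
_EMISSION_TABLE: Dict[str, EmissionParams] = {
    "heart_rate": EmissionParams(0.45, "linear", +4.0, 10.0),
    "systolic_bp": EmissionParams(0.45, "linear", -4.9, 14.0),
    "diastolic_bp": EmissionParams(0.7, "linear", -10.0, 10.0),
    "mean_arterial_pressure": EmissionParams(0.7, "linear", -2.25, 13.0),
    "resp_rate": EmissionParams(0.45, "linear", +1.75, 4.0),
    "temperature": EmissionParams(0.45, "linear", +0.16, 0.5),
    "spo2": EmissionParams(0.45, "linear", -4.0, 2.5),
    "fio2": EmissionParams(0.6, "linear", +20.0, 5.0),
    "urine_output_rate": EmissionParams(0.6, "linear", -30.0, 12.0),
    "wbc": EmissionParams(0.3, "linear", +4.0, 2.5),
    "hemoglobin": EmissionParams(0.15, "linear", -1.2, 1.0),
    "platelets": EmissionParams(0.15, "linear", -7.5, 80.0),
    "sodium": EmissionParams(0.15, "linear", 0.0, 3.0),
    "potassium": EmissionParams(0.15, "linear", +0.3, 0.4),
    "bicarbonate": EmissionParams(0.3, "linear", -3.0, 2.0),
    "creatinine": EmissionParams(0.15, "linear", +0.1, 0.9),
    "bun": EmissionParams(0.35, "linear", +12.0, 5.0),
    "glucose": EmissionParams(0.18, "linear", 0.0, 30.0),
    "bilirubin": EmissionParams(0.10, "linear", +0.125, 1.1),
    "lactate": EmissionParams(0.35, "linear", +1.5, 0.4),
    "albumin": EmissionParams(0.10, "linear", -0.5, 0.35),
    "pao2_fio2_ratio": EmissionParams(0.10, "linear", -11.0, 100.0),
    "med_vasopressor": EmissionParams(0.25, "binary", base_logit=-5.5, sev_logit=0.9),
    "med_antibiotic": EmissionParams(0.20, "binary", base_logit=-3.0, sev_logit=1.2),
    "med_opioid": EmissionParams(0.20, "binary", base_logit=-2.5, sev_logit=0.8),
    "med_anticoagulant": EmissionParams(0.15, "binary", base_logit=-2.5, sev_logit=0.5),
    "med_insulin": EmissionParams(0.15, "binary", base_logit=-2.2, sev_logit=0.0),
    "med_diuretic": EmissionParams(0.15, "binary", base_logit=-3.0, sev_logit=0.8),
    "mechanical_ventilation": EmissionParams(0.30, "binary", base_logit=-6.0, sev_logit=2.2),
    "supplemental_oxygen": EmissionParams(0.40, "binary", base_logit=-3.0, sev_logit=1.5),
    "central_line": EmissionParams(0.20, "binary", base_logit=-5.0, sev_logit=1.5),
    "foley_catheter": EmissionParams(0.20, "binary", base_logit=-3.5, sev_logit=1.0),
    "dialysis": EmissionParams(0.15, "binary", base_logit=-7.0, sev_logit=1.5),
    "morse_score": EmissionParams(0.5, "linear", +30.0, 8.0),
    "braden_score": EmissionParams(0.5, "linear", -4.0, 1.2),
    "avpu_level": EmissionParams(0.25, "avpu", noise_sd=0.6),
    "gcs_total": EmissionParams(0.20, "gcs", noise_sd=0.6),
    "pain_score": EmissionParams(0.20, "linear", 0.0, 2.0),
    "chest_xray": EmissionParams(0.06, "binary", base_logit=-1.5, sev_logit=1.0),
    "ecg": EmissionParams(0.05, "binary", base_logit=-1.5, sev_logit=0.6),
    "ct_scan": EmissionParams(0.04, "binary", base_logit=-2.5, sev_logit=0.8),
    "blood_culture": EmissionParams(0.05, "binary", base_logit=-2.0, sev_logit=1.2),
}


def default_emissions(catalogue: Catalogue) -> Dict[str, EmissionParams]:
    """Emission parameters for every dynamic (non-static) catalogue variable.

    Generic padding channels alternate between severity-linked and pure-noise
    so that both presets contain designated signal and null rows.
    """
    out: Dict[str, EmissionParams] = {}
    for v in catalogue:
        if v.group in STATIC_GROUPS:
            continue
        if v.name in _EMISSION_TABLE:
            out[v.name] = _EMISSION_TABLE[v.name]
        elif v.name.startswith("lab_generic_"):
            i = int(v.name.rsplit("_", 1)[1])
            link = 8.0 if i % 2 else 0.0
            out[v.name] = EmissionParams(0.08, "linear", link, 10.0)
        elif v.name.startswith("med_class_"):
            i = int(v.name.rsplit("_", 1)[1])
            out[v.name] = EmissionParams(0.10, "binary", base_logit=-4.0,
                                         sev_logit=1.0 if i % 2 else 0.0)
        else:
            raise ValueError(f"no emission parameters for variable {v.name!r}")
    return out


def null_variables(catalogue: Catalogue,
                   emissions: Optional[Dict[str, EmissionParams]] = None) -> List[str]:
    """Rows that carry no outcome signal under the default generative model.

    Dynamic channels with a zero severity link, plus the static rows the
    outcome model ignores (race and comorbidity flags). Age, sex and
    admission location are *not* null: the death logit uses them.
    """
    emissions = emissions or default_emissions(catalogue)
    sig = set(signal_variables(catalogue, emissions))
    out = []
    for v in catalogue:
        if v.group in STATIC_GROUPS:
            if v.name == "race_black" or v.name.startswith("comorbidity_"):
                out.append(v.name)
        elif v.name not in sig:
            out.append(v.name)
    return out


def localized_signal_config(signal_rows: Sequence[str], n_admissions: int,
                            seed: int, preset: str = "demo") -> "CohortConfig":
    """Config for interpretability experiments: outcome signal only in ``signal_rows``.

    Every channel outside ``signal_rows`` is de-linked from severity (pure
    noise around its normal value); location baselines are flattened and the
    demographic terms of the outcome logit zeroed, so the *only* image rows
    informative about the outcome are the designated ones. Used to check
    that attention maps localize onto rows known to carry signal.
    """
    catalogue = default_catalogue(preset)
    signal = set(signal_rows)
    unknown = signal - set(catalogue.names)
    if unknown:
        raise ValueError(f"unknown signal rows {sorted(unknown)}")
    emissions = {}
    for name, p in default_emissions(catalogue).items():
        if name in signal:
            emissions[name] = p
        elif p.mode in ("avpu", "gcs"):
            spec = catalogue[name]
            emissions[name] = EmissionParams(p.rate_per_h, "linear", 0.0, 0.3)
        else:
            emissions[name] = EmissionParams(p.rate_per_h, p.mode, 0.0, p.noise_sd,
                                             p.base_logit, 0.0)
    return CohortConfig(
        n_admissions=n_admissions, seed=seed, catalogue_preset=preset,
        sev_baseline={"ward": 1.0, "ED": 1.0, "ICU": 1.0, "other": 1.0},
        outcome_intercept=-5.6, outcome_beta_age=0.0, outcome_beta_female=0.0,
        emissions=emissions)


def signal_variables(catalogue: Catalogue,
                     emissions: Optional[Dict[str, EmissionParams]] = None) -> List[str]:
    """Dynamic variables whose emission actually depends on severity."""
    emissions = emissions or default_emissions(catalogue)
    out = []
    for name, p in emissions.items():
        if p.mode in ("avpu", "gcs"):
            out.append(name)
        elif p.mode == "linear" and p.link != 0.0:
            out.append(name)
        elif p.mode == "binary" and p.sev_logit != 0.0:
            out.append(name)
    return out


@dataclass
class CohortConfig:
    """Full parameterization of the synthetic cohort.

    The defaults are the packaged calibration: they reproduce the target
    admission-level marginals (mortality 2.5%; ICU 25% of deaths vs 5% of
    survivors; mean age 63 vs 55; female 47% vs 57%; median LOS 9 days among
    deaths) at large n.
    """

    n_admissions: int = 1000
    seed: int = 0
    catalogue_preset: str = "demo"

    # admission-level marginals
    location_probs: Tuple[float, float, float, float] = (0.308, 0.413, 0.058, 0.221)
    age_mean: float = 54.4
    age_sd: float = 19.0
    age_bounds: Tuple[float, float] = (18.0, 100.0)
    p_female: float = 0.5675
    p_black: float = 0.539
    comorbidity_base: Tuple[float, ...] = (0.12, 0.10, 0.22, 0.10)  # chf, copd, dm, ckd

    # latent severity process
    sev_baseline: Dict[str, float] = field(
        default_factory=lambda: {"ward": 1.0, "ED": 1.1, "ICU": 2.25, "other": 0.0})
    sev_reversion: float = 0.25
    sev_drift: float = 0.0
    sev_noise_sd: float = 0.15
    sev_trend_sd: float = 0.03  # sd of per-hour linear slope, per admission
    sev_init_sd: float = 0.6

    # outcome logit: intercept + b_sev*max48(sev) + b_age*(age-55) + b_sex*female
    outcome_intercept: float = -7.745
    outcome_beta_sev: float = 1.7
    outcome_beta_age: float = 0.034
    outcome_beta_female: float = -0.48

    # LOS, outcome-conditional lognormal (of days), floored at 2 days
    los_mu_died: float = math.log(9.0)
    los_sigma_died: float = 0.907
    los_mu_alive: float = math.log(5.0)
    los_sigma_alive: float = 0.628

    # observation emission
    rate_sev_scale: float = 0.0  # Poisson rate multiplier: rate*(1+scale*relu(sev))
    emissions: Optional[Dict[str, EmissionParams]] = None

    def validate(self) -> None:
        if self.n_admissions < 1:
            raise ValueError("n_admissions: must be >= 1")
        if abs(sum(self.location_probs) - 1.0) > 1e-9:
            raise ValueError("location_probs: must sum to 1")
        if any(p < 0 or p > 1 for p in self.location_probs):
            raise ValueError("location_probs: entries must be in [0,1]")
        for name in ("p_female", "p_black"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name}: must be in [0,1]")
        if self.age_bounds[0] >= self.age_bounds[1]:
            raise ValueError("age_bounds: low must be < high")
        if self.sev_noise_sd < 0 or self.sev_init_sd < 0 or self.sev_trend_sd < 0:
            raise ValueError("sev_noise_sd/sev_init_sd/sev_trend_sd: must be >= 0")
        if not 0 < self.sev_reversion <= 1:
            raise ValueError("sev_reversion: must be in (0,1]")
        missing = [k for k in LOCATIONS if k not in self.sev_baseline]
        if missing:
            raise ValueError(f"sev_baseline: missing locations {missing}")


class Cohort:
    """Column-wise cohort container behaving as a sequence of AdmissionRecords.

    ``admissions`` is one row per admission; ``observations`` is long-format
    (id, variable, time_h, value). Per-admission record objects are built
    lazily so that 50k-admission cohorts stay cheap.
    """

    def __init__(self, admissions: pd.DataFrame, observations: pd.DataFrame,
                 catalogue: Catalogue, severity: Optional[np.ndarray] = None):
        self.admissions = admissions.reset_index(drop=True)
        self.observations = observations
        self.catalogue = catalogue
        self.severity = severity  # (n, 48) latent traces, test-only
        self._obs_groups = None

    # -- sequence protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.admissions)

    @property
    def ids(self) -> np.ndarray:
        return self.admissions["id"].to_numpy()

    def _groups(self):
        if self._obs_groups is None:
            self._obs_groups = {
                k: g for k, g in self.observations.groupby("id", observed=True, sort=False)
            }
        return self._obs_groups

    def __getitem__(self, i: int) -> AdmissionRecord:
        row = self.admissions.iloc[i]
        obs = self._groups().get(row["id"])
        if obs is None:
            obs = self.observations.iloc[0:0]
        comorb = {c: int(row[c]) for c in row.index if c.startswith("comorbidity_")}
        return AdmissionRecord(
            id=row["id"],
            age=float(row["age"]),
            female=int(row["female"]),
            race_black=int(row["race_black"]),
            admission_location=row["admission_location"],
            comorbidity_flags=comorb,
            observations=obs[["variable", "time_h", "value"]].reset_index(drop=True),
            outcome=row["outcome"],
            los_days=float(row["los_days"]),
            latent_trace=None if self.severity is None else self.severity[i],
        )

    def __iter__(self) -> Iterator[AdmissionRecord]:
        for i in range(len(self)):
            yield self[i]

    def record(self, admission_id: str) -> AdmissionRecord:
        idx = int(np.flatnonzero(self.ids == admission_id)[0])
        return self[idx]


def _relu(x):
    return np.maximum(x, 0.0)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_severity(config: CohortConfig, location: str, n_hours: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Simulate one per-hour latent severity trace.

    Mean-reverting around the location baseline plus a per-admission random
    linear trend; deterministic given the generator state.
    """
    if n_hours < 48:
        raise ValueError(f"n_hours must be >= 48, got {n_hours}")
    if location not in config.sev_baseline:
        raise ValueError(f"unknown location {location!r}")
    base = config.sev_baseline[location]
    slope = rng.normal(0.0, config.sev_trend_sd) if config.sev_trend_sd > 0 else 0.0
    s = np.empty(n_hours)
    s[0] = base + (rng.normal(0.0, config.sev_init_sd) if config.sev_init_sd > 0 else 0.0)
    theta = config.sev_reversion
    for t in range(1, n_hours):
        target = base + (slope + config.sev_drift) * t
        eps = rng.normal(0.0, config.sev_noise_sd) if config.sev_noise_sd > 0 else 0.0
        s[t] = s[t - 1] + theta * (target - s[t - 1]) + eps
    return s


def _simulate_severity_matrix(config: CohortConfig, locations: np.ndarray,
                              n_hours: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorized severity traces for a whole cohort, (n, n_hours)."""
    n = len(locations)
    base = np.array([config.sev_baseline[l] for l in LOCATIONS])[locations]
    slope = rng.normal(0.0, config.sev_trend_sd, size=n)
    s = np.empty((n, n_hours))
    s[:, 0] = base + rng.normal(0.0, config.sev_init_sd, size=n)
    theta = config.sev_reversion
    for t in range(1, n_hours):
        target = base + (slope + config.sev_drift) * t
        s[:, t] = s[:, t - 1] + theta * (target - s[:, t - 1]) \
            + rng.normal(0.0, config.sev_noise_sd, size=n)
    return s


_AVPU_THRESHOLDS = np.array([2.8, 3.4, 4.0])


def _emit_values(spec, params: EmissionParams, sev: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Observation values for one variable given severity at emission times."""
    k = sev.shape[0]
    noise = rng.normal(0.0, 1.0, size=k)
    if params.mode == "linear":
        lo, hi = spec.plausible_range
        v = spec.normal_value + params.link * _relu(sev) + params.noise_sd * noise
        return np.clip(v, lo, hi)
    if params.mode == "avpu":
        level = (sev + params.noise_sd * noise)[:, None] > _AVPU_THRESHOLDS[None, :]
        return level.sum(axis=1).astype(float)
    if params.mode == "gcs":
        drop = np.round(3.0 * _relu(sev + params.noise_sd * noise - 2.0))
        return np.clip(15.0 - drop, 3.0, 15.0)
    if params.mode == "binary":
        p = _sigmoid(params.base_logit + params.sev_logit * sev)
        return (rng.random(k) < p).astype(float)
    raise ValueError(f"unknown emission mode {params.mode!r}")


def emit_observations(trace: np.ndarray, catalogue: Catalogue, config: CohortConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Emit one admission's observations from its severity trace.

    Per dynamic variable, per-hour counts are Poisson with rate
    ``rate*(1+rate_sev_scale*relu(sev))``; every vital-sign variable is
    guaranteed at least one observation in hour [0,1). Returns a long-format
    frame (variable, time_h, value) sorted by time.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.shape[0] < 48:
        raise ValueError("severity trace must cover >= 48 hours")
    emissions = config.emissions or default_emissions(catalogue)
    n_hours = trace.shape[0]
    frames = []
    for spec in catalogue:
        if spec.group in STATIC_GROUPS:
            continue
        if spec.name not in emissions:
            raise ValueError(f"variable {spec.name!r} has no emission parameters")
        p = emissions[spec.name]
        rate = p.rate_per_h * (1.0 + config.rate_sev_scale * _relu(trace))
        counts = rng.poisson(rate)
        if spec.group is Group.VITALS:
            counts[0] = max(counts[0], 1)
        total = int(counts.sum())
        if total == 0:
            continue
        hours = np.repeat(np.arange(n_hours), counts)
        times = hours + rng.random(total)
        values = _emit_values(spec, p, trace[hours], rng)
        frames.append(pd.DataFrame({"variable": spec.name, "time_h": times, "value": values}))
    if not frames:
        return pd.DataFrame(columns=["variable", "time_h", "value"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values("time_h", kind="stable").reset_index(drop=True)


def _emit_cohort_observations(severity: np.ndarray, ids: np.ndarray,
                              catalogue: Catalogue, config: CohortConfig,
                              rng: np.random.Generator) -> pd.DataFrame:
    """Vectorized emission across all admissions (same model as
    :func:`emit_observations`, drawn variable-by-variable across the cohort)."""
    n, n_hours = severity.shape
    emissions = config.emissions or default_emissions(catalogue)
    cols_id, cols_var, cols_t, cols_v = [], [], [], []
    sev_relu = _relu(severity)
    for spec in catalogue:
        if spec.group in STATIC_GROUPS:
            continue
        p = emissions[spec.name]
        rate = p.rate_per_h * (1.0 + config.rate_sev_scale * sev_relu)
        counts = rng.poisson(rate)
        if spec.group is Group.VITALS:
            counts[:, 0] = np.maximum(counts[:, 0], 1)
        total = int(counts.sum())
        if total == 0:
            continue
        flat = counts.ravel()
        cell = np.repeat(np.arange(n * n_hours), flat)
        adm = cell // n_hours
        hour = cell % n_hours
        times = hour + rng.random(total)
        values = _emit_values(spec, p, severity[adm, hour], rng)
        cols_id.append(adm.astype(np.int32))
        cols_var.append(np.full(total, catalogue.index(spec.name), dtype=np.int16))
        cols_t.append(times.astype(np.float32))
        cols_v.append(values.astype(np.float32))
    adm_idx = np.concatenate(cols_id)
    var_idx = np.concatenate(cols_var)
    names = pd.CategoricalDtype(categories=catalogue.names)
    df = pd.DataFrame({
        "id": pd.Categorical.from_codes(
            adm_idx, categories=pd.Index(ids)),
        "variable": pd.Categorical.from_codes(var_idx, dtype=names),
        "time_h": np.concatenate(cols_t),
        "value": np.concatenate(cols_v),
    })
    return df


def generate_cohort(config: CohortConfig, with_observations: bool = True,
                    keep_severity: bool = True) -> Cohort:
    """Generate a fully seeded synthetic cohort.

    Admission-level attributes, severity traces and observations are drawn
    from independent child streams of ``config.seed``, so the admission
    table is identical whether or not observations are emitted.
    """
    config.validate()
    catalogue = default_catalogue(config.catalogue_preset)
    ss = np.random.SeedSequence(config.seed)
    rng_adm, rng_sev, rng_obs = [np.random.default_rng(s) for s in ss.spawn(3)]
    n = config.n_admissions

    # admission-level draws
    loc_idx = rng_adm.choice(4, size=n, p=np.asarray(config.location_probs))
    lo, hi = config.age_bounds
    age = rng_adm.normal(config.age_mean, config.age_sd, size=n)
    bad = (age < lo) | (age > hi)
    while bad.any():  # truncated normal by redraw
        age[bad] = rng_adm.normal(config.age_mean, config.age_sd, size=int(bad.sum()))
        bad = (age < lo) | (age > hi)
    female = (rng_adm.random(n) < config.p_female).astype(int)
    black = (rng_adm.random(n) < config.p_black).astype(int)
    comorb_names = ("comorbidity_chf", "comorbidity_copd",
                    "comorbidity_diabetes", "comorbidity_ckd")
    comorb = {}
    for name, p0 in zip(comorb_names, config.comorbidity_base):
        logit = math.log(p0 / (1 - p0)) + 0.02 * (age - 55.0)
        comorb[name] = (rng_adm.random(n) < _sigmoid(logit)).astype(int)

    severity = _simulate_severity_matrix(config, loc_idx, 48, rng_sev)
    max_sev = severity.max(axis=1)

    logit = (config.outcome_intercept
             + config.outcome_beta_sev * max_sev
             + config.outcome_beta_age * (age - 55.0)
             + config.outcome_beta_female * female)
    died = rng_adm.random(n) < _sigmoid(logit)

    los = np.where(
        died,
        rng_adm.lognormal(config.los_mu_died, config.los_sigma_died, size=n),
        rng_adm.lognormal(config.los_mu_alive, config.los_sigma_alive, size=n),
    )
    los = np.maximum(los, 2.0)

    ids = np.array([f"adm-{i:06d}" for i in range(n)])
    admissions = pd.DataFrame({
        "id": ids,
        "age": np.round(age, 1),
        "female": female,
        "race_black": black,
        "admission_location": pd.Categorical(
            np.array(LOCATIONS)[loc_idx], categories=list(LOCATIONS)),
        "outcome": np.where(died, "died", "alive"),
        "los_days": np.round(los, 2),
        **comorb,
    })

    if with_observations:
        observations = _emit_cohort_observations(severity, ids, catalogue, config, rng_obs)
    else:
        observations = pd.DataFrame({
            "id": pd.Categorical([], categories=pd.Index(ids)),
            "variable": pd.Categorical([], categories=catalogue.names),
            "time_h": np.array([], dtype=np.float32),
            "value": np.array([], dtype=np.float32),
        })
    return Cohort(admissions, observations, catalogue,
                  severity=severity if keep_severity else None)


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

ADMISSION_COLUMNS = ["id", "age", "female", "race_black", "admission_location",
                     "outcome", "los_days", "comorbidity_chf", "comorbidity_copd",
                     "comorbidity_diabetes", "comorbidity_ckd"]
OBSERVATION_COLUMNS = ["id", "variable", "time_h", "value"]


def write_cohort_csv(cohort: Cohort, admissions_path, observations_path) -> None:
    """Write the two-file CSV form (admissions + long-format observations)."""
    adm = cohort.admissions[ADMISSION_COLUMNS]
    adm.to_csv(admissions_path, index=False)
    obs = cohort.observations[OBSERVATION_COLUMNS].copy()
    obs["time_h"] = obs["time_h"].map(lambda t: f"{t:.4f}")
    obs["value"] = obs["value"].map(lambda v: f"{v:.4f}")
    obs.to_csv(observations_path, index=False)


def read_cohort_csv(admissions_path, observations_path,
                    catalogue: Optional[Catalogue] = None,
                    preset: str = "demo") -> Cohort:
    """Read a cohort written by :func:`write_cohort_csv`, validating rows."""
    catalogue = catalogue or default_catalogue(preset)
    adm = pd.read_csv(admissions_path)
    missing = [c for c in ADMISSION_COLUMNS if c not in adm.columns]
    if missing:
        raise ValueError(f"admissions file missing columns {missing}")
    bad_loc = ~adm["admission_location"].isin(LOCATIONS)
    if bad_loc.any():
        row = int(np.flatnonzero(bad_loc)[0])
        raise ValueError(f"admissions row {row}: unknown location "
                         f"{adm['admission_location'].iloc[row]!r}")
    bad_los = adm["los_days"] < 2
    if bad_los.any():
        row = int(np.flatnonzero(bad_los)[0])
        raise ValueError(f"admissions row {row}: los_days < 2")
    obs = pd.read_csv(observations_path)
    missing = [c for c in OBSERVATION_COLUMNS if c not in obs.columns]
    if missing:
        raise ValueError(f"observations file missing columns {missing}")
    neg = obs["time_h"] < 0
    if neg.any():
        row = int(np.flatnonzero(neg)[0])
        raise ValueError(f"observations row {row}: negative time_h")
    unknown = ~obs["variable"].isin(catalogue.names)
    if unknown.any():
        row = int(np.flatnonzero(unknown)[0])
        raise ValueError(f"observations row {row}: unknown variable "
                         f"{obs['variable'].iloc[row]!r}")
    unknown_id = ~obs["id"].isin(adm["id"])
    if unknown_id.any():
        row = int(np.flatnonzero(unknown_id)[0])
        raise ValueError(f"observations row {row}: unknown admission id "
                         f"{obs['id'].iloc[row]!r}")
    adm["admission_location"] = pd.Categorical(
        adm["admission_location"], categories=list(LOCATIONS))
    obs["id"] = pd.Categorical(obs["id"], categories=adm["id"])
    obs["variable"] = pd.Categorical(obs["variable"], categories=catalogue.names)
    return Cohort(adm, obs, catalogue)


# ---------------------------------------------------------------------------
# YAML config round trip
# ---------------------------------------------------------------------------

def cohort_config_to_dict(config: CohortConfig) -> dict:
    from dataclasses import asdict
    d = asdict(config)
    if config.emissions is not None:
        d["emissions"] = {k: asdict(v) for k, v in config.emissions.items()}
    d["location_probs"] = list(config.location_probs)
    d["age_bounds"] = list(config.age_bounds)
    d["comorbidity_base"] = list(config.comorbidity_base)
    return d


def cohort_config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    if d.get("emissions"):
        d["emissions"] = {k: EmissionParams(**v) for k, v in d["emissions"].items()}
    for key in ("location_probs", "age_bounds", "comorbidity_base"):
        if key in d:
            d[key] = tuple(d[key])
    return CohortConfig(**d)


def write_cohort_config_yaml(config: CohortConfig, path) -> None:
    import yaml
    with open(path, "w") as f:
        yaml.safe_dump(cohort_config_to_dict(config), f, sort_keys=True)


def read_cohort_config_yaml(path) -> CohortConfig:
    import yaml
    with open(path) as f:
        return cohort_config_from_dict(yaml.safe_load(f))
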