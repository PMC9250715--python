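"""Seeded synthetic ICU cohorts with known trajectory archetypes.

Real sepsis trajectory cohorts (MIMIC-III, eICU and similar) are
access-restricted, so this module generates cohorts whose ground truth is
known by construction: each patient is drawn from one of four latent
organ-dysfunction archetypes —

* **RW** (Rapidly Worsening): total SOFA rising steadily, ~4.5 at admission
  to ~7.2 at 72 h;
* **DW** (Delayed Worsening): falling to a nadir around 48 h (~5.2 → 3.7)
  then rising again (→ ~4.8);
* **RI** (Rapidly Improving): steady improvement, ~5.5 → ~2.8;
* **DI** (Delayed Improving): a rise peaking near 30-36 h (~4.0 → 5.2) then
  a gradual fall (→ ~3.5).

For every patient a noisy copy of the archetype's 12-point mean curve is
drawn, rounded and decomposed into six organ subscores via an
archetype-specific organ weighting; raw measurement values are then
back-generated by picking, for each subscore, a value in the interior of the
corresponding scoring band. With zero noise and zero missingness the SOFA
engine therefore reproduces the archetype curve exactly at subscore level.

Archetype prevalences (13.1/20.5/41.3/25.1 %) and in-hospital mortality
(28.3/10.6/5.5/10.7 % for RW/DW/RI/DI) default to the rates reported for
the development cohort the package emulates.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .sofa import N_WINDOWS, ORGANS

ARCHETYPES = ("RW", "DW", "RI", "DI")

#: value emitted for subscore s of each scored variable (interior of band)
_BAND_VALUES = {
    "pao2_fio2_ratio": [450.0, 350.0, 250.0, 150.0, 80.0],
    "platelets": [250.0, 120.0, 75.0, 35.0, 10.0],
    "bilirubin": [0.6, 1.6, 3.9, 8.9, 14.0],
    "map": [80.0, 60.0, 65.0, 63.0, 55.0],
    "gcs": [15.0, 14.0, 11.0, 7.0, 4.0],
    "creatinine": [0.8, 1.5, 2.7, 4.2, 6.0],
}
# cardiovascular scores 2/3/4 additionally need a vasopressor dose
_CARDIO_DOSE = {2: ("dopamine", 3.0), 3: ("norepinephrine", 0.05), 4: ("norepinephrine", 0.3)}

_UNITS = {
    "pao2_fio2_ratio": "mmHg",
    "platelets": "10^3/uL",
    "bilirubin": "mg/dL",
    "map": "mmHg",
    "dopamine": "ug/kg/min",
    "norepinephrine": "ug/kg/min",
    "gcs": "points",
    "creatinine": "mg/dL",
    "urine_6h": "mL/6h",
    "lactate": "mmol/L",
    "heart_rate": "bpm",
}

_ICU_UNITS = ("SICU", "CCU", "TSICU", "MICU", "CSRU")
_ICU_UNIT_P = (0.165, 0.095, 0.127, 0.558, 0.055)


@dataclasses.dataclass(frozen=True)
class ArchetypeSpec:
    """One latent trajectory class.

    ``organ_weights`` spreads the total score across the six organs
    (respiration, coagulation, liver, cardiovascular, cns, renal); the
    defaults mirror the organ-dysfunction patterns associated with each
    archetype (RW skewed to liver/coagulation, RI to cardiovascular/CNS).
    """

    name: str
    mean_curve: tuple[float, ...]
    noise_sd: float
    prevalence: float
    mortality_rate: float
    organ_weights: tuple[float, ...]
    male_rate: float = 0.56
    septic_shock_rate: float = 0.136
    comorbidity_mean: float = 4.0
    los_median_days: float = 2.8

    def __post_init__(self) -> None:
        if self.name not in ARCHETYPES:
            raise ValueError(f"archetype name must be one of {ARCHETYPES}")
        if len(self.mean_curve) != N_WINDOWS:
            raise ValueError("mean_curve must have 12 values")
        if not all(0.0 <= v <= 24.0 for v in self.mean_curve):
            raise ValueError("mean_curve values must lie in [0, 24]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")
        if not (0.0 <= self.mortality_rate <= 1.0):
            raise ValueError("mortality_rate must lie in [0, 1]")
        if self.name == "RW" and not self.mean_curve[-1] > self.mean_curve[0]:
            raise ValueError("RW curve must end above its start")
        if self.name == "RI" and not self.mean_curve[-1] < self.mean_curve[0]:
            raise ValueError("RI curve must end below its start")
        if abs(sum(self.organ_weights) - 1.0) > 1e-9 or len(self.organ_weights) != 6:
            raise ValueError("organ_weights must be 6 values summing to 1")


def _piecewise(points: Sequence[tuple[int, float]]) -> tuple[float, ...]:
    """Linear interpolation through (window, value) anchors, windows 1..12."""
    w = np.arange(1, N_WINDOWS + 1)
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    return tuple(np.interp(w, xs, ys))


def default_archetypes(noise_sd: float = 1.0) -> list[ArchetypeSpec]:
    """The four default archetypes at the emulated cohort's prevalences."""
    return [
        ArchetypeSpec(
            name="RW",
            mean_curve=_piecewise([(1, 4.5), (12, 7.2)]),
            noise_sd=noise_sd,
            prevalence=0.131,
            mortality_rate=0.283,
            organ_weights=(0.25, 0.25, 0.30, 0.08, 0.06, 0.06),
            male_rate=0.626,
            septic_shock_rate=0.142,
            comorbidity_mean=5.0,
            los_median_days=2.9,
        ),
        ArchetypeSpec(
            name="DW",
            mean_curve=_piecewise([(1, 5.2), (8, 3.7), (12, 4.8)]),
            noise_sd=noise_sd,
            prevalence=0.205,
            mortality_rate=0.106,
            organ_weights=(0.22, 0.22, 0.06, 0.06, 0.22, 0.22),
            male_rate=0.571,
            septic_shock_rate=0.105,
            comorbidity_mean=4.0,
            los_median_days=2.9,
        ),
        ArchetypeSpec(
            name="RI",
            mean_curve=_piecewise([(1, 5.5), (12, 2.8)]),
            noise_sd=noise_sd,
            prevalence=0.413,
            mortality_rate=0.055,
            organ_weights=(0.08, 0.06, 0.06, 0.30, 0.25, 0.25),
            male_rate=0.569,
            septic_shock_rate=0.155,
            comorbidity_mean=4.0,
            los_median_days=2.4,
        ),
        ArchetypeSpec(
            name="DI",
            mean_curve=_piecewise([(1, 4.0), (6, 5.2), (12, 3.5)]),
            noise_sd=noise_sd,
            prevalence=0.251,
            mortality_rate=0.107,
            organ_weights=(0.25, 0.25, 0.06, 0.30, 0.07, 0.07),
            male_rate=0.506,
            septic_shock_rate=0.126,
            comorbidity_mean=4.0,
            los_median_days=2.9,
        ),
    ]


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    n_patients: int
    archetypes: tuple[ArchetypeSpec, ...] = None  # type: ignore[assignment]
    missing_rate: float = 0.1
    full_missing_rate: float = 0.02
    seed: int = 0
    noise_sd: float | None = None  # overrides every archetype's noise_sd

    def __post_init__(self) -> None:
        if self.archetypes is None:
            object.__setattr__(
                self,
                "archetypes",
                tuple(default_archetypes(self.noise_sd if self.noise_sd is not None else 1.0)),
            )
        elif self.noise_sd is not None:
            object.__setattr__(
                self,
                "archetypes",
                tuple(
                    dataclasses.replace(a, noise_sd=self.noise_sd) for a in self.archetypes
                ),
            )
        else:
            object.__setattr__(self, "archetypes", tuple(self.archetypes))
        if self.n_patients < 8:
            raise ValueError("n_patients must be >= 8 (at least 2 per archetype)")
        total = sum(a.prevalence for a in self.archetypes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype prevalences must sum to 1 (got {total})")
        for rate, name in [
            (self.missing_rate, "missing_rate"),
            (self.full_missing_rate, "full_missing_rate"),
        ]:
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")


@dataclasses.dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth.

    ``truth_subscores`` (n, 6, 12) and ``truth_totals`` (n, 12) are the
    latent values the measurements were back-generated from; real cohorts
    have no analogue, they exist for validation only.
    """

    measurements: pd.DataFrame
    covariates: pd.DataFrame
    truth_labels: pd.Series
    outcomes: pd.DataFrame
    truth_subscores: np.ndarray
    truth_totals: np.ndarray

    @property
    def patient_ids(self) -> list[str]:
        return list(self.truth_labels.index)

    def validate(self) -> None:
        ids = set(self.truth_labels.index)
        if ids != set(self.covariates.index):
            raise ValueError("covariates must cover exactly the labelled patients")
        if len(self.outcomes) and ids != set(self.outcomes.index):
            raise ValueError("outcomes must cover exactly the labelled patients")
        if len(self.outcomes):
            t = self.outcomes["survival_time"]
            if (t <= 0).any() or (t > 28).any():
                raise ValueError("survival times must lie in (0, 28]")
            bad = (~self.outcomes["death"]) & (~self.outcomes["censored"])
            if bad.any():
                raise ValueError("survivors must be censored")


def _decompose_total(total: int, shares: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Split an integer total into six integer subscores in [0, 4].

    Largest-remainder rounding of the (nonnegative, rescaled) organ shares
    with the sum preserved, then any subscore above 4 redistributed to the
    organs with the most headroom.
    """
    shares = np.clip(shares, 0.0, None)
    share_sum = shares.sum()
    shares = shares * (total / share_sum) if share_sum > 0 else weights * float(total)
    base = np.floor(shares).astype(int)
    remainder = total - base.sum()
    order = np.argsort(-(shares - base), kind="stable")
    base[order[:remainder]] += 1
    # cap at 4, pushing overflow to organs with spare capacity
    while (base > 4).any():
        hi = int(np.argmax(base))
        excess = base[hi] - 4
        base[hi] = 4
        room = np.flatnonzero(base < 4)
        take = room[np.argsort(-weights[room], kind="stable")]
        for organ in take:
            if excess == 0:
                break
            add = min(excess, 4 - base[organ])
            base[organ] += add
            excess -= add
    return base


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full cohort: archetypes, measurements, covariates, outcomes.

    Identical config (including seed) gives bitwise-identical output. The
    three stages (measurement generation, missingness injection, outcome
    attachment) use independent child random streams, so
    :func:`inject_missingness` and :func:`attach_outcomes` are reproducible
    when invoked standalone with the same config/seed.
    """
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_patients
    specs = list(config.archetypes)
    prevalences = np.array([a.prevalence for a in specs])

    arch_idx = rng.choice(len(specs), size=n, p=prevalences)
    ids = [f"P{i:05d}" for i in range(n)]

    mean_curves = np.array([a.mean_curve for a in specs])
    noise_sds = np.array([a.noise_sd for a in specs])
    weights = np.array([a.organ_weights for a in specs])

    # noise enters at the subscore-generating latents: organ o's latent is
    # mean_curve[k] * w_o plus Gaussian noise with sd noise_sd * w_o, so
    # the per-window sd of the latent total is noise_sd * sqrt(sum w^2)
    w_patient = weights[arch_idx]  # (n, 6)
    organ_latents = mean_curves[arch_idx][:, None, :] * w_patient[:, :, None] + (
        noise_sds[arch_idx][:, None, None]
        * w_patient[:, :, None]
        * rng.normal(0.0, 1.0, (n, len(ORGANS), N_WINDOWS))
    )
    latent_totals = organ_latents.sum(axis=1)
    truth_totals = np.clip(np.rint(latent_totals), 0, 24).astype(int)

    truth_subscores = np.empty((n, len(ORGANS), N_WINDOWS), dtype=int)
    for i in range(n):
        w = w_patient[i]
        for k in range(N_WINDOWS):
            truth_subscores[i, :, k] = _decompose_total(
                truth_totals[i, k], organ_latents[i, :, k], w
            )

    measurements = _back_generate_measurements(ids, truth_subscores, truth_totals, rng)

    ventilated = (truth_subscores[:, 0, :] >= 3).any(axis=1)
    covariates = pd.DataFrame(
        {
            "age": np.clip(rng.normal(66.0, 15.0, n), 18.0, 99.0).round(1),
            "sex": np.where(
                rng.random(n) < np.array([specs[a].male_rate for a in arch_idx]),
                "male",
                "female",
            ),
            "comorbidity_index": rng.poisson(
                np.array([specs[a].comorbidity_mean for a in arch_idx])
            ),
            "ventilated": ventilated,
            "icu_unit": rng.choice(_ICU_UNITS, size=n, p=_ICU_UNIT_P),
            "septic_shock": rng.random(n)
            < np.array([specs[a].septic_shock_rate for a in arch_idx]),
        },
        index=pd.Index(ids, name="patient_id"),
    )
    truth_labels = pd.Series(
        [specs[a].name for a in arch_idx], index=covariates.index, name="archetype"
    )

    cohort = SyntheticCohort(
        measurements=measurements,
        covariates=covariates,
        truth_labels=truth_labels,
        outcomes=pd.DataFrame(index=covariates.index),
        truth_subscores=truth_subscores,
        truth_totals=truth_totals,
    )
    cohort = inject_missingness(cohort, config)
    cohort = attach_outcomes(cohort, config.seed, config.archetypes)
    cohort.validate()
    return cohort


def _back_generate_measurements(
    ids: list[str], subscores: np.ndarray, totals: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Invert the scoring rubric: one measurement per variable per window."""
    n = len(ids)
    frames = []
    hours_jitter = rng.uniform(0.0, 6.0, (n, N_WINDOWS))
    base_hours = 6.0 * np.arange(N_WINDOWS)
    hours = base_hours[None, :] + hours_jitter  # same timestamp reused per variable

    organ_to_var = {
        0: "pao2_fio2_ratio",
        1: "platelets",
        2: "bilirubin",
        4: "gcs",
        5: "creatinine",
    }
    pid_col = np.repeat(ids, N_WINDOWS)
    hour_col = hours.ravel()

    for organ, var in organ_to_var.items():
        values = np.asarray(_BAND_VALUES[var])[subscores[:, organ, :]]
        frames.append(
            pd.DataFrame(
                {"patient_id": pid_col, "hour": hour_col, "variable": var,
                 "value": values.ravel(), "unit": _UNITS[var]}
            )
        )

    # cardiovascular: a MAP value always, a pressor dose when subscore >= 2
    cardio = subscores[:, 3, :]
    map_values = np.asarray(_BAND_VALUES["map"])[cardio]
    frames.append(
        pd.DataFrame(
            {"patient_id": pid_col, "hour": hour_col, "variable": "map",
             "value": map_values.ravel(), "unit": _UNITS["map"]}
        )
    )
    for score, (drug, dose) in _CARDIO_DOSE.items():
        mask = (cardio == score).ravel()
        if mask.any():
            frames.append(
                pd.DataFrame(
                    {"patient_id": pid_col[mask], "hour": hour_col[mask],
                     "variable": drug, "value": dose, "unit": _UNITS[drug]}
                )
            )

    # normal urine output (renal signal carried by creatinine)
    frames.append(
        pd.DataFrame(
            {"patient_id": pid_col, "hour": hour_col, "variable": "urine_6h",
             "value": np.round(rng.uniform(250.0, 400.0, n * N_WINDOWS), 0),
             "unit": _UNITS["urine_6h"]}
        )
    )

    # auxiliary predictors loosely tracking illness severity
    lactate = np.clip(1.0 + 0.25 * totals + rng.normal(0.0, 0.5, totals.shape), 0.2, None)
    heart_rate = 80.0 + 2.0 * totals + rng.normal(0.0, 8.0, totals.shape)
    for var, vals in [("lactate", lactate), ("heart_rate", heart_rate)]:
        frames.append(
            pd.DataFrame(
                {"patient_id": pid_col, "hour": hour_col, "variable": var,
                 "value": np.round(vals.ravel(), 2), "unit": _UNITS[var]}
            )
        )

    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["patient_id", "hour", "variable"], kind="stable")
    return out.reset_index(drop=True)


def inject_missingness(cohort: SyntheticCohort, config: CohortConfig) -> SyntheticCohort:
    """Delete measurements completely at random.

    Each (patient, variable, window) cell independently vanishes with
    probability ``missing_rate``; each (patient, variable) pair loses its
    entire 72-hour record with probability ``full_missing_rate``. Truth
    labels, covariates and outcomes are untouched.
    """
    if config.missing_rate == 0.0 and config.full_missing_rate == 0.0:
        return cohort
    rng = np.random.default_rng([config.seed, 1])
    meas = cohort.measurements
    keep_row = rng.random(len(meas)) >= config.missing_rate

    pv = meas["patient_id"].astype(str) + "\x00" + meas["variable"].astype(str)
    unique_pv, inverse = np.unique(pv.to_numpy(), return_inverse=True)
    keep_pv = rng.random(len(unique_pv)) >= config.full_missing_rate
    keep = keep_row & keep_pv[inverse]
    # administration records (vasopressor doses) are complete by nature:
    # an absent dose row means the drug was not given, so deleting them
    # would silently change the ground truth rather than hide it
    from .sofa import DOSE_VARIABLES

    keep |= meas["variable"].isin(DOSE_VARIABLES).to_numpy()

    return dataclasses.replace(
        cohort, measurements=meas[keep].reset_index(drop=True)
    )


def attach_outcomes(
    cohort: SyntheticCohort,
    seed: int,
    archetypes: Sequence[ArchetypeSpec] | None = None,
) -> SyntheticCohort:
    """Draw death, 28-day survival time, censoring and length of stay.

    Death is Bernoulli with the patient's archetype mortality rate; death
    times are uniform on (0, 28] days; survivors are administratively
    censored at 28 days. Length of stay is log-normal around the
    archetype's median.
    """
    if cohort.truth_labels.isna().any() or len(cohort.truth_labels) == 0:
        raise ValueError("truth labels are required to attach outcomes")
    specs = {a.name: a for a in (archetypes or default_archetypes())}
    unknown = set(cohort.truth_labels.unique()) - set(specs)
    if unknown:
        raise ValueError(f"no archetype spec for labels {sorted(unknown)}")
    rng = np.random.default_rng([seed, 2])
    n = len(cohort.truth_labels)
    mort = np.array([specs[a].mortality_rate for a in cohort.truth_labels])
    death = rng.random(n) < mort
    u = rng.random(n)
    survival_time = np.where(death, 28.0 * (1.0 - u), 28.0)  # uniform on (0, 28]
    survival_time = np.round(np.maximum(survival_time, 1e-3), 3)
    los_median = np.array([specs[a].los_median_days for a in cohort.truth_labels])
    los = np.minimum(np.exp(np.log(los_median) + rng.normal(0.0, 0.9, n)), 28.0)
    outcomes = pd.DataFrame(
        {
            "death": death,
            "survival_time": survival_time,
            "censored": ~death,
            "los": np.round(los, 2),
        },
        index=cohort.truth_labels.index,
    )
    return dataclasses.replace(cohort, outcomes=outcomes)
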