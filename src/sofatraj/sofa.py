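"""SOFA trajectory construction from raw ICU measurement streams.

Turns a long-format table of time-stamped measurements (labs, vitals,
vasopressor doses, urine output, GCS) into per-patient Sequential Organ
Failure Assessment (SOFA) trajectories: six organ subscores and their total,
evaluated on twelve 6-hour windows covering the first 72 hours of the ICU
stay.

Aggregation and imputation rules:

* within each 6-hour window the *worst* value per variable is kept, where
  "worst" is the direction that maximises the resulting subscore (minimum
  for platelets, MAP, PaO2/FiO2, GCS, urine; maximum for bilirubin,
  creatinine and vasopressor doses);
* daily urine output is converted to the 6-hour scale by dividing by 4;
* the lowest GCS in a window is used irrespective of sedation;
* missing subscores are imputed per organ row by last observation carried
  forward, then next observation carried backward for leading gaps, and an
  organ with no observation at all in the 72 hours is filled with 0.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ORGANS = ("respiration", "coagulation", "liver", "cardiovascular", "cns", "renal")

N_WINDOWS = 12
WINDOW_HOURS = 6.0
HORIZON_HOURS = 72.0

#: direction in which a variable's value worsens its subscore
WORST_DIRECTION: Mapping[str, str] = {
    "pao2_fio2_ratio": "min",
    "platelets": "min",
    "bilirubin": "max",
    "map": "min",
    "dopamine": "max",
    "dobutamine": "max",
    "epinephrine": "max",
    "norepinephrine": "max",
    "gcs": "min",
    "creatinine": "max",
    "urine_6h": "min",
    "urine_24h": "min",
    # auxiliary labs/vitals: not scored, carried through for prediction
    "lactate": "max",
    "wbc": "max",
    "heart_rate": "max",
    "temperature": "max",
}

#: administered-drug variables: a record exists only when the drug is given,
#: so an absent window means "not administered", never "missing" — these are
#: exempt from variable-level imputation
DOSE_VARIABLES = frozenset({"dopamine", "dobutamine", "epinephrine", "norepinephrine"})

NONNEGATIVE_VARIABLES = frozenset(
    {
        "platelets",
        "urine_6h",
        "urine_24h",
        "dopamine",
        "dobutamine",
        "epinephrine",
        "norepinephrine",
        "bilirubin",
        "creatinine",
        "pao2_fio2_ratio",
    }
)


@dataclasses.dataclass(frozen=True)
class WindowGrid:
    """Half-open 6-hour windows [6(k-1), 6k), k = 1..12, partitioning [0, 72)."""

    horizon_hours: float = HORIZON_HOURS
    width_hours: float = WINDOW_HOURS

    @property
    def n_windows(self) -> int:
        return int(round(self.horizon_hours / self.width_hours))

    def window_of(self, hours: np.ndarray) -> np.ndarray:
        """1-based window index; hours outside [0, horizon) map to -1."""
        h = np.asarray(hours, dtype=float)
        k = np.floor(h / self.width_hours).astype(int) + 1
        k[(h < 0) | (h >= self.horizon_hours)] = -1
        return k


DEFAULT_GRID = WindowGrid()


@dataclasses.dataclass
class SofaTrajectory:
    """Per-patient 6x12 subscore matrix plus window totals.

    ``observed_mask`` records which (organ, window) cells were resolvable
    from data before imputation.
    """

    patient_id: str
    subscores: np.ndarray  # (6, 12) int
    totals: np.ndarray  # (12,) int
    observed_mask: np.ndarray  # (6, 12) bool

    def __post_init__(self) -> None:
        if self.subscores.shape[0] != len(ORGANS):
            raise ValueError("subscores must have one row per organ")
        if not np.array_equal(self.subscores.sum(axis=0), self.totals):
            raise ValueError("totals must be the column sums of subscores")


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    required = {"patient_id", "hour", "variable", "value"}
    missing_cols = required - set(records.columns)
    if missing_cols:
        raise ValueError(f"measurement table missing columns: {sorted(missing_cols)}")
    unknown = set(records["variable"].unique()) - set(WORST_DIRECTION)
    if unknown:
        raise ValueError(f"unknown measurement variable(s): {sorted(unknown)}")
    if (records["hour"] < 0).any():
        raise ValueError("measurement hours must be >= 0")
    gcs = records.loc[records["variable"] == "gcs", "value"]
    if len(gcs) and ((gcs < 3) | (gcs > 15)).any():
        raise ValueError("GCS values must lie in [3, 15]")
    for var in NONNEGATIVE_VARIABLES:
        vals = records.loc[records["variable"] == var, "value"]
        if len(vals) and (vals < 0).any():
            raise ValueError(f"negative value for nonnegative variable {var!r}")
    return records


def aggregate_windows(
    records: pd.DataFrame, grid: WindowGrid = DEFAULT_GRID
) -> pd.DataFrame:
    """Worst value per (patient, window, variable).

    Records at or beyond the 72-hour horizon are dropped. Daily urine
    (``urine_24h``, mL/day) is rescaled to a 6-hour equivalent (÷4) and
    merged into ``urine_6h`` before taking the per-window minimum.

    Returns a tidy frame with columns patient_id, window (1-based),
    variable, value; windows with no observation are simply absent.
    """
    records = _validate_records(records)
    rec = records.loc[:, ["patient_id", "hour", "variable", "value"]].copy()
    daily = rec["variable"] == "urine_24h"
    rec.loc[daily, "value"] = rec.loc[daily, "value"] / 4.0
    rec.loc[daily, "variable"] = "urine_6h"
    rec["window"] = grid.window_of(rec["hour"].to_numpy())
    rec = rec[rec["window"] > 0]
    if rec.empty:
        return pd.DataFrame(columns=["patient_id", "window", "variable", "value"])
    direction = rec["variable"].map(lambda v: WORST_DIRECTION[v])
    grouped = rec.groupby(["patient_id", "window", "variable"], sort=True)["value"]
    worst = grouped.agg(["min", "max"]).reset_index()
    dir_per_row = worst["variable"].map(lambda v: WORST_DIRECTION[v])
    worst["value"] = np.where(dir_per_row == "min", worst["min"], worst["max"])
    del direction
    return worst.loc[:, ["patient_id", "window", "variable", "value"]]


# ---------------------------------------------------------------------------
# Organ scoring. All functions are NaN-transparent: a missing input that is
# required yields a NaN subscore, resolved later by imputation.
# ---------------------------------------------------------------------------


def _score_respiration(pf: np.ndarray, ventilated: np.ndarray) -> np.ndarray:
    s = np.select([pf < 100, pf < 200, pf < 300, pf < 400], [4, 3, 2, 1], default=0.0)
    # scores 3-4 require respiratory support; otherwise capped at 2
    s = np.where((~ventilated) & (s > 2), 2.0, s)
    return np.where(np.isnan(pf), np.nan, s)


def _score_coagulation(platelets: np.ndarray) -> np.ndarray:
    s = np.select(
        [platelets < 20, platelets < 50, platelets < 100, platelets < 150],
        [4, 3, 2, 1],
        default=0.0,
    )
    return np.where(np.isnan(platelets), np.nan, s)


def _score_liver(bilirubin: np.ndarray) -> np.ndarray:
    s = np.select(
        [bilirubin >= 12.0, bilirubin >= 6.0, bilirubin >= 2.0, bilirubin >= 1.2],
        [4, 3, 2, 1],
        default=0.0,
    )
    return np.where(np.isnan(bilirubin), np.nan, s)


def _score_cardiovascular(
    map_: np.ndarray,
    dopamine: np.ndarray,
    dobutamine: np.ndarray,
    epinephrine: np.ndarray,
    norepinephrine: np.ndarray,
) -> np.ndarray:
    """Max of the MAP band and the vasopressor-dose bands.

    An unmeasured dose is treated as drug not administered; the subscore is
    missing only when MAP and every dose are unmeasured.
    """
    all_missing = (
        np.isnan(map_)
        & np.isnan(dopamine)
        & np.isnan(dobutamine)
        & np.isnan(epinephrine)
        & np.isnan(norepinephrine)
    )
    dop = np.nan_to_num(dopamine)
    dob = np.nan_to_num(dobutamine)
    epi = np.nan_to_num(epinephrine)
    nor = np.nan_to_num(norepinephrine)
    s = np.zeros(np.broadcast(map_, dop).shape)
    s = np.where(np.nan_to_num(map_, nan=100.0) < 70.0, np.maximum(s, 1), s)
    s = np.where((dob > 0) | ((dop > 0) & (dop <= 5)), np.maximum(s, 2), s)
    s = np.where(
        (dop > 5) | ((epi > 0) & (epi <= 0.1)) | ((nor > 0) & (nor <= 0.1)),
        np.maximum(s, 3),
        s,
    )
    s = np.where((dop > 15) | (epi > 0.1) | (nor > 0.1), 4.0, s)
    return np.where(all_missing, np.nan, s)


def _score_cns(gcs: np.ndarray) -> np.ndarray:
    s = np.select([gcs < 6, gcs <= 9, gcs <= 12, gcs <= 14], [4, 3, 2, 1], default=0.0)
    return np.where(np.isnan(gcs), np.nan, s)


def _score_renal(creatinine: np.ndarray, urine_6h: np.ndarray) -> np.ndarray:
    """max(creatinine band, urine band); missing only when both are missing."""
    cr = np.select(
        [creatinine >= 5.0, creatinine >= 3.5, creatinine >= 2.0, creatinine >= 1.2],
        [4, 3, 2, 1],
        default=0.0,
    )
    cr = np.where(np.isnan(creatinine), np.nan, cr)
    ur = np.select([urine_6h < 50.0, urine_6h < 125.0], [4, 3], default=0.0)
    ur = np.where(np.isnan(urine_6h), np.nan, ur)
    return np.fmax(cr, ur)  # NaN-ignoring max; NaN only when both are missing


def score_window(
    worst_values: Mapping[str, float], ventilated: bool = False
) -> tuple[dict[str, float], float]:
    """Score a single 6-hour window from its worst values.

    Parameters
    ----------
    worst_values
        variable name -> worst value in the window; absent or NaN means
        unmeasured.
    ventilated
        whether the patient receives respiratory support (required for
        respiration subscores 3-4).

    Returns
    -------
    (subscores, total)
        subscores maps organ name to a float (NaN when the organ could not
        be resolved); total is NaN unless all six subscores resolved.
    """

    def get(name: str) -> np.ndarray:
        v = worst_values.get(name, np.nan)
        v = np.nan if v is None else float(v)
        if name in NONNEGATIVE_VARIABLES and not np.isnan(v) and v < 0:
            raise ValueError(f"negative value for {name!r}")
        if name == "gcs" and not np.isnan(v) and not (3 <= v <= 15):
            raise ValueError("GCS must lie in [3, 15]")
        return np.asarray([v])

    urine = get("urine_6h")
    if np.isnan(urine[0]):
        daily = get("urine_24h")
        urine = daily / 4.0
    vent = np.asarray([bool(ventilated)])
    scores = {
        "respiration": _score_respiration(get("pao2_fio2_ratio"), vent)[0],
        "coagulation": _score_coagulation(get("platelets"))[0],
        "liver": _score_liver(get("bilirubin"))[0],
        "cardiovascular": _score_cardiovascular(
            get("map"), get("dopamine"), get("dobutamine"),
            get("epinephrine"), get("norepinephrine"),
        )[0],
        "cns": _score_cns(get("gcs"))[0],
        "renal": _score_renal(get("creatinine"), urine)[0],
    }
    vals = np.array([scores[o] for o in ORGANS])
    total = float(vals.sum()) if not np.isnan(vals).any() else float("nan")
    return scores, total


def impute_trajectory(subscores: np.ndarray) -> np.ndarray:
    """LOCF, then NOCB for leading gaps, then zero-fill all-missing rows.

    Accepts a (n_organs, n_windows) float matrix with NaN for missing cells
    and returns an integer matrix of the same shape. Idempotent.
    """
    filled = pd.DataFrame(np.asarray(subscores, dtype=float)).ffill(axis=1).bfill(axis=1)
    filled = filled.fillna(0.0)
    return filled.to_numpy().astype(int)


def build_trajectories(
    measurements: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    grid: WindowGrid = DEFAULT_GRID,
    patient_ids: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, list[SofaTrajectory]]:
    """Full pipeline: aggregate -> score -> impute, for a whole cohort.

    Parameters
    ----------
    measurements
        long table (patient_id, hour, variable, value[, unit]).
    covariates
        optional per-patient table indexed by patient_id with a boolean
        ``ventilated`` column; patients absent from it count as not
        ventilated.
    patient_ids
        optional explicit roster; defaults to the ids present in
        ``measurements``. Row order of the output is sorted patient id.

    Returns
    -------
    (totals, trajectories)
        ``totals``: DataFrame (n_patients x 12), index sorted patient_id,
        columns ``sofa_w1..sofa_w12``. ``trajectories``: matching list of
        :class:`SofaTrajectory`.
    """
    if patient_ids is None:
        patient_ids = measurements["patient_id"].unique()
    ids = sorted(pd.unique(pd.Series(list(patient_ids))))
    if not ids:
        raise ValueError("empty cohort: no patients")
    n = len(ids)
    id_index = {p: i for i, p in enumerate(ids)}

    worst = aggregate_windows(measurements, grid)
    nw = grid.n_windows

    def raw_grid(var: str) -> np.ndarray:
        out = np.full((n, nw), np.nan)
        sub = worst[worst["variable"] == var]
        if len(sub):
            rows = sub["patient_id"].map(id_index).to_numpy()
            cols = sub["window"].to_numpy() - 1
            out[rows, cols] = sub["value"].to_numpy()
        return out

    def variable_grid(var: str) -> np.ndarray:
        # missing lab/vital values are imputed at the variable level (LOCF
        # then NOCB) before scoring; a variable never observed stays missing
        # and is resolved by the subscore-level zero fill. Doses are taken
        # as recorded: absence means the drug was not given.
        grid = raw_grid(var)
        if var in DOSE_VARIABLES:
            return grid
        return pd.DataFrame(grid).ffill(axis=1).bfill(axis=1).to_numpy()

    if covariates is not None and "ventilated" in covariates.columns:
        vent_map = covariates["ventilated"].astype(bool)
        vent = np.array([bool(vent_map.get(p, False)) for p in ids])
    else:
        vent = np.zeros(n, dtype=bool)

    def score_all(grid_of) -> np.ndarray:
        s = np.full((n, len(ORGANS), nw), np.nan)
        s[:, 0, :] = _score_respiration(grid_of("pao2_fio2_ratio"), vent[:, None])
        s[:, 1, :] = _score_coagulation(grid_of("platelets"))
        s[:, 2, :] = _score_liver(grid_of("bilirubin"))
        s[:, 3, :] = _score_cardiovascular(
            grid_of("map"),
            grid_of("dopamine"),
            grid_of("dobutamine"),
            grid_of("epinephrine"),
            grid_of("norepinephrine"),
        )
        s[:, 4, :] = _score_cns(grid_of("gcs"))
        s[:, 5, :] = _score_renal(grid_of("creatinine"), grid_of("urine_6h"))
        return s

    raw = score_all(variable_grid)
    observed = ~np.isnan(score_all(raw_grid))  # pre-imputation observability
    trajectories: list[SofaTrajectory] = []
    totals = np.empty((n, nw), dtype=int)
    for i, pid in enumerate(ids):
        sub = impute_trajectory(raw[i])
        tot = sub.sum(axis=0)
        trajectories.append(
            SofaTrajectory(
                patient_id=pid,
                subscores=sub,
                totals=tot,
                observed_mask=observed[i],
            )
        )
        totals[i] = tot

    frame = pd.DataFrame(
        totals,
        index=pd.Index(ids, name="patient_id"),
        columns=[f"sofa_w{k}" for k in range(1, nw + 1)],
    )
    return frame, trajectories
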