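"""Early prediction of trajectory subphenotypes.

A random forest is trained to predict each patient's subphenotype from the
information available by a cutoff hour t in {6, 24, 36, 48, 60}: age, sex,
comorbidity burden, ventilation, per-organ SOFA subscores computed from
measurements strictly before t (both the latest and the worst-so-far
value per organ), and the worst laboratory/vital values before t. Snapshots
are leakage-free by construction — no measurement with hour >= t enters
the feature matrix.

Accuracy is reported with a percentile bootstrap CI over resamples of the
held-out set, and feature attributions use Monte-Carlo permutation Shapley
values (Strumbelj-Kononenko): the marginal contribution of each feature is
averaged over random feature orderings, with absent features filled in
from a background sample. For each explained observation the attributions
telescope exactly, so they sum to f(x) minus the mean model output over
the background rows actually drawn.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import train_test_split

from .sofa import ORGANS, WINDOW_HOURS, WORST_DIRECTION, WindowGrid, build_trajectories

CUTOFF_HOURS = (6, 24, 36, 48, 60)


@dataclasses.dataclass
class FeatureSnapshot:
    cutoff_hour: int
    X: pd.DataFrame  # one row per patient, index = patient_id

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)


@dataclasses.dataclass
class PredictionReport:
    cutoff_hour: int
    accuracy: float
    ci_low: float
    ci_high: float
    per_class: pd.DataFrame  # precision/recall/support per class
    confusion: pd.DataFrame
    n_test: int


@dataclasses.dataclass
class TrainedClassifier:
    model: RandomForestClassifier
    train_ids: list
    test_ids: list
    classes: list


@dataclasses.dataclass
class AttributionReport:
    feature_names: list[str]
    values: np.ndarray  # (n_obs, n_features) signed Shapley values
    baselines: np.ndarray  # (n_obs,) mean model output over drawn background
    outputs: np.ndarray  # (n_obs,) model output at the explained point
    explained_class: list  # class whose probability was explained, per obs
    mean_abs: pd.Series  # per-feature mean |value|
    n_permutations: int
    seed: int


def build_feature_snapshot(
    measurements: pd.DataFrame,
    covariates: pd.DataFrame,
    t: int,
) -> FeatureSnapshot:
    """Assemble the hour-t feature matrix from data strictly before t."""
    if t not in CUTOFF_HOURS:
        raise ValueError(f"cutoff hour must be one of {CUTOFF_HOURS}")
    ids = sorted(covariates.index)
    early = measurements[measurements["hour"] < t]

    features = pd.DataFrame(index=pd.Index(ids, name="patient_id"))
    features["age"] = covariates["age"]
    features["male"] = (covariates["sex"] == "male").astype(float)
    features["comorbidity_index"] = covariates["comorbidity_index"].astype(float)
    features["ventilated"] = covariates["ventilated"].astype(float)
    if "septic_shock" in covariates.columns:
        features["septic_shock"] = covariates["septic_shock"].astype(float)

    # SOFA subscores from the windows fully contained in [0, t)
    grid = WindowGrid(horizon_hours=float(t), width_hours=WINDOW_HOURS)
    _, trajectories = build_trajectories(early, covariates, grid=grid, patient_ids=ids)
    sub = np.stack([tr.subscores for tr in trajectories])  # (n, 6, windows)
    for o, organ in enumerate(ORGANS):
        features[f"sofa_{organ}_latest"] = sub[:, o, -1].astype(float)
        features[f"sofa_{organ}_worst"] = sub[:, o, :].max(axis=1).astype(float)
    features["sofa_total_latest"] = sub[:, :, -1].sum(axis=1).astype(float)

    # worst raw value per variable before t, median-imputed with indicators
    for var in sorted(early["variable"].unique()):
        rows = early[early["variable"] == var]
        agg = rows.groupby("patient_id")["value"]
        worst = agg.min() if WORST_DIRECTION[var] == "min" else agg.max()
        col = worst.reindex(ids)
        observed = col.notna()
        median = col.median()
        features[f"{var}_worst"] = col.fillna(0.0 if np.isnan(median) else median)
        if (~observed).any():
            features[f"{var}_missing"] = (~observed).astype(float)

    return FeatureSnapshot(cutoff_hour=t, X=features)


def train_classifier(
    snapshot: FeatureSnapshot,
    labels: pd.Series,
    seed: int = 0,
    test_size: float = 0.3,
    n_estimators: int = 500,
    split: tuple[Sequence, Sequence] | None = None,
) -> TrainedClassifier:
    """Fit a seeded random forest on a stratified 70/30 split.

    ``split`` optionally pins (train_ids, test_ids) so that successive
    cutoffs evaluate on the identical held-out patients.
    """
    y = labels.loc[snapshot.X.index]
    if split is None:
        train_ids, test_ids = train_test_split(
            list(snapshot.X.index),
            test_size=test_size,
            stratify=y,
            random_state=seed,
        )
    else:
        train_ids, test_ids = list(split[0]), list(split[1])
    y_train = y.loc[train_ids]
    if set(y.unique()) - set(y_train.unique()):
        raise ValueError("a class is absent from the training split")
    model = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    model.fit(snapshot.X.loc[train_ids], y_train)
    return TrainedClassifier(
        model=model,
        train_ids=train_ids,
        test_ids=test_ids,
        classes=list(model.classes_),
    )


def evaluate(
    trained: TrainedClassifier,
    snapshot: FeatureSnapshot,
    labels: pd.Series,
    n_boot: int = 1000,
    seed: int = 0,
) -> PredictionReport:
    """Held-out accuracy with a percentile bootstrap CI."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    test_ids = trained.test_ids
    if len(test_ids) == 0:
        raise ValueError("empty test set")
    X_test = snapshot.X.loc[test_ids]
    y_test = labels.loc[test_ids].to_numpy()
    pred = trained.model.predict(X_test)
    correct = (pred == y_test).astype(float)
    accuracy = float(correct.mean())
    rng = np.random.default_rng([seed, 23])
    idx = rng.integers(0, len(correct), size=(n_boot, len(correct)))
    boots = correct[idx].mean(axis=1)
    ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    classes = trained.classes
    prec, rec, _, support = precision_recall_fscore_support(
        y_test, pred, labels=classes, zero_division=0
    )
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "support": support}, index=classes
    )
    conf = pd.DataFrame(
        confusion_matrix(y_test, pred, labels=classes), index=classes, columns=classes
    )
    return PredictionReport(
        cutoff_hour=snapshot.cutoff_hour,
        accuracy=accuracy,
        ci_low=float(min(ci_low, accuracy)),
        ci_high=float(max(ci_high, accuracy)),
        per_class=per_class,
        confusion=conf,
        n_test=len(test_ids),
    )


def accuracy_over_time(
    measurements: pd.DataFrame,
    covariates: pd.DataFrame,
    labels: pd.Series,
    times: Sequence[int] = CUTOFF_HOURS,
    seed: int = 0,
    n_boot: int = 1000,
    n_estimators: int = 500,
) -> list[PredictionReport]:
    """One train/evaluate cycle per cutoff hour on a single fixed split."""
    ids = sorted(covariates.index)
    y = labels.loc[ids]
    train_ids, test_ids = train_test_split(
        ids, test_size=0.3, stratify=y, random_state=seed
    )
    reports = []
    for t in sorted(times):
        snapshot = build_feature_snapshot(measurements, covariates, t)
        trained = train_classifier(
            snapshot, labels, seed=seed, split=(train_ids, test_ids),
            n_estimators=n_estimators,
        )
        reports.append(evaluate(trained, snapshot, labels, n_boot=n_boot, seed=seed))
    return reports


def shapley_attribution(
    predict: Callable[[np.ndarray], np.ndarray] | TrainedClassifier,
    X_explain,
    background,
    n_permutations: int = 200,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> AttributionReport:
    """Monte-Carlo permutation Shapley values.

    Parameters
    ----------
    predict
        either a vectorised function mapping an (m, p) array to m scalar
        outputs, or a :class:`TrainedClassifier`, in which case the
        probability of each observation's predicted class is explained.
    X_explain, background
        rows to explain and the background sample used to marginalise
        absent features (typically training rows).
    """
    if n_permutations < 50:
        raise ValueError("n_permutations must be >= 50")
    Xe = X_explain.to_numpy(dtype=float) if isinstance(X_explain, pd.DataFrame) else np.asarray(X_explain, float)
    if feature_names is None:
        feature_names = (
            list(X_explain.columns)
            if isinstance(X_explain, pd.DataFrame)
            else [f"x{j}" for j in range(Xe.shape[1])]
        )
    B = background.to_numpy(dtype=float) if isinstance(background, pd.DataFrame) else np.asarray(background, float)
    if B.ndim != 2 or B.shape[0] == 0:
        raise ValueError("background sample must be a non-empty 2-d array")
    n_obs, p = Xe.shape

    explained_class: list = []
    if isinstance(predict, TrainedClassifier):
        model = predict.model
        pred_classes = model.predict(pd.DataFrame(Xe, columns=feature_names))

        def make_fn(cls):
            ci = predict.classes.index(cls)
            return lambda Z: model.predict_proba(
                pd.DataFrame(Z, columns=feature_names)
            )[:, ci]

        fns = [make_fn(c) for c in pred_classes]
        explained_class = list(pred_classes)
    else:
        fns = [predict] * n_obs
        explained_class = [None] * n_obs

    rng = np.random.default_rng([seed, 31])
    values = np.zeros((n_obs, p))
    baselines = np.zeros(n_obs)
    outputs = np.zeros(n_obs)
    for i in range(n_obs):
        x = Xe[i]
        b_idx = rng.integers(0, B.shape[0], size=n_permutations)
        orders = np.stack([rng.permutation(p) for _ in range(n_permutations)])
        # z-matrix: n_permutations blocks of (p+1) rows; block r walks from
        # the background row to x along the order of permutation r
        Z = np.empty((n_permutations * (p + 1), p))
        for r in range(n_permutations):
            z = B[b_idx[r]].copy()
            block = r * (p + 1)
            Z[block] = z
            for step, j in enumerate(orders[r]):
                z[j] = x[j]
                Z[block + step + 1] = z
        out = np.asarray(fns[i](Z), dtype=float)
        out = out.reshape(n_permutations, p + 1)
        marginals = np.diff(out, axis=1)  # (n_permutations, p), in order position
        for r in range(n_permutations):
            values[i, orders[r]] += marginals[r]
        values[i] /= n_permutations
        baselines[i] = out[:, 0].mean()
        outputs[i] = out[:, -1].mean()
    mean_abs = pd.Series(np.abs(values).mean(axis=0), index=list(feature_names)).sort_values(
        ascending=False
    )
    return AttributionReport(
        feature_names=list(feature_names),
        values=values,
        baselines=baselines,
        outputs=outputs,
        explained_class=explained_class,
        mean_abs=mean_abs,
        n_permutations=n_permutations,
        seed=seed,
    )
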