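"""Group-based trajectory modeling (latent-class growth curves).

A finite mixture of polynomial-in-time regressions: patient i's 12-window
SOFA vector y_i belongs to latent class g with probability pi_g, and within
class g

    y_it ~ Normal( sum_j beta_gj * t^j , sigma^2 )

with time t rescaled to [0, 1] over the 12 windows and a single residual
variance shared across classes and time points. Fitting is by EM with
k-means initialisation and multiple restarts; the per-iteration
log-likelihood is monotone non-decreasing (standard EM guarantee). Model
size is selected by BIC. This re-derives the trajectory subphenotypes under
a parametric model, as a sensitivity check on the nonparametric DTW +
hierarchical clustering route; agreement between the two partitions is
quantified with the adjusted Rand index.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .clustering import ClusterAssignment, relabel_by_size

_MIN_SIGMA2 = 1e-12


@dataclasses.dataclass
class TrajectoryMixtureModel:
    G: int
    degree: int
    weights: np.ndarray  # (G,)
    coefficients: np.ndarray  # (G, degree+1), ascending powers of t in [0,1]
    sigma2: float
    loglik: float
    n_params: int
    bic: float
    converged: bool
    loglik_trace: np.ndarray
    n_obs: int

    def class_curves(self, n_windows: int = 12) -> np.ndarray:
        """(G, n_windows) fitted mean curves."""
        t = np.linspace(0.0, 1.0, n_windows)
        X = np.vander(t, self.degree + 1, increasing=True)
        return self.coefficients @ X.T

    def to_dict(self) -> dict:
        return {
            "G": self.G,
            "degree": self.degree,
            "weights": self.weights.tolist(),
            "coefficients": self.coefficients.tolist(),
            "sigma2": self.sigma2,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "bic": self.bic,
            "converged": self.converged,
        }


@dataclasses.dataclass
class PosteriorMembership:
    patient_ids: list
    probabilities: np.ndarray  # (n, G), rows sum to 1
    hard: np.ndarray  # argmax class index, 0-based

    def to_assignment(self) -> ClusterAssignment:
        clusters = relabel_by_size(self.hard)
        return ClusterAssignment(
            patient_ids=list(self.patient_ids),
            clusters=clusters,
            k=len(np.unique(clusters)),
        )


def _as_matrix(traj) -> tuple[list, np.ndarray]:
    if isinstance(traj, pd.DataFrame):
        return list(traj.index), traj.to_numpy(dtype=float)
    values = np.asarray(traj, dtype=float)
    return list(range(values.shape[0])), values


def _log_densities(Y: np.ndarray, mu: np.ndarray, sigma2: float) -> np.ndarray:
    """(n, G) log N(y_i; mu_g, sigma2 I) for the 12-dim rows."""
    T = Y.shape[1]
    sq = ((Y[:, None, :] - mu[None, :, :]) ** 2).sum(axis=2)
    return -0.5 * (T * np.log(2.0 * np.pi * sigma2) + sq / sigma2)


def _em_once(
    Y: np.ndarray,
    X: np.ndarray,
    G: int,
    resp0: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float, float, np.ndarray, bool, bool]:
    n, T = Y.shape
    XtX_inv_Xt = np.linalg.solve(X.T @ X, X.T)
    resp = resp0
    trace = []
    converged = False
    collapsed = False
    weights = coef = None
    sigma2 = 1.0
    prev = -np.inf
    for _ in range(max_iter):
        # M-step
        nk = resp.sum(axis=0)
        if (nk < 1e-8).any():
            collapsed = True
            break
        weights = nk / n
        ybar = (resp.T @ Y) / nk[:, None]  # (G, T) responsibility-weighted means
        coef = (XtX_inv_Xt @ ybar.T).T  # (G, p+1)
        mu = coef @ X.T
        sq = ((Y[:, None, :] - mu[None, :, :]) ** 2).sum(axis=2)
        sigma2 = max(float((resp * sq).sum() / (n * T)), _MIN_SIGMA2)
        # E-step
        log_r = np.log(weights)[None, :] + _log_densities(Y, mu, sigma2)
        norm = logsumexp(log_r, axis=1)
        loglik = float(norm.sum())
        resp = np.exp(log_r - norm[:, None])
        trace.append(loglik)
        if loglik - prev < tol and np.isfinite(prev):
            converged = True
            break
        prev = loglik
    return weights, coef, sigma2, (trace[-1] if trace else -np.inf), np.array(trace), converged, collapsed


def fit_gbtm(
    traj,
    G: int,
    degree: int = 2,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> TrajectoryMixtureModel:
    """Fit a G-class polynomial trajectory mixture by multi-start EM.

    Restart r initialises responsibilities from a seeded k-means partition
    of the trajectory rows; the best (highest final log-likelihood)
    non-collapsed restart is returned. A restart whose classes empty out is
    discarded; if every restart collapses an error is raised.
    """
    ids, Y = _as_matrix(traj)
    n, T = Y.shape
    if G < 1:
        raise ValueError("G must be >= 1")
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    if n < G * (degree + 2):
        raise ValueError(f"need at least G*(degree+2)={G * (degree + 2)} trajectories")
    t = np.linspace(0.0, 1.0, T)
    X = np.vander(t, degree + 1, increasing=True)

    best = None
    rng = np.random.default_rng([seed, 17])
    for restart in range(max(n_restarts, 1) if G > 1 else 1):
        if G == 1:
            resp0 = np.ones((n, 1))
        else:
            km = KMeans(
                n_clusters=G,
                n_init=1,
                random_state=int(rng.integers(0, 2**31 - 1)),
            ).fit(Y)
            resp0 = np.full((n, G), 0.05 / max(G - 1, 1))
            resp0[np.arange(n), km.labels_] = 0.95
            resp0 /= resp0.sum(axis=1, keepdims=True)
        weights, coef, sigma2, loglik, trace, converged, collapsed = _em_once(
            Y, X, G, resp0, max_iter, tol
        )
        if collapsed or weights is None:
            continue
        if best is None or loglik > best[3]:
            best = (weights, coef, sigma2, loglik, trace, converged)
    if best is None:
        raise RuntimeError("every EM restart collapsed to an empty class")
    weights, coef, sigma2, loglik, trace, converged = best
    n_params = G * (degree + 1) + (G - 1) + 1
    bic = -2.0 * loglik + n_params * np.log(n)
    return TrajectoryMixtureModel(
        G=G,
        degree=degree,
        weights=weights,
        coefficients=coef,
        sigma2=sigma2,
        loglik=loglik,
        n_params=n_params,
        bic=float(bic),
        converged=converged,
        loglik_trace=trace,
        n_obs=n,
    )


def select_model(
    traj,
    G_range=range(1, 7),
    degree: int = 2,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[TrajectoryMixtureModel, pd.DataFrame]:
    """Fit every candidate class count and return the minimum-BIC model.

    Returns (best model, BIC table indexed by G).
    """
    G_range = [int(g) for g in G_range]
    if any(g < 1 or g > 8 for g in G_range):
        raise ValueError("G_range must lie within [1, 8]")
    models = {g: fit_gbtm(traj, g, degree=degree, seed=seed, **fit_kwargs) for g in G_range}
    table = pd.DataFrame(
        {"bic": {g: m.bic for g, m in models.items()},
         "loglik": {g: m.loglik for g, m in models.items()},
         "converged": {g: m.converged for g, m in models.items()}}
    ).sort_index()
    table.index.name = "G"
    best_g = int(table["bic"].idxmin())
    return models[best_g], table


def posterior_assign(model: TrajectoryMixtureModel, traj) -> PosteriorMembership:
    """Bayes posterior class memberships under a fitted model."""
    ids, Y = _as_matrix(traj)
    t = np.linspace(0.0, 1.0, Y.shape[1])
    X = np.vander(t, model.degree + 1, increasing=True)
    mu = model.coefficients @ X.T
    log_r = np.log(model.weights)[None, :] + _log_densities(Y, mu, model.sigma2)
    probs = np.exp(log_r - logsumexp(log_r, axis=1)[:, None])
    return PosteriorMembership(
        patient_ids=ids, probabilities=probs, hard=probs.argmax(axis=1)
    )


def agreement(a: ClusterAssignment, b: ClusterAssignment) -> tuple[float, pd.DataFrame]:
    """Adjusted Rand index and cross-tabulation of two partitions."""
    if list(a.patient_ids) != list(b.patient_ids):
        if set(a.patient_ids) != set(b.patient_ids):
            raise ValueError("assignments cover different patient sets")
        order = {p: i for i, p in enumerate(a.patient_ids)}
        perm = np.argsort([order[p] for p in b.patient_ids])
        b_clusters = np.asarray(b.clusters)[perm]
    else:
        b_clusters = np.asarray(b.clusters)
    ari = float(adjusted_rand_score(a.clusters, b_clusters))
    tab = pd.crosstab(
        pd.Series(a.clusters, name="a"), pd.Series(b_clusters, name="b")
    )
    return ari, tab
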