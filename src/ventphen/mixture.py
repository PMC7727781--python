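"""Latent profile analysis: diagonal Gaussian mixtures fitted by EM.

The model is a K-component mixture of diagonal-covariance Gaussians,
p(x) = sum_l p_l N(x; mu_l, sigma), in one of two constraint modes:

* ``model_1`` — pooled variance: one variance per dimension shared by all
  classes (equal variance, zero covariance);
* ``model_2`` — class-specific variance per dimension (varying variance,
  zero covariance).

Fitting alternates the E-step (posterior class responsibilities via the
Bayes rule) and the M-step (responsibility-weighted weights, means and
variances), which never decreases the observed-data log-likelihood. Model
quality is summarized by BIC and by the relative-entropy criterion of
classification crispness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

from .preprocess import Scaler

MODEL_1 = "model_1"   # equal variance, zero covariance
MODEL_2 = "model_2"   # varying variance, zero covariance
_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class MixtureModel:
    weights: np.ndarray                 # (K,)
    means: np.ndarray                   # (K, D)
    variances: np.ndarray               # (D,) for model_1, (K, D) for model_2
    mode: str
    feature_names: list[str]
    scaler: Scaler | None = None
    fit_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.variances = np.asarray(self.variances, dtype=float)
        if self.mode not in (MODEL_1, MODEL_2):
            raise ValueError(f"unknown covariance mode {self.mode!r}")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        expected = (self.D,) if self.mode == MODEL_1 else (self.K, self.D)
        if self.variances.shape != expected:
            raise ValueError(
                f"variances shape {self.variances.shape}, expected {expected}")
        if (self.variances <= 0).any():
            raise ValueError("variances must be positive")

    @property
    def K(self) -> int:
        return len(self.weights)

    @property
    def D(self) -> int:
        return self.means.shape[1]

    @property
    def class_variances(self) -> np.ndarray:
        """(K, D) variances regardless of mode."""
        if self.mode == MODEL_1:
            return np.broadcast_to(self.variances, (self.K, self.D))
        return self.variances

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "mode": self.mode,
            "K": self.K,
            "feature_names": self.feature_names,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "scaler": json.loads(self.scaler.to_json()) if self.scaler else None,
            "fit_info": _jsonable(self.fit_info),
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MixtureModel":
        doc = json.loads(text)
        scaler = (Scaler.from_json(json.dumps(doc["scaler"]))
                  if doc.get("scaler") else None)
        return cls(np.array(doc["weights"]), np.array(doc["means"]),
                   np.array(doc["variances"]), doc["mode"],
                   list(doc["feature_names"]), scaler, doc.get("fit_info", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


@dataclass
class PosteriorMatrix:
    """Row-stochastic posterior class memberships with max-posterior labels."""

    patient_ids: list
    probs: np.ndarray              # (n, K)
    class_labels: list[int]        # 1-based phenotype labels per column

    @property
    def assignment(self) -> np.ndarray:
        """1-based phenotype label of the maximum-posterior class per row."""
        return np.asarray(self.class_labels)[np.argmax(self.probs, axis=1)]

    @property
    def max_posterior(self) -> np.ndarray:
        return self.probs.max(axis=1)

    def counts(self) -> np.ndarray:
        a = self.assignment
        return np.array([(a == lab).sum() for lab in self.class_labels])

    def proportions(self) -> np.ndarray:
        return self.counts() / len(self.patient_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs, index=pd.Index(self.patient_ids,
                                                     name="patient_id"),
                          columns=[f"p{lab}" for lab in self.class_labels])
        df["assignment"] = self.assignment
        df["max_posterior"] = self.max_posterior
        return df


# -------------------------------------------------------------- density math

def _as_matrix(x, D: int) -> np.ndarray:
    X = np.asarray(x, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != D:
        raise ValueError(f"expected dimension {D}, got {X.shape[1]}")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in input")
    return X


def component_log_pdf(model: MixtureModel, x) -> np.ndarray:
    """(n, K) log N(x_i; mu_k, sigma_k) for diagonal Gaussians."""
    X = _as_matrix(x, model.D)
    var = model.class_variances                    # (K, D)
    diff2 = (X[:, None, :] - model.means[None, :, :]) ** 2
    return -0.5 * (np.sum(np.log(var) + _LOG2PI + diff2 / var, axis=2))


def log_density(model: MixtureModel, x) -> np.ndarray | float:
    """Log mixture density log p(x), stabilized with log-sum-exp."""
    lp = component_log_pdf(model, x) + np.log(model.weights)
    out = logsumexp(lp, axis=1)
    return float(out[0]) if np.asarray(x).ndim == 1 else out


def posterior(model: MixtureModel, x) -> np.ndarray:
    """Posterior class memberships p(z=l | x), rows summing to 1."""
    lp = component_log_pdf(model, x) + np.log(model.weights)
    lp -= logsumexp(lp, axis=1, keepdims=True)
    P = np.exp(lp)
    return P[0] if np.asarray(x).ndim == 1 else P


# ------------------------------------------------------------------------ EM

def _m_step(X: np.ndarray, resp: np.ndarray, mode: str,
            var_floor: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, D = X.shape
    nk = resp.sum(axis=0)                          # (K,)
    weights = nk / n
    means = (resp.T @ X) / nk[:, None]
    sq = resp.T @ (X ** 2)                         # (K, D)
    var_k = sq / nk[:, None] - means ** 2
    if mode == MODEL_1:
        variances = (nk[:, None] * var_k).sum(axis=0) / n   # pooled per dim
    else:
        variances = var_k
    variances = np.maximum(variances, var_floor)
    return weights, means, variances


def _loglik(X, weights, means, variances, mode):
    model = MixtureModel(weights, means, variances, mode,
                         [f"f{i}" for i in range(X.shape[1])])
    return float(np.sum(log_density(model, X)))


def fit_em(data: pd.DataFrame | np.ndarray, K: int, mode: str = MODEL_1,
           n_restarts: int = 10, tol: float = 1e-6, max_iter: int = 500,
           seed: int = 0, var_floor: float = 1e-6,
           scaler: Scaler | None = None) -> MixtureModel:
    """Fit a K-class diagonal-Gaussian mixture by EM with restarts.

    Each restart seeds the class means k-means++-style on the data, starts
    from uniform weights and the pooled per-dimension variance, and iterates
    E/M until the relative log-likelihood gain drops below ``tol`` or
    ``max_iter`` is reached. The restart with the highest log-likelihood
    wins; restarts where a class collapses (weight < 1/(10n)) are flagged
    and skipped when a valid one exists. Classes are canonically ordered by
    descending weight. Deterministic under ``seed``.
    """
    if isinstance(data, pd.DataFrame):
        names = list(data.columns)
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    n, D = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds n={n}")
    if np.isnan(X).any():
        raise ValueError("fit_em requires a complete matrix")

    pooled_var = np.maximum(X.var(axis=0), var_floor)
    master = np.random.default_rng(seed)
    best: dict | None = None
    best_valid: dict | None = None
    for restart in range(max(1, n_restarts)):
        rs = int(master.integers(2**31))
        if K == 1:
            centers = X.mean(axis=0, keepdims=True)
        else:
            centers, _ = kmeans_plusplus(X, n_clusters=K, random_state=rs)
        weights = np.full(K, 1.0 / K)
        means = centers.astype(float)
        variances = (pooled_var.copy() if mode == MODEL_1
                     else np.tile(pooled_var, (K, 1)))
        trace: list[float] = []
        ll = -np.inf
        converged = False
        for _ in range(max_iter):
            lp = (component_log_pdf(
                MixtureModel(weights, means, variances, mode, names), X)
                + np.log(weights))
            norm = logsumexp(lp, axis=1, keepdims=True)
            ll_new = float(norm.sum())
            resp = np.exp(lp - norm)
            weights, means, variances = _m_step(X, resp, mode, var_floor)
            trace.append(ll_new)
            if np.isfinite(ll) and abs(ll_new - ll) <= tol * abs(ll):
                converged = True
                ll = ll_new
                break
            ll = ll_new
        # degenerate restarts: an (almost) empty class, or a variance crushed
        # onto the floor — the spurious unbounded-likelihood maxima that
        # atoms (e.g. capped SpO2 at 100%) induce in varying-variance fits
        collapsed = bool((weights < 1.0 / (10 * n)).any()
                         or (variances <= var_floor * 1.001).any())
        cand = dict(weights=weights, means=means, variances=variances,
                    loglik=ll, trace=trace, converged=converged,
                    collapsed=collapsed, restart=restart)
        if best is None or ll > best["loglik"]:
            best = cand
        if not collapsed and (best_valid is None or ll > best_valid["loglik"]):
            best_valid = cand
    chosen = best_valid if best_valid is not None else best

    order = np.argsort(-chosen["weights"], kind="stable")
    weights = chosen["weights"][order]
    means = chosen["means"][order]
    variances = (chosen["variances"] if mode == MODEL_1
                 else chosen["variances"][order])
    fit_info = {
        "loglik": chosen["loglik"],
        "loglik_trace": chosen["trace"],
        "n_iter": len(chosen["trace"]),
        "converged": chosen["converged"],
        "collapsed_restart": chosen["collapsed"],
        "n_restarts": n_restarts,
        "seed": seed,
        "n": n,
    }
    return MixtureModel(weights, means, variances, mode, names, scaler,
                        fit_info)


# ------------------------------------------------------------- fit summaries

def n_parameters(model: MixtureModel) -> int:
    K, D = model.K, model.D
    return (K - 1) + K * D + (D if model.mode == MODEL_1 else K * D)


def bic(model: MixtureModel, data: pd.DataFrame | np.ndarray) -> float:
    """Bayesian information criterion, -2 loglik + q ln n (lower is better)."""
    X = data.to_numpy(dtype=float) if isinstance(data, pd.DataFrame) else \
        np.asarray(data, dtype=float)
    ll = float(np.sum(log_density(model, X)))
    return -2.0 * ll + n_parameters(model) * np.log(X.shape[0])


def entropy_measure(probs: np.ndarray) -> float:
    """Relative-entropy criterion: 1 - Shannon entropy / (n ln K).

    1 means perfectly crisp assignment, 0 means uniform memberships.
    """
    P = np.asarray(probs, dtype=float)
    n, K = P.shape
    if K < 2:
        raise ValueError("entropy is undefined for K=1")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    return float(1.0 + plogp.sum() / (n * np.log(K)))


# ----------------------------------------------------------- label canonics

def match_labels(means_a: np.ndarray, means_b: np.ndarray) -> np.ndarray:
    """Permutation mapping rows of ``means_a`` to nearest rows of ``means_b``.

    Euclidean one-to-one matching (Hungarian algorithm); ``perm[i]`` is the
    row of ``means_b`` matched to row ``i`` of ``means_a``.
    """
    cost = np.linalg.norm(means_a[:, None, :] - means_b[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(rows), dtype=int)
    perm[rows] = cols
    return perm


def relabel_to_reference(model: MixtureModel,
                         reference_means: np.ndarray) -> MixtureModel:
    """Reorder classes so class i sits nearest reference row i.

    Used to map fitted classes onto the phenotype labels I..V via the
    published per-phenotype profiles (compared on the model's fitting scale).
    """
    perm = match_labels(reference_means, model.means)
    variances = (model.variances if model.mode == MODEL_1
                 else model.variances[perm])
    info = dict(model.fit_info, label_map=perm.tolist())
    return MixtureModel(model.weights[perm], model.means[perm], variances,
                        model.mode, model.feature_names, model.scaler, info)
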