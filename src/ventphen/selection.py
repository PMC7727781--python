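"""Phenotype-number selection and population-stability validation.

``sweep_k`` fits the mixture over a range of class counts and selects the
number of phenotypes by BIC among models that keep every class adequately
sized and crisply assigned (minimum class proportion and median
max-posterior floors). ``psi`` implements the population stability index,
PSI = sum (actual% - expected%) * ln(actual% / expected%), the scorecard
drift measure used to compare phenotype distributions between cohorts;
values below 0.1 are conventionally read as "no meaningful shift".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixture import (
    MODEL_1,
    MixtureModel,
    PosteriorMatrix,
    bic,
    entropy_measure,
    fit_em,
    posterior,
)


@dataclass
class SelectionReport:
    table: pd.DataFrame          # per-K metrics and verdicts
    chosen_k: int
    fallback: bool               # no K passed the floors; pure BIC minimum
    models: dict[int, MixtureModel] = field(default_factory=dict)


def sweep_k(data: pd.DataFrame | np.ndarray, k_range=range(2, 9),
            mode: str = MODEL_1, n_restarts: int = 10, tol: float = 1e-6,
            max_iter: int = 500, seed: int = 0, size_floor: float = 0.04,
            posterior_floor: float = 0.7, keep_models: bool = True,
            ) -> SelectionReport:
    """Fit every K in ``k_range`` and pick the phenotype number.

    The chosen K minimizes BIC among fits whose smallest class proportion is
    at least ``size_floor`` and whose median max-posterior is at least
    ``posterior_floor`` (adequate size, high membership certainty). Relative
    entropy is reported for inspection. If no K is admissible, the pure BIC
    minimum is returned with a warning and ``fallback=True``. The rule trace
    in the report covers every K with its pass/fail verdict.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty K range")
    X = data.to_numpy(dtype=float) if isinstance(data, pd.DataFrame) else \
        np.asarray(data, dtype=float)
    rows = []
    models: dict[int, MixtureModel] = {}
    for k in ks:
        model = fit_em(data, k, mode=mode, n_restarts=n_restarts, tol=tol,
                       max_iter=max_iter, seed=seed + k)
        probs = posterior(model, X)
        med_post = float(np.median(probs.max(axis=1)))
        # class size = estimated mixing proportion (the latent class
        # proportion, the standard reading in latent-class practice)
        min_prop = float(model.weights.min())
        ent = entropy_measure(probs) if k >= 2 else np.nan
        size_ok = min_prop >= size_floor
        post_ok = med_post >= posterior_floor
        degenerate = bool(model.fit_info.get("collapsed_restart", False))
        reasons = []
        if not size_ok:
            reasons.append(f"min class proportion {min_prop:.3f} < {size_floor}")
        if not post_ok:
            reasons.append(f"median max-posterior {med_post:.3f} < {posterior_floor}")
        if degenerate:
            reasons.append("no non-degenerate restart (class or variance collapse)")
        rows.append(dict(K=k, loglik=model.fit_info["loglik"],
                         bic=bic(model, X), entropy=ent,
                         min_class_prop=min_prop, median_max_posterior=med_post,
                         admissible=size_ok and post_ok and not degenerate,
                         reasons="; ".join(reasons) or "pass"))
        if keep_models:
            models[k] = model
    table = pd.DataFrame(rows)
    admissible = table[table["admissible"]]
    if len(admissible):
        chosen = int(admissible.loc[admissible["bic"].idxmin(), "K"])
        fallback = False
    else:
        warnings.warn("no K passed the size/posterior floors; "
                      "falling back to the pure BIC minimum")
        chosen = int(table.loc[table["bic"].idxmin(), "K"])
        fallback = True
    return SelectionReport(table, chosen, fallback, models)


# ------------------------------------------------------------------------ PSI

@dataclass
class PSIResult:
    bin_labels: list
    expected_prop: np.ndarray
    actual_prop: np.ndarray
    terms: np.ndarray
    total: float
    smoothed_bins: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin": self.bin_labels,
            "expected_prop": self.expected_prop,
            "actual_prop": self.actual_prop,
            "psi_term": self.terms,
        })


def psi(expected_counts, actual_counts, bin_labels=None) -> PSIResult:
    """Population stability index between two count distributions.

    Counts are converted to proportions; any bin empty in either vector
    receives an additive 0.5-count smoothing in both vectors (flagged in the
    result) so the logarithm stays finite. The index is symmetric in its
    arguments and zero exactly when the proportion vectors coincide.
    """
    e = np.asarray(expected_counts, dtype=float)
    a = np.asarray(actual_counts, dtype=float)
    if e.shape != a.shape or e.ndim != 1:
        raise ValueError("count vectors must be 1-D and of equal length")
    if (e < 0).any() or (a < 0).any():
        raise ValueError("counts must be non-negative")
    if e.sum() <= 0 or a.sum() <= 0:
        raise ValueError("both count totals must be positive")
    labels = list(bin_labels) if bin_labels is not None else \
        list(range(1, len(e) + 1))
    zero = (e == 0) | (a == 0)
    smoothed = [labels[i] for i in np.flatnonzero(zero)]
    if smoothed:
        e = e + 0.5 * zero
        a = a + 0.5 * zero
    ep = e / e.sum()
    ap = a / a.sum()
    terms = (ap - ep) * np.log(ap / ep)
    return PSIResult(labels, ep, ap, terms, float(terms.sum()), smoothed)


# ------------------------------------------------------------ cohort scoring

def assign_cohort(model: MixtureModel, data: pd.DataFrame,
                  class_labels: list[int] | None = None) -> PosteriorMatrix:
    """Score a cohort: posterior memberships and maximum-posterior phenotypes.

    ``data`` must be on the model's fitting scale (i.e. scaled with the
    model's stored training scaler) with matching feature columns.
    """
    if list(data.columns) != model.feature_names:
        raise ValueError("feature names do not match the model")
    probs = posterior(model, data.to_numpy(dtype=float))
    labels = class_labels if class_labels is not None \
        else list(range(1, model.K + 1))
    return PosteriorMatrix(list(data.index), probs, labels)
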