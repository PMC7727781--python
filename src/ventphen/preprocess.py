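"""Feature-matrix preparation: 24-h aggregation, imputation, screening, scaling.

The chained-equation imputer follows the classic MICE-with-PMM recipe:
missing cells start at column means, then each incomplete column is cycled
through in order, regressing it on all other columns over its originally
observed rows and redrawing the missing entries by predictive mean matching
(nearest-donor draw), for a fixed number of cycles. A fitted imputer can be
re-applied to a held-out cohort so validation data never informs the
training-set models.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

SPREAD_FLOOR = 1e-8


# ---------------------------------------------------------------- aggregation

def aggregate_24h(obs: pd.DataFrame,
                  known_features: list[str] | None = None) -> pd.DataFrame:
    """Collapse long-format first-24-h observations to per-patient means.

    ``obs`` columns: patient_id, feature, time_offset_hours, value. A cell is
    left missing when a patient has no observation of that feature. Offsets
    outside [0, 24) and (when ``known_features`` is given) unknown feature
    names raise.
    """
    required = {"patient_id", "feature", "time_offset_hours", "value"}
    if not required.issubset(obs.columns):
        raise ValueError(f"long table must have columns {sorted(required)}")
    t = obs["time_offset_hours"].to_numpy(dtype=float)
    if (t < 0).any() or (t >= 24).any():
        raise ValueError("time_offset_hours outside the [0, 24) window")
    if known_features is not None:
        unknown = set(obs["feature"]) - set(known_features)
        if unknown:
            raise ValueError(f"unknown feature name(s): {sorted(unknown)}")
    wide = obs.pivot_table(index="patient_id", columns="feature",
                           values="value", aggfunc="mean")
    if known_features is not None:
        wide = wide.reindex(columns=known_features)
    wide.columns.name = None
    return wide


# -------------------------------------------------------------------- scaling

@dataclass
class Scaler:
    """Per-feature z-scaler (center = mean, spread = sample SD, ddof=1)."""

    feature_names: list[str]
    center: np.ndarray
    spread: np.ndarray
    floored: list[str] = field(default_factory=list)

    def transform(self, m: pd.DataFrame) -> pd.DataFrame:
        m = m[self.feature_names]
        return (m - self.center) / self.spread

    def inverse_transform(self, z: pd.DataFrame) -> pd.DataFrame:
        z = z[self.feature_names]
        return z * self.spread + self.center

    def to_json(self) -> str:
        doc = {name: {"center": float(c), "spread": float(s)}
               for name, c, s in zip(self.feature_names, self.center, self.spread)}
        return json.dumps({"features": doc, "floored": self.floored}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Scaler":
        doc = json.loads(text)
        names = list(doc["features"])
        center = np.array([doc["features"][n]["center"] for n in names])
        spread = np.array([doc["features"][n]["spread"] for n in names])
        return cls(names, center, spread, list(doc.get("floored", [])))


def fit_scaler(m: pd.DataFrame) -> Scaler:
    """Fit a z-scaler on a complete matrix; zero-variance spreads are floored."""
    if m.isna().any().any():
        raise ValueError("fit_scaler requires a complete matrix")
    center = m.mean(axis=0).to_numpy()
    spread = m.std(axis=0, ddof=1).to_numpy()
    floored = [name for name, s in zip(m.columns, spread) if s < SPREAD_FLOOR]
    if floored:
        warnings.warn(f"zero-variance column(s) floored: {floored}")
        spread = np.maximum(spread, SPREAD_FLOOR)
    return Scaler(list(m.columns), center, spread, floored)


def apply_scaler(m: pd.DataFrame, scaler: Scaler) -> pd.DataFrame:
    return scaler.transform(m)


# ----------------------------------------------------------------- imputation

@dataclass
class _ColumnModel:
    predictors: list[str]
    coef: np.ndarray          # intercept first
    donor_pred: np.ndarray    # sorted predicted values of training donors
    donor_obs: np.ndarray     # observed values, aligned with donor_pred


class ChainedImputer:
    """MICE with predictive mean matching.

    Parameters mirror the conventional defaults: 10 cycles, 5 donors,
    a single imputation (multiple imputations are averaged cell-wise into
    one completed table, which is what a downstream single-model fit needs).
    """

    def __init__(self, n_cycles: int = 10, n_imputations: int = 1,
                 n_donors: int = 5, seed: int = 0):
        if n_cycles < 1 or n_imputations < 1 or n_donors < 1:
            raise ValueError("n_cycles, n_imputations, n_donors must be >= 1")
        self.n_cycles = n_cycles
        self.n_imputations = n_imputations
        self.n_donors = n_donors
        self.seed = seed
        self.column_means_: dict[str, float] | None = None
        self.models_: dict[str, _ColumnModel] = {}
        self.dropped_: list[str] = []

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _ols(Xo: np.ndarray, yo: np.ndarray) -> np.ndarray:
        A = np.column_stack([np.ones(len(Xo)), Xo])
        coef, *_ = np.linalg.lstsq(A, yo, rcond=None)
        return coef

    @staticmethod
    def _predict(coef: np.ndarray, X: np.ndarray) -> np.ndarray:
        return coef[0] + X @ coef[1:]

    def _pmm_draw(self, pred_mis: np.ndarray, donor_pred: np.ndarray,
                  donor_obs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """For each target, draw one of the n_donors nearest-prediction donors."""
        k = min(self.n_donors, len(donor_pred))
        order = np.argsort(donor_pred, kind="stable")
        dp, do = donor_pred[order], donor_obs[order]
        pos = np.searchsorted(dp, pred_mis)
        out = np.empty(len(pred_mis))
        for i, (p, target) in enumerate(zip(pos, pred_mis)):
            lo = max(0, p - k)
            hi = min(len(dp), p + k)
            cand = np.arange(lo, hi)
            nearest = cand[np.argsort(np.abs(dp[cand] - target), kind="stable")[:k]]
            out[i] = do[nearest[rng.integers(len(nearest))]]
        return out

    # -- fitting -----------------------------------------------------------

    def fit_transform(self, m: pd.DataFrame) -> pd.DataFrame:
        """Impute ``m`` and retain the final-cycle column models + donor pools."""
        m = m.copy()
        all_missing = [c for c in m.columns if m[c].isna().all()]
        if all_missing:
            warnings.warn(f"all-missing column(s) dropped: {all_missing}")
            self.dropped_ = all_missing
            m = m.drop(columns=all_missing)
        obs_mask = m.notna()
        if not obs_mask.all(axis=0).any():
            raise ValueError("at least one fully observed column is required")

        self.column_means_ = m.mean(axis=0).to_dict()
        incomplete = [c for c in m.columns if m[c].isna().any()]
        completed = []
        master = np.random.default_rng(self.seed)
        for _ in range(self.n_imputations):
            rng = np.random.default_rng(master.integers(2**31))
            completed.append(self._one_imputation(m, obs_mask, incomplete, rng,
                                                  store_models=not completed))
        out = completed[0] if len(completed) == 1 else (
            sum(completed) / len(completed))
        # observed cells are preserved bit-exactly
        out = out.where(~obs_mask, m)
        return out

    def _one_imputation(self, m, obs_mask, incomplete, rng,
                        store_models: bool) -> pd.DataFrame:
        filled = m.fillna(self.column_means_)
        others = {c: [o for o in m.columns if o != c] for c in incomplete}
        for cycle in range(self.n_cycles):
            last = cycle == self.n_cycles - 1
            for col in incomplete:
                obs_rows = obs_mask[col].to_numpy()
                mis_rows = ~obs_rows
                X = filled[others[col]].to_numpy(dtype=float)
                y = filled[col].to_numpy(dtype=float)
                coef = self._ols(X[obs_rows], y[obs_rows])
                donor_pred = self._predict(coef, X[obs_rows])
                pred_mis = self._predict(coef, X[mis_rows])
                drawn = self._pmm_draw(pred_mis, donor_pred, y[obs_rows], rng)
                y[mis_rows] = drawn
                filled[col] = y
                if last and store_models:
                    order = np.argsort(donor_pred, kind="stable")
                    self.models_[col] = _ColumnModel(
                        others[col], coef, donor_pred[order], y[obs_rows][order])
        return filled

    # -- application to held-out data ---------------------------------------

    def transform(self, m: pd.DataFrame) -> pd.DataFrame:
        """Impute a new cohort with training-fitted models and donor pools."""
        if self.column_means_ is None:
            raise RuntimeError("imputer is not fitted")
        m = m.drop(columns=[c for c in self.dropped_ if c in m], errors="ignore")
        obs_mask = m.notna()
        filled = m.fillna(self.column_means_)
        rng = np.random.default_rng(self.seed + 1)
        incomplete = [c for c in m.columns if m[c].isna().any()]
        for _ in range(self.n_cycles):
            for col in incomplete:
                model = self.models_.get(col)
                if model is None:       # complete in training: mean fill stands
                    continue
                mis_rows = (~obs_mask[col]).to_numpy()
                X = filled[model.predictors].to_numpy(dtype=float)
                pred_mis = self._predict(model.coef, X[mis_rows])
                y = filled[col].to_numpy(dtype=float)
                y[mis_rows] = self._pmm_draw(pred_mis, model.donor_pred,
                                             model.donor_obs, rng)
                filled[col] = y
        return filled.where(~obs_mask, m)


def impute_mice(m: pd.DataFrame, n_cycles: int = 10, n_imputations: int = 1,
                seed: int = 0) -> pd.DataFrame:
    """Chained-equation imputation returning one completed table."""
    return ChainedImputer(n_cycles=n_cycles, n_imputations=n_imputations,
                          seed=seed).fit_transform(m)


# ------------------------------------------------------------------ screening

@dataclass
class ScreenReport:
    dropped: list[str]
    pairs: list[tuple[str, str, float]]   # (dropped, kept, rho)


def screen_correlated(m: pd.DataFrame, threshold: float = 0.75,
                      missing_counts: dict[str, int] | None = None,
                      ) -> tuple[pd.DataFrame, ScreenReport]:
    """Drop one member of each highly rank-correlated pair.

    Pairs with \\|Spearman rho\\| >= ``threshold`` are resolved greedily from
    the strongest correlation down; the member with more original missingness
    is dropped (tie: the later column). Deterministic for a given input.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    if m.isna().any().any():
        raise ValueError("screen_correlated requires a complete matrix")
    missing_counts = missing_counts or {}
    cols = list(m.columns)
    rho = m.corr(method="spearman").to_numpy()
    np.fill_diagonal(rho, 0.0)

    alive = dict.fromkeys(cols, True)
    pairs: list[tuple[str, str, float]] = []
    order = {c: i for i, c in enumerate(cols)}
    while True:
        best, best_abs = None, threshold - 1e-15
        for i, a in enumerate(cols):
            if not alive[a]:
                continue
            for j in range(i + 1, len(cols)):
                b = cols[j]
                if alive[b] and abs(rho[i, j]) > best_abs:
                    best_abs, best = abs(rho[i, j]), (a, b, rho[i, j])
        if best is None:
            break
        a, b, r = best
        ma, mb = missing_counts.get(a, 0), missing_counts.get(b, 0)
        drop = a if ma > mb else b if mb > ma else max(a, b, key=order.get)
        keep = b if drop == a else a
        alive[drop] = False
        pairs.append((drop, keep, float(r)))
    kept = [c for c in cols if alive[c]]
    return m[kept], ScreenReport([p[0] for p in pairs], pairs)
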