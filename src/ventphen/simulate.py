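"""Synthetic cohort generator.

Draws patients from a latent K-class diagonal-Gaussian mixture over the
feature panel, injects MCAR missingness at each variable's marginal ratio,
and attaches a phenotype-linked 28-day mortality outcome. The defaults
reproduce the statistical structure of the source training cohort (five
phenotypes, published mixing weights, per-phenotype feature distributions
and mortality), so the whole pipeline can be exercised end to end without
any hospital data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import (
    DEFAULT_MIX_WEIGHTS,
    DEFAULT_MORTALITY,
    FeatureSpec,
    class_mean_matrix,
    class_sd_matrix,
    default_feature_panel,
    feature_names,
)

OUTCOME_COLUMNS = ["death28", "death_day", "true_class", "split"]
MIN_AGE = 18.0


@dataclass(frozen=True)
class CohortSpec:
    """Size, class mixture, mortality and follow-up of a synthetic cohort."""

    n_patients: int
    mix_weights: tuple[float, ...] = DEFAULT_MIX_WEIGHTS
    mortality_by_class: tuple[float, ...] = DEFAULT_MORTALITY
    max_follow_up_days: int = 28
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        w = np.asarray(self.mix_weights, dtype=float)
        if abs(float(w.sum()) - 1.0) > 1e-9 or (w < 0).any():
            raise ValueError("mix_weights must be a simplex vector")
        m = np.asarray(self.mortality_by_class, dtype=float)
        if len(m) != len(w):
            raise ValueError("mortality_by_class length must match mix_weights")
        if ((m < 0) | (m > 1)).any():
            raise ValueError("mortality fractions must lie in [0, 1]")

    @property
    def n_classes(self) -> int:
        return len(self.mix_weights)


def simulate_cohort(spec: CohortSpec,
                    panel: list[FeatureSpec] | None = None) -> pd.DataFrame:
    """Draw a cohort table from the latent-class generative model.

    Each patient draws a latent class from ``mix_weights``; features are
    independent Normal(per-class mean, per-class SD) within class; each
    feature cell is then blanked MCAR at its ``missing_ratio``. 28-day death
    is Bernoulli(mortality of the class), with the death day uniform on
    1..max_follow_up_days and survivors administratively censored. Ages are
    clipped at 18 (adult cohort) and SpO2 capped at 100%.

    Deterministic under ``spec.seed``. ``true_class`` is 1-based (1..K).
    """
    panel = default_feature_panel() if panel is None else panel
    K = spec.n_classes
    if any(f.n_classes != K for f in panel):
        raise ValueError("panel class count does not match spec.mix_weights")

    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    classes = rng.choice(K, size=n, p=np.asarray(spec.mix_weights, dtype=float))

    mu = class_mean_matrix(panel)        # (K, D)
    sd = class_sd_matrix(panel)          # (K, D)
    X = rng.normal(mu[classes], sd[classes])   # (n, D)

    cols = feature_names(panel)
    df = pd.DataFrame(X, columns=cols)
    if "age" in df:
        df["age"] = df["age"].clip(lower=MIN_AGE)
    if "spo2" in df:
        df["spo2"] = df["spo2"].clip(upper=100.0)

    # MCAR missingness, independent of class and value
    for j, f in enumerate(panel):
        if f.missing_ratio > 0:
            mask = rng.random(n) < f.missing_ratio
            df.iloc[mask, j] = np.nan

    mort = np.asarray(spec.mortality_by_class, dtype=float)[classes]
    dead = rng.random(n) < mort
    death_day = np.where(
        dead, rng.integers(1, spec.max_follow_up_days + 1, size=n), -1)

    df.insert(0, "patient_id", [f"P{i:06d}" for i in range(n)])
    df["death28"] = dead
    df["death_day"] = pd.array(
        [d if d > 0 else pd.NA for d in death_day], dtype="Int64")
    df["true_class"] = classes + 1
    df["split"] = "unassigned"
    return df


def split_cohort(cohort: pd.DataFrame, ratio: float = 0.8,
                 seed: int = 0) -> pd.DataFrame:
    """Tag each patient train/validation with an exact-count random split.

    The training cohort receives ``round(ratio * n)`` patients (half rounds
    toward train); membership is a seeded permutation, so the tagging is
    reproducible and partitions the cohort exactly.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    n = len(cohort)
    if n == 0:
        raise ValueError("cannot split an empty cohort")
    n_train = int(np.floor(ratio * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    tags = np.full(n, "validation", dtype=object)
    tags[order[:n_train]] = "train"
    out = cohort.copy()
    out["split"] = tags
    return out


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write the cohort table as UTF-8 CSV; missing cells are empty fields."""
    cohort.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV (empty field = missing) back into canonical dtypes."""
    df = pd.read_csv(path)
    if "death28" in df:
        df["death28"] = df["death28"].astype(bool)
    if "death_day" in df:
        df["death_day"] = df["death_day"].astype("Int64")
    if "true_class" in df:
        df["true_class"] = df["true_class"].astype("Int64")
    return df


def features_frame(cohort: pd.DataFrame,
                   panel: list[FeatureSpec] | None = None) -> pd.DataFrame:
    """Feature columns only, indexed by patient_id, in panel order."""
    cols = feature_names(panel)
    return cohort.set_index("patient_id")[cols]
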