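"""Phenotype-stratified clinical reporting.

Per-phenotype feature profiles (original and z scale, with descriptive
ANOVA p-values), SOFA-segment mortality tables with the >2% display filter,
relative-difference statistics, and 28-day Kaplan–Meier cumulative
mortality curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .mixture import PosteriorMatrix
from .preprocess import Scaler

SOFA_SEGMENT_EDGES = (0.0, 4.0, 6.0, 9.0, 22.0)
DISPLAY_THRESHOLD = 0.02
FOLLOW_UP_DAYS = 28


@dataclass
class PhenotypeProfile:
    summary: pd.DataFrame        # per phenotype: n, proportion
    feature_table: pd.DataFrame  # feature x phenotype mean/sd (+ scaled mean)
    anova_p: pd.Series           # per feature, descriptive


@dataclass
class SofaSegmentTable:
    table: pd.DataFrame          # phenotype, segment, n, deaths, rate, display
    segments: list[str]
    n_clamped: int = 0


def _segment_labels(edges=SOFA_SEGMENT_EDGES) -> list[str]:
    labels = [f"[{edges[0]:g},{edges[1]:g}]"]
    labels += [f"({a:g},{b:g}]" for a, b in zip(edges[1:-1], edges[2:])]
    return labels


def profile_report(cohort: pd.DataFrame, post: PosteriorMatrix,
                   feature_names: list[str],
                   scaler: Scaler | None = None) -> PhenotypeProfile:
    """Per-phenotype n/proportion and per-feature mean ± sd profiles.

    Means/SDs are reported on the original scale; when a scaler is supplied
    the z-scale class means are added (profile-plot data). The per-feature
    p-value is a one-way ANOVA across phenotypes, reported descriptively
    without multiplicity correction. Empty phenotypes yield an n=0 row with
    absent statistics.
    """
    df = cohort.set_index("patient_id") if "patient_id" in cohort else cohort
    df = df.loc[list(post.patient_ids)]
    assign = pd.Series(post.assignment, index=df.index, name="phenotype")
    labels = list(post.class_labels)

    counts = [(assign == lab).sum() for lab in labels]
    summary = pd.DataFrame({"phenotype": labels, "n": counts})
    summary["proportion"] = summary["n"] / len(df)

    rows = []
    pvals = {}
    for feat in feature_names:
        groups = [df.loc[assign == lab, feat].dropna() for lab in labels]
        row: dict = {"feature": feat}
        for lab, g in zip(labels, groups):
            row[f"mean_{lab}"] = g.mean() if len(g) else np.nan
            row[f"sd_{lab}"] = g.std(ddof=1) if len(g) > 1 else np.nan
            if scaler is not None:
                j = scaler.feature_names.index(feat)
                row[f"zmean_{lab}"] = ((g.mean() - scaler.center[j])
                                       / scaler.spread[j]) if len(g) else np.nan
        valid = [g for g in groups if len(g) > 1]
        if len(valid) >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pvals[feat] = float(stats.f_oneway(*valid).pvalue)
        else:
            pvals[feat] = np.nan
        rows.append(row)
    return PhenotypeProfile(summary, pd.DataFrame(rows),
                            pd.Series(pvals, name="anova_p"))


def relative_excess(value: float, references) -> np.ndarray:
    """Percent by which ``value`` exceeds each reference: 100·(value/ref − 1)."""
    refs = np.asarray(references, dtype=float)
    if (refs == 0).any():
        raise ValueError("zero reference")
    if ((refs > 0) != (value > 0)).any():
        raise ValueError("reference and value must share a sign")
    return 100.0 * (value / refs - 1.0)


def sofa_mortality_table(cohort: pd.DataFrame, post: PosteriorMatrix,
                         edges=SOFA_SEGMENT_EDGES,
                         display_threshold: float = DISPLAY_THRESHOLD,
                         sofa_col: str = "sofa") -> SofaSegmentTable:
    """Counts, deaths and mortality per (phenotype, SOFA segment).

    Segments follow the printed convention: the first bin is closed
    ``[e0, e1]`` and later bins half-open ``(a, b]``. Scores outside the
    overall range are clamped into the boundary bins and counted in
    ``n_clamped``. The display flag is False wherever the segment mortality
    is at or below ``display_threshold`` (the >2% display filter that drops
    uniformly low-mortality phenotypes from the chord plot).
    """
    df = cohort.set_index("patient_id") if "patient_id" in cohort else cohort
    df = df.loc[list(post.patient_ids)]
    sofa = df[sofa_col].to_numpy(dtype=float)
    if np.isnan(sofa).any():
        raise ValueError("SOFA must be complete (impute first)")
    lo, hi = edges[0], edges[-1]
    n_clamped = int(((sofa < lo) | (sofa > hi)).sum())
    if n_clamped:
        warnings.warn(f"{n_clamped} SOFA value(s) outside "
                      f"[{lo:g}, {hi:g}] clamped into boundary segments")
        sofa = np.clip(sofa, lo, hi)
    labels = _segment_labels(edges)
    seg = pd.cut(sofa, bins=list(edges), right=True, include_lowest=True,
                 labels=labels)
    dead = df["death28"].to_numpy(dtype=bool)
    assign = post.assignment
    rows = []
    for lab in post.class_labels:
        for s in labels:
            in_cell = (assign == lab) & (np.asarray(seg) == s)
            n_cell = int(in_cell.sum())
            d_cell = int(dead[in_cell].sum())
            rate = d_cell / n_cell if n_cell else 0.0
            rows.append(dict(phenotype=lab, segment=s, n=n_cell,
                             deaths=d_cell, rate=rate,
                             display=rate > display_threshold))
    return SofaSegmentTable(pd.DataFrame(rows), labels, n_clamped)


@dataclass
class SurvivalCurves:
    curves: dict[int, pd.DataFrame]        # phenotype -> day grid table
    day28_mortality: pd.Series             # phenotype -> 1 - S(28)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for lab, cur in self.curves.items():
            c = cur.copy()
            c.insert(0, "phenotype", lab)
            frames.append(c)
        return pd.concat(frames, ignore_index=True)


def survival_curves(cohort: pd.DataFrame, post: PosteriorMatrix,
                    follow_up: int = FOLLOW_UP_DAYS) -> SurvivalCurves:
    """Kaplan–Meier cumulative 28-day mortality per phenotype.

    Deaths occur on ``death_day`` (1..follow_up); survivors are
    administratively censored at ``follow_up``. With no earlier censoring
    the day-28 cumulative mortality equals the crude deaths/n.
    """
    df = cohort.set_index("patient_id") if "patient_id" in cohort else cohort
    df = df.loc[list(post.patient_ids)]
    dead = df["death28"].to_numpy(dtype=bool)
    day = pd.to_numeric(df["death_day"], errors="coerce").to_numpy(dtype=float)
    if np.isnan(day[dead]).any():
        raise ValueError("death_day missing for a 28-day death")
    dur = np.where(dead, day, float(follow_up))
    if dead.any() and (np.nanmin(day[dead]) <= 0
                       or np.nanmax(day[dead]) > follow_up):
        raise ValueError(f"death_day must lie in 1..{follow_up}")
    grid = np.arange(0, follow_up + 1, dtype=float)
    assign = post.assignment
    curves: dict[int, pd.DataFrame] = {}
    final = {}
    for lab in post.class_labels:
        sel = assign == lab
        if sel.sum() == 0:
            curves[lab] = pd.DataFrame({"day": grid,
                                        "cum_mortality": np.nan,
                                        "at_risk": 0})
            final[lab] = np.nan
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(dur[sel], event_observed=dead[sel], timeline=grid)
        surv = kmf.survival_function_.iloc[:, 0].to_numpy()
        at_risk = np.array([(dur[sel] >= t).sum() for t in grid], dtype=int)
        curves[lab] = pd.DataFrame({"day": grid, "cum_mortality": 1.0 - surv,
                                    "at_risk": at_risk})
        final[lab] = float(1.0 - surv[-1])
    return SurvivalCurves(curves, pd.Series(final, name="day28_mortality"))
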