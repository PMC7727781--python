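"""Default 22-variable feature panel for mechanical-ventilation phenotyping.

The panel covers demographics (age, temperature), severity scores (APACHE II,
SOFA), ventilator/respiratory variables (RR, FiO2, SpO2, Pmean, Ppeak, PEEP,
VT, pO2, pCO2), circulation and perfusion (HR, MAP, CVP, Pv-aCO2, lactate,
Pv-aCO2/Ca-vO2 ratio, perfusion index, hemoglobin) and 24-h fluid balance.
Each :class:`FeatureSpec` carries the published per-phenotype mean/SD for the
five phenotypes (I–V) of the source training cohort, plus the marginal
missingness ratio observed in that cohort — these parameterize the synthetic
generator so every downstream stage is testable without hospital data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_CLASSES = 5

#: Training-cohort phenotype mixing proportions (phenotypes I..V). The
#: printed percentages sum to 99.99%; they are renormalized to an exact
#: simplex here (relative change < 2e-4 per class).
_RAW_WEIGHTS = np.array([0.542, 0.120, 0.0601, 0.0918, 0.186])
DEFAULT_MIX_WEIGHTS = tuple(float(w) for w in _RAW_WEIGHTS / _RAW_WEIGHTS.sum())

#: Observed 28-day mortality fraction per phenotype (I..V).
DEFAULT_MORTALITY = (0.0123, 0.181, 0.0140, 0.274, 0.0159)


@dataclass(frozen=True)
class FeatureSpec:
    """One clinical variable: units, per-phenotype Normal parameters, missingness."""

    name: str
    unit: str
    per_class_mean: tuple[float, ...]
    per_class_sd: tuple[float, ...]
    missing_ratio: float = 0.0

    def __post_init__(self) -> None:
        if len(self.per_class_mean) != len(self.per_class_sd):
            raise ValueError(f"{self.name}: mean/sd length mismatch")
        if any(s <= 0 for s in self.per_class_sd):
            raise ValueError(f"{self.name}: per_class_sd must be positive")
        if not 0.0 <= self.missing_ratio <= 1.0:
            raise ValueError(f"{self.name}: missing_ratio outside [0, 1]")

    @property
    def n_classes(self) -> int:
        return len(self.per_class_mean)


# name, unit, per-class means (I..V), per-class SDs (I..V), missing ratio
_PANEL_ROWS: list[tuple] = [
    ("age", "years",
     (66.10, 58.36, 62.63, 55.85, 38.15), (11.87, 16.13, 14.54, 17.36, 11.84), 0.0),
    ("temp_c", "degC",
     (36.83, 37.19, 37.13, 37.07, 37.17), (0.51, 0.63, 0.57, 0.81, 0.51), 0.0),
    ("apache2", "score",
     (13.96, 23.40, 16.64, 21.31, 11.51), (4.97, 7.49, 6.32, 10.29, 5.05), 0.1245),
    ("sofa", "score",
     (5.90, 11.45, 6.78, 9.80, 5.01), (2.71, 2.75, 3.19, 5.04, 2.71), 0.1003),
    ("rr", "insp/min",
     (15.32, 17.60, 16.22, 18.92, 15.62), (1.98, 2.64, 2.22, 5.02, 2.21), 0.0),
    ("fio2", "%",
     (37.25, 43.47, 40.74, 49.00, 36.88), (5.48, 7.44, 4.81, 19.29, 5.17), 0.0),
    ("spo2", "%",
     (99.03, 98.19, 99.01, 96.45, 99.35), (1.12, 1.45, 1.27, 4.66, 0.88), 0.0),
    ("pmean", "cmH2O",
     (8.21, 10.60, 9.32, 11.86, 8.11), (1.13, 1.90, 1.50, 4.18, 1.14), 0.0),
    ("ppeak", "cmH2O",
     (17.10, 20.38, 19.25, 21.86, 16.72), (3.15, 3.45, 3.04, 6.47, 3.16), 0.0),
    ("peep", "cmH2O",
     (5.75, 8.32, 7.52, 10.63, 5.94), (1.58, 2.81, 3.13, 6.20, 1.89), 0.0),
    ("vt", "mL/breath",
     (420.78, 426.28, 427.26, 439.69, 424.44), (63.22, 66.26, 64.11, 129.85, 68.16), 0.0),
    ("po2", "mmHg",
     (133.22, 115.18, 137.10, 129.79, 159.41), (31.97, 31.35, 32.97, 61.95, 36.47), 0.0),
    ("pco2", "mmHg",
     (38.26, 40.67, 38.56, 42.48, 37.49), (4.26, 4.61, 4.27, 9.31, 4.36), 0.0),
    ("hr", "beats/min",
     (81.52, 100.85, 88.45, 97.79, 98.29), (12.22, 14.83, 14.57, 20.56, 12.58), 0.0),
    ("map", "mmHg",
     (88.86, 90.82, 89.10, 89.51, 92.29), (10.25, 9.54, 9.54, 17.33, 11.05), 0.0),
    ("cvp", "mmHg",
     (7.56, 10.13, 8.43, 9.60, 7.47), (1.29, 2.14, 1.96, 2.97, 1.49), 0.4318),
    ("pva_co2", "mmHg",
     (5.55, 5.33, 5.96, 5.41, 5.82), (1.60, 2.27, 2.52, 2.57, 1.59), 0.4502),
    ("lactate", "mmol/L",
     (1.91, 2.37, 2.11, 3.82, 1.91), (1.05, 1.67, 1.35, 4.83, 1.17), 0.0),
    ("pva_cav_ratio", "ratio",
     (1.39, 1.63, 1.87, 0.82, 1.84), (2.68, 1.93, 5.52, 15.05, 4.22), 0.4709),
    ("pi", "index",
     (2.86, 1.52, 2.22, 2.49, 2.32), (1.34, 1.05, 1.20, 2.36, 1.17), 0.0),
    ("hb", "g/dL",
     (111.57, 100.22, 107.79, 108.39, 105.03), (18.25, 19.43, 17.35, 23.52, 18.77), 0.0),
    ("balance", "mL",
     (-123.08, -1613.92, -225.94, -691.79, -300.57),
     (1186.21, 2873.50, 2316.81, 3158.67, 1288.97), 0.0),
]


def default_feature_panel() -> list[FeatureSpec]:
    """Return the 22-variable panel with published per-phenotype parameters.

    Order matches the cohort summary table of the source analysis; means/SDs
    are the training-cohort per-phenotype values and ``missing_ratio`` the
    whole-cohort marginal missingness of each variable.
    """
    return [FeatureSpec(name, unit, means, sds, miss)
            for name, unit, means, sds, miss in _PANEL_ROWS]


def feature_names(panel: list[FeatureSpec] | None = None) -> list[str]:
    panel = default_feature_panel() if panel is None else panel
    return [spec.name for spec in panel]


def class_mean_matrix(panel: list[FeatureSpec]) -> np.ndarray:
    """(K, D) matrix of per-class means in panel column order."""
    return np.array([spec.per_class_mean for spec in panel]).T


def class_sd_matrix(panel: list[FeatureSpec]) -> np.ndarray:
    """(K, D) matrix of per-class SDs in panel column order."""
    return np.array([spec.per_class_sd for spec in panel]).T
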