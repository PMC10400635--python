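"""Discovery of putative xenobiotic-related features.

Three intensity-based filters isolate features that behave like a xenobiotic
or one of its biotransformation products rather than an endogenous
metabolite:

1. presence in at least ``exposed_presence_min`` (default 80%) of exposed
   biological samples — xenobiotic-related features should be present in
   every exposed sample, with leniency for dropout at low concentration;
2. presence in at most ``control_presence_max`` (default 50%) of biological
   control samples — allows for carry-over and co-eluting peaks;
3. median intensity in exposed samples at least ``fold_min`` (default 10x)
   the median in controls — in principle the fold change is infinite for a
   truly foreign compound, and a feature entirely absent from controls is
   scored as fold = +inf and passes.

QC and blank columns are ignored by all three filters.  Medians ignore
missing values and nothing is imputed here; imputation applies only to the
suspect exposure-labelling rule where it is part of the rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peakmatrix import PeakMatrix


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the three discovery filters."""

    exposed_presence_min: float = 0.80
    control_presence_max: float = 0.50
    fold_min: float = 10.0

    def __post_init__(self):
        for name in ("exposed_presence_min", "control_presence_max"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not self.fold_min > 1:
            raise ValueError(f"fold_min must be > 1, got {self.fold_min}")


def presence_fraction(values) -> float:
    """Fraction of non-missing entries in a vector."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("presence_fraction of an empty vector")
    return float(np.sum(~np.isnan(values)) / values.size)


def _nanmedian(v: np.ndarray) -> float:
    v = v[~np.isnan(v)]
    return float(np.median(v)) if v.size else np.nan


def xenobiotic_filter(
    matrix: PeakMatrix, config: FilterConfig = FilterConfig()
) -> tuple[set[str], pd.DataFrame]:
    """Apply the three discovery filters.

    Returns the set of feature ids passing all three filters and a
    per-feature report frame with columns ``presence_exposed``,
    ``presence_control``, ``fold_change`` (may be +inf), the three pass
    flags and ``passed``.
    """
    exp_cols = matrix.class_columns("exposed")
    ctl_cols = matrix.class_columns("control")
    if exp_cols.size == 0:
        raise ValueError("matrix has no exposed samples")
    if ctl_cols.size == 0:
        raise ValueError("matrix has no control samples")

    rows = []
    for i, feat in enumerate(matrix.features):
        exp = matrix.intensity[i, exp_cols]
        ctl = matrix.intensity[i, ctl_cols]
        pres_e = presence_fraction(exp)
        pres_c = presence_fraction(ctl)
        med_e = _nanmedian(exp)
        med_c = _nanmedian(ctl)
        if np.isnan(med_e):
            fold = 0.0
        elif np.isnan(med_c):
            fold = np.inf  # absent from controls: in principle infinite
        else:
            fold = med_e / med_c
        p1 = pres_e >= config.exposed_presence_min
        p2 = pres_c <= config.control_presence_max
        p3 = fold >= config.fold_min
        rows.append({
            "feature_id": feat.feature_id,
            "mz": feat.mz,
            "rt": feat.rt,
            "presence_exposed": pres_e,
            "presence_control": pres_c,
            "fold_change": fold,
            "passed_presence_exposed": p1,
            "passed_presence_control": p2,
            "passed_fold": p3,
            "passed": p1 and p2 and p3,
        })
    report = pd.DataFrame(rows)
    ids = set(report.loc[report["passed"], "feature_id"])
    return ids, report


def label_exposure_by_suspect(
    matrix: PeakMatrix, suspect_feature_id: str, fold: float = 10.0
) -> dict[str, str]:
    """Label each biological/QC sample exposed or control from one suspect feature.

    Missing values of the suspect feature are imputed with the lowest
    non-missing intensity across *all* features of the matrix; a sample is
    exposed iff its imputed intensity exceeds ``fold`` times the median over
    biological samples and QCs.
    """
    i = matrix.feature_index(suspect_feature_id)
    cols = matrix.class_columns("exposed", "control", "QC")
    if cols.size == 0:
        raise ValueError("matrix has no biological or QC samples")
    global_min = np.nanmin(matrix.intensity)
    if np.isnan(global_min):
        raise ValueError("matrix is entirely missing")
    v = matrix.intensity[i, cols].copy()
    v[np.isnan(v)] = global_min
    med = float(np.median(v))
    labels = {}
    for j, x in zip(cols, v):
        labels[matrix.samples[j].sample_id] = "exposed" if x > fold * med else "control"
    return labels


def pick_representative_feature(matrix: PeakMatrix, candidate_ids) -> str:
    """Choose the representative ion among several features matching one suspect.

    Default rule: highest median intensity over biological + QC samples
    (ties broken by feature id for determinism).
    """
    candidate_ids = sorted(candidate_ids)
    if not candidate_ids:
        raise ValueError("no candidate features")
    cols = matrix.class_columns("exposed", "control", "QC")
    best, best_med = None, -np.inf
    for fid in candidate_ids:
        med = _nanmedian(matrix.intensity[matrix.feature_index(fid), cols])
        med = -np.inf if np.isnan(med) else med
        if med > best_med:
            best, best_med = fid, med
    return best


def assign_confidence(
    mz_match: bool,
    rt_standard_match: bool = False,
    ms2_standard_match: bool = False,
    ms2_insilico_or_db_match: bool = False,
    formula_only: bool = False,
) -> int:
    """Schymanski-style identification confidence level.

    Level 1: m/z + retention time + MS2 all match an authentic standard.
    Level 2: m/z plus an in-silico or database MS2 match (no standard).
    Level 3: m/z match against a suspect or predicted structure only.
    Level 4: unequivocal molecular formula, no structural candidate.
    """
    if not mz_match:
        raise ValueError("no annotation without an m/z match")
    if rt_standard_match and ms2_standard_match:
        return 1
    if ms2_insilico_or_db_match:
        return 2
    if formula_only:
        return 4
    return 3
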