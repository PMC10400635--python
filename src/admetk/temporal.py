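"""Temporal analysis of parent and biotransformation-product intensities.

Median intensity profiles across biological replicates per timepoint are
centred and scaled to unit variance, clustered with k-means (Lloyd, multiple
restarts), with k chosen by an automated elbow criterion on the
within-cluster sum of squares curve — the largest second difference of
WSS(k), overridable by the user.  Per-compound (or per-cluster) timepoint
differences are tested with one-way ANOVA followed by Tukey's HSD post-hoc
test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .peakmatrix import PeakMatrix


@dataclass
class TimeProfile:
    """Median time profile of one compound, centred and unit-variance scaled."""

    compound_id: str
    timepoints: list[str]
    medians: np.ndarray
    scaled: np.ndarray | None  # None when the raw profile is constant/incomplete
    flagged: bool


def profile_compounds(
    matrix: PeakMatrix, compound_ids, timepoints: list[str] | None = None
) -> list[TimeProfile]:
    """Median-per-timepoint profiles over exposed biological replicates.

    Medians ignore missing values.  A compound missing at every replicate of
    some timepoint, or with a constant profile, is flagged and excluded from
    clustering (its scaled profile is None).
    """
    if timepoints is None:
        seen = []
        for s in matrix.samples:
            if s.cls == "exposed" and s.timepoint is not None and s.timepoint not in seen:
                seen.append(s.timepoint)
        timepoints = seen
    if not timepoints:
        raise ValueError("no timepoints available")
    cols_per_tp = {
        tp: [j for j, s in enumerate(matrix.samples)
             if s.cls == "exposed" and s.timepoint == tp]
        for tp in timepoints
    }
    empty = [tp for tp, cols in cols_per_tp.items() if not cols]
    if empty:
        raise ValueError(f"timepoints without exposed replicates: {empty}")

    profiles = []
    for cid in compound_ids:
        i = matrix.feature_index(cid)
        meds = []
        for tp in timepoints:
            v = matrix.intensity[i, cols_per_tp[tp]]
            v = v[~np.isnan(v)]
            meds.append(np.median(v) if v.size else np.nan)
        meds = np.array(meds)
        flagged = bool(np.isnan(meds).any() or np.ptp(meds[~np.isnan(meds)]) == 0)
        if flagged:
            scaled = None
        else:
            scaled = (meds - meds.mean()) / meds.std(ddof=0)
        profiles.append(TimeProfile(cid, list(timepoints), meds, scaled, flagged))
    return profiles


@dataclass
class ClusterResult:
    assignments: dict[str, int]  # compound id -> cluster label (1-based)
    chosen_k: int
    wss_curve: pd.DataFrame  # columns k, wss
    centroids: np.ndarray
    flagged: list[str]  # compounds excluded from clustering


def elbow_kmeans(
    profiles: list[TimeProfile],
    k_max: int = 8,
    restarts: int = 20,
    seed: int = 0,
    k: int | None = None,
) -> ClusterResult:
    """k-means over scaled profiles with an automated elbow choice of k.

    WSS(k) is computed for k = 1..k_max (best of ``restarts`` random
    initialisations each); the chosen k maximises the second difference
    WSS(k-1) - 2 WSS(k) + WSS(k+1), i.e. the sharpest bend of the curve.
    Pass ``k`` to override the automatic choice.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    usable = [p for p in profiles if p.scaled is not None]
    flagged = [p.compound_id for p in profiles if p.scaled is None]
    if len(usable) < k_max + 1:
        raise ValueError(f"need more than k_max={k_max} clusterable profiles, "
                         f"got {len(usable)}")
    x = np.vstack([p.scaled for p in usable])

    wss = {}
    fits = {}
    for kk in range(1, k_max + 1):
        km = KMeans(n_clusters=kk, n_init=restarts, random_state=seed,
                    algorithm="lloyd")
        km.fit(x)
        wss[kk] = float(km.inertia_)
        fits[kk] = km
    curve = pd.DataFrame({"k": list(wss), "wss": list(wss.values())})

    if k is None:
        # elbow: largest second difference, defined for k = 2..k_max-1
        best_k, best_d2 = 2, -np.inf
        for kk in range(2, k_max):
            d2 = wss[kk - 1] - 2 * wss[kk] + wss[kk + 1]
            if d2 > best_d2:
                best_k, best_d2 = kk, d2
        k = best_k
    elif not 1 <= k <= k_max:
        raise ValueError(f"k override {k} outside 1..{k_max}")

    km = fits[k]
    assignments = {p.compound_id: int(lbl) + 1
                   for p, lbl in zip(usable, km.labels_)}
    return ClusterResult(assignments, k, curve, km.cluster_centers_, flagged)


def timepoint_anova(values_per_timepoint: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA across timepoints plus Tukey HSD pairwise comparisons.

    Groups with fewer than two observations are excluded with a warning.
    Returns {"anova_F", "anova_p", "tukey": DataFrame(group1, group2, p)}.
    """
    groups = {}
    for tp, v in values_per_timepoint.items():
        v = np.asarray(v, dtype=float)
        v = v[~np.isnan(v)]
        if v.size < 2:
            warnings.warn(f"timepoint {tp!r} has <2 observations; excluded")
            continue
        groups[tp] = v
    if len(groups) < 2:
        raise ValueError("need at least two timepoints with >=2 observations")
    names = list(groups)
    arrays = [groups[n] for n in names]
    f, p = stats.f_oneway(*arrays)
    tk = stats.tukey_hsd(*arrays)
    rows = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            rows.append({"group1": names[a], "group2": names[b],
                         "p_value": float(tk.pvalue[a, b])})
    return {"anova_F": float(f), "anova_p": float(p),
            "tukey": pd.DataFrame(rows)}
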