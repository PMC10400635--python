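"""Endogenous preprocessing and statistics after xenobiotic-feature removal.

Once putative xenobiotic-related features are removed, the remaining
endogenous matrix is cleaned and analysed with a standard quality-control
driven pipeline:

    prefilter -> PQN -> t-tests               (univariate branch)
    prefilter -> PQN -> kNN impute -> glog -> PCA   (multivariate branch)

Prefilter rules, in order: blank filter (drop features whose biological
median is < 20x the blank median), QC relative-standard-deviation filter
(>= 30% RSD across QCs dropped), sample-missingness filter (> 50% missing),
feature-missingness filters (missing in >= 10% of QCs and/or >= 50% of all
samples), and finally removal of the supplied xenobiotic feature ids.
A removal ledger records what each rule removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .peakmatrix import PeakMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    blank_fold_min: float = 20.0
    qc_rsd_max: float = 0.30
    sample_missing_max: float = 0.50
    qc_missing_max: float = 0.10
    feature_missing_max: float = 0.50
    knn_k: int = 5

    def __post_init__(self):
        if self.blank_fold_min <= 0 or self.knn_k <= 0:
            raise ValueError("blank_fold_min and knn_k must be positive")
        for name in ("qc_rsd_max", "sample_missing_max", "qc_missing_max",
                     "feature_missing_max"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


def _nanmedian_rows(x: np.ndarray) -> np.ndarray:
    with np.errstate(all="ignore"):
        out = np.nanmedian(x, axis=1) if x.shape[1] else np.full(x.shape[0], np.nan)
    return out


def prefilter(
    matrix: PeakMatrix, xeno_ids=(), config: PreprocessConfig = PreprocessConfig()
) -> tuple[PeakMatrix, pd.DataFrame]:
    """Quality filters plus xenobiotic-feature removal, with a removal ledger.

    Returns the filtered matrix and a ledger frame (rule, n_removed, ids).
    Raises if the matrix has no QC samples; the blank filter is skipped
    (logged) when no blank class exists.
    """
    qc_cols = matrix.class_columns("QC")
    if qc_cols.size == 0:
        raise ValueError("prefilter requires QC samples")
    bio_cols = matrix.class_columns("exposed", "control")
    blank_cols = matrix.class_columns("blank")

    ledger_rows = []
    work = matrix.copy()

    def drop_features(rule: str, bad_ids: list[str]):
        nonlocal work
        ledger_rows.append({"rule": rule, "n_removed": len(bad_ids),
                            "ids": ";".join(bad_ids)})
        if bad_ids:
            keep = [i for i, f in enumerate(work.features)
                    if f.feature_id not in set(bad_ids)]
            work = PeakMatrix([work.features[i] for i in keep], list(work.samples),
                              work.intensity[keep, :])

    def cols_of(classes):
        return work.class_columns(*classes)

    # 1. blank filter: biological median < blank_fold_min x blank median
    if blank_cols.size == 0:
        log.info("no blank samples: blank filter skipped")
        ledger_rows.append({"rule": "blank", "n_removed": 0, "ids": "(skipped: no blanks)"})
    else:
        med_bio = _nanmedian_rows(work.intensity[:, cols_of(("exposed", "control"))])
        med_blank = _nanmedian_rows(work.intensity[:, cols_of(("blank",))])
        bad = []
        for i, f in enumerate(work.features):
            if not np.isnan(med_blank[i]):
                bio = 0.0 if np.isnan(med_bio[i]) else med_bio[i]
                if bio < config.blank_fold_min * med_blank[i]:
                    bad.append(f.feature_id)
        drop_features("blank", bad)

    # blanks have served their purpose; drop the columns
    if blank_cols.size:
        keep = [j for j, s in enumerate(work.samples) if s.cls != "blank"]
        work = PeakMatrix(list(work.features), [work.samples[j] for j in keep],
                          work.intensity[:, keep])

    # 2. QC RSD filter
    qc = work.intensity[:, cols_of(("QC",))]
    with np.errstate(all="ignore"):
        mean = np.nanmean(qc, axis=1)
        sd = np.nanstd(qc, axis=1, ddof=1)
        rsd = sd / mean
    bad = [f.feature_id for i, f in enumerate(work.features)
           if np.isfinite(rsd[i]) and rsd[i] >= config.qc_rsd_max]
    drop_features("qc_rsd", bad)

    # 3. sample missingness (biological samples only judged on all features)
    frac_missing = np.isnan(work.intensity).mean(axis=0)
    bad_samples = [work.samples[j].sample_id for j in cols_of(("exposed", "control"))
                   if frac_missing[j] > config.sample_missing_max]
    ledger_rows.append({"rule": "sample_missing", "n_removed": len(bad_samples),
                        "ids": ";".join(bad_samples)})
    if bad_samples:
        keep = [j for j, s in enumerate(work.samples)
                if s.sample_id not in set(bad_samples)]
        work = PeakMatrix(list(work.features), [work.samples[j] for j in keep],
                          work.intensity[:, keep])

    # 4. feature missingness: >= qc_missing_max of QCs and/or >= feature_missing_max overall
    qc2 = cols_of(("QC",))
    miss_qc = np.isnan(work.intensity[:, qc2]).mean(axis=1)
    miss_all = np.isnan(work.intensity).mean(axis=1)
    bad = [f.feature_id for i, f in enumerate(work.features)
           if miss_qc[i] >= config.qc_missing_max
           or miss_all[i] >= config.feature_missing_max]
    drop_features("feature_missing", bad)

    # 5. xenobiotic-related features
    bad = [f.feature_id for f in work.features if f.feature_id in set(xeno_ids)]
    drop_features("xenobiotic", bad)

    return work, pd.DataFrame(ledger_rows, columns=["rule", "n_removed", "ids"])


def pqn_normalise(
    matrix: PeakMatrix,
    reference: np.ndarray | None = None,
    coefficient_source: list[str] | None = None,
) -> tuple[PeakMatrix, np.ndarray]:
    """Probabilistic quotient normalisation.

    Each sample is divided by the median, over ``coefficient_source``
    features (default: all), of its intensity quotients against the
    reference profile (default: median over QC samples, falling back to the
    median over all samples when no QCs exist).  Coefficients computed on an
    endogenous feature subset may thereby be applied to xenobiotic features
    of the same samples.  Returns the normalised matrix and the per-sample
    coefficients.
    """
    x = matrix.intensity
    if reference is None:
        qc_cols = matrix.class_columns("QC")
        cols = qc_cols if qc_cols.size else np.arange(matrix.n_samples)
        reference = _nanmedian_rows(x[:, cols])
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (matrix.n_features,):
        raise ValueError("reference length must equal the feature count")

    if coefficient_source is None:
        src = np.arange(matrix.n_features)
    else:
        src = np.array([matrix.feature_index(fid) for fid in coefficient_source])
    usable = src[~np.isnan(reference[src]) & (reference[src] > 0)]
    if usable.size == 0:
        raise ValueError("reference profile has no usable features")

    coefs = np.empty(matrix.n_samples)
    for j in range(matrix.n_samples):
        q = x[usable, j] / reference[usable]
        q = q[~np.isnan(q)]
        if q.size == 0:
            raise ValueError(
                f"sample {matrix.samples[j].sample_id!r} is all-missing on the "
                "coefficient-source features"
            )
        coefs[j] = np.median(q)
    out = matrix.copy()
    out.intensity = out.intensity / coefs[np.newaxis, :]
    return out, coefs


def knn_impute(matrix: PeakMatrix, k: int = 5) -> PeakMatrix:
    """Feature-wise k-nearest-neighbour imputation.

    A missing cell is replaced by the mean, over the k features nearest to
    its feature, of their (observed) values at that sample.  Distance is
    Euclidean between unit-variance-standardised feature rows on their
    shared-present columns, scaled by the number of shared columns; ties
    break on feature id order for determinism.
    """
    x = matrix.intensity.copy()
    nf = matrix.n_features
    if nf <= 1:
        raise ValueError("need at least two features to impute")
    obs_counts = (~np.isnan(x)).sum(axis=1)
    if (obs_counts == 0).any():
        bad = [matrix.features[i].feature_id for i in np.flatnonzero(obs_counts == 0)]
        raise ValueError(f"features with zero observed values: {bad}")
    if not np.isnan(x).any():
        return matrix.copy()

    with np.errstate(all="ignore"):
        mu = np.nanmean(x, axis=1, keepdims=True)
        sd = np.nanstd(x, axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd

    out = x.copy()
    for i in range(nf):
        miss = np.flatnonzero(np.isnan(x[i]))
        if miss.size == 0:
            continue
        dists = np.full(nf, np.inf)
        for j in range(nf):
            if j == i:
                continue
            shared = ~np.isnan(z[i]) & ~np.isnan(z[j])
            if not shared.any():
                continue
            d = z[i, shared] - z[j, shared]
            dists[j] = np.sqrt(np.mean(d * d))
        order = sorted(range(nf), key=lambda j: (dists[j], matrix.features[j].feature_id))
        for col in miss:
            vals = []
            for j in order:
                if not np.isfinite(dists[j]):
                    break
                if not np.isnan(x[j, col]):
                    vals.append(x[j, col])
                if len(vals) == k:
                    break
            out[i, col] = np.mean(vals) if vals else np.nanmean(x[i])
    res = matrix.copy()
    res.intensity = out
    return res


def glog(x, lam: float):
    """Generalised log: ln((x + sqrt(x^2 + lambda)) / 2); finite at x = 0."""
    if lam <= 0:
        raise ValueError(f"lambda must be > 0, got {lam}")
    x = np.asarray(x, dtype=float)
    return np.log((x + np.sqrt(x * x + lam)) / 2.0)


def tune_glog_lambda(matrix: PeakMatrix, grid=None) -> float:
    """Choose glog lambda minimising the technical-variance profile across QCs.

    Grid search over candidate lambdas; the score is the spread (SD) of
    per-feature QC standard deviations after transformation — a good lambda
    flattens technical variance across the intensity range.
    """
    qc_cols = matrix.class_columns("QC")
    if qc_cols.size < 2:
        raise ValueError("lambda tuning needs at least two QC samples")
    qc = matrix.intensity[:, qc_cols]
    if np.isnan(qc).any():
        raise ValueError("tune after imputation: QC block must be complete")
    if grid is None:
        scale = float(np.median(qc[qc > 0])) if (qc > 0).any() else 1.0
        grid = scale**2 * np.logspace(-6, 4, 41)
    best_lam, best_score = None, np.inf
    for lam in grid:
        sds = glog(qc, lam).std(axis=1, ddof=1)
        score = float(sds.std())
        if score < best_score:
            best_lam, best_score = float(lam), score
    return best_lam


def glog_transform(matrix: PeakMatrix, lam: float | None = None) -> tuple[PeakMatrix, float]:
    """Apply the glog transform; lambda tuned on QCs when not supplied."""
    if np.isnan(matrix.intensity).any():
        raise ValueError("glog_transform expects a complete (imputed) matrix")
    if lam is None:
        lam = tune_glog_lambda(matrix)
    out = matrix.copy()
    out.intensity = glog(out.intensity, lam)
    return out, lam


def exposure_tests(matrix: PeakMatrix) -> pd.DataFrame:
    """Per-feature exposed-vs-control two-sample t-tests with BH correction.

    Run on PQN-normalised intensities.  Fold change is the ratio of class
    medians; p-values are from Student's two-tailed t-test and q-values from
    Benjamini-Hochberg over the testable features.  Features with degenerate
    variance or fewer than two observations per class get NaN p.
    """
    exp_cols = matrix.class_columns("exposed")
    ctl_cols = matrix.class_columns("control")
    if exp_cols.size < 2 or ctl_cols.size < 2:
        raise ValueError("need at least two samples per class")
    rows = []
    for i, f in enumerate(matrix.features):
        a = matrix.intensity[i, exp_cols]
        b = matrix.intensity[i, ctl_cols]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        med_a = np.median(a) if a.size else np.nan
        med_b = np.median(b) if b.size else np.nan
        fold = med_a / med_b if med_b and not np.isnan(med_b) else np.nan
        if a.size >= 2 and b.size >= 2 and (np.ptp(a) > 0 or np.ptp(b) > 0):
            _, p = stats.ttest_ind(a, b, equal_var=True)
            p = float(p)
        else:
            p = np.nan
        rows.append({"feature_id": f.feature_id, "fold_change": fold, "p_value": p})
    df = pd.DataFrame(rows)
    q = np.full(len(df), np.nan)
    mask = df["p_value"].notna().to_numpy()
    if mask.any():
        q[mask] = multipletests(df.loc[mask, "p_value"], method="fdr_bh")[1]
    df["q_value"] = q
    return df


def pca_scores(matrix: PeakMatrix, n_components: int | None = None):
    """SVD-based PCA on samples (features are variables).

    Input should be complete, glog-transformed data; features are
    mean-centred here.  Sign convention: the largest-|loading| element of
    each component is made positive.  Returns (scores, loadings,
    explained-variance fractions) as DataFrames/Series.
    """
    if matrix.n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    if np.isnan(matrix.intensity).any():
        raise ValueError("PCA expects a complete matrix")
    x = matrix.intensity.T  # samples x features
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    ncomp = n_components or min(xc.shape)
    u, s, vt = u[:, :ncomp], s[:ncomp], vt[:ncomp]
    # fix signs: largest-|loading| entry positive per component
    for c in range(ncomp):
        k = np.argmax(np.abs(vt[c]))
        if vt[c, k] < 0:
            vt[c] *= -1
            u[:, c] *= -1
    scores = u * s
    total_var = (xc**2).sum()
    explained = (s**2) / total_var if total_var > 0 else np.zeros(ncomp)
    comp_names = [f"PC{c + 1}" for c in range(ncomp)]
    return (
        pd.DataFrame(scores, index=matrix.sample_ids, columns=comp_names),
        pd.DataFrame(vt.T, index=matrix.feature_ids, columns=comp_names),
        pd.Series(explained, index=comp_names, name="explained_variance"),
    )
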