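"""Peak-matrix data model and I/O.

A peak matrix is a features x samples table of MS1 intensities from an
untargeted LC-MS metabolomics experiment.  Rows are metabolite features
(m/z-retention-time pairs), columns are samples.  Samples carry one of four
roles: ``exposed`` (dosed biological sample), ``control`` (undosed biological
sample), ``QC`` (pooled intra-study quality control) or ``blank`` (extract
blank).

Missing values: non-detection is encoded as 0 or an empty cell in typical
XCMS-style exports; both are mapped onto ``NaN`` on load, and "present"
everywhere downstream means non-NaN.  Intensities are stored as-is;
normalisation is an explicit pipeline stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_CLASSES = ("exposed", "control", "QC", "blank")

#: aliases accepted in metadata files, mapped onto the canonical class labels
_CLASS_ALIASES = {
    "exposed": "exposed",
    "exposure": "exposed",
    "dosed": "exposed",
    "control": "control",
    "qc": "QC",
    "pool": "QC",
    "blank": "blank",
    "extract_blank": "blank",
}


@dataclass(frozen=True)
class Feature:
    """One metabolite feature: an m/z-retention-time pair."""

    feature_id: str
    mz: float
    rt: float
    assay: str = ""

    def __post_init__(self):
        if not self.mz > 0:
            raise ValueError(f"feature {self.feature_id!r}: mz must be > 0, got {self.mz}")
        if self.rt < 0:
            raise ValueError(f"feature {self.feature_id!r}: rt must be >= 0, got {self.rt}")


@dataclass(frozen=True)
class SampleRecord:
    """One sample column with its study role."""

    sample_id: str
    cls: str
    subject: str | None = None
    timepoint: str | None = None
    assay: str = ""

    def __post_init__(self):
        if self.cls not in SAMPLE_CLASSES:
            raise ValueError(
                f"sample {self.sample_id!r}: class must be one of {SAMPLE_CLASSES}, got {self.cls!r}"
            )


def default_feature_id(mz: float, rt: float) -> str:
    """Deterministic feature id ``M<mz to 4 dp>T<rt to 1 dp>``."""
    return f"M{mz:.4f}T{rt:.1f}"


@dataclass
class PeakMatrix:
    """Features x samples intensity table with explicit missingness (NaN)."""

    features: list[Feature]
    samples: list[SampleRecord]
    intensity: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        nf, ns = len(self.features), len(self.samples)
        if self.intensity.shape != (nf, ns):
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match "
                f"{nf} features x {ns} samples"
            )
        fids = [f.feature_id for f in self.features]
        if len(set(fids)) != nf:
            dupes = sorted({x for x in fids if fids.count(x) > 1})
            raise ValueError(f"duplicate feature ids: {dupes}")
        sids = [s.sample_id for s in self.samples]
        if len(set(sids)) != ns:
            dupes = sorted({x for x in sids if sids.count(x) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        with np.errstate(invalid="ignore"):
            if np.any(self.intensity < 0):
                raise ValueError("negative intensities are not allowed")
        if ns and np.isnan(self.intensity).all(axis=0).any():
            bad = [s.sample_id for j, s in enumerate(self.samples)
                   if np.isnan(self.intensity[:, j]).all()]
            warnings.warn(f"sample column(s) entirely missing: {bad}")

    # -- convenience accessors -------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_classes(self) -> np.ndarray:
        return np.array([s.cls for s in self.samples])

    def class_columns(self, *classes: str) -> np.ndarray:
        """Column indices of samples whose class is in ``classes``."""
        cls = self.sample_classes()
        return np.flatnonzero(np.isin(cls, classes))

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"feature {feature_id!r} not in matrix") from None

    def row(self, feature_id: str) -> np.ndarray:
        return self.intensity[self.feature_index(feature_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intensity, index=self.feature_ids, columns=self.sample_ids)

    def copy(self) -> "PeakMatrix":
        return PeakMatrix(list(self.features), list(self.samples), self.intensity.copy())


# -- I/O -----------------------------------------------------------------


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_metadata(path) -> list[SampleRecord]:
    """Read a sample-metadata CSV (sample_id, class, subject, timepoint, assay)."""
    meta = pd.read_csv(path, dtype=str)
    meta.columns = [c.strip().lower() for c in meta.columns]
    if "sample_id" not in meta.columns or "class" not in meta.columns:
        raise ValueError(f"metadata {path}: needs at least sample_id and class columns")
    records = []
    for _, r in meta.iterrows():
        raw = str(r["class"]).strip()
        cls = _CLASS_ALIASES.get(raw.lower())
        if cls is None:
            raise ValueError(f"metadata {path}: unknown sample class {raw!r}")
        records.append(SampleRecord(
            sample_id=str(r["sample_id"]).strip(),
            cls=cls,
            subject=None if pd.isna(r.get("subject")) else str(r.get("subject")),
            timepoint=None if pd.isna(r.get("timepoint")) else str(r.get("timepoint")),
            assay="" if pd.isna(r.get("assay")) else str(r.get("assay")),
        ))
    return records


def read_peak_matrix(path, metadata_path) -> PeakMatrix:
    """Read a delimited peak matrix plus its sample metadata.

    The matrix file has one header row of sample ids and leading columns
    ``feature_id``, ``mz``, ``rt`` (feature_id may be empty; ids are then
    derived from m/z and RT).  Zeros and empty cells become NaN (missing).
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    lower = [c.strip().lower() for c in df.columns]
    colmap = {}
    for want in ("feature_id", "mz", "rt"):
        if want in lower:
            colmap[want] = df.columns[lower.index(want)]
    if "mz" not in colmap or "rt" not in colmap:
        raise ValueError(f"{path}: matrix must have 'mz' and 'rt' columns")
    annot_cols = [c for c in colmap.values()]
    assay_col = df.columns[lower.index("assay")] if "assay" in lower else None
    if assay_col is not None:
        annot_cols.append(assay_col)
    sample_cols = [c for c in df.columns if c not in annot_cols]

    meta = {m.sample_id: m for m in read_metadata(metadata_path)}
    missing_meta = [c for c in sample_cols if c not in meta]
    if missing_meta:
        raise ValueError(
            f"metadata {metadata_path} lacks entries for sample column(s): {missing_meta}"
        )
    samples = [meta[c] for c in sample_cols]

    features = []
    seen = set()
    for i, r in df.iterrows():
        mz, rt = float(r[colmap["mz"]]), float(r[colmap["rt"]])
        fid = r.get(colmap.get("feature_id"))
        if colmap.get("feature_id") is None or pd.isna(fid) or str(fid).strip() == "":
            fid = default_feature_id(mz, rt)
        fid = str(fid).strip()
        if fid in seen:
            raise ValueError(f"{path}: duplicate feature id {fid!r} at row {i}")
        seen.add(fid)
        assay = str(r[assay_col]) if assay_col is not None else ""
        features.append(Feature(fid, mz, rt, assay))

    raw = df[sample_cols]
    for col in sample_cols:
        bad = pd.to_numeric(raw[col], errors="coerce").isna() & raw[col].notna() \
            & (raw[col].astype(str).str.strip() != "")
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric intensity {raw[col].iloc[i]!r} at row {i}, column {col!r}"
            )
    vals = raw.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    vals[vals == 0] = np.nan  # zeros encode non-detection
    return PeakMatrix(features, samples, vals)


def write_peak_matrix(matrix: PeakMatrix, path, metadata_path=None) -> None:
    """Write a peak matrix (and optionally its metadata) back to delimited text.

    Missing values are written as empty cells so that a read/write round trip
    preserves the missingness pattern.
    """
    df = pd.DataFrame({
        "feature_id": matrix.feature_ids,
        "mz": [f.mz for f in matrix.features],
        "rt": [f.rt for f in matrix.features],
    })
    inten = pd.DataFrame(matrix.intensity, columns=matrix.sample_ids)
    pd.concat([df, inten], axis=1).to_csv(path, sep=_sep_for(path), index=False, na_rep="")
    if metadata_path is not None:
        write_metadata(matrix.samples, metadata_path)


def write_metadata(samples: list[SampleRecord], path) -> None:
    pd.DataFrame({
        "sample_id": [s.sample_id for s in samples],
        "class": [s.cls for s in samples],
        "subject": [s.subject for s in samples],
        "timepoint": [s.timepoint for s in samples],
        "assay": [s.assay for s in samples],
    }).to_csv(path, index=False)


# -- structural operations -----------------------------------------------


def subset(matrix: PeakMatrix, classes) -> PeakMatrix:
    """Restrict the matrix to samples of the given classes (features unchanged)."""
    classes = set(classes)
    if not classes:
        raise ValueError("classes must be non-empty")
    unknown = classes - set(SAMPLE_CLASSES)
    if unknown:
        raise ValueError(f"unknown sample classes: {sorted(unknown)}")
    keep = [j for j, s in enumerate(matrix.samples) if s.cls in classes]
    if not keep:
        raise ValueError(f"no sample matches classes {sorted(classes)}")
    return PeakMatrix(
        list(matrix.features),
        [matrix.samples[j] for j in keep],
        matrix.intensity[:, keep].copy(),
    )


def split_by_feature_ids(matrix: PeakMatrix, ids) -> tuple[PeakMatrix, PeakMatrix]:
    """Partition the matrix into (features in ``ids``, the complement).

    This is the step that removes putative xenobiotic-related features from
    the full peak matrix, leaving a filtered endogenous matrix.
    """
    ids = set(ids)
    known = set(matrix.feature_ids)
    offenders = sorted(ids - known)
    if offenders:
        raise KeyError(f"feature ids not in matrix: {offenders}")
    in_rows = [i for i, f in enumerate(matrix.features) if f.feature_id in ids]
    out_rows = [i for i, f in enumerate(matrix.features) if f.feature_id not in ids]

    def take(rows):
        return PeakMatrix(
            [matrix.features[i] for i in rows],
            list(matrix.samples),
            matrix.intensity[rows, :].copy() if rows else np.empty((0, matrix.n_samples)),
        )

    return take(in_rows), take(out_rows)
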