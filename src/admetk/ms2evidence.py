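"""MS2 spectrum handling and fragment-shift substructure evidence.

Fragmentation spectra of a biotransformation product typically retain
several fragments of the parent compound (conserved substructures) while
fragments containing the modified site shift by exactly the transformation's
mass delta.  ``align_to_parent`` counts both: a candidate is deemed related
to the parent when at least ``conserved_min`` (default 3) parent substructure
fragments are conserved, mirroring the evidence standard of annotating a
product only when several parent substructures are recognisable in its
spectrum.

Also provided: precursor-purity filtering (spectra acquired with a
contaminated isolation window are dropped below ``plim``, default 0.5),
replicate averaging with ppm-linkage clustering, and plain-text MGF/MSP
readers/writers.  Purity is consumed from file annotations; computing it
from raw scans is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class Ms2Spectrum:
    """A centroided fragmentation spectrum."""

    precursor_mz: float
    precursor_rt: float = 0.0
    fragments: list[tuple[float, float]] = field(default_factory=list)
    purity: float | None = None
    title: str = ""

    def __post_init__(self):
        self.fragments = sorted((float(m), float(i)) for m, i in self.fragments)
        if any(i < 0 for _, i in self.fragments):
            raise ValueError("fragment intensities must be >= 0")
        if self.purity is not None and not 0 <= self.purity <= 1:
            raise ValueError(f"purity must be in [0, 1], got {self.purity}")

    @property
    def mz(self) -> np.ndarray:
        return np.array([m for m, _ in self.fragments])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([i for _, i in self.fragments])


# -- file I/O (MGF / MSP, plain text) ------------------------------------


def read_mgf(path) -> list[Ms2Spectrum]:
    spectra = []
    cur = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                cur = {"fragments": []}
            elif line == "END IONS":
                if cur is None:
                    raise ValueError(f"{path}: END IONS without BEGIN IONS")
                spectra.append(Ms2Spectrum(
                    precursor_mz=float(cur.get("PEPMASS", "nan").split()[0]),
                    precursor_rt=float(cur.get("RTINSECONDS", 0.0)),
                    fragments=cur["fragments"],
                    purity=float(cur["PURITY"]) if "PURITY" in cur else None,
                    title=cur.get("TITLE", ""),
                ))
                cur = None
            elif cur is not None:
                if "=" in line:
                    k, v = line.split("=", 1)
                    cur[k.upper()] = v
                else:
                    parts = line.split()
                    cur["fragments"].append((float(parts[0]), float(parts[1])))
    return spectra


def write_mgf(spectra: list[Ms2Spectrum], path) -> None:
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            if s.title:
                fh.write(f"TITLE={s.title}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"RTINSECONDS={s.precursor_rt:.3f}\n")
            if s.purity is not None:
                fh.write(f"PURITY={s.purity:.4f}\n")
            for m, i in s.fragments:
                fh.write(f"{m:.6f} {i:.4f}\n")
            fh.write("END IONS\n\n")


def read_msp(path) -> list[Ms2Spectrum]:
    spectra = []
    meta: dict = {}
    frags: list = []
    n_expected = 0

    def flush():
        if meta:
            spectra.append(Ms2Spectrum(
                precursor_mz=float(meta.get("PRECURSORMZ", "nan")),
                precursor_rt=float(meta.get("RETENTIONTIME", 0.0)),
                fragments=list(frags),
                purity=float(meta["PURITY"]) if "PURITY" in meta else None,
                title=meta.get("NAME", ""),
            ))

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                flush()
                meta, frags, n_expected = {}, [], 0
                continue
            if ":" in line and not line[0].isdigit():
                k, v = line.split(":", 1)
                k = k.strip().upper().replace(" ", "")
                meta[k] = v.strip()
                if k == "NUMPEAKS":
                    n_expected = int(v)
            else:
                parts = line.replace(";", " ").split()
                frags.append((float(parts[0]), float(parts[1])))
    flush()
    return spectra


def write_msp(spectra: list[Ms2Spectrum], path) -> None:
    with open(path, "w") as fh:
        for s in spectra:
            fh.write(f"NAME: {s.title or 'spectrum'}\n")
            fh.write(f"PRECURSORMZ: {s.precursor_mz:.6f}\n")
            fh.write(f"RETENTIONTIME: {s.precursor_rt:.3f}\n")
            if s.purity is not None:
                fh.write(f"PURITY: {s.purity:.4f}\n")
            fh.write(f"Num Peaks: {len(s.fragments)}\n")
            for m, i in s.fragments:
                fh.write(f"{m:.6f} {i:.4f}\n")
            fh.write("\n")


# -- processing ----------------------------------------------------------


def purity_filter(spectra: list[Ms2Spectrum], plim: float = 0.5) -> list[Ms2Spectrum]:
    """Keep spectra whose precursor purity is >= plim.

    Spectra with no purity annotation pass with a warning (nothing to judge
    them by).
    """
    kept = []
    n_unknown = 0
    for s in spectra:
        if s.purity is None:
            n_unknown += 1
            kept.append(s)
        elif s.purity >= plim:
            kept.append(s)
    if n_unknown:
        warnings.warn(f"{n_unknown} spectra lack a purity annotation; kept")
    return kept


def average_spectra(replicates: list[Ms2Spectrum], ppm_tol: float = 5.0) -> Ms2Spectrum:
    """Average replicate spectra of one precursor.

    Fragments from all replicates are clustered greedily by ascending m/z
    with ppm linkage; each cluster becomes one peak at the intensity-weighted
    mean m/z with the mean intensity across cluster members.
    """
    if not replicates:
        raise ValueError("no replicate spectra to average")
    ref = replicates[0]
    for s in replicates[1:]:
        if abs(s.precursor_mz - ref.precursor_mz) / ref.precursor_mz * 1e6 > ppm_tol:
            raise ValueError("replicates do not share a precursor within tolerance")
    allfrags = sorted((m, i) for s in replicates for m, i in s.fragments)
    clusters: list[list[tuple[float, float]]] = []
    for m, i in allfrags:
        if clusters and (m - clusters[-1][-1][0]) / clusters[-1][-1][0] * 1e6 <= ppm_tol:
            clusters[-1].append((m, i))
        else:
            clusters.append([(m, i)])
    merged = []
    for cl in clusters:
        mz = np.array([m for m, _ in cl])
        it = np.array([i for _, i in cl])
        w = it if it.sum() > 0 else np.ones_like(it)
        merged.append((float(np.average(mz, weights=w)), float(it.mean())))
    purities = [s.purity for s in replicates if s.purity is not None]
    return Ms2Spectrum(
        precursor_mz=ref.precursor_mz,
        precursor_rt=float(np.mean([s.precursor_rt for s in replicates])),
        fragments=merged,
        purity=float(np.mean(purities)) if purities else None,
        title=ref.title,
    )


@dataclass(frozen=True)
class AlignmentEvidence:
    """Outcome of aligning a candidate spectrum to the parent's spectrum."""

    n_conserved: int
    n_shifted: int
    conserved_mz: tuple[float, ...]
    shifted_mz: tuple[float, ...]
    related: bool


def _greedy_match(targets: np.ndarray, candidates: np.ndarray, ppm_tol: float):
    """One-to-one greedy assignment by smallest ppm error; returns matched target idx."""
    pairs = []
    for ti, t in enumerate(targets):
        for ci, c in enumerate(candidates):
            err = abs(c - t) / t * 1e6
            if err <= ppm_tol:
                pairs.append((err, ti, ci))
    pairs.sort()
    used_t, used_c = set(), set()
    matched = []
    for err, ti, ci in pairs:
        if ti in used_t or ci in used_c:
            continue
        used_t.add(ti)
        used_c.add(ci)
        matched.append(ti)
    return matched


def align_to_parent(
    candidate: Ms2Spectrum,
    parent: Ms2Spectrum,
    delta: float,
    ppm_tol: float = 5.0,
    conserved_min: int = 3,
) -> AlignmentEvidence:
    """Count conserved and delta-shifted parent fragments in a candidate spectrum.

    ``delta`` is the candidate's neutral-mass change relative to the parent.
    A parent fragment is conserved when a candidate fragment lies within
    ppm_tol of it, and shifted when one lies within ppm_tol of (fragment +
    delta); matching is greedy one-to-one by smallest ppm error.  Shifted
    counting is suppressed at delta = 0, where it would duplicate the
    conserved count.  ``related`` is n_conserved >= conserved_min.
    """
    if not candidate.fragments or not parent.fragments:
        raise ValueError("both spectra must be non-empty")
    pmz = parent.mz
    cmz = candidate.mz
    conserved_idx = _greedy_match(pmz, cmz, ppm_tol)
    if delta == 0:
        shifted_idx = []
    else:
        shifted = pmz + delta
        ok = shifted > 0
        shifted_idx = [int(np.flatnonzero(ok)[k]) for k in
                       _greedy_match(shifted[ok], cmz, ppm_tol)]
    return AlignmentEvidence(
        n_conserved=len(conserved_idx),
        n_shifted=len(shifted_idx),
        conserved_mz=tuple(sorted(float(pmz[i]) for i in conserved_idx)),
        shifted_mz=tuple(sorted(float(pmz[i]) for i in shifted_idx)),
        related=len(conserved_idx) >= conserved_min,
    )


def link_spectra_to_features(
    spectra: list[Ms2Spectrum], features, ppm_tol: float = 5.0, rt_tol: float = 10.0
) -> dict[str, list[int]]:
    """Assign MS2 spectra to MS1 features by precursor m/z (ppm) and RT window."""
    links: dict[str, list[int]] = {}
    for si, s in enumerate(spectra):
        for f in features:
            if abs(s.precursor_mz - f.mz) / f.mz * 1e6 <= ppm_tol and \
                    abs(s.precursor_rt - f.rt) <= rt_tol:
                links.setdefault(f.feature_id, []).append(si)
    return links
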