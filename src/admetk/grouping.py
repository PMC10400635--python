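"""Ion-form annotation and grouping of co-eluting features.

A single compound typically yields several features in an LC-MS peak
matrix: its molecular ion plus adducts ([M+Na]+, [M+NH4]+ ...), isotopologue
satellites (13C peaks) and dimers, all co-eluting.  This module groups
putative xenobiotic-related features into compound groups by linking
co-eluting pairs (|dRT| <= rt_tol, default 5 s) whose m/z difference is
explained by a known ion-form relation within a ppm tolerance (default
5 ppm), then taking connected components.

Each ion rule is an affine, charge-aware map from neutral mass M to the
observed m/z, and is invertible so that every member of a group yields a
neutral-mass estimate; the group's neutral mass is the median of these.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .peakmatrix import Feature

PROTON = 1.007276  # mass of H+ (electron-corrected), Da
C13_DELTA = 1.003355  # 13C - 12C
NA = 22.989770  # monoisotopic Na
H = 1.0078250319
NH4 = 18.034374
CL = 34.968853


@dataclass(frozen=True)
class IonRule:
    """Observed m/z = (multiplier * M + offset) / charge, for neutral mass M."""

    name: str
    multiplier: float  # number of M units (2 for dimers)
    offset: float  # mass added to multiplier*M before charge division
    charge: int
    polarity: str  # "+" or "-"

    def mz(self, neutral_mass: float) -> float:
        return (self.multiplier * neutral_mass + self.offset) / self.charge

    def neutral_mass(self, mz: float) -> float:
        return (mz * self.charge - self.offset) / self.multiplier


def positive_rules() -> list[IonRule]:
    return [
        IonRule("[M+H]+", 1, PROTON, 1, "+"),
        IonRule("[M+Na]+", 1, NA - H + PROTON, 1, "+"),
        IonRule("[M+NH4]+", 1, NH4 + PROTON - H, 1, "+"),
        IonRule("[2M+H]+", 2, PROTON, 1, "+"),
        IonRule("[M+H]+ 13C1", 1, PROTON + C13_DELTA, 1, "+"),
        IonRule("[M+H]+ 13C2", 1, PROTON + 2 * C13_DELTA, 1, "+"),
    ]


def negative_rules() -> list[IonRule]:
    return [
        IonRule("[M-H]-", 1, -PROTON, 1, "-"),
        IonRule("[M+Cl]-", 1, CL + (H - PROTON), 1, "-"),  # + electron
        IonRule("[2M-H]-", 2, -PROTON, 1, "-"),
        IonRule("[M-H]- 13C1", 1, -PROTON + C13_DELTA, 1, "-"),
    ]


@dataclass
class FeatureGroup:
    """A connected component of co-eluting, rule-related features."""

    group_id: str
    member_ids: list[str]
    ion_forms: dict[str, str]
    neutral_mass: float
    ppm_errors: dict[str, float]
    representative_id: str
    alternatives: list[tuple[str, str, str, float]] = field(default_factory=list)


def _ppm(a: float, b: float) -> float:
    return abs(a - b) / b * 1e6


def group_features(
    features: list[Feature],
    intensities: dict[str, float] | None = None,
    rules: list[IonRule] | None = None,
    ppm_tol: float = 5.0,
    rt_tol: float = 5.0,
    polarity: str = "+",
) -> list[FeatureGroup]:
    """Group features into compound groups via ion-form relations.

    ``intensities`` maps feature_id to a summary intensity (e.g. median over
    exposed samples); used only to pick representatives.  Features must come
    from a single assay/polarity.
    """
    if rules is None:
        rules = positive_rules() if polarity == "+" else negative_rules()
    if any(r.polarity != polarity for r in rules):
        raise ValueError("mixed polarities in one grouping call")
    intensities = intensities or {}

    # Edge (i, j) when the pair's neutral-mass estimates under some rule pair
    # agree within ppm_tol and they co-elute.
    g = nx.Graph()
    for f in features:
        g.add_node(f.feature_id)
    edge_labels: dict[tuple[str, str], tuple[str, str, float]] = {}
    alternatives: dict[tuple[str, str], list[tuple[str, str, float]]] = {}
    feats = sorted(features, key=lambda f: f.mz)
    for a_idx in range(len(feats)):
        for b_idx in range(a_idx + 1, len(feats)):
            fa, fb = feats[a_idx], feats[b_idx]
            if abs(fa.rt - fb.rt) > rt_tol:
                continue
            cands = []
            for ra in rules:
                ma = ra.neutral_mass(fa.mz)
                if ma <= 0:
                    continue
                for rb in rules:
                    if rb.name == ra.name:
                        continue
                    mb = rb.neutral_mass(fb.mz)
                    if mb <= 0:
                        continue
                    err = _ppm(mb, ma)
                    if err <= ppm_tol:
                        cands.append((ra.name, rb.name, err))
            if cands:
                cands.sort(key=lambda t: (t[2], t[0], t[1]))
                g.add_edge(fa.feature_id, fb.feature_id)
                edge_labels[(fa.feature_id, fb.feature_id)] = cands[0]
                if len(cands) > 1:
                    alternatives[(fa.feature_id, fb.feature_id)] = cands[1:]

    by_id = {f.feature_id: f for f in features}
    groups = []
    comps = sorted(nx.connected_components(g), key=lambda c: min(by_id[m].mz for m in c))
    for gi, comp in enumerate(comps):
        members = sorted(comp, key=lambda m: by_id[m].mz)
        ion_forms, neutral_estimates, ppm_errors = _assign_ion_forms(
            members, by_id, edge_labels, rules, ppm_tol
        )
        mass = float(np.median(list(neutral_estimates.values()))) if neutral_estimates else np.nan
        for m in members:
            ppm_errors[m] = _ppm(neutral_estimates[m], mass) if m in neutral_estimates else np.nan
        rep = _pick_representative(members, ion_forms, intensities)
        alts = [
            (u, v, f"{ra}/{rb}", err)
            for (u, v), cands in alternatives.items()
            if u in comp
            for (ra, rb, err) in cands
        ]
        groups.append(FeatureGroup(
            group_id=f"G{gi + 1}",
            member_ids=members,
            ion_forms=ion_forms,
            neutral_mass=mass,
            ppm_errors=ppm_errors,
            representative_id=rep,
            alternatives=alts,
        ))
    return groups


def _assign_ion_forms(members, by_id, edge_labels, rules, ppm_tol):
    """Find one consistent ion-form label per member.

    For each candidate 'anchor' hypothesis (some member observed under some
    rule), compute the implied neutral mass and label every member with the
    best-fitting rule at that mass; keep the hypothesis explaining the most
    members with the lowest total ppm error.
    """
    rule_by_name = {r.name: r for r in rules}
    best = None
    for anchor in members:
        for r in rules:
            mass = r.neutral_mass(by_id[anchor].mz)
            if mass <= 0:
                continue
            labels, estimates, total_err, n_ok = {}, {}, 0.0, 0
            for m in members:
                cand = []
                for r2 in rules:
                    est = r2.neutral_mass(by_id[m].mz)
                    if est <= 0:
                        continue
                    err = _ppm(est, mass)
                    if err <= ppm_tol:
                        cand.append((err, r2.name, est))
                if cand:
                    cand.sort()
                    err, name, est = cand[0]
                    labels[m] = name
                    estimates[m] = est
                    total_err += err
                    n_ok += 1
                else:
                    labels[m] = "?"
            key = (-n_ok, total_err, r.name, anchor)
            if best is None or key < best[0]:
                best = (key, labels, estimates)
    if best is None:  # all singleton, unexplainable: fall back to [M+H]+-style anchor
        only = members[0]
        r0 = rules[0]
        return {only: r0.name}, {only: r0.neutral_mass(by_id[only].mz)}, {}
    _, labels, estimates = best
    return labels, estimates, {}


_MOLECULAR_IONS = ("[M+H]+", "[M-H]-")


def _pick_representative(members, ion_forms, intensities):
    """Molecular ion if annotated, else highest summary intensity."""
    mol = [m for m in members if ion_forms.get(m) in _MOLECULAR_IONS]
    pool = mol if mol else members
    return max(pool, key=lambda m: (intensities.get(m, 0.0), m))


def groups_to_frame(groups: list[FeatureGroup]) -> pd.DataFrame:
    rows = []
    for g in groups:
        for m in g.member_ids:
            rows.append({
                "group_id": g.group_id,
                "feature_id": m,
                "ion_form": g.ion_forms.get(m, "?"),
                "neutral_mass": g.neutral_mass,
                "ppm_error": g.ppm_errors.get(m, np.nan),
                "representative": m == g.representative_id,
            })
    return pd.DataFrame(rows)
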