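"""Molecular formulae and rule-based biotransformation prediction.

The metabolic fate of a xenobiotic is modelled at the molecular-formula
level: each Phase I reaction (oxidation, dealkylation, dehydrogenation,
saturation, oxidative defluorination ...) or Phase II conjugation
(glucuronidation, sulfation, methylation, glycine conjugation) is a formula
delta — elements added and removed.  Multi-step products are enumerated
breadth-first up to ``max_steps`` total steps with at most ``max_phase2``
conjugations, deduplicated by formula keeping the shortest transformation
path.  Predictions are matched to discovered feature groups by neutral
monoisotopic mass within a ppm tolerance (default 5 ppm).

No structures are generated and no site-of-metabolism scoring is done; the
transformation-path length serves as the plausibility proxy for ranking.
"""

from __future__ import annotations

import re
from collections import deque
from dataclasses import dataclass, field

import pandas as pd

# IUPAC monoisotopic atomic masses (Da)
ATOMIC_MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
    "F": 18.9984032,
    "Cl": 34.96885271,
    "Br": 78.9183376,
    "Na": 22.98976928,
}

_HILL_FIRST = ("C", "H")
_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map with monoisotopic mass arithmetic."""

    counts: tuple[tuple[str, int], ...]

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "MolecularFormula":
        for el, n in d.items():
            if el not in ATOMIC_MASS:
                raise ValueError(f"unknown element symbol {el!r}")
            if n < 0:
                raise ValueError(f"negative count for {el}")
        items = tuple(sorted((el, n) for el, n in d.items() if n > 0))
        return cls(items)

    def to_dict(self) -> dict[str, int]:
        return dict(self.counts)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        d = self.to_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) + n
        return MolecularFormula.from_dict(d)

    def __sub__(self, other: "MolecularFormula"):
        """Subtraction; returns None (invalid) if any count would go negative."""
        d = self.to_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) - n
            if d[el] < 0:
                return None
        return MolecularFormula.from_dict(d)

    def __str__(self) -> str:
        return format_formula(self)


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula string such as ``C22H27FN4O2``."""
    text = text.strip()
    if not text:
        return MolecularFormula.from_dict({})
    pos = 0
    d: dict[str, int] = {}
    for m in _FORMULA_RE.finditer(text):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        pos = m.end()
        el, num = m.group(1), m.group(2)
        if el not in ATOMIC_MASS:
            raise ValueError(f"unknown element symbol {el!r} in {text!r}")
        d[el] = d.get(el, 0) + (int(num) if num else 1)
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at position {pos}")
    return MolecularFormula.from_dict(d)


def format_formula(f: MolecularFormula) -> str:
    """Canonical Hill order: C, H, then other elements alphabetically."""
    d = f.to_dict()
    out = []
    for el in _HILL_FIRST:
        if el in d:
            out.append(el + (str(d[el]) if d[el] > 1 else ""))
    for el in sorted(set(d) - set(_HILL_FIRST)):
        out.append(el + (str(d[el]) if d[el] > 1 else ""))
    return "".join(out)


def monoisotopic_mass(f: MolecularFormula | str) -> float:
    if isinstance(f, str):
        f = parse_formula(f)
    return sum(ATOMIC_MASS[el] * n for el, n in f.counts)


PROTON = 1.007276


def mz_from_neutral(neutral_mass: float, ion: str = "[M+H]+") -> float:
    """Observed m/z for the common protonation states."""
    if ion == "[M+H]+":
        return neutral_mass + PROTON
    if ion == "[M-H]-":
        return neutral_mass - PROTON
    raise ValueError(f"unsupported ion form {ion!r}")


@dataclass(frozen=True)
class TransformationRule:
    """A biotransformation as a formula delta: elements added and removed."""

    name: str
    phase: str  # "I" or "II"
    added: MolecularFormula
    removed: MolecularFormula

    def __post_init__(self):
        if self.phase not in ("I", "II"):
            raise ValueError(f"rule {self.name!r}: phase must be I or II")

    @property
    def delta_mass(self) -> float:
        return self.added.mass - self.removed.mass

    def apply(self, f: MolecularFormula):
        """Apply to a formula; None if any element count would go negative."""
        return (f + self.added) - self.removed


def _rule(name, phase, added="", removed=""):
    return TransformationRule(name, phase, parse_formula(added), parse_formula(removed))


def default_rules() -> list[TransformationRule]:
    """The Phase I/II reaction vocabulary used for formula-level prediction."""
    return [
        _rule("oxidation", "I", added="O"),
        _rule("de-ethylation", "I", removed="C2H4"),
        _rule("demethylation", "I", removed="CH2"),
        _rule("dehydrogenation", "I", removed="H2"),
        _rule("saturation", "I", added="H2"),
        _rule("oxidative defluorination", "I", added="OH", removed="F"),
        _rule("glucuronidation", "II", added="C6H8O6"),
        _rule("sulfation", "II", added="SO3"),
        _rule("methylation", "II", added="CH2"),
        _rule("glycine conjugation", "II", added="C2H3NO"),
    ]


def read_rules(path) -> list[TransformationRule]:
    """Read a rule table (TSV/CSV: name, phase, added, removed)."""
    df = pd.read_csv(path, sep="\t" if str(path).endswith(".tsv") else ",", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    rules = []
    for _, r in df.iterrows():
        rules.append(_rule(
            str(r["name"]).strip(),
            str(r["phase"]).strip(),
            "" if pd.isna(r.get("added")) else str(r["added"]).strip(),
            "" if pd.isna(r.get("removed")) else str(r["removed"]).strip(),
        ))
    return rules


@dataclass(frozen=True)
class PredictedProduct:
    formula: MolecularFormula
    path: tuple[str, ...]
    n_phase1: int
    n_phase2: int

    @property
    def neutral_mass(self) -> float:
        return self.formula.mass


def enumerate_products(
    parent: MolecularFormula | str,
    rules: list[TransformationRule] | None = None,
    max_steps: int = 3,
    max_phase2: int = 1,
) -> list[PredictedProduct]:
    """Breadth-first enumeration of multi-step biotransformation products.

    Deduplicated by formula keeping the shortest path (ties: fewer Phase II
    steps, then lexicographic rule names); the parent itself is excluded.
    """
    if isinstance(parent, str):
        parent = parse_formula(parent)
    if rules is None:
        rules = default_rules()
    if not rules:
        raise ValueError("rules must be non-empty")
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")

    best: dict[MolecularFormula, PredictedProduct] = {}
    queue = deque([(parent, (), 0, 0)])
    while queue:
        f, path, n1, n2 = queue.popleft()
        if len(path) >= max_steps:
            continue
        for r in sorted(rules, key=lambda r: r.name):
            if r.phase == "II" and n2 >= max_phase2:
                continue
            nf = r.apply(f)
            if nf is None:
                continue
            npath = path + (r.name,)
            nn1 = n1 + (r.phase == "I")
            nn2 = n2 + (r.phase == "II")
            cand = PredictedProduct(nf, npath, nn1, nn2)
            if nf != parent:
                prev = best.get(nf)
                if prev is None or (len(cand.path), cand.n_phase2, cand.path) < (
                    len(prev.path), prev.n_phase2, prev.path
                ):
                    best[nf] = cand
            queue.append((nf, npath, nn1, nn2))
    return sorted(best.values(), key=lambda p: (p.neutral_mass, p.path))


@dataclass
class AnnotatedCompound:
    """A feature group annotated with matching predicted products."""

    group_id: str
    neutral_mass: float
    candidates: list[dict] = field(default_factory=list)  # formula, ppm, path, ...


def match_products(
    groups,
    products: list[PredictedProduct],
    parent: MolecularFormula | str | None = None,
    ppm_tol: float = 5.0,
) -> list[AnnotatedCompound]:
    """Match group neutral masses against predicted products within ppm_tol.

    Multi-match groups keep all candidates ranked by |ppm error| then
    shortest path.  If ``parent`` is given it competes like any product
    (with an empty path).
    """
    if isinstance(parent, str):
        parent = parse_formula(parent)
    pool: list[tuple[MolecularFormula, float, tuple[str, ...], int, int]] = [
        (p.formula, p.neutral_mass, p.path, p.n_phase1, p.n_phase2) for p in products
    ]
    if parent is not None:
        pool.append((parent, parent.mass, (), 0, 0))

    out = []
    for g in groups:
        ann = AnnotatedCompound(group_id=g.group_id, neutral_mass=g.neutral_mass)
        seen_formulae = set()
        cands = []
        for formula, mass, path, n1, n2 in pool:
            if mass <= 0:
                continue
            ppm = abs(g.neutral_mass - mass) / mass * 1e6
            if ppm <= ppm_tol and formula not in seen_formulae:
                seen_formulae.add(formula)
                cands.append({
                    "formula": format_formula(formula),
                    "neutral_mass": mass,
                    "ppm_error": ppm,
                    "path": " > ".join(path) if path else "(parent)",
                    "n_steps": len(path),
                    "n_phase1": n1,
                    "n_phase2": n2,
                })
        cands.sort(key=lambda c: (c["ppm_error"], c["n_steps"], c["path"]))
        ann.candidates = cands
        out.append(ann)
    return out


def annotations_to_frame(annotated: list[AnnotatedCompound]) -> pd.DataFrame:
    rows = []
    for a in annotated:
        for rank, c in enumerate(a.candidates, start=1):
            rows.append({"group_id": a.group_id, "group_mass": a.neutral_mass,
                         "rank": rank, **c})
    cols = ["group_id", "group_mass", "rank", "formula", "neutral_mass",
            "ppm_error", "path", "n_steps", "n_phase1", "n_phase2"]
    return pd.DataFrame(rows, columns=cols)
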