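"""Ground-truth simulator for the untargeted ADME/TK workflow.

Generates a peak matrix, sample metadata, an MS2 library and a ground-truth
table with the statistical structure the rest of the package assumes:

* a parent xenobiotic dosed over several timepoints, its intensity rising
  to a plateau and dropping after washout, with between-subject variability;
* biotransformation products whose intensities are coupled to the parent's
  per-sample level (multiplicative coupling x lognormal measurement noise);
* adduct / isotopologue satellites at rule-exact m/z offsets co-eluting
  with their molecular ion;
* endogenous features with lognormal baselines, a subset class-shifted by a
  stated effect size and a subset dose-coupled to the parent;
* blanks carrying only contaminant features, QCs pooling the biological
  mean;
* intensity-dependent dropout (missingness rises as intensity falls below
  a detection threshold) rather than uniform missingness.

All randomness flows from the single ``seed``.  The defaults are the
package's stated world: a parent plus 15 product/satellite features, absent
from controls, against 500 endogenous features whose class effects stay
below 10-fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from . import biotransform as bt
from . import grouping
from .ms2evidence import Ms2Spectrum
from .peakmatrix import Feature, PeakMatrix, SampleRecord


def _default_timepoints() -> dict[str, float]:
    # accumulation to steady state, then washout
    return {"day1": 0.35, "day2": 0.60, "day4": 0.85, "day8": 1.00, "day15": 0.45}


def _default_product_rules() -> list[str]:
    return ["oxidation", "de-ethylation", "demethylation",
            "dehydrogenation", "glucuronidation", "sulfation"]


def _default_parent_fragments() -> list[float]:
    # plausible substructure fragment set for an oxindole-type parent
    return [185.1073, 210.0914, 238.1227, 255.1492, 283.1441, 326.1863]


@dataclass
class SimConfig:
    """Parameters of the simulated study (defaults: rat-plasma-style design)."""

    n_exposed: int = 3  # per timepoint
    n_control: int = 3  # per timepoint
    n_qc: int = 8  # total
    n_blank: int = 3  # total
    timepoints: dict[str, float] = dc_field(default_factory=_default_timepoints)
    n_endogenous: int = 500
    parent_formula: str = "C22H27FN4O2"
    parent_rt: float = 210.0
    parent_base_intensity: float = 5e7
    product_rules: list[str] = dc_field(default_factory=_default_product_rules)
    product_couplings: tuple = (0.5, 0.3, 0.25, 0.2, 0.15, 0.1)
    satellite_fraction: float = 0.25  # satellite intensity relative to its ion
    base_log_mean: float = np.log(1e6)
    base_log_sd: float = 1.2
    measurement_cv: float = 0.2  # per-feature measurement noise (log-scale SD)
    sample_scaling_sd: float = 0.3  # per-sample dilution/loading factor (log SD)
    qc_scaling_sd: float = 0.15  # QC injections vary less than samples
    between_subject_sd: float = 0.8  # lognormal sd of subject exposure levels
    mz_ppm_noise: float = 0.5
    rt_jitter_sd: float = 0.5  # satellites co-elute within ~2 s
    dropout_threshold: float = 1e4
    dropout_rate: float = 0.8  # P(missing) below threshold
    dropout_base_rate: float = 0.01  # P(missing) above threshold
    n_dose_coupled: int = 20
    dose_coupling_strength: float = 1.0
    dose_coupling_noise_cv: float = 0.05
    n_class_shifted: int = 50
    class_shift_sd: float = 1.5  # effect size in units of the raw technical SD (log scale)
    n_blank_contaminants: int = 10
    n_decoy_ms2: int = 5
    seed: int = 1

    def __post_init__(self):
        counts = (self.n_exposed, self.n_control, self.n_qc, self.n_blank,
                  self.n_endogenous, self.n_dose_coupled, self.n_class_shifted)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        if self.n_dose_coupled + self.n_class_shifted > self.n_endogenous:
            raise ValueError("more special endogenous features than endogenous features")
        if self.measurement_cv < 0 or self.dose_coupling_noise_cv < 0:
            raise ValueError("CVs must be >= 0")
        for p in (self.satellite_fraction, self.dropout_rate, self.dropout_base_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities/fractions must be in [0, 1]")
        if len(self.product_couplings) < len(self.product_rules):
            raise ValueError("need a coupling strength per product rule")


@dataclass
class GroundTruth:
    """What was planted: per-feature roles and generative structure."""

    roles: dict[str, str]  # feature_id -> role
    parent_feature_id: str
    product_paths: dict[str, tuple[str, ...]]  # molecular-ion feature id -> path
    satellite_of: dict[str, str]  # satellite feature id -> molecular-ion feature id
    ion_forms: dict[str, str]  # xenobiotic feature id -> ion-form label
    neutral_masses: dict[str, float]  # molecular-ion feature id -> neutral mass
    dose_profile: dict[str, float]
    coupled_signs: dict[str, int]  # dose-coupled endogenous id -> +1/-1
    ms2_roles: dict[str, str]  # spectrum title -> {parent, product, decoy}
    ms2_deltas: dict[str, float]  # product spectrum title -> neutral-mass delta

    def xenobiotic_ids(self) -> set[str]:
        return {f for f, r in self.roles.items()
                if r in ("parent_ion", "product_ion", "satellite")}


_POS_RULES = {r.name: r for r in grouping.positive_rules()}
_PARENT_SATELLITES = ["[M+Na]+", "[M+NH4]+", "[M+H]+ 13C1"]
_PRODUCT_SATELLITES = ["[M+H]+ 13C1"]


def simulate(config: SimConfig = SimConfig()):
    """Run the generator.

    Returns ``(matrix, truth, ms2_library)``; the matrix carries the sample
    metadata in its SampleRecords.
    """
    rng = np.random.default_rng(config.seed)
    rule_by_name = {r.name: r for r in bt.default_rules()}
    unknown = [n for n in config.product_rules if n not in rule_by_name]
    if unknown:
        raise ValueError(f"unknown product rules: {unknown}")

    # ---- samples -------------------------------------------------------
    samples: list[SampleRecord] = []
    tps = list(config.timepoints)
    for tp in tps:
        for i in range(config.n_exposed):
            samples.append(SampleRecord(f"E_{tp}_{i + 1}", "exposed",
                                        subject=f"rat{i + 1}", timepoint=tp))
        for i in range(config.n_control):
            samples.append(SampleRecord(f"C_{tp}_{i + 1}", "control",
                                        subject=f"ctl{i + 1}", timepoint=tp))
    for i in range(config.n_qc):
        samples.append(SampleRecord(f"QC_{i + 1}", "QC"))
    for i in range(config.n_blank):
        samples.append(SampleRecord(f"BL_{i + 1}", "blank"))
    ns = len(samples)
    exposed_idx = [j for j, s in enumerate(samples) if s.cls == "exposed"]
    control_idx = [j for j, s in enumerate(samples) if s.cls == "control"]
    qc_idx = [j for j, s in enumerate(samples) if s.cls == "QC"]
    blank_idx = [j for j, s in enumerate(samples) if s.cls == "blank"]

    # per-subject exposure multiplier (between-subject variability)
    subjects = sorted({s.subject for s in samples if s.cls == "exposed"})
    subj_mult = {s: float(np.exp(rng.normal(0, config.between_subject_sd)))
                 for s in subjects}

    # per-sample dilution/loading factor — the variation PQN removes
    dilution = np.ones(ns)
    for j in exposed_idx + control_idx:
        dilution[j] = np.exp(rng.normal(0, config.sample_scaling_sd))
    for j in qc_idx:
        dilution[j] = np.exp(rng.normal(0, config.qc_scaling_sd))

    features: list[Feature] = []
    rows: list[np.ndarray] = []
    roles: dict[str, str] = {}
    product_paths: dict[str, tuple[str, ...]] = {}
    satellite_of: dict[str, str] = {}
    ion_forms: dict[str, str] = {}
    neutral_masses: dict[str, float] = {}

    def jitter_mz(mz: float) -> float:
        if config.mz_ppm_noise <= 0:
            return mz
        return mz * (1 + rng.normal(0, config.mz_ppm_noise) * 1e-6)

    def add_feature(fid, mz, rt, values, role):
        features.append(Feature(fid, jitter_mz(mz), rt))
        rows.append(values)
        roles[fid] = role

    # ---- parent and products ------------------------------------------
    parent_formula = bt.parse_formula(config.parent_formula)
    parent_mass = parent_formula.mass
    profile = config.timepoints

    def xeno_values(base: float) -> np.ndarray:
        """Per-sample intensity of a xenobiotic-derived molecular ion."""
        v = np.zeros(ns)
        for j in exposed_idx:
            s = samples[j]
            level = base * profile[s.timepoint] * subj_mult[s.subject]
            v[j] = level * np.exp(rng.normal(0, config.measurement_cv))
        # QC pools all biological samples: exposed contribute half the pool
        pooled = base * np.mean([profile[t] for t in tps]) \
            * np.mean(list(subj_mult.values())) \
            * len(exposed_idx) / max(len(exposed_idx) + len(control_idx), 1)
        for j in qc_idx:
            v[j] = pooled * np.exp(rng.normal(0, config.measurement_cv / 2))
        return v

    parent_id = "XENO_PARENT"
    mzH = _POS_RULES["[M+H]+"].mz(parent_mass)
    add_feature(parent_id, mzH, config.parent_rt, xeno_values(config.parent_base_intensity),
                "parent_ion")
    ion_forms[parent_id] = "[M+H]+"
    neutral_masses[parent_id] = parent_mass

    def add_satellites(owner_id, owner_mass, owner_rt, owner_values, names):
        for name in names:
            rule = _POS_RULES[name]
            fid = f"{owner_id}_{name.replace(' ', '')}"
            rt = owner_rt + rng.normal(0, config.rt_jitter_sd)
            vals = owner_values * config.satellite_fraction \
                * np.exp(rng.normal(0, config.measurement_cv / 2))
            add_feature(fid, rule.mz(owner_mass), max(rt, 0.0), vals, "satellite")
            satellite_of[fid] = owner_id
            ion_forms[fid] = name

    parent_vals = rows[0]
    add_satellites(parent_id, parent_mass, config.parent_rt, parent_vals,
                   _PARENT_SATELLITES)

    product_infos = []
    for pi, rule_name in enumerate(config.product_rules):
        rule = rule_by_name[rule_name]
        f = rule.apply(parent_formula)
        if f is None:
            raise ValueError(f"rule {rule_name!r} not applicable to the parent")
        mass = f.mass
        coupling = config.product_couplings[pi]
        rt = 120.0 + 40.0 * pi  # well separated chromatographically
        fid = f"XENO_PROD{pi + 1}"
        vals = np.zeros(ns)
        vals[exposed_idx] = parent_vals[exposed_idx] * coupling \
            * np.exp(rng.normal(0, config.measurement_cv, len(exposed_idx)))
        vals[qc_idx] = parent_vals[qc_idx] * coupling
        add_feature(fid, _POS_RULES["[M+H]+"].mz(mass), rt, vals, "product_ion")
        product_paths[fid] = (rule_name,)
        ion_forms[fid] = "[M+H]+"
        neutral_masses[fid] = mass
        add_satellites(fid, mass, rt, vals, _PRODUCT_SATELLITES)
        product_infos.append((fid, rule_name, mass))

    # ---- endogenous features ------------------------------------------
    n_endo = config.n_endogenous
    coupled_ids = [f"ENDO_DC{i + 1}" for i in range(config.n_dose_coupled)]
    shifted_ids = [f"ENDO_CS{i + 1}" for i in range(config.n_class_shifted)]
    plain_ids = [f"ENDO{i + 1}" for i in
                 range(n_endo - config.n_dose_coupled - config.n_class_shifted)]
    coupled_signs = {fid: int(rng.choice([-1, 1])) for fid in coupled_ids}
    parent_rel = np.ones(ns)
    pos = parent_vals > 0
    parent_rel[pos] = parent_vals[pos] / config.parent_base_intensity

    bio_idx = exposed_idx + control_idx
    for fid in coupled_ids + shifted_ids + plain_ids:
        base = float(np.exp(rng.normal(config.base_log_mean, config.base_log_sd)))
        mz = float(rng.uniform(100, 1000))
        rt = float(rng.uniform(30, 900))
        v = np.zeros(ns)
        noise = np.exp(rng.normal(0, config.measurement_cv, ns))
        v[bio_idx] = base * noise[bio_idx]
        v[qc_idx] = base * np.exp(rng.normal(0, config.measurement_cv / 2, len(qc_idx)))
        role = "endogenous"
        if fid in coupled_signs:
            role = "dose_coupled"
            sign = coupled_signs[fid]
            small = np.exp(rng.normal(0, config.dose_coupling_noise_cv, ns))
            for j in exposed_idx:
                v[j] = base * parent_rel[j] ** (sign * config.dose_coupling_strength) \
                    * small[j]
        elif fid.startswith("ENDO_CS"):
            role = "class_shifted"
            # effect size relative to the raw technical SD (dilution + measurement)
            raw_sd = np.hypot(config.sample_scaling_sd, config.measurement_cv)
            v[exposed_idx] = v[exposed_idx] * np.exp(config.class_shift_sd * raw_sd)
        add_feature(fid, mz, rt, v, role)

    # ---- blank contaminants -------------------------------------------
    for i in range(config.n_blank_contaminants):
        fid = f"CONTAM{i + 1}"
        base = float(np.exp(rng.normal(config.base_log_mean, config.base_log_sd)))
        v = np.zeros(ns)
        v[blank_idx] = base * np.exp(rng.normal(0, config.measurement_cv, len(blank_idx)))
        # contaminants bleed into every injection at comparable level
        other = [j for j in range(ns) if j not in blank_idx]
        v[other] = base * np.exp(rng.normal(0, config.measurement_cv, len(other)))
        add_feature(fid, float(rng.uniform(100, 1000)), float(rng.uniform(30, 900)),
                    v, "blank_contaminant")

    # ---- dilution then dropout ----------------------------------------
    x = np.vstack(rows) * dilution[np.newaxis, :]
    p_drop = np.where(x < config.dropout_threshold,
                      config.dropout_rate, config.dropout_base_rate)
    drop = rng.random(x.shape) < p_drop
    x = x.copy()
    x[drop] = np.nan
    x[x == 0] = np.nan

    matrix = PeakMatrix(features, samples, x)

    # ---- MS2 library ---------------------------------------------------
    frag_base = list(_default_parent_fragments())
    ms2_roles: dict[str, str] = {}
    ms2_deltas: dict[str, float] = {}
    library: list[Ms2Spectrum] = []
    parent_spec = Ms2Spectrum(
        precursor_mz=mzH, precursor_rt=config.parent_rt,
        fragments=[(m, 100.0 * (i + 1)) for i, m in enumerate(frag_base)],
        purity=0.95, title="parent",
    )
    library.append(parent_spec)
    ms2_roles["parent"] = "parent"
    for fid, rule_name, mass in product_infos:
        delta = mass - parent_mass
        n_frag = len(frag_base)
        n_shift = int(rng.integers(1, max(2, n_frag - 3)))  # keep >= 3 conserved
        shifted = set(rng.choice(n_frag, size=n_shift, replace=False))
        frags = []
        for i, m in enumerate(frag_base):
            fm = m + delta if i in shifted else m
            if fm > 50:
                frags.append((fm, 100.0 * (i + 1)))
        title = f"product:{fid}"
        library.append(Ms2Spectrum(
            precursor_mz=_POS_RULES["[M+H]+"].mz(mass),
            precursor_rt=120.0 + 40.0 * product_infos.index((fid, rule_name, mass)),
            fragments=frags, purity=0.9, title=title,
        ))
        ms2_roles[title] = "product"
        ms2_deltas[title] = delta
    for d in range(config.n_decoy_ms2):
        # decoys share at most two parent fragments
        shared = list(rng.choice(len(frag_base), size=2, replace=False))
        frags = [(frag_base[i], 50.0) for i in shared]
        frags += [(float(rng.uniform(60, 360)), float(rng.uniform(10, 200)))
                  for _ in range(4)]
        title = f"decoy{d + 1}"
        library.append(Ms2Spectrum(
            precursor_mz=float(rng.uniform(150, 600)),
            precursor_rt=float(rng.uniform(30, 900)),
            fragments=frags, purity=0.85, title=title,
        ))
        ms2_roles[title] = "decoy"

    truth = GroundTruth(
        roles=roles,
        parent_feature_id=parent_id,
        product_paths=product_paths,
        satellite_of=satellite_of,
        ion_forms=ion_forms,
        neutral_masses=neutral_masses,
        dose_profile=dict(config.timepoints),
        coupled_signs=coupled_signs,
        ms2_roles=ms2_roles,
        ms2_deltas=ms2_deltas,
    )
    return matrix, truth, library


def score_discovery(predicted_ids, truth: GroundTruth) -> tuple[float | None, float]:
    """Precision and recall of a predicted id set against the planted
    xenobiotic-related features (parent, products, satellites).

    Precision is None (undefined) for an empty prediction.
    """
    predicted = set(predicted_ids)
    positives = truth.xenobiotic_ids()
    tp = len(predicted & positives)
    precision = tp / len(predicted) if predicted else None
    recall = tp / len(positives) if positives else 1.0
    return precision, recall


def simulate_profiles(
    n_per_shape: int = 20, n_timepoints: int = 5, noise_sd: float = 0.2,
    seed: int = 0,
):
    """Synthetic scaled time profiles drawn from three planted shapes.

    Shapes: monotone rise, rise-then-fall, monotone fall — the canonical
    temporal behaviours of a parent drug and its metabolites.  Returns
    (profiles: n x T array of unit-variance profiles, labels).
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, n_timepoints)
    shapes = [t, np.sin(np.pi * t), 1 - t]
    profiles, labels = [], []
    for lbl, shape in enumerate(shapes):
        base = (shape - shape.mean()) / shape.std(ddof=0)
        for _ in range(n_per_shape):
            p = base + rng.normal(0, noise_sd, n_timepoints)
            p = (p - p.mean()) / p.std(ddof=0)
            profiles.append(p)
            labels.append(lbl)
    return np.vstack(profiles), np.array(labels)
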