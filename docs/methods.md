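# Methods

`admetk` implements an untargeted ADME/TK (absorption, distribution,
metabolism, elimination / toxicokinetics) workflow: given a picked LC-MS
metabolomics peak matrix from an exposure study, it discovers the features
that belong to the administered xenobiotic and its biotransformation
products, annotates them, analyses their kinetic behaviour, and hands back
a cleaned endogenous matrix for effect analysis.

## Discovery: three intensity filters

A feature is called *putatively xenobiotic-related* when all three hold:

1. present (non-missing) in ≥ 80 % of exposed biological samples — a truly
   foreign compound should appear in every exposed sample, but dropout at
   low concentration is routine, so the filter is lenient;
2. present in ≤ 50 % of biological control samples — carry-over and
   co-eluting peaks produce spurious control detections;
3. median intensity in exposed samples ≥ 10× the control median. A control
   median over zero observed values yields fold = +∞ and passes: for a
   xenobiotic the fold change is infinite in principle.

QC and blank columns are ignored; medians ignore missing values and nothing
is imputed inside the filters. Presence comparisons are inclusive
(control presence exactly 0.50 passes). Input zeros and empty cells are
both treated as missing: XCMS-style matrices encode non-detection either
way, and treating zeros as true measurements would corrupt the presence
fractions. For human-style suspect screening the exposed-presence threshold
drops to 50 %, and per-sample exposure labels come from a representative
suspect feature: missing values are imputed with the lowest observed
intensity in the whole matrix, and a sample is *exposed* when the feature
exceeds 10× the median across biological samples and QCs. When several ion
forms match one suspect the representative defaults to the
highest-median-intensity feature (configurable).

## Grouping and ion-form annotation

Co-eluting features (|ΔRT| ≤ 5 s) whose m/z difference is explained by a
known ion-form relation within 5 ppm are linked; compound groups are the
connected components, so grouping is order-independent by construction.
Default rules: positive mode [M+H]+, [M+Na]+, [M+NH4]+, [2M+H]+ and one or
two ¹³C isotopologues; negative mode [M−H]−, [M+Cl]−, [2M−H]−, ¹³C1.
Adduct offsets are electron-corrected (proton 1.007276 Da). Each rule is
invertible, every member yields a neutral-mass estimate, and the group mass
is the members' median. Ion-form labels are chosen by the anchor hypothesis
explaining the most members at the lowest total ppm error; when two rules
fit a pair, the smaller ppm error wins and the alternative is recorded. The
representative feature is the annotated molecular ion, else the
highest-intensity member. Unexplained co-eluting features stay singletons —
no in-source fragment prediction is attempted.

## Biotransformation prediction

Metabolism is modelled at molecular-formula level. Each rule is a formula
delta: Phase I — oxidation (+O), de-ethylation (−C₂H₄), demethylation
(−CH₂), dehydrogenation (−H₂), saturation (+H₂), oxidative defluorination
(F→OH); Phase II — glucuronidation (+C₆H₈O₆), sulfation (+SO₃), methylation
(+CH₂), glycine conjugation (+C₂H₃NO). Multi-step products are enumerated
breadth-first, by default up to 3 total steps with at most 1 conjugation,
deduplicated by formula keeping the shortest path (ties: fewer Phase II
steps, then lexicographic names). Predictions are matched to group neutral
masses within 5 ppm; candidates rank by |ppm error| then path length.
There is no structure generation or site-of-metabolism scoring: path length
is the plausibility proxy, and hydrolysis-type cleavages must be declared
as explicit fragment formulas in a user rule file. Identification
confidence follows the Schymanski scale: level 1 requires RT + MS²
agreement with an authentic standard, level 2 an MS² database/in-silico
match, level 3 an m/z match to a candidate structure, level 4 formula only.

## MS² substructure evidence

In place of combinatorial in-silico fragmentation, product spectra are
aligned to the parent's spectrum: a parent fragment is *conserved* when a
candidate fragment matches it within 5 ppm, and *shifted* when one matches
fragment + Δ, where Δ is the candidate's neutral-mass change. Matching is
greedy one-to-one by smallest ppm error; shifted counting is suppressed at
Δ = 0, where it would duplicate the conserved count. A candidate is
*related* when ≥ 3 parent substructure fragments are conserved. Upstream,
spectra below precursor purity 0.5 are dropped (purity is read from file
annotations; computing it from raw scans is out of scope) and replicates
are averaged by greedy ppm-linkage clustering with intensity-weighted mean
m/z.

## Networks and enrichment

Two network flavours mirror the workflow's two questions. *Co-response*:
Pearson correlation of putative xenobiotic features on PQN-normalised
intensities, edges at Holm-adjusted p < 0.05 and R ≥ 0.75; Holm is applied
over the full pairwise family (the per-node alternative is not used; this
is the conservative reading). *Dose–response*: Spearman correlation of
annotated compounds against the parent, edges at raw p < 0.05 and
|ρ| ≥ 0.9, the network restricted to the parent's neighbourhood. Missing
values are handled pairwise-complete; pairs with < 3 shared observations or
a constant vector are untested. Class enrichment among parent-correlated
compounds uses a one-sided Fisher exact test (hypergeometric upper tail)
against the full annotated list.

## Endogenous preprocessing

After removing xenobiotic features the matrix passes, in order: blank
filter (biological median < 20× blank median → removed; skipped with a log
message when no blanks exist, as in cell-culture designs), QC RSD filter
(≥ 30 %), sample filter (> 50 % missing), feature filters (missing in
≥ 10 % of QCs or ≥ 50 % of samples), then the xenobiotic id list. Blank
columns are dropped once the blank filter has used them. A ledger records
each rule's removals. Statistics run as two branches:
PQN → t-tests (fold changes are ratios of class medians; q-values by
Benjamini–Hochberg), and PQN → kNN imputation (k = 5, Euclidean distance on
unit-variance rows over shared-present columns, ties broken by feature id)
→ glog → PCA. The glog λ is grid-searched to flatten the per-feature QC
standard-deviation profile — the selection the underlying toolboxes perform
on QCs — or user-fixed. PCA is SVD-based with the largest-|loading| element
of each component made positive for sign stability.

## Temporal analysis

Per compound, the median intensity across exposed replicates at each
timepoint is centred and scaled to unit variance (a constant or incomplete
profile is flagged and excluded). k-means (Lloyd, 20 restarts, seeded) runs
for k = 1..k_max; the automated elbow takes the largest second difference
of the WSS curve. The elbow is a heuristic the original analysis applied by
eye, so the WSS curve is always emitted and `--k` overrides the choice.
Timepoint differences use one-way ANOVA with Tukey HSD post-hoc p-values.

## Synthetic ground truth

The generator emulates the data structures the pipeline assumes, not raw
chromatography. Defaults describe a rat-style study: five timepoints
(day 1/2/4/8/15) with a dose profile rising to a plateau and dropping after
washout (0.35, 0.60, 0.85, 1.00, 0.45 relative), 3 exposed + 3 control
subjects per timepoint, 8 pooled QCs, 3 extract blanks. The parent
(C₂₂H₂₇FN₄O₂, [M+H]+ 399.2191) is planted at 5×10⁷ with between-subject
lognormal variability (σ = 0.8); six single-step products couple
multiplicatively to the parent's per-sample level (relative abundance
0.5…0.1); satellites ([M+Na]+, [M+NH4]+, ¹³C for the parent; ¹³C per
product) sit at rule-exact m/z offsets and co-elute within ~2 s — 16
xenobiotic features in total, absent from controls by construction.

Noise has two components chosen to reflect LC-MS reality: a per-sample
dilution/loading factor (lognormal σ = 0.3 for samples, 0.15 for QC
injections) — precisely the variation PQN removes — and per-feature
measurement noise (σ = 0.2). 500 endogenous features have lognormal
baselines (median 10⁶, σ = 1.2); 50 are class-shifted by 1.5× the total raw
technical SD (√(0.3² + 0.2²) ≈ 0.36 log units, fold ≈ 1.7 — well under the
10-fold discovery threshold), and 20 are dose-coupled to the parent with
sign ±1 and small residual noise (σ = 0.05). Missingness is
intensity-dependent: dropout probability 0.8 below a detection threshold of
10⁴, 0.01 above — uniform missingness would misrepresent why presence
filters need leniency. Blanks carry only contaminant features, which bleed
into every injection and are therefore caught by the blank filter. The MS²
library holds the parent's six-fragment spectrum, per-product spectra with
conserved + Δ-shifted fragments (always ≥ 3 conserved), and decoys sharing
at most two fragments. All randomness flows from one integer seed.

What a green test does establish: the filters, grouping, annotation,
statistics and clustering behave correctly on data with exactly the assumed
structure. What it does not: robustness to RT drift, in-source fragments
outside the rule set, ion suppression, batch effects, or real biological
covariance — none of which the generator models.

## Known limitations

- Formula-level prediction cannot distinguish isomers; a group matching
  two isomeric products reports one candidate.
- The BEAMSpy adduct library used originally is not enumerated anywhere;
  the default rule set is a curated choice and is user-extensible.
- The elbow criterion (max second difference) can disagree with a visual
  elbow on flat WSS curves; the override exists for that reason.
- No SyGMa-style probability scores: path length is a crude proxy and is
  documented as such rather than imitated.
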