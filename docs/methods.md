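# Methods

This note documents the models and procedures implemented in `photoreact`,
the parameters that matter, the synthetic data the tests run on, and the
design decisions taken where the design was genuinely open.

## Spectrum classification rule

A molecule's UV–Vis spectrum class is computed from its list of absorption
maxima (λ in nm, MEC in L·mol⁻¹·cm⁻¹):

- **POS** iff at least one peak satisfies 290 ≤ λ ≤ 700 **and** MEC ≥ 1000,
  with all three bounds inclusive. The MEC threshold is taken inclusively
  (≥ 1000); the underlying ICH S10 guidance phrases it as "greater than",
  but the inclusive form is the one that defines the data sets this package
  mirrors, and the difference affects only exact-threshold peaks.
- Peaks with a missing MEC can never qualify: the rule requires a quantified
  coefficient. An empty peak list is NEG with an `empty_list` flag.

POS molecules get a sub-category from the in-window peak with maximal MEC.
The printed band edges overlap at exactly 5000; the bands here are half-open
— [1000, 5000), [5000, 10000), [10000, ∞) — so every value lands in exactly
one band, with 5000 assigned upward to mirror the strict upper bound of the
middle band. NEG molecules get one flag per listed peak by (λ, MEC) region;
peaks sitting exactly at 290 or 700 nm count as in-window. In-window NEG
peaks split at MEC 900 (by construction no in-window NEG peak reaches 1000).

### Data-quality flags

Literature peak lists carry characteristic noise. Four advisory flags mark
the known failure modes; they never influence the label itself:

| flag | fires when | default window |
|---|---|---|
| `suspect_log_mec` | every present MEC lies in a narrow low band | MEC ∈ [3, 5] |
| `near_lower_endpoint` | any peak wavelength near the 290 nm edge | λ ∈ [281, 317] nm |
| `near_mec_threshold` | any in-window MEC near the 1000 threshold | MEC ∈ [661, 1500] |
| `missing_mec` | any peak lacks a MEC | — |

The windows are the ranges in which high-confidence misclassifications
concentrate in practice (borderline chromophores and log-unit transcription
errors); all are configurable on `LabelConfig`.

## Curation contract

Standardization is defined as a *contract*, not as parity with any specific
commercial normalizer: deterministic output, one fixed aromaticity model,
one canonical tautomer, mesomeric forms collapsed (e.g. the two common
nitro-group notations map to a single form). RDKit's `rdMolStandardize`
cleanup plus tautomer canonicalization implements the contract. Structures
failing sanitization are flagged and rejected with reason `valence`.

Eligibility: average molecular weight in [98, 1080] g/mol (monoisotopic
optional), exactly one fragment, no net charge, no radicals, and elements
restricted to {H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I} — "metal" is read
as anything outside this organic whitelist, the conventional interpretation
when no list is given. Each rejection carries one primary reason, assigned
in the fixed precedence valence → metal → radical → charged → multifragment
→ mw_low → mw_high.

Deduplication keys on the InChIKey computed with stereochemistry stripped
(`/SNon`), so enantiomers and diastereomers collapse; the first occurrence
is kept and the peak lists of merged duplicates are unioned — the least
lossy choice, since labeling needs only the existence of one qualifying
peak.

## Modified Distance (Md) descriptors

Md descriptors count heavy-atom pairs at "modified" topological distances.
For atoms i, j at shortest-path distance `path_len` bonds (1–4):

```
rho(a)  = r_vdw(a) · mean_EN(neighbors of a, H included) / EN(C)
d(i, j) = path_len · distance_factor − (rho(i) + rho(j))
bin     = clip(floor(d / resolution), 0, n_bins − 1)
```

Defaults: 1010 bins, resolution 0.017, distance factor 4, paths up to 4
bonds, Bondi vdW radii and Sanderson electronegativities (shipped versioned
in `element_data.py`). The histogram range is anchored at 0; the anchor is
recorded in the provenance sidecar. The functional form above honors the
descriptor's stated ingredients — vdW radius, neighbor electronegativity,
bond-count distance, distance factor — and is isolated behind
`modified_distance` so a different pair formula can be swapped in without
touching the histogram logic.

Hydrogens are excluded from pair enumeration (heavy-atom convention for
topological histograms) but included in the neighbor-electronegativity mean,
since explicit H shapes the electronic environment. The descriptor is a pure
function of the connection table and element identities: no conformers,
aromaticity perception, bond orders or formal charges enter. With the
default configuration every pair value is positive (the distance term ≥ 4
dominates radii ≤ ~2.4), so clipping at bin 0 is a safety net, not a normal
path.

## Classifiers

**Random forest** (primary): scikit-learn `RandomForestClassifier` with
500 unpruned trees by default (500–1000 supported), mtry = √p or p/3,
bootstrap sampling and OOB accuracy as internal validation. Prediction
probabilities are vote fractions; because unpruned trees grow to purity,
scikit-learn's averaged per-tree probabilities coincide with vote fractions
except in the degenerate case of identical rows with conflicting labels.
Exact ties (vote fraction 0.5) resolve to POS: in photosafety screening,
sensitivity outranks specificity.

**Importances**: Gini importances are always recorded; the accuracy-based
score is the classic per-tree OOB permutation scheme — for each tree,
accuracy on its out-of-bag samples is compared before and after permuting
one descriptor (one permutation per tree), averaged over the forest. It is
implemented directly on the fitted trees (note that trees inside a forest
predict encoded class indices) because no OOB-based variant exists in
scikit-learn. Top-k selection uses the accuracy-based score by default,
with deterministic tie-breaking by lower column index. Cost is one tree
evaluation per descriptor per tree; compute it on demand
(`compute_mda=True` or `oob_permutation_importance`) rather than by default.

**Classification tree**: `DecisionTreeClassifier` with cost-complexity
pruning. The `cp` parameter follows the rpart convention (minimum relative
risk improvement per split, default 0.01); it maps to scikit-learn as
`ccp_alpha = cp × R(root)` with R(root) the root misclassification risk.
Root-to-leaf rules are extractable for interpretability reports.

**Y-scrambling**: labels are uniformly permuted, the forest retrained, and
OOB accuracy recorded per round; a valid model collapses to ≈ 0.5 on
balanced classes. Each round's forest seed derives from the scramble seed,
so runs are exactly reproducible.

**Plug-ins**: RBF-kernel SVM with the tuned working values C = 500,
γ = 0.004 (class output only, no probability calibration), and a deep MLP
with hidden layers (250, 250, 8, 4), relu activations, a single sigmoid
output unit, adam (learning rate 0.001), batch size 36 and 100 epochs,
implemented with scikit-learn's `MLPClassifier`. Two architecture details —
the random-normal initializer and the 10⁻⁶ weight decay — are recorded in
provenance but not applied, as `MLPClassifier` exposes neither; at the
accuracies involved this is immaterial to the plug-in's role.

## Evaluation

SE, SP, Q and MCC are computed directly from confusion counts with POS as
the positive class. MCC with any zero marginal is reported as 0 with an
`mcc_undefined` flag (standard convention). Display values are rounded
half-up to two decimals; full precision is kept internally. ROC curves use
a threshold sweep over distinct scores with ties grouped and trapezoidal
AUC (scikit-learn backend); comparison tables sort by descending MCC, then
Q, stably.

## Triage

Misclassifications with vote probability strictly greater than 0.8 are
collected as FP/FN entries. Each is explained by (a) the quality flags of
its spectrum record and (b) a Tanimoto similarity search (fingerprint
intersection over union; two empty fingerprints are 1.0 by convention)
against the training set: a neighbor at similarity ≥ 0.7 whose label
matches the wrong prediction marks a `training_neighbor_conflict` — the
model faithfully reproduced a contradictory training example. Defaults
k = 3 neighbors and floor 0.7 reflect the similarity range (0.70–0.99) at
which such conflicts are informative in practice; both are configurable.
The similarity fingerprint defaults to the Morgan set used by the best
model. Entries with no firing rule are `unexplained`.

## Phototoxicity cross-evaluation

The 2×2 table crosses assay outcome (toxic / non-toxic) with spectrum class
(POS / NEG), treating POS as the alarm: sensitivity = toxic∧POS / toxic,
specificity = non-toxic∧NEG / non-toxic. Undefined rates (empty margin) are
flagged, not zeroed. `compare_predictors` puts a classifier-derived and an
experimental-class table side by side with concordant totals and per-cell
deltas. The package deliberately does not model phototoxicity itself:
absorption is necessary but not sufficient for a phototoxic response.

## Synthetic data: what it emulates, what it does not

The generator draws molecules from a finite curated scaffold library with
enumerable substituent tails — saturated scaffolds (alkanes, alcohols,
amines, ethers; no pi system) and conjugated scaffolds, split into
single-ring chromophores (~6–8 pi atoms) and extended systems (fused
aromatics, biaryls, polyenes, push-pull dyes; ≥ 10 pi atoms). Every emitted
structure parses, standardizes and passes the eligibility filter; tails are
extended with methylenes when a combination falls under the MW floor.

The primary absorption maximum follows a transparent monotone rule:

```
λ = 150 + 16 · conjugation + N(0, 12) nm
```

where conjugation is the atom count of the largest conjugated system
computed from the emitted structure. MEC is log-normal with
family-dependent location (log₁₀ mean 2.0 / 3.5 / 4.0 for saturated /
small / extended, s.d. 0.5 / 0.45 / 0.35), giving the characteristic
sub-290 nm high-MEC negative peaks alongside genuinely weak absorbers. Up
to three secondary maxima sit blue of the primary at lower MEC. Drawing
extended scaffolds with probability 0.5 yields a realized POS fraction
within ±0.05 of one half at n ≥ 1000. Intercept and slope were fixed once
so that saturated scaffolds absorb far below the window, benzene-sized
chromophores land just under 290 nm (the borderline region where real
misclassifications concentrate), and extended systems land inside it.

Three corruption modes are injected per molecule with ground truth
retained: **log-unit MEC transcription** (all MECs replaced by log₁₀(MEC);
injected only where every MEC lies in [10³, 10⁵], the regime in which a
log(MEC) error is plausible and lands in the telltale [3, 5] band),
**boundary-proximal peaks** (primary λ moved into [281, 317] nm) and
**missing MEC** (one peak's MEC blanked). Default rates 3 / 4 / 3 %.
Phototoxicity outcomes are Bernoulli with P(toxic|POS) = 0.5 and
P(toxic|NEG) = 0.1, reproducing the sensitive-but-unspecific behavior of an
absorption-based alarm.

What passing tests on this fixture shows: the pipeline's plumbing, the
labeling semantics, the learnability of a genuine structure→spectrum signal
and the flagging of injected noise. What it does not show: performance on
real chemical space — the generator has no solvatochromism, no substituent
band shifts beyond the monotone rule, no correlated literature biases, and
far less scaffold diversity than a real database.

## Problem sizes and numerics

The test suite and the acceptance script run the synthetic end-to-end at
1000 molecules / 500 trees (held-out split 800/200) and the noise-robustness
sweep at 600 molecules / 150 trees — sizes chosen so the complete suite
runs in well under a minute of forest training while keeping the binomial
noise on accuracy estimates around one percentage point. Wavelengths and
MECs are compared as floating point with no rounding anywhere in labeling;
two-decimal rounding is display-only (half-up via `decimal`). Stable sorts
and explicit index tie-breaks make selection and tables deterministic; all
stochastic components (generator, forests, scrambling, splits) take
explicit integer seeds.

## Known limitations

- Fingerprint families from the CDK/PaDEL ecosystem (CDK, ExtCDK, PubChem,
  Substructure) need a backend this package does not bundle; requesting
  them raises with a clear message. Cross-toolkit bit parity is a non-goal.
- The quantum-descriptor interface (`external_qd`) loads 10-column
  E_HOMO/E_LUMO/GAP tables produced by external estimators; the estimators
  themselves are out of scope.
- The Md pair formula is one faithful realization of the stated ingredients,
  not a bit-exact reproduction of any external implementation; it is
  deliberately swappable.
- Standardization guarantees determinism and the three named normalizations
  under RDKit's models, not agreement with other normalizers' tautomer
  choices.
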