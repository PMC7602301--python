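# Methods

## Problem and model

The task is binary classification of RNA cytosines into m5C and non-m5C
given only local sequence context. A candidate site is represented by a
window of `2λ + 1` nucleotides centered on the cytosine (λ = 20 by
default, giving the field-standard 41-nt fragment); windows extending past
a sequence end are padded with `N`. The classifier is a support vector
machine with an RBF kernel acting on a concatenation of sequence-derived
feature families; the subset of families is selected per dataset by greedy
forward search.

## Feature encodings

All encoders treat `N` as padding, never as a nucleotide: `N`-containing
k-mers and pairs are excluded from counts, `N` positions have zero
propensity, a zero chemical triple and zero density. This guarantees that
padding cannot masquerade as signal when scanning near sequence ends.

* **KNF** — for word length K, the count of each of the 4^K k-mers divided
  by `L − K + 1`. K = 4 (`4NF`) is the default reporting variant.
* **KSNPF** — counts of the 16 ordered nucleotide pairs separated by
  exactly K positions, divided by `L − K + 1`. Only `L − K − 1` gapped
  pairs exist in a window, so this published denominator makes the vector
  sum to `(L−K−1)/(L−K+1)` rather than 1; we keep it as the default for
  fidelity (the constant rescaling is absorbed by kernel-scale tuning) and
  expose `denominator="count"` for the sum-to-one variant.
* **PSNP** — fit per-position nucleotide frequency matrices `M⁺` (4 ×
  (2λ+1), positives) and `M⁻` (negatives), each column normalized over
  non-`N` occurrences, and take `X = M⁺ − M⁻`. A fragment is encoded by
  looking up its observed nucleotide's propensity at every position. The
  matrices define only the lookup table; the per-fragment vector follows
  the convention of the related m6A predictors (per-position lookup). The
  center column is identically zero (both classes carry C there) and is
  retained, so the dimension is 2λ+1; dropping it would only remove a
  constant-zero column that the scaler discards anyway.
* **KSPSDP** — the same construction over gapped dinucleotides
  `(n_i, n_{i+K+1})` at each of the `2λ − K` start positions; K = 0
  reproduces the classic PSDP.
* **PseDNC** — the standard pseudo-dinucleotide composition: the first 16
  components are normalized dinucleotide frequencies `f_i / (Σf + w Σθ)`,
  the last λ_pse are `w θ_j / (Σf + w Σθ)`, where `θ_j` averages, over all
  valid position pairs `j` apart, the mean squared difference of the three
  z-scored physicochemical properties (free energy, hydrophilicity,
  stacking energy) of the two dinucleotides. The property table ships as a
  packaged CSV; each property is standardized to zero mean / unit SD
  across the 16 dinucleotides before use (the conventional normalization
  for these correlation factors; configurable via a custom table).
  Defaults λ_pse = 2, w = 0.1 — small enough that the tier terms refine
  rather than dominate the composition part; both configurable.
* **CPD** — per position, the chemical triple (A = (1,1,1), U = (0,0,1),
  G = (0,1,0), C = (1,0,0); ring structure, hydrogen bonding, functional
  group) plus the prefix density `d_i = |{j ≤ i : n_j = n_i}| / i`,
  concatenated position-major: 4·(2λ+1) = 164 values at λ = 20.

## Training and validation

Features are z-scored per column with training statistics; zero-variance
columns are dropped and recorded. The SVM follows the `fitcsvm`
parameterization — kernel scale s with `K(x,y) = exp(−‖x−y‖²/s²)`, mapped
internally to `gamma = 1/s²` — and both hyper-parameters are searched over
powers of two, C in 2⁻⁵…2¹⁵ and s in 2⁻¹⁰…2⁶. The full exponent-step-1
grid (21 × 17) is available behind `SVMGrid.full()`; the default
`SVMGrid.coarse(step)` uses the same bounds at a wider step, trading
resolution for speed. Selection maximizes mean stratified 10-fold CV
AUROC; exact ties prefer smaller C, then larger kernel scale (the smoother
model), making the result independent of grid enumeration order.

Inside cross-validation, the propensity matrices and the scaler are
refitted on the nine training folds for every fold; the fitted model
records a SHA-256 fingerprint of the exact fragments and labels it saw, so
tests can prove the held-out fold never leaked into its own encoding.
Hyper-parameter selection reuses the same ten folds whose metrics are
reported; this is mildly optimistic relative to nested CV but matches
common practice for this predictor class, and the independent-test path
(`evaluate`) is unaffected. Reported metrics are fold-averaged threshold
metrics (decision threshold 0 on the SVM decision value) plus AUROC/AUPRC
of the pooled held-out scores.

Threshold metrics use the standard forms (Sn, Sp, Pre, Acc =
(TP+TN)/total, Mcc with numerator TP·TN − FP·FN, F1); a zero-denominator
ratio is reported as 0 with a `degenerate` flag instead of raising, so
greedy selection survives pathological folds. AUROC is the trapezoidal
area over the tie-grouped threshold sweep (equal to the tie-corrected
Mann–Whitney statistic); AUPRC uses the step-wise, non-interpolated sum.

## Feature selection

Sequential forward selection evaluates each candidate family alone in
round 1, then each extension of the incumbent by one remaining family,
re-searching (C, s) for every candidate subset. It stops when no addition
strictly improves CV AUROC (strict improvement guarantees termination);
exact AUROC ties prefer the lower-dimensional subset. For k families this
costs at most k(k+1)/2 cross-validated evaluations. `select_gap_k` chooses
the gap K for KSNPF/KSPSDP by single-family CV AUROC over a K grid, ties
to the smaller K.

## Synthetic data

The generator emulates the structure of real m5C benchmark sets: two
classes of fixed-width fragments sharing the central C, with negatives
i.i.d. from a background nucleotide distribution and positives optionally
modified by (a) per-position probability boosts (added mass, renormalized)
— a positional motif; (b) a global compositional tilt; and (c) a gapped
pair planted at a random valid location with a given probability. Default
shapes follow the published benchmarks (e.g. 200+200 training and 69+69
test fragments per class for the small-species configuration).

The default study conditions used by the tests and the acceptance script
are: a positional condition boosting G/G/A/G at window positions
18/19/23/24 to probability 0.9 against a uniform background (a
several-position preference, as the real data's nucleotide-distribution
contrasts show); a compositional condition tilting G/C up and A/U down by
0.05 each — moderate on purpose, since at large tilts every compositional
family saturates near AUROC 1 and the family comparison becomes
uninformative; and a gapped-pair condition planting A·G at spacing 3 with
probability 0.9.

What the generator does **not** emulate: transcriptome-derived sequence
dependence between fragments (real fragments overlap transcripts and
share k-mer structure), redundancy patterns that CD-HIT filtering leaves
behind, species-specific background composition (supported but not
defaulted), and any coupling between positions beyond the planted
effects. Passing tests therefore demonstrate correctness and
detectability of the modeled signal classes, not field performance on
GEO-derived data.

## Numerical choices and degenerate inputs

* Coordinates are 1-based in every report (the central C of a 41-nt
  fragment is position 21); internal indices are 0-based.
* Sequences shorter than the window are still scanned, with N-padding, and
  a fragment of all-N flanks receives a finite score.
* Columns of `M±` with no non-`N` observations are all-zero rather than
  NaN; an all-`N` window yields an all-zero PseDNC vector.
* Propensity encode-time checks: λ must match the fitted model; a gap K
  not fitted raises.
* Model artifacts are single `.npz` archives holding a JSON manifest plus
  the support vectors, dual coefficients, intercept, scaler statistics and
  propensity matrices — scoring after reload is bit-identical and does not
  depend on pickling estimator objects.
* Test and acceptance runs use the coarse power-of-two grid (exponent
  step 4, 30 points) and datasets of 100–400 fragments per class; these
  sizes make every planted effect comfortably detectable while keeping
  each cross-validated evaluation to seconds.

## Known limitations

* Hyper-parameter selection and reported CV metrics share folds (above).
* The decision threshold is fixed at 0; no probability calibration.
* KSNPF's published denominator makes its vectors non-normalized (above).
* GEO retrieval and CD-HIT redundancy removal are out of scope; users
  supply their own non-redundant FASTA pairs for real data (any tool can
  be applied upstream, the loader only checks window shape and the
  central C).
* Single-species models transfer poorly across distant species; train per
  species.
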