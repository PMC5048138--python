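# Methods

This note documents the models, defaults and design choices behind
`phosthr`, and what the synthetic benchmarks do and do not demonstrate.

## Windows and coordinates

A candidate site is a 31-residue peptide centered on a threonine.
External file coordinates are 1-based; internally every position is a
signed offset from the center (−15…+15, center = 0). Sites closer than
15 residues to a terminus are padded with the neutral symbol X
(secondary structure X, accessibility 0) rather than discarded, so every
annotated site stays usable; all encoders treat X as neutral (score 0,
mid-scale property value, zero accessibility). Unannotated residues
default to coil with accessibility 0, with a logged count. Accessibility
units are taken as annotated and are only ever used after scaling to
[0, 1] by the dataset-wide maximum, so absolute vs. relative units do
not change the encoding.

## Conservation, PWMs and the position score

Position conservation is the relative entropy of the observed residue
distribution at an offset against a uniform background p0 = 0.05, in
bits (base 2 throughout; the zero point and ordering are
base-invariant). It is zero exactly on a background-distributed column
and log2(20) on a fully conserved one.

The class PWMs are log-ratio weights of pseudocount-smoothed residue
frequency over background. The pseudocount defaults to α = 1 (additive
smoothing proportional to background): a positive class of a few hundred
windows cannot populate all 20 × 31 cells, and α = 0 would produce −∞
weights on unobserved cells. α = 0 is allowed only behind an explicit
flag. The per-window position score F(l) is the positive-minus-negative
PWM lookup of the observed residue, evaluated per window (the only
reading that yields per-sample features); the invariant central
threonine is excluded.

## Feature encoding

Group window sizes count flanking residues, split symmetrically (w/2 per
side); this is the only reading under which a size of 12 yields 12
position-score dimensions and all default sizes are even. Defaults
(12, 12, 24, 18) give 216 features. Secondary structure is one scalar
per position (H → 0.0, E → 0.5, C → 1.0), forced by the 2-per-offset
dimension count of the structure group; the mapping is data, not logic,
and configurable in principle. Property values are min-max scaled per
property over the 20 residues because RBF-SVM behavior depends on scale.

Offsets are laid out center-outward (−1, +1, −2, +2, …) so that widening
a group appends outer-offset columns without renaming or moving inner
ones; sweep results at different sizes are therefore column-compatible.

The nine physicochemical properties ship as an editable TSV
(`src/phosthr/data/aa_properties.tsv`). Masses, pK1, pK2 and pI are
standard amino-acid chemistry; hydrophobicity is Kyte–Doolittle,
hydrophilicity Hopp–Woods, flexibility the Bhaskaran–Ponnuswamy average
flexibility index, irreplaceability the inverse Dayhoff relative
mutability, and rigidity a curated side-chain scale (ring content and
branching; proline highest, glycine lowest). Only orderings and relative
spacings survive the min-max scaling, but results remain
configuration-sensitive to this table, which is why it is shipped as
data with provenance comments.

## Leakage control in evaluation

The F1 group is derived from class-labelled PWMs, which creates two
traps under jackknife (leave-one-out) evaluation:

1. encoding a window against a PWM containing that window leaks its own
   label into its features, inflating auROC;
2. rebuilding PWMs per fold only for the held-out window creates a
   train/test mismatch — training windows' F1 scores are inflated by
   self-inclusion while the held-out window's are not — which deflates
   auROC below even an F1-free model.

Both are avoided with leave-one-out feature encoding
(`assemble_features_loo`): every window's F1 scores are computed against
its own class's PWM rebuilt without that window, symmetrically for all
samples. Each sample's features are then a function of the other
samples only, and train and held-out F1 distributions coincide.
`jackknife_windows` evaluates on this encoding; it can additionally
recompute the mRMR ranking on each training fold (`select_k`) so that
feature selection never observes the held-out label. The fixed-matrix
`jackknife_eval` is the evaluator used inside window sweeps, grid search
and IFS, matching the protocol in which model selection wraps the
jackknife; a nested variant would be less optimistic but combinatorially
heavier.

A related caveat worth knowing: leave-one-out on a balanced binary
dataset has a pessimistic class-imbalance artifact (each fold trains on
99 vs 100), which is strongest for degenerate features — constant
feature rows yield auROC near 0 rather than 0.5. On noise features with
variance the estimator is chance-level within ~0.1 at n = 200.

## Default hyperparameters

The SVM defaults sit at the midpoints of the search grids: C = 2^5,
γ = 2^−10 (grids C ∈ 2^−5…2^15, γ ∈ 2^−15…2^−5, exponent step 1 — the
only reading of the stated ranges under which both endpoints are hit).
Note that generic gamma heuristics such as 1/(d·Var) fall *outside* this
γ range for 216 bounded features and measurably underperform it. Grid
search scored by jackknife auROC is available at every stage but is off
by default in the pipeline for runtime reasons; ties break toward
smaller C, then smaller γ.

mRMR uses the MID (difference) criterion with three-state
discretization at mean ± σ — the reference defaults of the method — and
breaks ties toward the lower feature index. The pairwise
mutual-information table is computed with indicator-matrix products, so
a full 216-feature ranking costs milliseconds and per-fold re-selection
inside the jackknife is affordable. IFS evaluates every nested prefix of
the ranking (216 subsets for the default encoding) and breaks best-k
ties toward the smaller prefix. By default (C, γ) are tuned (or fixed)
once and reused across IFS subsets rather than re-tuned per subset.

## Class balancing

Benchmarks are balanced by k-means (k = 100 per class by default) on the
full 216-dimension encoding, keeping the member nearest each centroid
(Euclidean; ties to the lowest input index, output ordered by cluster
index, fixed seed). "First member of each group" is not well-defined
without an ordering; nearest-to-centroid is deterministic and keeps one
representative context per cluster. With k equal to the class size the
input is returned unchanged. Both classes are clustered symmetrically.

## The synthetic generator

The generator emulates the statistical signatures of phosphothreonine
contexts: planted residue effects at chosen offsets (default: proline
with probability 0.30 at +1 — matching the >25% proline frequency
observed immediately downstream of real sites — plus milder L/K/G
enrichments at −13, −11, −4, +3, +8), coil probability raised from 0.4
to 0.7 at positive centers, and accessibility elevated by 30 units over
a gamma-noise base with mean 30 (so mean accessibility roughly doubles
at the site). Structure and accessibility effects decay exponentially
with distance (scale 5 residues) or can be hard-confined to a chosen
half-width, which makes window-size recovery testable against a known
ground truth. `weak` halves all effects; `null` removes them, making
classes exchangeable.

Every threonine in the output is a planted site center: flank residues
come from a threonine-free background (uniform 0.05 renormalized over
the other 19 residues), so positive/negative counts are exact by
construction, and each protein (20 sites per protein, ~116 proteins at
study scale) contains at least one positive. This is a deliberate
simplification — real proteins contain threonines at uncontrolled
positions, autocorrelated structure, and homology between sites. The
generator also does not emulate kinase-specific motifs, 3D structure, or
database redundancy. Passing recovery tests therefore demonstrates that
the pipeline detects the planted effect classes at realistic effect
sizes and sample sizes, not that the reported accuracies transfer to
real proteomes.

## Benchmark problem sizes

The heavier validation runs use deliberately desk-scaled conditions:
parameter recovery generates 150 positive / 600 negative sites and
balances to the standard 100 + 100 benchmark before a leakage-controlled
jackknife at the default (12, 12, 24, 18) encoding; window-size recovery
uses 150 + 150 windows with weak effects hard-confined to ±5 and sweeps
the structure group over sizes {10, 14, 18, 22, 26, 30} — the sparser
grid halves the sweep cost and, with a leave-one-out evaluator whose
per-size noise is ~0.01–0.02 auROC, reduces the chance that a noise bump
at a large size outranks the true small-window optimum. Study-scale
(151/2158) generation and balancing are fast and run at full size.

## Known limitations

* IFS inside the pipeline evaluates prefixes on a fixed encoded matrix,
  so its peak auROC is selection-biased upward (the peak is chosen and
  reported on the same jackknife scores); the leakage-controlled
  `jackknife_windows` number is the honest single-model estimate.
* The rigidity/irreplaceability columns of the property table are
  curated approximations; swap in preferred scales via
  `PropertyTable.load(path)`.
* k-means undersampling with k near the class size degenerates toward
  random thinning; representativeness claims hold only for k well below
  the class size.
* The generator's independence assumptions (per-position draws) make
  conservation signals cleaner than in real alignments; absolute auROC
  values on synthetic data are not comparable to real-data accuracies.
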