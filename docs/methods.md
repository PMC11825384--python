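# Methods

## Scope and model

`shapemut` scores candidate point mutations of a DNA sequence along two
axes of protein–DNA recognition. Base readout is modeled by a frozen
physicochemical encoding of Watson–Crick edge chemistry; shape readout by
a pluggable sequence-to-structure predictor evaluated per candidate. The
package deliberately models only *local, unbound* B-DNA structure: a
k-mer predictor cannot express non-local deformations, protein-induced
bending, or chemically modified bases.

## Functional-group encoding

Each base pair presents an ordered pattern of groups at its groove edges:
four on the major-groove edge, three on the minor-groove edge, each one of
{acceptor, donor, nonpolar-H, methyl}. We read the groups in a fixed
spatial order, 5'→3' along the reference strand across the pair:

| base | major edge | minor edge |
|------|------------------------|---------------|
| A | A, D, A, M | A, H, A |
| G | A, A, D, H | A, D, A |
| T | reverse of A's = M, A, D, A | A, H, A |
| C | reverse of G's = H, D, A, A | A, D, A |

The minor-edge patterns are palindromic, so A/T and G/C are
indistinguishable from the minor groove — the structural reason
minor-groove-binding proteins cannot read base-pair orientation there.
Each group becomes a length-4 one-hot; concatenation gives 16 + 12 = 28
binary slots per base pair with exactly 7 set. The encoding of a
complement is the group-order reversal of the encoding of the base, which
makes the induced distance exactly strand invariant.

The base distance is the position-wise L1 difference of these vectors,
summed along the sequence. Under the frozen table the per-substitution
costs are 6 for A↔C and G↔T and 8 for the remaining four substitution
types. Note the code is injective — informationally equivalent to one-hot
encoding — but the induced *metric* differs from the one-hot metric
(constant 2 per substitution); both are exposed and neither is forced to
agree with the other. Levenshtein distance (unit-cost two-row dynamic
program, the package's own implementation, cross-checked against edlib in
tests) is provided for unequal-length comparisons; it is not used by the
designer itself, which only produces equal-length candidates.

## Shape features and the lookup predictor

The catalogue is the standard 14-feature set: six base-pair-step
parameters (Shift, Slide, Rise, Tilt, Roll, HelT), six intra-base-pair
parameters (Shear, Stretch, Stagger, Buckle, ProT, Opening), and two
minor-groove features (MGW, EP). Step vectors have length n−1 (entry i
describes the step between base pairs i and i+1), the rest length n.
Parities under strand flip follow the standard sign conventions: the
x-axis parameters Shift, Tilt, Shear, Buckle are antisymmetric (negated
and reversed on the opposite strand), all others symmetric (reversed
only). EP is stored as given by the table, no rescaling; more negative
means more negative minor-groove potential.

The reference backend is a k-mer central-value lookup (k ∈ {3, 5, 7},
default 5), the same family as classical pentamer shape tables. A table
is *parity-consistent* when `value(revcomp(w)) == parity * value(w)` for
every k-mer.

**Step-feature windows.** An odd-width window has no strand-symmetric
central step: its k−1 steps map i ↦ k−i under reverse complement, and no
integer is fixed by that map. Assigning a window's value to any single
step therefore breaks reverse-complement equivariance of the predicted
profiles. We instead predict the value at step i as the mean of the two
windows centered on the step's endpoint base pairs i and i+1 — the device
classical pentamer tables use for Roll/HelT. With a parity-consistent
table this makes prediction exactly equivariant: symmetric features
reverse, antisymmetric features reverse and negate, at every position
with full window context.

**Edges.** The (k−1)/2 positions at each end have overhanging windows. The
default policy (`mean`) substitutes the marginal mean of the table over
the missing flank bases — an explicit, deterministic stand-in that
preserves the n / n−1 length contract and commutes with reverse
complementation. Alternatives: `nan` (emit NaN) and `trim` (drop the
affected entries, shortening vectors). Edge values are a modeling choice,
not a claim about how any trained predictor treats sequence ends.

**Synthetic tables.** `synth_table(k, features, seed)` draws one value per
k-mer per feature from a normal distribution around rough B-DNA central
values (e.g. MGW 5.1 ± 0.6 Å, HelT 34.3 ± 3°, Roll 2 ± 4.5°,
EP −4.5 ± 1.5 kT/e; antisymmetric features centered at 0, as parity
forces) and symmetrizes: `value(w) = (g(w) + parity·g(revcomp(w)))/2`.
Draws are seeded per (seed, feature-catalogue index), so a feature's
values are independent of which other features were requested. These
tables emulate the *structure* of a real predictor backend — completeness,
parity, locality, realistic magnitudes — but not real sequence-dependent
shape: neighboring k-mers are uncorrelated, so passing tests demonstrate
the engine's contracts (lengths, equivariance, locality, determinism,
ranking), not biological accuracy of any particular profile. Published
pentamer tables in the documented TSV dialect plug in unchanged for real
analyses.

## Design engine

Candidates are the full Cartesian product of {A, C, G, T} over the (at
most 7) mutable positions — 4^m sequences in lexicographic order,
including the wild type, which is kept and flagged as the comparison
baseline rather than dropped. The 7-position cap bounds a run at
4^7 = 16384 candidates.

**Focal restriction.** Shape distances may be restricted to focal
positions. Per-base-pair features use the focal positions directly; a
step is included when either endpoint is focal (excluding half-overlapping
steps would hide shape change at a focal base). Since a substitution at
position p can alter values only within (k−1)/2 of p (one further step
for step features), candidates mutated beyond that reach of every focal
point score exactly 0 — useful as a designed-in control.

**Euclidean distance** is a single square root over the sum of squared
differences pooled across selected features and focal indices; each
feature's own root-sum-of-squares is also reported. Because features
carry incommensurate units (Å vs degrees), values are z-scored per
feature — mean/SD pooled over the focal values of the *entire candidate
ensemble*, a run-level normalization that keeps every pairwise distance
on one common scale — whenever two or more features are selected
(default; overridable with `normalize`). A feature untouched by any
candidate has pooled SD 0 and falls back to SD 1, contributing zero
difference rather than NaN.

**Pearson distance** is 1 − r per feature over the focal indices,
averaged unweighted across features (per-feature values are reported so
users can re-weight); range [0, 2], 0 for identical patterns regardless
of constant offset, 2 for anticorrelated patterns. It requires ≥ 3 focal
values and nonzero variance in both restricted vectors; a constant
profile raises an error rather than silently scoring 0.

**Ranking and Pareto front.** Results are sorted by shape distance in the
objective direction (`max` for shape-perturbing design — the common case —
`min` for shape-neutral recoding), ties broken by ascending base
distance, then lexicographic sequence, so output order is a pure function
of the inputs. The Pareto front keeps candidates not dominated in the
(base distance, shape distance) plane, always minimizing base distance;
under `max` the wild type is excluded (it is trivially non-dominated but
never a useful design). The sweep implementation is cross-checked against
an exhaustive O(n²) dominance oracle in the tests.

## Determinism and I/O

All randomness (synthetic tables, demo scenarios) flows from explicit
seeds through `numpy.random.default_rng`; floats are serialized at fixed
6-decimal precision and rows in ranked order, so identical invocations
produce byte-identical TSV/JSON, which the tests assert at the byte
level. Coordinates are 1-based inclusive in every user-facing surface
(flags, output columns) and converted once at the library boundary.

## Problem sizes used in tests

Property tests run on random sequences of length 5–50; exhaustive oracle
comparisons cover all sequence pairs up to length 3 (naive-recursion edit
oracle, metric axioms) and length 5 (edlib oracle); strand invariance of
whole design runs is checked on 20 random (sequence, table) instances
with 2 mutable positions; enumeration is verified up to the full
16384-candidate budget. These sizes exercise every code path, including
both edge windows, at sub-minute cost.

## Known limitations

- The lookup backend is local by construction: no coupling beyond
  (k−1)/2 base pairs, no bound-DNA or non-B structure.
- Only the four canonical bases; modified bases (e.g. 5mC) and non-
  Watson–Crick pairing are outside the encoding table.
- Insertions/deletions are not design moves (shape comparison requires
  equal lengths); Levenshtein is provided for measurement only.
- Ensemble-pooled z-normalization makes normalized Euclidean distances
  comparable within a run but not across runs with different candidate
  ensembles; use `normalize=False` for run-to-run comparability.
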