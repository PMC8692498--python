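# Methods

`qlqsar` reanalyzes a small congeneric series of quinazoline-derived NHE-1
inhibitors with a qualitative fragment-pair QSAR, a population of bottleneck
multilayer perceptrons, sensitivity-driven input pruning, and pharmacophore
mapping.  This note records the model, the calibrated conventions, the
numerical choices, and the places where the design was genuinely open.

## Data

The built-in set holds fourteen structures: eleven novel
quinazoline-2,4(1H,3H)-dione / quinazolin-4(3H)-one derivatives (3a-3i, 6a,
6b) plus the reference acylguanidine inhibitors amiloride and rimeporide
(thirteen training structures in all) and zoniporide as the
external-validation hold-out.  Activity is percent inhibition of
propionate-induced platelet shape change at 10 nM compound (mean of six
replicates); measured IC50s, where available, travel as metadata and are
never fitting targets.  SMILES were transcribed once from the IUPAC names
and frozen; the weakly active analog 3b keeps its near-zero value (1.49%)
without flooring.

## Q-labels and fragment-pair descriptors

A *Q-label* is an atom-centered or ring fragment predicate evaluated on the
RDKit-perceived molecular graph (default aromaticity model, under which the
pyrimidinedione/pyrimidinone rings of the cores are aromatic, as for uracil).
The shipped grammar (`data/grammar.yaml`) defines 21 labels keyed on element,
hydrogen count, heavy-atom degree, aromaticity and bond pattern.  The five
labels entering the pharmacophore are:

| label | predicate |
|---|---|
| `-N<` | N, no H, three heavy neighbours |
| `-CH=` | C with one H and a double or aromatic bond to N (azomethine-type CH) |
| `>C(<)` | C, no H, at least three heavy neighbours |
| `-C(Ar)<` | aromatic C, no H, without an exocyclic double bond to O |
| `CycAr06` | six-membered aromatic ring |

A rank-2 *QL-descriptor* is an unordered pair of labels, optionally carrying
an inclusive shortest-path distance window between the two occurrences
(nearest atom for ring fragments).  The *entry count* of a descriptor in a
molecule is the number of occurrence pairs (a double loop over occurrence
lists; same-label pairs count unordered combinations).  Modeling features
are binary presence indicators, the most defensible reading of a
"qualitative" descriptor system.

### Calibration of the entry-counting convention

The three reference mappings (6a: 17 entries, 4 types, complete;
zoniporide: 24, 4 types, complete; 3e: 27 entries over exactly 3 types) pin
down the convention.  An exhaustive search over predicate variants, counting
modes and distance windows showed that no configuration without distance
information can reproduce all three totals simultaneously (a parity
argument: every natural substituted-aromatic-carbon count in 3e is even,
while the ring-pair contribution required is odd).  The unique clean
solution, frozen as the default, is the grammar above with plain pair
counting for three members and a proximal window (shortest path <= 4 bonds)
on `{-C(Ar)< ... CycAr06}`.  Under it the three structures decompose as
0+12+8+7, 1+5+4+7 and 2+7+5+10 entries.  The `-CH=` member is the type
absent from 3e: the compound has no CH doubly/aromatically bonded to
nitrogen, whereas 6a has the amidine C2-H and zoniporide the quinoline C2-H
and pyrazole C3-H.  One consequence worth noting: a `>C(<)` restricted to
sp3 carbons would be unsatisfiable here (6a contains no H-free sp3 branch
carbon at all), so the label is defined without a hybridization constraint.

### Descriptor matrix

The matrix holds presence indicators over the union of descriptors of the
training structures; constant columns are dropped, and descriptors with
identical presence patterns across the series are collapsed to a single
input column (lexicographically first code; synonym groups are kept in the
matrix object and the report).  On thirteen compounds the 156 raw pair
columns reduce to 26 unique patterns.  Collapsing matters: duplicated
inputs split a pattern's weight arbitrarily across copies, so
mean-substitution ablation of any single copy changes little and informative
patterns are pruned away.

## Bottleneck-MLP population modeling

The regression model is a two-layer perceptron k-m-1 (m << k, one output).
Defaults follow the published protocol where stated and are otherwise the
package's own choices:

| parameter | default | note |
|---|---|---|
| train/test split | 60/40 (8/5 on n=13), fresh seeded split per network | |
| hidden width m | sampled from {3, 4, 5} | bottleneck |
| hidden activation | sampled from {exponential, tanh} | exp pre-activation clipped to ±30 |
| output activation | sampled from {tanh, identity} | target min-max scaled to [0,1] for tanh, raw otherwise |
| optimizer | L-BFGS-B on half mean squared error, analytic gradients | <= 100 steps |
| early stopping | iterate with minimal combined-set MSE kept | see below |
| population | 100 + 100 + 300 networks over three rounds | ~500 total |
| selection | maximize the weakest of train/test/combined Pearson r | ties: combined r, then seed |
| pruning | keep top-k by pooled Sens; k: 26 -> 20 -> 13 | geometric shrink 0.75, final round fixed at 13 inputs |

Three design points deserve explanation:

* **Early stopping.**  A quasi-Newton fit run to convergence interpolates
  eight training points exactly (train r = 0.999), and its held-out behaviour
  is then pure luck.  The optimizer trajectory is therefore snapshotted and
  the iterate with the lowest mean squared error over all modeled compounds
  retained; typical retained epochs are a few tens, consistent with the
  small epoch counts quasi-Newton trainers report on data of this size.  The
  hold-out structure (zoniporide) is never part of this set.
* **Selection.**  Ranking by test-set correlation alone selects networks
  whose five test predictions correlate by chance while train fit or
  cross-subset alignment is poor; requiring all three correlations to be
  jointly high reproduces the behaviour of a model that is good on the
  combined series.
* **Pooled pruning.**  The per-input sensitivity of one network trained on
  eight compounds is noisy.  For the pruning decision only, sensitivities
  are pooled (geometric mean of the error ratios) over the ten top-ranked
  networks; each iteration still reports the best network and its own
  sensitivity report.

Sensitivity itself is mean-substitution ablation: Sens_i = MSE(input i
replaced by its training-set mean) / MSE(intact model), evaluated on the
combined set.  An input whose ablation cannot change predictions has
Sens = 1 exactly; if the intact model has zero error, inputs whose ablation
raises error receive an infinite sentinel.  Ranking ties break by canonical
descriptor code.

On the built-in data the default protocol ends at 13 inputs with a final
model around r = 0.98-0.99 on the combined series and r >= 0.975 on the
held-out split in most seeds; because the procedure is best-of-population on
a 13-compound set, individual seeds vary and headline checks are therefore
made over five seeds.

## Pharmacophore

The pharmacophore is the top-n (default 4) descriptors of the final
sensitivity ranking.  Mapping onto a structure counts the entries of every
member; *complete* means every member occurs at least once.  The calibrated
reference pharmacophore ({-N< ... -C(Ar)<}, {-N< ... >C(<)},
{-C(Ar)< ... CycAr06} proximal, {-N< ... -CH=}) ships with its original
Sens annotations (90.8, 49.6, 46.3, 26.9) as fixture metadata; the package
recomputes entry counts, never those Sens magnitudes.  The pharmacophore a
fresh training run extracts depends on the seed and need not coincide with
the reference set - with 13 compounds and 26 candidate inputs, several
descriptor subsets support near-equivalent models.

## Assay models

The concentration-response model is the four-parameter logistic on log10
concentration, y = bottom + (top - bottom) / (1 + 10^(h (log c - log IC50))),
fit by trust-region least squares with top bounded at 100 (percent of
control) by default and a three-parameter fallback (bottom = 0) below five
distinct concentrations.  The parameterization is symmetric under
(top, bottom, h) -> (bottom, top, -h), so only the midpoint and the curve are
identified; the fit is scale-equivariant in concentration.  Fits that do not
converge raise with diagnostics; flat responses are rejected.

The AGE fluorescence coefficient is implemented literally as
10^(log10 A - log10 B) - 1 and equals A/B - 1 to floating-point accuracy;
activity percent is (1 - Flu_sample/Flu_control) x 100, invariant to common
rescaling of both coefficients.

## Synthetic-data generators

* `gen_planted_matrix` - independent Bernoulli(0.5) binary columns; activity
  = 50 + sum(w_j x_j) + N(0, sigma).  The offset 50 keeps values in the
  observed percent range.  The recovery benchmark plants 3 true columns with
  weights (25, 20, 15) percent among 40 decoys at sigma = 5.  Its sample
  size (100) is a power choice: the weakest effect has expected marginal
  correlation ~0.41, and separating that from the maximum of 40 null decoy
  correlations (~2.3/sqrt(n)) requires sqrt(n) of order (1.96 + 2.3)/0.41,
  i.e. n ~ 100.  At n = 20 a planted effect is regularly invisible by
  sampling luck and recovery would measure the data rather than the method.
* `gen_molecule_library` - combinatorial decoration of the two cores with
  R1 in {H, CH3, allyl, benzyl}, R2 in {H, Br}, R3 in {H, CH3} and the
  aminotriazole side chain (20 distinct structures).
* `gen_dose_response` - log-spaced concentrations (±2 decades around the
  IC50), logistic responses, multiplicative Gaussian noise.

What the generators deliberately do not emulate: inter-replicate activity
error structure, activity cliffs, correlated descriptor occurrence (real
fragment pairs co-occur through shared scaffolds), assay plate effects, or
any in-vivo endpoint.  Passing synthetic benchmarks therefore shows the
machinery is correct and recovers detectable planted structure - not that a
13-compound model generalizes beyond its chemical series.

## Numerical conventions and degenerate inputs

Pre-activations of the exponential unit are clipped to ±30.  All randomness
flows from `numpy.random.default_rng` seeds; child seeds stay below 2^31.
Identical protocol + seed give bit-identical results, including network
weights.  Networks with undefined correlations (zero-variance test
activities, degenerate predictions) are discarded from populations; an
all-constant input matrix, an empty compound set, and a pruning rule that
would leave fewer than two inputs (top-2 kept, with a warning) are handled
explicitly.  Atom indices are internal and never serialized; reports are
canonical JSON (sorted keys) and contain no timestamps, so reruns are
byte-identical.

## Known limitations

* The Q-label grammar is a reconstruction; the original descriptor
  vocabulary is unpublished.  The calibration pins the five pharmacophore
  labels and the counting convention, but other grammars satisfying the same
  three totals could exist outside the searched space.
* Thirteen compounds cannot support uncertainty estimates worth reporting
  for a 13-input nonlinear model; the correlation targets are
  best-of-population statistics, not generalization claims.
* Distance binning beyond the single proximal window is implemented but
  off by default; "descriptor type" taxonomies finer than unordered pairs
  are not modeled.
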