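# Methods

This note records the models implemented in `chemscreen`, the defaults they
ship with, and the design decisions taken where the underlying procedures
admit more than one reasonable rendering.

## Activity scale

All learners regress a continuous activity value rather than a binary
label: `pIC50 = −log10(IC50 / 1 M)` (identically for EC50). Inactive
compounds are assigned 1 mM (pIC50 = 3); actives carry their measured
potency, expected in the 0.1–25 µM range (pIC50 7–4.6), or a representative
1 µM (pIC50 = 6) when no measurement exists. This keeps unmeasured actives
usable for training while preserving differential-activity information.
When a hard label is needed (decision-tree targets, TNR/TPR counting during
training) predictions and targets are thresholded at pIC50 ≥ 3.5,
comfortably between the inactive value 3 and the weakest active 4.6; the
cutoff is configurable.

## Per-atom properties

Nine properties per heavy atom feed the descriptor encoders.

* **σ charges** — damped partial equalization of orbital electronegativity
  (PEOE): six iterations, damping (1/2)^k, electronegativity
  χ(q) = a + bq + cq², transfer normalized by the donor's cation
  electronegativity (hydrogen: the conventional 20.02 eV). The σ parameter
  table is the published PEOE set for H, C, N, O, F, Cl, Br, I, S by
  hybridization. Elements outside the table raise an explicit error —
  never a silent zero.
* **π charges** — the same damped equalization restricted to the π system
  (atoms with π parameters joined by double/triple/aromatic bonds),
  starting from zero; σ iterations start from the formal charges, so
  σ + π sums to the molecular net charge exactly.
* **Electronegativities** — σ, π and lone-pair χ(q) evaluated at the
  converged total charge; atoms without a π system or lone pairs score 0.
  The π and lone-pair parameter tables are *reconstructed approximations*
  (the original parameterizations are not reproducible from the available
  sources); they are shipped as a versioned JSON data file
  (`data/peoe_params.json`) and can be replaced wholesale.
* **Effective polarizability** — distance-damped contribution sum
  α_eff(i) = Σ_j (1/2)^d(i,j) α_j over the hydrogen-expanded graph, with
  standard atomic polarizabilities.
* **VC2003 charge** — the original charge model's parameters are not
  available; the column is a clearly flagged substitute equal to the total
  PEOE charge. It is kept as a separate catalog entry so the nine-property
  descriptor layout (and the 1,284-value total) is preserved.
* **VdW surface area** (weighting factor) — sphere area at Bondi-type radii
  minus spherical-cap overlaps of bonded neighbours (including implicit
  hydrogens); bond lengths from coordinates when present, otherwise
  covalent-radius sums. Exact parity with any particular reference
  implementation is a non-goal.

**Implicit hydrogens.** Property iterations run on an internally
hydrogen-expanded graph. Charge-like columns fold each implicit hydrogen's
charge into its parent heavy atom, so the per-atom table sums to the net
formal charge and descriptor atom pairs range over heavy atoms only
(polar-hydrogen information enters through the folded charges).
Consequently, per-atom charges of conjugated heteroatoms can deviate from
toolkits that resonance-average orbital parameters; the test suite checks
σ charges against an independent PEOE implementation on saturated molecules
(within 0.05 e).

## Descriptor catalog

The default configuration has 60 groups / 1,284 values:
6 scalars + 9 properties × 3 encoders × {unweighted, VdW-weighted} with
11 (2D autocorrelation, bond distances 0–10), 12 (3D autocorrelation,
0–12 Å, half-open 1 Å bins) and 48 (RDF, r = 0.1–4.8 Å step 0.1, smoothing
B = 100 Å⁻²) bins. Only the totals are externally fixed; bin counts are
configuration-driven (`DescriptorConfig`), and the defaults were chosen so
the catalog reproduces those printed totals exactly.

Conventions: unordered atom pairs count once; self-pairs (p_i²) appear only
in autocorrelation bin 0; RDF sums run over i < j only; pairs beyond the
binned range are ignored; unreachable (disconnected) pairs are skipped. An
all-zero SDF coordinate block means "no geometry", and 3D encoders then
raise instead of computing on a fake origin cluster. Scalars: HBD = N/O
atoms bearing ≥ 1 H, HBA = N/O count, logP by Crippen atomic contributions
and TPSA by Ertl's scheme (both delegated to RDKit), MW with implicit
hydrogens, net formal charge.

Feature normalization for the learners is per-column min-max to [0, 1],
fitted on the training partition only; constant columns map to 0.

## Curation and dataset assembly

HTS campaigns are curated with set algebra over per-assay active/inactive
compound sets: union, intersect and (left-associative) subtract. Inactives
come from the designated primary screen(s) minus the curated actives, so
the output sets are disjoint by construction. The nine benchmark recipes
(PubChem summary assays 435008, 1798, 435034, 2258, 1843, 463087, 488997,
2689, 485290) ship as JSON files encoding the published
confirmatory/counter-screen logic; the real outcome tables are optional
external inputs, and tests exercise the engine on synthetic tables with
planted overlaps and brute-force expected sets.

For descriptor selection the training/monitoring partitions are thinned to
30,000/10,000 randomly chosen inactives (all actives kept; the independent
partition untouched). ANN/SVR training partitions are balanced by cyclic
oversampling of actives up to the inactive count; monitoring and
independent partitions are never oversampled.

## Cross-validation

Compounds are assigned to k stratified partitions per class, keyed by an
MD5 hash of (seed, compound id) — assignments are therefore independent of
row order. Full mode enumerates every ordered (independent, monitoring)
pair: 10 × 9 = 90 splits for k = 10, eight partitions (80% of the data)
training in each, and every compound serves in an independent partition.
The reduced plan used during descriptor selection fixes partition 0 as
independent and cycles the monitoring partition over the remainder; the
default k = 6 yields the 5-split plan (the source wording "5 × 1 = 5 fold"
does not pin the partition count; this choice gives exactly five monitoring
configurations and is configurable).

## Learners

* **ANN** — one hidden layer of 32 sigmoid units, linear output on the
  min-max-normalized target; full-batch gradient descent with learning rate
  η = 0.05 and momentum α = 0.5 ("simple propagation"); the monitoring
  objective (full-range TNR–TPR integral) is checked every 10 epochs and
  training stops after 10 checks without improvement, returning the
  best-on-monitor weights. Architecture and rates are not externally fixed;
  these defaults train the separable fixtures to integral ≥ 0.95 within
  200 epochs. A single-class monitoring partition falls back to negative
  MSE as the objective.
* **ε-SVR** — scikit-learn's RBF-kernel support-vector regression.
  Defaults C = 1, γ = 0.1 (used throughout descriptor selection), ε = 0.1.
  The grid search sweeps C ∈ {2⁻³…2⁹}, γ ∈ {2⁻⁹…2¹}, selects by the
  monitoring TNR–TPR integral, and breaks ties toward smaller C then
  smaller γ.
* **Decision tree** — CART with Gini impurity on binary labels
  (scikit-learn). A leaf scores compounds by its training active fraction
  s; predictions map onto the activity scale as 3 + s·span (span = 3, so a
  pure active leaf predicts 6, the representative active value), which lets
  tree outputs be thresholded and averaged alongside the regressors.
* **Kohonen network** — 10 × 10 grid, 100 epochs, Gaussian neighbourhood
  whose width decays linearly from half the grid diagonal to 0.5, learning
  rate 0.5 → 0.01. The update is a deterministic blended *batch* step
  (nodes move toward their neighbourhood-weighted sample means by the
  scheduled rate) rather than per-sample online updates — same model
  family, orders of magnitude faster in vectorized form, and bit-for-bit
  reproducible per seed. A node predicts the mean training p-activity of
  its captured compounds; empty nodes inherit the value of the nearest
  (grid-distance) occupied node, ties to the lower index.

All training is deterministic given the seed; ANN training logs are
bit-identical across runs.

## Evaluation

The TNR–TPR curve sweeps unique score thresholds in descending order,
treating tied scores as one atomic step; the curve starts at (TPR 0,
TNR 1). Its trapezoidal integral equals the ROC AUC (cross-checked against
an independent rank-statistic computation to < 1e-9); the partial integral
over TPR ∈ [0, tpr_max] (default 0.25, maximum value 0.25) is the
early-recognition objective. Enrichment is precision at the loosest
threshold reaching the TPR target divided by the baseline active fraction;
it is bounded by (P+N)/P. "FR" in the source's specificity formula is read
as FP (an apparent typo).

Consensus prediction is the unweighted mean of predicted p-activities over
the cross-validation models of the chosen method subset; models must share
a descriptor-set fingerprint. `consensus_ranking` evaluates all 2^m − 1
subsets, ranks by ENR (ties: fewer methods first, favouring parsimony) and
reports Diff = 100 · (ENR_best_consensus − ENR_best_single) / ratio, where
ratio is the rounded inactives-to-actives ratio and "best consensus" is the
best subset of ≥ 2 methods — the reading under which a negative Diff (best
single beating every combination) is expressible.

## Descriptor selection

Information gain uses the best single binary threshold (midpoints of
consecutive distinct values) on a column — the standard attribute-IG
rendering for continuous descriptors, which admits an exact enumeration
oracle. F-score is ((x̄⁺−x̄)² + (x̄⁻−x̄)²) / (s⁺² + s⁻²) with n−1
variances; zero denominators yield +inf (separated means) or 0. A group
scores as the maximum over its member columns, so one discriminating bin
promotes the whole group; appending duplicate columns never changes a
score. Since no external rule fixes how many top-ranked groups form the
final set, prefixes of sizes {1, 2, 4, 8, 16, 32, 60} are evaluated under
reduced CV and the argmax is kept (`evaluate_prefix_sizes`).

SFFS starts from the empty set, adds per round the group with the best
mean cross-validated objective (ties to the lower group index), skips and
logs candidates whose training fails, stops after ten rounds without
improvement (or an optional round cap), and returns the best cumulative
set ever seen. The best-so-far objective sequence is non-decreasing by
construction. In the packaged pipeline the wrapper model is the decision
tree (cheapest of the four) scored on the monitoring partitions; the fixed
independent partition is never consulted during selection.

## Synthetic fixtures

The generator emulates the *structure* of a curated HTS campaign, not
chemical realism: random valence-valid bond trees (8–18 heavy atoms) over a
C-rich C/N/O/S/F/Cl alphabet with occasional carbonyls, template geometry
(fixed 1.54 Å bond length, clash-avoiding directions) instead of conformer
search, an activity rule thresholding a named descriptor function (default:
molecular weight at the (1 − f) quantile, f = 0.01 — the low end of the
1:100–1:1000 imbalance range), potencies log-spaced over 0.1–25 µM by rule
margin, inactives at 1 mM, and optional label-flip noise (default 0).
Assay-table scenarios plant known overlaps between primary, confirmatory
and counter screens and return brute-force expected sets.

Because the default rule is a threshold on one scalar descriptor, the
benchmark expectations (the informative group selected in SFFS round one;
ANN/SVR integrals ≥ 0.95; consensus ENR within 1 of the best single
method) test the machinery end to end, but say nothing about performance
on real pharmacophores, where no single descriptor group is sufficient and
label noise is substantial. The standard run uses 5,000 compounds — large
enough for ~50 actives under 1:100 imbalance and stratified 10-fold
partitioning, small enough to run in about a minute on one CPU.

## Numerical choices and degenerate inputs

* Autocorrelation/RDF encoders accept property matrices and are evaluated
  by small dense matrix products; agreement with double-loop oracles is
  exact up to summation order (< 1e-12 relative).
* Half-open 3D bins: a pair exactly at a bin boundary counts in the upper
  bin.
* Single-class curve/enrichment requests raise; an unreachable TPR target
  raises rather than extrapolating.
* Empty active sets from curation warn (a legitimate screen outcome);
  unknown assay ids raise with the offending id named.
* Compounds with fewer class members than partitions, non-positive
  potencies, V3000 records, width-mismatched feature rows and
  fingerprint-mismatched consensus requests all fail loudly.
* Molecules that fail featurization are excluded row-wise with a logged
  per-molecule report; unparseable SDF records are skipped and counted.

## Known limitations

* No conformer generation: 3D descriptors use whatever coordinates the
  input provides (or the fixtures' template geometry); aromaticity is
  taken from input bond flags, and stereochemistry is ignored.
* The π/lone-pair electronegativity tables and the VC2003 substitute are
  approximations; descriptor *values* are therefore not comparable across
  implementations, though all invariances and conventions are enforced.
* Study-scale results on the nine public PubChem campaigns require those
  datasets as external inputs; nothing in the package fetches data.
* Fragment/substructure fingerprints (ECFP-style) are out of scope.
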