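# chemscreen

Ligand-based virtual screening for high-throughput screening (HTS) campaigns:
a QSAR (quantitative structure–activity relationship) toolkit that encodes
small molecules as fixed-length descriptor vectors, curates noisy HTS assay
outcomes into labelled datasets, trains four orthogonal machine-learning
models under a bespoke cross-validation design, and evaluates them with
early-recognition metrics tailored to the extreme class imbalance of real
screens (1 active per 100–1,000 compounds).

It is aimed at cheminformaticians and probe-development groups who want to
rank a compound library by predicted activity so that only an enriched
fraction needs to be tested experimentally.

## What it computes

**Descriptors.** Each molecule becomes a 1,284-value vector in 60 atomically
selectable groups: six scalars (MW, H-bond donors/acceptors, Crippen logP,
net charge, Ertl TPSA) plus, for each of nine per-atom chemical properties
(atom identity; σ/π/total partial charges from a damped partial-equalization
(PEOE) iteration; σ/π/lone-pair orbital electronegativities; effective
polarizability; a total-charge stand-in for the VC2003 charge), three
transformation-invariant encoders, unweighted and van-der-Waals-surface
weighted:

* 2D autocorrelation (Moreau–Broto): `AC(d) = Σ_{i<j, d_ij=d} p_i p_j`
  over topological distance d (11 bins; self-pairs in bin 0),
* 3D autocorrelation over Euclidean distance (12 × 1 Å bins),
* radial distribution function
  `g(r_k) = Σ_{i<j} p_i p_j exp(−B (r_k − d_ij)²)`, r = 0.1…4.8 Å,
  B = 100 Å⁻².

**Labels.** Activity is regressed on the pIC50/pEC50 scale
`pIC50 = −log10(IC50 / 1 M)`: inactives 3 (1 mM), measured actives 4.6–7
(25–0.1 µM), unmeasured actives a representative 6 (1 µM).

**Models.** ANN (one sigmoid hidden layer, simple-propagation updates with
learning rate η and momentum α, early termination on a monitoring
partition), ε-SVR (RBF kernel, C = 1, γ = 0.1 during selection, then grid
search), a Gini decision tree whose leaves score by training active
fraction, and a Kohonen self-organizing map with a Gaussian neighbourhood.

**Validation and metrics.** Data are split into k = 10 stratified partitions;
every ordered (independent, monitoring) pair gives 10 × 9 = 90 training
configurations (descriptor selection uses a reduced 5-split plan). Model
quality is the integral of the TNR–TPR curve (the ROC curve rotated 90°
clockwise; 0.5 for a random predictor), its partial integral over
TPR ∈ [0, 0.25], and enrichment — precision at the TPR cutoff divided by
the library's baseline active fraction. Consensus predictors average the
predicted p-activities of any subset of the four model types and are ranked
by enrichment.

**Descriptor selection.** Per-column information gain (best binary
threshold) and F-score filters, and sequential forward feature selection
(SFFS) — a greedy wrapper over descriptor groups with a ten-round patience
rule.

## Worked example

```python
import numpy as np
from chemscreen import DescriptorConfig, assemble_feature_matrix, rank_groups
from chemscreen.synthetic import FixtureSpec, generate_library, generate_activity
from chemscreen.activity import QsarDataset
from chemscreen.pipeline import reduced_cv_sffs, train_selected_methods
from chemscreen.learners import predict
from chemscreen.evaluation import tnr_tpr_curve, consensus_ranking

spec = FixtureSpec(n_compounds=1000, seed=7, base_active_fraction=0.02)
library = generate_library(spec)
records = generate_activity(library, spec)
features = assemble_feature_matrix(library, DescriptorConfig.default())
labels = np.array([r.is_active for r in records])

dataset = QsarDataset(features=features, records=records)
traj = reduced_cv_sffs(dataset, seed=7, max_rounds=1)
models, independent = train_selected_methods(dataset, traj.selected_groups, seed=7)
for method, ms in models.items():
    auc = tnr_tpr_curve(predict(ms[0], independent["x"]), independent["labels"]).integral()
    print(f"{method}: independent TNR-TPR integral {auc:.3f}")
cr = consensus_ranking(models, independent["x"], independent["labels"])
best = cr.rows[0]
print(f"best subset {'+'.join(best.methods)}: ENR {best.enr:.1f}")
```

prints

```
ANN: independent TNR-TPR integral 1.000
SVM: independent TNR-TPR integral 1.000
DT: independent TNR-TPR integral 1.000
KN: independent TNR-TPR integral 0.969
best subset ANN: ENR 50.0
```

The fixture's activity rule thresholds molecular weight, so SFFS selects the
`weight` scalar group in round one; all four learners then separate actives
almost perfectly on the held-out independent partition, and the best
predictor reaches the theoretical maximum enrichment (1 / active fraction =
50) at the TPR 0.25 cutoff.

The same stages are available from the shell:

```bash
chemscreen fixtures --n 1000 --seed 7 --out-dir run/
chemscreen featurize --sdf run/library.sdf --out run/features.csv
chemscreen select --features run/features.csv --activity run/activity.csv \
    --method IG --out run/ranking.tsv
chemscreen split --k 10 --mode full --out run/plan.json
chemscreen train --features run/features.csv --activity run/activity.csv \
    --method DT --groups weight --out run/dt.joblib
chemscreen evaluate --model run/dt.joblib --features run/features.csv \
    --activity run/activity.csv
```

Every command writes a JSON manifest (configuration, seeds, version) next
to its outputs.

## Layout

* `chemscreen.molgraph` — molecular graph model, SDF (V2000) I/O,
  topological distances
* `chemscreen.atom_properties` — PEOE charges, electronegativities,
  polarizability, VdW surface areas
* `chemscreen.descriptors` — encoders, descriptor catalog, feature matrices
* `chemscreen.activity` — pIC50 labelling, assay set-algebra curation
  (the nine benchmark recipes ship as JSON), dataset statistics
* `chemscreen.crossval` — 10 × 9 and reduced cross-validation plans
* `chemscreen.feature_selection` — IG, F-score, SFFS
* `chemscreen.learners` — ANN, ε-SVR, decision tree, Kohonen network
* `chemscreen.evaluation` — TNR–TPR curves, enrichment, consensus
* `chemscreen.synthetic` — deterministic fixture generators
* `chemscreen.pipeline` / `chemscreen.cli` — orchestration and CLI

See `docs/methods.md` for the modelling choices and their rationale.
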