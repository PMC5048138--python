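# phosthr

Prediction of phosphothreonine sites in proteins from fused sequence,
structure and physicochemical features.

Protein kinases phosphorylate threonine residues in specific sequence and
structural contexts. Given protein sequences, per-residue secondary
structure / solvent accessibility annotations and a table of
experimentally confirmed phosphothreonines, `phosthr` builds 31-residue
threonine-centered windows (signed offsets −15…+15), characterizes what
distinguishes phosphorylated from non-phosphorylated contexts, and trains
and evaluates an RBF-kernel SVM classifier. A bundled synthetic-data
generator emulates the known signatures of phosphothreonine contexts
(proline enrichment at +1, loop preference and elevated accessibility near
the site), so the entire pipeline is testable without any downloads.

## Method

**Position conservation.** For a set of aligned windows, the conservation
of position *l* is the relative entropy (bits) against a uniform
background *p*₀ = 0.05:

    M(l) = Σᵢ fᵢ(l) · log₂( fᵢ(l) / p₀ )

where *fᵢ(l)* is the frequency of residue *i* at position *l* (X/padding
excluded). M(l) = 0 iff the column is background-distributed; a fully
conserved column attains log₂ 20 ≈ 4.32 bits.

**Position scoring (F1).** Class-specific position weight matrices hold
pseudocount-smoothed log-ratio weights

    w(x, l) = log₂( (n_xl + α·p₀·N_l) / ((N_l + α·N_l·Σp₀) · p₀) )

built separately from positive and negative windows (α = 1 by default).
A query window scores F(l) = w₊(x_l, l) − w₋(x_l, l) at each flank
offset; large positive F(l) marks phosphothreonine-like contexts.

**Feature groups.** Each window yields four groups at independent window
sizes *w* (flanking residues, center excluded): F1 position scores
(*w* values), F2 secondary structure + scaled accessibility (2·*w*),
F3 physical properties — rigidity, flexibility, irreplaceability
(3·*w*), and F4 chemical properties — hydrophobicity, hydrophilicity,
mass, pK₁, pK₂, pI (6·*w*). At the default sizes (12, 12, 24, 18) the
full vector has 12 + 24 + 72 + 108 = **216 dimensions**.

**Selection and evaluation.** Classes are balanced by k-means
undersampling (one nearest-to-centroid representative per cluster);
features are ranked by mRMR (mutual-information difference criterion) and
pruned by incremental feature selection (IFS); the classifier is an
RBF-SVM evaluated by jackknife (leave-one-out) ROC analysis, with
hyperparameters (C, γ) searchable over C ∈ {2⁻⁵…2¹⁵}, γ ∈ {2⁻¹⁵…2⁻⁵}.

## Worked example

Run the full pipeline on a small synthetic dataset (30 positive + 90
negative sites, balanced to 30 + 30, compact 48-feature encoding):

```python
from phosthr.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(
    simulate_preset="small", seed=5, balance_k=30,
    windows={"w1": 4, "w2": 4, "w3": 4, "w4": 4}, run_ifs=True,
)
summary = run_pipeline(config, "demo_run")
print(summary)
```

prints

```
{'n_positive_raw': 30, 'n_negative_raw': 90, 'n_per_class_balanced': 30,
 'window_sizes': {'w1': 4, 'w2': 4, 'w3': 4, 'w4': 4}, 'n_features': 48,
 'best_k': 4, 'auroc': 0.9655555555555556, 'config_hash': '10792682f02ce961'}
```

Reading: 30 phosphothreonine and 90 other threonine windows were built,
undersampled to a 30 + 30 benchmark, and encoded into 48 features; IFS
found that the top 4 mRMR-ranked features already maximize the jackknife
auROC, which reaches 0.966 — the generator's planted signal (strong
proline/loop/accessibility effects near the center) is easily recovered.
The run directory holds every artifact (`features.csv`, `ranking.tsv`,
`ifs_curve.tsv`, `eval.json`, `summary.json`, the resolved config and its
hash), sufficient to re-derive every number.

The same stages are available as a CLI:

```bash
phosthr simulate --preset small --seed 5 --out data/
phosthr profile --dataset data/ --out stats.tsv
phosthr encode --dataset data/ --out features.csv
phosthr select --features features.csv --ranking-out ranking.tsv --ifs-out ifs.tsv
phosthr evaluate --features features.csv --out eval.json
phosthr run --config config.yaml --out run/
```

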