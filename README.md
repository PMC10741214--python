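# thermofoot

Early diabetic-foot screening from plantar infrared thermograms: angiosome
temperature features, dropout-based neural feature ranking, and SVM
classification — with a synthetic-phantom generator so the whole pipeline is
testable without patient data.

## The problem

Diabetic feet lose the symmetric, "butterfly-like" plantar temperature pattern
of healthy feet: perfusion changes produce left–right asymmetry and focal hot
spots long before ulcers appear. Screening pipelines therefore summarize a
plantar thermogram into region-level temperature statistics and ask a
classifier to separate diabetic from healthy subjects. This package implements
that pipeline end to end:

1. **Decoding** — thermograms arrive as 8-bit grayscale images with a per-image
   temperature range (t_min, t_max); pixel temperature is
   T = t_min + g/255 · (t_max − t_min). Pixels below an 18 °C floor are
   discarded as non-tissue.
2. **Angiosomes** — each foot is split into the four plantar arterial
   territories (MPA, LPA, MCA, LCA). Subjects with any empty angiosome after
   the floor are excluded.
3. **Features** — a named 188-feature vector per subject: per-region moments
   (mean, std, max, min, skew, kurtosis), hot spot estimator (HSE), estimated
   temperature and its left–right difference (ET, ETD), thermal change index
   (TCI) and normalized temperature range classes (NTR_C1..C5).
4. **Selection** — Pearson pruning of |r| > 0.95 pairs, then ranking by four
   approaches: lasso, random forest, and two neural selectors — a **concrete
   dropout** input gate (relaxed-Bernoulli keep-probabilities p_i with an
   L0-style penalty λ·Σp_i) and **variational dropout** (multiplicative
   Gaussian input noise ξ_i ∼ N(1, α_i); large learned α_i marks a prunable
   feature). Scores are averaged over stratified 5-fold CV; a min-rank
   consensus collects features every approach ranks inside 50.
5. **Classification** — SMOTE balances the case-heavy cohorts (each synthetic
   minority sample is x + u·(x_nn − x) toward a minority neighbor); an
   RBF-kernel SVM (standard γ = 0.1, C = 1, or randomized-search optimized) is
   scored by accuracy/precision/recall/F1 over 5 folds.

The synthetic module supplies both thermal phantoms (foot-shaped blobs with
configured angiosome temperatures, asymmetry, hot spots and sensor noise) and
planted feature tables whose informative columns separate the classes by a
known standardized effect d (single-feature AUC = Φ(d/√2)), which anchor the
recovery benchmarks.

## Worked example

Rank a planted table at the published 88:34 imbalance (141 features, 10
informative at effect size 3):

```python
import numpy as np
from thermofoot.synthetic import PlantedTableConfig, generate_planted_table
from thermofoot.balance import smote, fit_eval_svm, SvmConfig
from thermofoot.selection import make_rankers, SelectorConfig, CorrelationFilter, consensus

cfg = PlantedTableConfig(n_majority=88, n_minority=34, n_features=141,
                         n_informative=10, effect_size=3.0, seed=1)
table, informative = generate_planted_table(cfg)
X, y = table.drop(columns="label"), table["label"].to_numpy()
Xb, yb = smote(X, y, k_neighbors=5, random_state=1)
print("class counts after SMOTE:", np.bincount(yb))

X_red = CorrelationFilter(threshold=0.95).fit(Xb).transform(Xb)
rankings = {}
for name, ranker in make_rankers(SelectorConfig(seed=1)).items():
    ranker.fit(X_red, yb)
    rankings[name] = ranker.ranked_features_
    hits = len(set(ranker.top_k(10)) & set(informative))
    print(f"{name}: {hits}/10 planted features in top 10")

top = rankings["lasso"][:10]
rep = fit_eval_svm(Xb, yb, feature_subset=top,
                   config=SvmConfig(mode="standard", gamma=0.1, C=1.0, seed=1))
acc, sd = rep.metrics["accuracy"]
print(f"standard SVM accuracy on lasso top-10: {acc:.4f} ± {sd:.4f}")
```

Output:

```
class counts after SMOTE: [88 88]
lasso: 9/10 planted features in top 10
random_forest: 10/10 planted features in top 10
concrete_dropout: 10/10 planted features in top 10
variational_dropout: 10/10 planted features in top 10
standard SVM accuracy on lasso top-10: 1.0000 ± 0.0000
```

SMOTE raises the 34-sample minority to 88 per class; every ranking approach
recovers at least 9 of the 10 planted features, and the SVM separates the
classes perfectly — expected at effect size 3, where each informative feature
alone has AUC ≈ 0.983.

The full image pipeline runs from the shell:

```bash
thermofoot simulate --out-dir cohort --n-diabetic 88 --n-healthy 34 --seed 1
thermofoot extract  --manifest cohort/manifest.csv --out features.csv
thermofoot run-all  --out-dir bundle --seed 1   # phantoms → rankings → consensus → SVM reports
```

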