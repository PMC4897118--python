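"""Train a K-FIS classifier and inspect its predictions.

Full single-split workflow: impute, rank genes on the training half,
min-max normalize with training statistics, fit the kernel TSK rule base,
and score the held-out half.
"""

import numpy as np

from kfis import (
    KernelSpec,
    KSCParams,
    SyntheticSpec,
    apply_normalization,
    confusion,
    fit,
    generate,
    impute_missing,
    metrics,
    minmax_normalize,
    predict_proba,
    select_features,
    t_test_rank,
)

X, y, _ = generate(SyntheticSpec(n_genes=200, n_informative=10,
                                 effect_size=3.0, missing_rate=0.02, seed=2))
X = impute_missing(X)
y = y.to_numpy()

train = np.arange(72) % 2 == 0  # alternate samples -> both classes present
test = ~train

ranking = t_test_rank(X.iloc[train], y[train])
genes = select_features(ranking, 10)
Xtr, table = minmax_normalize(X.iloc[train][genes])
Xte = apply_normalization(X.iloc[test][genes], table)

model = fit(Xtr, y[train], KernelSpec("rbf", gamma=0.5),
            KSCParams(cluster_radius=0.5))
print(f"rule base: {model.n_rules} fuzzy rules over {len(genes)} genes")

proba = predict_proba(model, Xte.to_numpy())
pred = (proba >= 0.5).astype(int)
rep = metrics(confusion(y[test], pred))
print(f"held-out accuracy {rep.accuracy:.4f}, precision {rep.precision:.4f}, "
      f"recall {rep.recall:.4f}, specificity {rep.specificity:.4f}")
print("probabilities are the logistic of the firing-strength-weighted "
      "rule outputs; 0.5 is the decision threshold")
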