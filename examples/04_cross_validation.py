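"""Interleaved 10-fold cross-validation and radius selection.

Pools held-out predictions from every fold into one confusion matrix over
all 72 samples — feature selection and normalization are redone inside
each training fold — then selects the cluster radius by the per-fold
winner's median on a small grid.
"""

from kfis import (
    KernelSpec,
    KSCParams,
    SyntheticSpec,
    cross_validate,
    generate,
    interleaved_cv_plan,
    metrics,
    model_select,
)

X, y, _ = generate(SyntheticSpec(n_genes=200, n_informative=10,
                                 effect_size=2.0, seed=3))
plan = interleaved_cv_plan(72, 10)
spec = KernelSpec("rbf", gamma=0.5)

for k in (5, 10, 20):
    res = cross_validate(X, y.to_numpy(), spec, KSCParams(cluster_radius=0.5),
                         plan, k)
    rep = metrics(res.pooled)
    cm = res.pooled
    print(f"F{k:<3d} pooled accuracy {rep.accuracy:.4f} "
          f"(TP={cm.tp} TN={cm.tn} FP={cm.fp} FN={cm.fn})")

ra, gamma, report = model_select(X, y.to_numpy(), spec,
                                 r_a_grid=[0.3, 0.5, 0.7],
                                 gamma_grid=[0.25, 0.5, 1.0],
                                 plan=interleaved_cv_plan(72, 5),
                                 k_features=10)
print(f"selected r_a={ra}, gamma={gamma} "
      f"(median of per-fold winners over a {3}x{3} grid)")
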