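"""Kernel subtractive clustering on two Gaussian blobs.

Density-based centroid selection through a kernel: each point's potential
sums Gaussian-decaying contributions from every other point, measured by
feature-space distance.  Two tight, well-separated blobs should give
exactly two rule centroids, one per blob, for any sensible radius.
"""

from kfis import KernelSpec, KSCParams, generate_blobs, ksc_cluster

X = generate_blobs(n_clusters=2, points_per_cluster=20, separation=0.8,
                   dim=2, seed=1, cluster_sd=0.03)

for name in ("linear", "rbf"):
    spec = KernelSpec(name, gamma=0.5)
    for ra in (0.3, 0.5, 0.7):
        model = ksc_cluster(X, spec, KSCParams(cluster_radius=ra))
        blobs = sorted({i // 20 for i in model.centroid_indices})
        print(f"{name:6s} kernel, r_a={ra}: {model.n_rules} centroids "
              f"(one in each blob: {blobs == [0, 1]})")
print("first centroid always has the maximal initial potential; "
      "every centroid is an actual data point")
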