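"""Detect the binding force threshold from pooled force-fluorescence points.

Generates pooled (force, normalized I_ABD/I_actin) points with a sigmoidal
step at 1.8 pN, finds the K-means (k = 2) force threshold, checks the
silhouette scores for k in {2, 3, 4}, and compares the ratio distributions
below and above the detected threshold with a KS test.  A flat-response
control shows the null behavior.
"""

from forcebind.stats_core import ks_two_sample
from forcebind.synth_fixtures import synth_force_response_points
from forcebind.trap_analysis import kmeans_force_threshold, split_by_threshold

points, f_th = synth_force_response_points(n_points=200, f_th=1.8, seed=7)
res = kmeans_force_threshold(points, seed=7)
print(f"true threshold: {f_th} pN, detected: {res.threshold_force:.2f} pN "
      f"(force-separating clusters: {res.separating})")
print("silhouette by k:", {k: round(v, 3) for k, v in res.silhouette_by_k.items()})

below, above = split_by_threshold(points, res.threshold_force)
ks = ks_two_sample(below, above)
print(f"below: n = {below.size}, above: n = {above.size}; "
      f"KS D = {ks.statistic:.3f}, p = {ks.p_value:.2e} ({ks.method})")

flat, _ = synth_force_response_points(n_points=200, dr=0.0, seed=7)
b, a = split_by_threshold(flat, 1.8)
ks0 = ks_two_sample(b, a)
print(f"flat control: KS p = {ks0.p_value:.2f} (no force dependence)")

print("\nThe silhouette maximum at k = 2 supports a single threshold; the")
print("significant KS difference appears only when binding is force-activated.")
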