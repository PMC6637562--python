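"""UPGMA clustering of the reference phosphoproteins on |RC| distances.

Rebuilds the relative-change coefficients from the reference summary,
clusters the 32 significant phosphoprotein spots with UPGMA on
d(i, j) = ||RC_i| - |RC_j||, cuts the dendrogram at the root into the two
major clusters and reports each cluster's mean |RC| with a 99% BC
percentile bootstrap CI.
"""

from phosphogel import (clusters_differ, records_from_means, reference,
                        to_newick, two_cluster_summaries)

ref = reference.load_significant_spots()
records = records_from_means(ref, "pr_dfd_mean", "pr_c_mean")
rc_by_protein = {ref.loc[r.spot_id, "protein"]: r.rc for r in records}

tree, summaries = two_cluster_summaries(rc_by_protein, conf=0.99,
                                        n_boot=20_000, seed=7)
for s in summaries:
    lo, hi = s.ci
    print(f"cluster {s.cluster_id}: n = {len(s.members):2d}, "
          f"mean |RC| = {s.mean_abs_rc:.2f}, 99% CI [{lo:.2f}, {hi:.2f}]")
    print("   " + ", ".join(sorted(s.members)))
print("cluster means differ (CIs disjoint):",
      "yes" if clusters_differ(summaries) else "no")
print("\nnewick:", to_newick(tree)[:120], "...")
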