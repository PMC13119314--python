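"""Localization indices over a time course, clustered by temporal shape.

Genes are planted as "rising" (steadily increasing compartment
association), "peaked" (transient association) or flat. LI = log2 of the
compartment-to-cytoplasm editing-efficiency ratio; rows are z-scored and
clustered by UPGMA under correlation distance.
"""

import pandas as pd

from rlpkit import (
    SimulationTruth, cluster_trajectories, localization_index,
    simulate_timecourse, upgma_cluster, zscore_rows,
)

truth = SimulationTruth(seed=2, n_genes=150, frac_rising=0.5, frac_peaked=0.5)
by_tp, cytoplasm, classes = simulate_timecourse(truth)

li_cols = {}
for tp, profiles in by_tp.items():
    records, _ = localization_index(profiles, cytoplasm)
    li_cols[tp] = pd.Series({r.gene_id: r.li for r in records})
li = pd.DataFrame(li_cols)
print(f"LI matrix: {li.shape[0]} genes x {li.shape[1]} timepoints "
      f"(worked identity: eff 0.1 vs 0.025 gives LI = 2)")

z, dropped = zscore_rows(li)
dend = upgma_cluster(z, k=2)
agreement = (pd.crosstab(classes.loc[z.index], dend.labels)
             .max(axis=1).sum() / len(z))
print(f"k=2 UPGMA recovers the planted classes for {agreement:.1%} of genes")

traj = cluster_trajectories(z, dend.labels)
for c, grp in traj.groupby("cluster"):
    means = " ".join(f"{v:+.2f}" for v in grp.sort_values("timepoint")["mean"])
    print(f"cluster {c} mean z-scored LI per timepoint: {means}")
print("A monotone row is the rising class; an interior maximum is the "
      "transiently associated (peaked) class.")
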