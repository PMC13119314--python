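"""Detained-intron ratios across cell-cycle phases.

The intron ratio (intron coverage over the mean of its flanking exon
coverages) measures nuclear intron detention per cell. Here intron 1
carries a planted 10x higher retention in S phase than in G2/M, the
signature of regulated post-transcriptional splicing.
"""

from rlpkit import SimulationTruth, simulate_intron_coverage
from rlpkit.intron_ratio import compare_groups, intron_ratio
from rlpkit.transcript_io import TranscriptModel

model = TranscriptModel("ZW-like", "ZW-like.t1", "chr_demo", "+",
                        ((0, 150), (300, 450), (600, 750)))
truth = SimulationTruth(seed=5, retention_by_phase={"S": 1.0, "G2M": 0.1})
coverage, phase = simulate_intron_coverage(truth, model, n_cells_per_phase=50)

for k in (1, 2):
    ratios, undefined = intron_ratio(coverage, model, k)
    res = compare_groups(ratios, phase)
    fold = res["fold_change"] if res["group_a"] == "S" else 1 / res["fold_change"]
    print(f"intron {k}: median ratio S = "
          f"{res['median_a'] if res['group_a'] == 'S' else res['median_b']:.2f}, "
          f"G2M = {res['median_b'] if res['group_a'] == 'S' else res['median_a']:.2f}; "
          f"S/G2M fold change {fold:.1f}, Mann-Whitney p = {res['pvalue']:.1e}")
print("A fold change near the planted 10x with a tiny p indicates the "
      "intron is detained in S phase and spliced out by G2/M.")
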