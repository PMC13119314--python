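"""Single-cell detection-rate heterogeneity against the shuffle null.

Simulates 60 cells x 300 genes where 20% of genes are edited only in a
10% cell subset, then asks whether the observed per-gene detection rates
(fraction of cells with >=3 edits) deviate from an expression-matched
null in which each cell's edit total is reassigned across genes
proportionally to TPM.
"""

from rlpkit import SimulationTruth, detection_rate_analysis, simulate_cells

hetero = SimulationTruth(seed=3, n_genes=300, n_cells=60,
                         core_fraction=0, rare_fraction=0,
                         hetero_fraction=0.2)
m, truth = simulate_cells(hetero)
res = detection_rate_analysis(m, n_shuffles=3, seed=4)

print("detection-rate bin:    " + " ".join(f"{i*10:>4d}%" for i in range(1, 11)))
print("observed gene counts:  " + " ".join(f"{c:>5d}" for c in res.observed))
print("shuffled mean (n=3):   " + " ".join(f"{v:>5.1f}" for v in res.shuffled_mean))
print(f"{res.n_zero_rate} genes had no edited cell and are excluded")
print(f"chi-square GOF: statistic {res.chi2:.1f}, df {res.df}, "
      f"p = {res.pvalue:.2e}")
print("A small p means detection heterogeneity exceeds what transcript "
      "abundance alone explains, i.e. genuine cell-to-cell localization "
      "differences.")

null = SimulationTruth(seed=5, n_genes=300, n_cells=60,
                       core_fraction=0, rare_fraction=0)
m0, _ = simulate_cells(null)
res0 = detection_rate_analysis(m0, n_shuffles=3, seed=6)
print(f"Null-generated control dataset: p = {res0.pvalue:.2f} "
      "(should not be significant)")
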