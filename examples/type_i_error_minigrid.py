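"""Estimate Type I error rates over a small design grid.

Runs 500 null replicates per condition on a 2x2 grid (K clusters x ICC) at
N=30 subjects per cluster and tabulates the empirical rejection rate of
each test at alpha = .05.  With more replicates (the package default is
10,000) the pattern sharpens: the LRT and residual-DF Wald test are
anti-conservative at small K and large ICC, while between-within and
Satterthwaite stay at or below the nominal level.
"""

from crtlmm import SimulationGrid, results_to_frame, run_grid

grid = SimulationGrid(
    K_values=(10, 40),
    N_values=(30,),
    sigma_b2_values=(0.01, 0.5),
    replicates=500,
    alpha=0.05,
    master_seed=7,
)
results = run_grid(grid)

table = results_to_frame(results).pivot_table(
    index=["K", "sigma_b2"], columns="method", values="tie"
)
order = ["wald_between_within", "wald_satterthwaite", "wald_residual", "wald_z",
         "lrt", "cluster_means_ttest"]
print(table[order].round(3).to_string())

mc_se = (0.05 * 0.95 / grid.replicates) ** 0.5
print(f"\nMonte Carlo SE at the nominal level: ~{mc_se:.3f} per entry.")
print("Within every row TIE(between-within) <= TIE(Satterthwaite) <= TIE(residual)")
print("<= TIE(z) holds exactly: the tests reject nested sets of datasets.")
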