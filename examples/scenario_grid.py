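"""The 30-scenario factorial study grid at 80% power.

Crosses five AUC differences (0.02-0.10 above a 0.80 baseline), three
inter-test correlations (0.3/0.5/0.8) and both data types, and prints the
per-group case counts with the min/max spread.
"""

from rocpower import ScenarioGrid, run_grid

result = run_grid(ScenarioGrid(powers=(0.80,)))
table = result.table.pivot_table(
    index=["delta_auc", "rho"], columns="data_type", values="n_pos"
).astype(int)
print("cases per group for 80% power:")
print(table.to_string())

s = result.summary()[0.80]
print()
print(
    f"most demanding cell needs {s['n_pos_max']} cases/group, the most "
    f"efficient {s['n_pos_min']} — a {s['fold_ratio']}-fold spread driven "
    "entirely by design choices (effect size, correlation, data type)."
)
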