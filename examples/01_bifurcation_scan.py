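"""Regime structure of the GAL switch along the glucose axis.

Scans glucose at fixed galactose (150 nM) with the default parameter set
and prints the regime at each grid point plus the two saddle-node
thresholds.  Between the thresholds the circuit is bistable: whether a cell
is induced depends on its history, which is what produces transient
bimodality in a population consuming glucose.
"""

import numpy as np

from galswitch import bifurcation_scan, default_params

params = default_params("repressor")
grid = np.geomspace(2.0, 500.0, 24)
diag = bifurcation_scan(params, gal_fixed=150.0, glu_grid=grid)

print("glucose (nM)   regime")
for glu, regime in zip(diag.glu_grid, diag.regime_per_point):
    print(f"{glu:12.1f}   {regime}")
print()
print(f"lower saddle-node glu_low*  = {diag.glu_low_star:.2f} nM")
print(f"upper saddle-node glu_high* = {diag.glu_high_star:.2f} nM")
print()
print("Below glu_low* every cell switches ON (coherent activation); between")
print("the thresholds ON and OFF states coexist; above glu_high* the")
print("repressed state is the only one available.")
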