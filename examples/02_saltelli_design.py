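"""Saltelli radial design: N(2k+2) model-input rows from a Sobol' stream.

Shows that base sample 128 reproduces the three reference experiment sizes
(2560, 1536 and 2304 runs for 9, 5 and 8 free factors).
"""

import numpy as np

from fallowsim import saltelli_design, sobol_sequence

print("first Sobol' points in 2-d:", sobol_sequence(2, 4).tolist())

for k in (9, 5, 8):
    d = saltelli_design(k, 128)
    print(f"k={k} free factors, N=128 -> {d.n_rows} rows")

d = saltelli_design(3, 8)
print("\ncross-block check (AB_0 vs A, second row):")
print("  A[1]   =", np.round(d.A[1], 3))
print("  B[1]   =", np.round(d.B[1], 3))
print("  AB_0[1]=", np.round(d.AB[0][1], 3), " (column 0 replaced from B)")
# Evaluating the model over all rows yields both first-order and
# total-effect variance shares for every factor at once.
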