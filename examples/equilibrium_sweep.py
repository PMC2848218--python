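"""Equilibrium response of the frontostriatal circuit to PFC activity.

Solves the normalized fixed point across a range of PFC activities for
several strengths of the presynaptic D2 heteroreceptor effect (b) and
prints the DA release at modest PFC activation.
"""

import numpy as np

from frontostriatal import CircuitParams, enhancement_percent, solve_equilibrium, sweep_equilibrium

params = CircuitParams(j_d=1.0)
grid = np.linspace(0.1, 0.9, 9)
curves = sweep_equilibrium(params, grid, b_values=[0.0, 0.25, 0.5, 0.75, 1.0])
print(curves.pivot(index="x_p", columns="b", values="y").round(3))
# Each column is Y(X_p) for one heteroreceptor strength: lower PFC activity
# disinhibits the midbrain DA nuclei and raises striatal DA release, and
# stronger D2 heteroreceptor feedback amplifies the elevation.

y0 = solve_equilibrium(params.with_(b=0.0), 0.7).y
y1 = solve_equilibrium(params.with_(b=1.0), 0.7).y
y_auto = solve_equilibrium(params.with_(a=0.2, b=1.0), 0.7).y
print(f"\nAt X_p = 0.7: Y = {y0:.3f} (b=0), {y1:.3f} (b=1), {y_auto:.3f} (a=0.2, b=1)")
print(f"Heteroreceptor elevation: {enhancement_percent(y1, y0):.0f}%")
print(f"With autoreceptor damping: {enhancement_percent(y_auto, y0):.0f}%")
# The heteroreceptor alone raises DA release by ~83%; adding autoreceptor
# suppression (a = 0.2) pulls the elevation back to ~66%.
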