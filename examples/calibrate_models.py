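"""Calibrate patient/control models from published depletion imaging.

Loads the packaged table of striatal D2 occupancies, averages the
healthy-control studies, extrapolates the patient occupancy, and shows the
implied SZ-HC differences in synaptic efficacy and PFC activity.
"""

import numpy as np

from frontostriatal import (
    average_hc_occupancy,
    extrapolate_sz_occupancy,
    load_occupancy_table,
    model_1,
    model_2,
    sz_hc_differences,
)

records = load_occupancy_table()
hc_avg = average_hc_occupancy(records)
m1, m2 = model_1(), model_2()
print(f"HC average occupancy across studies: {100 * hc_avg:.1f}%")
print(f"Extrapolated SZ occupancy (Model 1 ratio): {100 * extrapolate_sz_occupancy(hc_avg, m1):.1f}%")

for m in (m1, m2):
    print(f"\n{m.label}:")
    for name, s in (("HC", m.hc), ("SZ", m.sz)):
        print(f"  {name}: B_max={s.b_max:.1f}  P={100 * s.occupancy:.1f}%  Y={s.y:.3f}")
# Y is the extracellular DA level in units of the D2 dissociation constant;
# patients carry both more receptors (B_max 1.2) and more DA.

df = sz_hc_differences(m1, a_values=[0.0, 0.2], b_grid=np.linspace(0, 1, 6))
print("\nModel 1 SZ-HC differences (negative delta_x_p = hypofrontality):")
print(df.round(4).to_string(index=False))
# delta_v_ps (efficacy difference) depends only on b; delta_x_p grows more
# negative as either D2 effect strengthens.
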