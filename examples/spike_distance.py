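"""Victor-Purpura spike-train distance in three regimes.

The VPd edit distance deletes/inserts spikes at cost 1 and shifts them at
cost q per ms.  Small q compares spike counts; large q demands coincidence.
"""

import numpy as np

from tactilesnn import vp_distance

a = np.array([10.0, 20.0, 30.0])
b = np.array([12.0, 20.0, 95.0])

for q in (0.0, 0.1, 1.0, 10.0):
    d = vp_distance(a, b, q=q)
    print(f"q = {q:5.1f} / ms: VPd = {d:.2f}")

print("\nq=0 sees equal counts (distance 0); at q=1 the 2 ms shift costs 2.0"
      "\nbut the 30 vs 95 ms spikes are cheaper to delete+insert (cost 2);"
      "\nlarge q treats every non-coincident spike as delete+insert.")
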