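"""Baseline EDL potential and ionic current across electrolytes.

Sweeps four 1:1 electrolytes over seven decades of concentration and prints
the predicted baseline-state EDL potential (V_bs) and transmembrane current
(I_bs) for a 2.3 nm-radius pore.  Expect every |V_bs| column to decrease as
the concentration rises, the polarity to stay opposite to the (cation)
majority ion, and different salts to offset the curves vertically.
"""

import numpy as np

import poresig as ps

pore = ps.NanoporeGeometry(r_np=2.3e-9)
salts = [("Na+", "F-"), ("K+", "Cl-"), ("Na+", "Cl-"), ("Li+", "F-")]

header = "conc (M)   " + "".join(f"{c}/{a:<12}" for c, a in salts)
print("V_bs (mV) per electrolyte")
print(header)
for conc in np.logspace(-7, -1, 7):
    row = f"{conc:8.1e}   "
    for cation, anion in salts:
        v = ps.predict_Vbs(ps.binary_solution(cation, anion, float(conc)), pore)
        row += f"{v * 1e3:+7.3f}      "
    print(row)

print("\nI_bs (nA) at 1 mM per electrolyte")
for cation, anion in salts:
    st = ps.baseline_state(ps.binary_solution(cation, anion, 1e-3), pore)
    print(
        f"  {cation}/{anion}: V_bs = {st.V_bs*1e3:+.3f} mV, "
        f"I_bs = {st.I_bs*1e9:+.4f} nA, majority ion = {st.majority.name}"
    )
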