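"""Forward-model signal pairs for small-molecule analytes.

Predicts the perturbed-state EDL potential signal (V_ps) and ionic current
signal (I_ps) for the four validation analytes in 1 mM NaF.  The potential
signals fall within +/-1 mV, ordered hydroquinone (most positive) to citric
acid (most negative) — the more negative the analyte charge, the more
negative the potential signal — while the current signals order the other
way.  The direct analyte current is a sub-percent correction.
"""

import poresig as ps

solution = ps.default_solution(1e-3)
pore = ps.default_pore(2.3e-9)
base = ps.baseline_state(solution, pore)
print(f"baseline: V_bs = {base.V_bs*1e3:+.3f} mV, I_bs = {base.I_bs*1e9:+.4f} nA\n")

print(f"{'analyte':15s} {'z':>3s} {'V_ps (mV)':>10s} {'I_ps (pA)':>10s} {'I_an/I_ps':>10s}")
for name in ("hydroquinone", "oxalic_acid", "ascorbic_acid", "citric_acid"):
    ion = ps.ion_from_table(name)
    analyte = ps.Analyte(name=name, r_analyte=ion.radius, z_analyte=ion.valence)
    st = ps.predict_signals(solution, pore, analyte, t_ic=1e-3, baseline=base)
    print(
        f"{name:15s} {ion.valence:3d} {st.V_ps*1e3:10.4f} {st.I_ps*1e12:10.4f} "
        f"{abs(st.I_analyte/st.I_ps):10.2e}"
    )
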