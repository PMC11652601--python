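"""Closed-form one-compartment kinetics: a typical patient's profile.

Builds the published final-model parameters for a 70-kg adult on 420 mg
twice daily, prints the steady-state trough and a few points across one
dosing interval.  The trough is the exposure metric the dosing analysis
uses; 100-500 ng/mL is the therapeutic window.
"""

from quetipk.core_pk import DoseRegimen, StructuralParams, concentration, steady_state_trough

params = StructuralParams(cl=76.1, v=530.0, ka=1.46)  # CL/F L/h, V/F L, ka 1/h
regimen = DoseRegimen(dose_amount=420.0, interval=12.0, n_doses=None)  # q12h, steady state

print(f"ke = CL/V = {params.ke:.4f} 1/h  (half-life {0.693 / params.ke:.1f} h)")
for t in (0.5, 1.5, 3.0, 6.0, 9.0, 12.0):
    c = concentration(params, regimen, t)
    print(f"  t = {t:4.1f} h after dose: {c:6.1f} ng/mL")
trough = steady_state_trough(params, regimen)
print(f"steady-state trough: {trough:.1f} ng/mL "
      f"({'inside' if 100 <= trough <= 500 else 'outside'} the 100-500 ng/mL window)")
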