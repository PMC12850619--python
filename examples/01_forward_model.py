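"""Forward-model a WEPCAST control/label signal pair.

Builds the default acquisition (4 s labeling, 3 s post-labeling delay, two
background-suppression pulses) and prints the venous signals at acquisition
for a few (E, delta_v) combinations. The control signal moves mainly with
the venous transit time, the label signal with both parameters — which is
what makes the two-parameter inversion possible.
"""

from wepcast import AcquisitionProtocol, PhysioParams, signal_pair

physio = PhysioParams()  # female blood T1 1742 ms, CBF 55 mL/100 g/min
protocol = AcquisitionProtocol()

print(f"acquisition at t = {protocol.t_acq:.0f} ms after labeling start")
print(f"{'E':>6} {'delta_v (ms)':>12} {'control':>9} {'label':>9} {'diff':>9}")
for e in (0.80, 0.90, 0.95):
    for dv in (2800.0, 3300.0, 3800.0):
        sp = signal_pair(e, dv, physio, protocol)
        print(f"{e:6.2f} {dv:12.0f} {sp.control:9.5f} {sp.label:9.5f} {sp.diff:9.5f}")
print(
    "\nSignals are fractions of the equilibrium venous magnetization M0;\n"
    "diff = control - label is the arterial-spin-labeling signal that\n"
    "survives transit to the superior sagittal sinus."
)
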