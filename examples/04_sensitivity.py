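"""Sensitivity of (E, PS, delta_v) estimates to the model assumptions.

Re-estimates one fixed synthetic dataset while perturbing each assumed
model parameter by +/-10%: the transit-dispersion width sigma, the
arterial-to-venous transit ratio, and tissue T1.
"""

from wepcast import AcquisitionProtocol, PhysioParams, generate_roi_table, sensitivity_harness

physio = PhysioParams()
protocol = AcquisitionProtocol()
table = generate_roi_table(noise_sd=0.0, seed=1, physio=physio, protocol=protocol)

report = sensitivity_harness(table, physio, protocol)
print(report.to_string(index=False))
base = report.loc[report.condition == "current", "ps_ml_100g_min"].iloc[0]
shift = (report.ps_ml_100g_min - base).abs().max() / base
print(
    f"\nLargest PS shift across all perturbations: {100 * shift:.1f}%.\n"
    "Overestimating sigma lowers E and raises delta_v (and vice versa):\n"
    "extra assumed dispersion is traded against a later, weaker bolus."
)
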