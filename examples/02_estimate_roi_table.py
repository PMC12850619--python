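"""Simulate an ROI table along the SSS and invert it back to physiology.

Generates eight noiseless ROI signals with a constant extraction fraction
(E = 0.9) and an anterior-to-posterior transit-time gradient (3000 to 3600
ms), then runs the full pipeline: M0 normalization, dictionary build,
nearest-neighbor inversion and Renkin-Crone permeability.
"""

from wepcast import AcquisitionProtocol, PhysioParams, generate_roi_table, run_pipeline

physio = PhysioParams()
protocol = AcquisitionProtocol()

table = generate_roi_table(noise_sd=0.0, seed=0, physio=physio, protocol=protocol)
results, config = run_pipeline(table, physio, protocol)
print(results.to_string(index=False))
print(
    "\nTruth: E = 0.9 in every ROI, delta_v rising 3000 -> 3600 ms.\n"
    "vtt_hat_ms recovers the gradient on the 25 ms grid; e_hat scatters by\n"
    "about +/-0.01 around the truth (transit-grid quantization aliasing);\n"
    "ps_ml_100g_min = -ln(1 - E) * CBF is the permeability-surface product."
)
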