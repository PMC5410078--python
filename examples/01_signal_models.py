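"""Evaluate the three signal representations for one tissue.

Builds the nine-b-value scheme, evaluates the IVIM biexponential decay for
typical pancreatic-tumor parameters, and computes the per-b two-point ADC —
showing how perfusion inflates the low-b ADC and why it declines with b.
"""

import numpy as np

from ivimdwi import BValueScheme, IVIMParams, biexp_signal, two_point_adc

scheme = BValueScheme.study_scheme()
tumor = IVIMParams(s0=100.0, f=0.42, adc_slow=0.84e-3, adc_fast=6.39e-3)

signal = biexp_signal(tumor, scheme.array)
print("b (s/mm^2) :", " ".join(f"{b:7.0f}" for b in scheme))
print("signal     :", " ".join(f"{s:7.2f}" for s in signal))

print("\ntwo-point ADC per b (x10^-3 mm^2/s):")
for i, b in enumerate(scheme.values):
    if b == 0:
        continue
    adc = two_point_adc(signal[0], signal[i], b) * 1e3
    print(f"  b={b:5.0f}: {adc:.3f}")
print(
    "\nThe ADC falls from ~3.1 at b=20 toward the tissue coefficient"
    " (0.84) as the pseudo-diffusion compartment is suppressed at high b."
)
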