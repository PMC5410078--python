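"""Fit a single noisy voxel with all three estimators.

Synthesizes a tumor-like decay, corrupts it with Rician noise at SNR 40,
and runs the monoexponential fit, the segmented IVIM fit and the full
nonlinear IVIM fit, printing estimates next to the generating truth.
"""

import numpy as np

from ivimdwi import (
    BValueScheme,
    DWIStack,
    IVIMParams,
    add_rician_noise,
    biexp_signal,
    fit_biexp_full,
    fit_biexp_segmented,
    fit_monoexp,
)

scheme = BValueScheme.study_scheme()
truth = IVIMParams(s0=100.0, f=0.42, adc_slow=0.84e-3, adc_fast=6.39e-3)

clean = biexp_signal(truth, scheme.array)
stack = DWIStack(data=clean.reshape(1, 1, 1, -1), scheme=scheme)
noisy = add_rician_noise(stack, sigma=100.0 / 40.0, seed=7).data[0, 0, 0]

mono = fit_monoexp(noisy, scheme)
seg, _ = fit_biexp_segmented(noisy, scheme)
full, _ = fit_biexp_full(noisy, scheme, init=seg)

print(f"{'':12} {'truth':>8} {'segmented':>10} {'full fit':>10}")
for name in ("f", "adc_slow", "adc_fast"):
    scale = 1.0 if name == "f" else 1e3
    print(
        f"{name:12} {getattr(truth, name) * scale:8.3f}"
        f" {getattr(seg, name) * scale:10.3f}"
        f" {getattr(full, name) * scale:10.3f}"
    )
print(f"\nADC_total (x10^-3 mm^2/s): {mono.adc_total * 1e3:.3f}")
print(
    "\nADC values are printed on the x10^-3 mm^2/s scale. The full fit"
    " refines the segmented initializer; residual deviations from truth"
    " reflect the injected noise, not the estimator."
)
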