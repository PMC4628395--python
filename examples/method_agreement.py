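"""Compare enhancement quantification by dS/S0 and by LGE across subjects.

Simulates ten subjects whose lesions span a range of sizes, quantifies the
enhanced area independently with both methods on the same noisy images,
and summarizes their agreement with Bland-Altman statistics and a Pearson
association.
"""

import numpy as np

from bssfp2pt import (
    PairedMeasurements,
    PhantomSpec,
    analyze_phantom,
    association,
    bland_altman,
    generate_phantom,
)

rng = np.random.default_rng(2024)
areas_ds, areas_lge = [], []
for extent in np.linspace(25, 150, 10):          # lesion arc in degrees
    spec = PhantomSpec(
        lesion_theta=(30.0, 30.0 + extent),
        noise_sigma=0.007,                       # SNR ~5 at the 5-deg image
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    rep = analyze_phantom(generate_phantom(spec))
    areas_ds.append(rep["ds_report"].enhanced_area_pct)
    areas_lge.append(rep["lge_report"].enhanced_area_pct)

pairs = PairedMeasurements(areas_ds, areas_lge)
ba = bland_altman(pairs)
fit = association(pairs)

print("subject-level enhanced areas (% of myocardium):")
for i, (a, b) in enumerate(zip(areas_ds, areas_lge)):
    print(f"  subject {i}: dS/S0 {a:5.1f}  LGE {b:5.1f}")
print(f"\nBland-Altman bias (dS/S0 - LGE): {ba.bias:+.2f} points")
print(f"limits of agreement: [{ba.loa_low:+.2f}, {ba.loa_high:+.2f}]")
print(f"coefficient of variation: {ba.cov:.3f}")
print(f"association: R^2 = {fit.r_squared:.3f} "
      f"(slope {fit.slope:.2f}, intercept {fit.intercept:.2f})")
print("\nA bias near zero with narrow limits and R^2 near 1 means the "
      "gadolinium-free map\nreproduces the contrast-based quantification.")
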