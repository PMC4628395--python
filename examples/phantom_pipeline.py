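"""Generate a synthetic short-axis slice and analyze it end to end.

Builds a phantom with a 60-degree half-thickness lesion and realistic
magnitude noise, runs the full analysis (dS/S0 mapping, 197 % threshold
classification, LGE 5 SD classification, quantification, GPC), and prints
recovered quantities next to the known ground truth.
"""

import numpy as np

from bssfp2pt import PhantomSpec, analyze_phantom, generate_phantom
from bssfp2pt.segmentation import sector_partition

spec = PhantomSpec(
    lesion_theta=(30.0, 90.0),      # 60-degree wedge starting at the +x axis
    lesion_transmurality=0.5,       # sub-endocardial, half the wall thickness
    noise_sigma=0.0018,             # Rician noise, SNR ~20 at the 5-deg image
    seed=42,
)
dataset = generate_phantom(spec)
report = analyze_phantom(dataset)

truth = dataset.truth
ds_rep, lge_rep = report["ds_report"], report["lge_report"]
print("                      truth    dS/S0     LGE")
print(f"enhanced area (%)   {truth.enhanced_area_pct:7.2f}  "
      f"{ds_rep.enhanced_area_pct:7.2f}  {lge_rep.enhanced_area_pct:7.2f}")
print(f"transmurality (%)   {truth.transmurality_pct:7.2f}  "
      f"{ds_rep.transmurality_pct:7.2f}  {lge_rep.transmurality_pct:7.2f}")
print(f"\ndS/S0 threshold applied: {report['threshold']['value']:.0f} % "
      f"({report['threshold']['rule']})")
print(f"5/45-degree breath-hold alignment DICE: {report['cine_dice']:.3f}")
print(f"dS/S0 vs LGE enhanced-label DICE:       {report['label_dice']:.3f}")

gpc = report["gpc_summary"]
print(f"\nGPC remote:   {gpc['remote_median']:.3f}  (truth {truth.gpc['remote']:.3f})")
print(f"GPC enhanced: {gpc['enhanced_median']:.3f}  (truth {truth.gpc['lesion']:.3f})")
print("GPC ~0.5 is healthy interstitium; ~1.1 marks expanded extracellular space.")

_, sectors = sector_partition(report["ds_rois"], report["dsmap"], n_sectors=12)
hot = sectors.loc[sectors["mean"].idxmax()]
print(f"\n12-sector analysis: hottest sector starts at "
      f"{hot.theta_start_deg:.0f} deg with mean dS/S0 {hot['mean']:.0f} % "
      f"(lesion was placed at 30-90 deg).")
print("mean dS/S0 by sector (%):",
      np.round(sectors['mean'].to_numpy()).astype(int).tolist())
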