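# bssfp2pt — gadolinium-free cardiac tissue characterization with 2-point cine bSSFP

Late gadolinium enhancement (LGE) is the clinical standard for imaging
myocardial edema, necrosis and focal fibrosis, but it requires a contrast
agent. The 2-point bSSFP method characterizes tissue without gadolinium:
two cine balanced steady-state free precession (bSSFP) image sets are
acquired at different excitation flip angles — a low angle (5°, essentially
proton-density weighted) and a high angle (45°, strongly weighted by
magnetization transfer and T1/T2 relaxation) — and the normalized signal
change is mapped per voxel:

    ΔS/S₀ = (S₄₅ − S₅) / S₅ × 100  (%)

Edematous and fibrotic myocardium has lengthened T2 and a depleted
macromolecular matrix (reduced magnetization transfer, MT), both of which
raise the 45° signal relative to healthy muscle, so ΔS/S₀ is elevated in
tissue that would enhance with gadolinium. Myocardial voxels above a
healthy-control-derived threshold (197 %, mean + 3 SD of per-subject
control means) are classified as enhanced, in analogy to the mean + 5 SD
remote-ROI rule used on LGE images.

This package is aimed at cardiac MRI researchers who want to simulate,
quantify and validate that contrast mechanism. It provides:

- **`signal_model`** — on-resonance Freeman–Hill bSSFP steady state,
  S = M₀ sin α (1−E₁)/(1−(E₁−E₂)cos α−E₁E₂)·e^(−TE/T2), plus a two-pool
  (binary spin-bath) extension in which each RF pulse partially saturates
  the bound pool (mean saturation rate W = π ω₁² G) while the pools
  exchange longitudinally between pulses; predicted ΔS/S₀ per tissue.
- **`phantom`** — a seeded synthetic mid-ventricular short-axis slice:
  annular myocardium, blood pool, wedge lesion with prescribed angular
  extent and transmurality, paired 5°/45° cine phases with Rician noise,
  an LGE-like image, pre/post-contrast T1 maps, and full ground truth.
- **`mapping`** — per-phase ΔS/S₀ maps, diastolic-phase averaging,
  mask-aware 3×2 median filtering, low-signal validity floor.
- **`segmentation`** — the 197 % and mean + n·SD classification rules,
  border erosion, 12-sector circumferential partition.
- **`quantify`** — enhanced area (% of myocardium), transmurality along
  the central radial ray, gadolinium partition coefficient maps
  GPC = ΔR₁,myo / ΔR₁,blood (R₁ = 1/T1), DICE overlap.
- **`stats`** — Bland–Altman bias/limits/coefficient of variation,
  Pearson association, descriptive cohort summaries.
- **`io` / `pipeline` / `cli`** — NIfTI (and DICOM-series) reading and
  writing with JSON sidecars, a serializable multi-subject pipeline, and a
  thin `bssfp2pt` command line (`simulate`, `dsmap`, `classify`,
  `quantify`, `agree`, `run`).

## Worked example

`examples/phantom_pipeline.py` builds a noisy phantom with a 60° wedge
lesion at half wall thickness and analyzes it end to end:

```
                      truth    dS/S0     LGE
enhanced area (%)      7.29     7.29     7.29
transmurality (%)     50.00    51.35    51.35

dS/S0 threshold applied: 197 % (fixed)
5/45-degree breath-hold alignment DICE: 1.000
dS/S0 vs LGE enhanced-label DICE:       1.000

GPC remote:   0.505  (truth 0.505)
GPC enhanced: 1.079  (truth 1.079)

12-sector analysis: hottest sector starts at 30 deg with mean dS/S0 162 %
mean dS/S0 by sector (%): [85, 162, 160, 85, 85, 85, 85, 86, 86, 85, 86, 86]
```

The gadolinium-free classification recovers the prescribed lesion area
(7.29 % of myocardium) and transmurality (50 %) and matches the LGE-based
labels voxel for voxel; myocardial GPC ≈ 0.5 is normal interstitium while
≈ 1.1 in the lesion marks expanded extracellular space; the sector means
localize the lesion to the 30°–90° arc. The other examples print the
predicted per-tissue ΔS/S₀ contrast (`signal_simulation.py`) and a
ten-subject Bland–Altman/association comparison of the two methods
(`method_agreement.py`).

From the shell, the same steps run as:

```bash
bssfp2pt simulate phantom_dir --seed 42
bssfp2pt dsmap phantom_dir/cine_low.nii.gz phantom_dir/cine_high.nii.gz ds.nii.gz
bssfp2pt classify ds.nii.gz phantom_dir/myocardium.nii.gz \
    phantom_dir/remote_roi.nii.gz labels.nii.gz --rule fixed
bssfp2pt quantify labels.nii.gz report.json
```

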