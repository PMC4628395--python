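# Methods

## Signal model

### Single pool

The on-resonance, phase-alternated bSSFP steady state is the Freeman–Hill
closed form

    S = M0 · sin α · (1 − E1) / (1 − (E1 − E2) cos α − E1·E2) · exp(−TE/T2),
    E1 = exp(−TR/T1),  E2 = exp(−TR/T2).

For TR ≪ T1, T2 the flip angle maximizing S satisfies
cos α* ≈ (T1/T2 − 1)/(T1/T2 + 1) with S(α*) ≈ (M0/2)√(T2/T1) — the
familiar √(T2/T1) weighting of bSSFP. Both limits are asserted by tests
(reduction to 10⁻⁶ relative over a 160-point grid; the optimal-angle limit
to 2 % at TR ≤ T2/50).

### Two pools (magnetization transfer)

Tissue is modelled as a binary spin bath: a free water pool carrying the
observable signal, fraction 1 − F of M0, and a macromolecular bound pool,
fraction F, with no observable transverse magnetization. One repetition
consists of

1. **RF event.** The free magnetization rotates by α. The bound
   longitudinal magnetization is attenuated by exp(−W·τ_rf) with mean
   saturation rate W = π·ω₁²·G, where ω₁ = α(rad)/τ_rf for a rectangular
   pulse of duration τ_rf and G is the bound-pool absorption lineshape
   value at resonance.
2. **Inter-pulse evolution.** Free transverse magnetization decays by
   exp(−TR/T2) and changes sign (the on-resonance equivalent of ±α phase
   cycling); the two longitudinal pools relax and exchange as a linear
   two-compartment system solved by matrix exponential over TR. The
   free→bound rate is the tissue's exchange rate k; the reverse rate
   k(1 − F)/F follows from detailed balance. The bound-pool T1 is fixed at
   1000 ms, the conventional choice in binary spin-bath fitting, because
   MT experiments constrain it poorly.

The per-TR propagation is affine in the state (My_free, Mz_free,
Mz_bound), so the converged steady state is computed exactly as the fixed
point of that affine map (a 3×3 linear solve) and verified against the
fixed-point equation at relative tolerance 10⁻⁹. Solving the fixed point
directly rather than by pulse-by-pulse sweeps matters numerically: the
sweep contraction rate approaches 1 at small flip angles, where a
successive-difference stopping rule would stall ~10⁻⁵ from the true
steady state. With F = 0 the model reduces exactly to the single-pool
closed form. The echo amplitude applies exp(−TE/T2) to the post-pulse
transverse magnetization; off-resonance banding, finite-pulse corrections
beyond the rectangular ω₁ approximation, and transient (non-steady-state)
signal are all out of scope.

Consequences asserted as properties: the signal is non-increasing in F at
every flip angle; attenuation at 45° exceeds attenuation at 5° (W ∝ α²);
ΔS/S₀ rises with T2, falls with T1, and falls with F — the opposing
T1-versus-MT balance that governs detectability of fibrotic tissue.

### Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| TR / TE | 3.2 / 1.2 | ms | typical 1.5 T cine bSSFP timing |
| flip angles | 5 / 45 | ° | proton-density reference / MT-weighted pair |
| τ_rf | 0.6 | ms | typical short rectangular excitation at this TR |
| G | 1.4×10⁻⁵ | s | bound-pool absorption value at resonance, typical tissue |
| k | 4.5 | 1/s | free→bound exchange, literature-plausible for muscle |
| bound-pool T1 | 1000 | ms | conventional fixed value |

## Phantom

The generator emulates one mid-ventricular short-axis slice on a 128×128
grid: a circular blood pool (radius 20 voxels) inside an annular
myocardium (outer radius 30), centered at (64, 64). An optional lesion is
a circumferential wedge [θ₁, θ₂) growing radially outward from the
endocardial border (sub-endocardial pattern) to a prescribed fraction of
the wall thickness. Angles are measured counter-clockwise from the image
+x axis; coordinates are 0-based row/column voxels.

Voxel intensities at both flip angles come from the two-pool signal model
with per-tissue parameters:

| tissue | T1 (ms) | T2 (ms) | F | post-contrast T1 (ms) | ΔS/S₀ |
|---|---|---|---|---|---|
| remote myocardium | 950 | 46 | 0.12 | 500 | ≈ 85 % |
| lesion | 1200 | 130 | 0.01 | 350 | ≈ 255 % |
| blood | 1600 | 250 | 0.00 | 400 | ≈ 358 % |

Remote and blood values are literature-plausible at 1.5 T. The lesion is
deliberately a strong-edema case — long T2 with an essentially depleted
macromolecular matrix — calibrated once so that the phantom reproduces
the contrast regime the clinical threshold presumes: remote tissue well
below 197 % and lesions well above it. Milder lesions (e.g. T2 ≈ 60 ms,
F ≈ 0.05) yield ΔS/S₀ ≈ 100 % under this model, i.e. below the fixed
threshold; the model thus also reproduces the known failure mode in which
modest T2 elevation is offset by increased T1. Ground-truth GPC per
tissue follows from the prescribed pre/post-contrast T1 values (remote
0.505, lesion 1.079, blood 1 by definition).

Each of the n_phases (default 3) images per flip angle receives
independent Rician noise: v → √((v+n₁)² + n₂²), n₁, n₂ ~ N(0, σ²). The
default σ = 0.0018 corresponds to SNR ≈ 20 on the 5° remote-myocardium
signal (M0 = 1). The LGE-like image uses three configurable intensity
levels (remote 10, blood 45, lesion 100) plus Rician noise; T1 maps can
carry optional Gaussian perturbation (default none). Identical spec and
seed reproduce every array bit for bit.

What the phantom does **not** emulate — and hence what passing tests do
not demonstrate about patient data: cardiac/respiratory motion and
breath-hold misregistration between the two acquisitions, B1
inhomogeneity, off-resonance banding, partial-volume mixing at tissue
interfaces (borders are crisp), realistic inversion-recovery LGE signal
formation, through-plane flow, and regional heterogeneity of healthy
tissue.

## Map construction and classification

ΔS/S₀ is computed per phase, averaged over the quiescent diastolic phases,
and only then (optionally) median filtered. Voxels whose 5° reference
signal falls below a validity floor (default twice the background noise
scale, estimated from the Rayleigh mean of the image corners) are marked
invalid and excluded from every downstream numerator and denominator —
an explicit guard against division blow-ups in the low-SNR reference that
the clinical protocol handles only implicitly by averaging.

The 3×2 median filter (3 rows × 2 columns, reflected edges, mask-aware:
medians are taken over valid window members, with even counts averaging
the two middle order statistics) is applied for display rather than
before classification by default. Filtering before thresholding mixes
blood-pool ΔS/S₀ (≈ 358 %) into endocardial-border myocardium and
mislabels a border ring — precisely the partial-volume effect that
motivates border erosion; `erode_borders` is provided for that purpose and
the filter position is configurable.

Classification uses strict inequalities and sample standard deviations
(n−1): LGE enhancement is remote-ROI mean + 5 SD; ΔS/S₀ enhancement is a
fixed 197 % by default, or mean + 3 SD across per-subject control means
when a control cohort is supplied ("SD of the mean" is read as the
across-subject SD of per-subject means; an SEM reading is hard to
reconcile with the magnitude of the published threshold). Sector analysis
assigns each myocardial voxel to one of 12 equal circumferential sectors
about the LV center, sector 0 starting at the +x axis, counter-clockwise;
anatomical naming is left to display metadata.

## Quantification

Enhanced area is the percentage of labelled myocardial voxels classified
enhanced. Transmurality takes the circular mean of the enhanced voxels'
angles about the LV center (robust to the 0°/360° wrap), marches a single
ray at that angle in 0.25-voxel steps with nearest-voxel lookup, and
reports the enhanced fraction of myocardium-classified samples; a single
ray (not an averaged band) is used, matching the definition of enhancement
"along the radial direction". An absent lesion raises a distinct
`NoEnhancementError` rather than returning 0 %. GPC uses blood T1 medians
over the blood ROI; myocardial voxels with non-positive ΔR₁ are invalid.
DICE of two empty masks is defined as 1 and flagged in the docstring.

## Agreement statistics

Bland–Altman reports bias = mean(a−b), limits bias ± 1.96·SD(differences)
(sample SD), and a coefficient of variation defined as SD(differences)
divided by the grand mean of per-pair means — the conventional choice,
stated explicitly because several definitions circulate; it is NaN when
the grand mean is zero. Association is Pearson's r with a least-squares
line of method A on method B. Inferential modelling (mixed models,
multiplicity-corrected contrasts, reader studies) is deliberately out of
scope; `cohort_summary` is descriptive only.

## Problem sizes

The test suite and `scripts/acceptance.py` use 128×128 phantoms, a
160-point signal-model grid, 10-subject lesion-size sweeps at SNR 5, and
20 noise replicates for the robustness check; the full suite runs in a
few seconds on one CPU. These sizes were chosen because results are
already stable at this scale — recovery errors are dominated by voxel
discretization, not sampling.

## Known limitations

- The two-pool MT parameterization (k, G, bound-pool T1) is not fitted to
  any measured myocardial MT data; only the qualitative mechanism
  (monotone attenuation, α² scaling, T1/MT opposition) is guaranteed.
- The fixed 197 % threshold is scanner- and protocol-specific in reality;
  the package treats it as a configurable constant with a derivation rule.
- Transmurality by a single central ray is sensitive to lesion shape for
  strongly non-wedge lesions.
- The phantom's crisp tissue borders make threshold classification easier
  than in vivo; noise robustness results should be read as upper bounds.
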