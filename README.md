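# kedgect

Simulation and metrology of K-edge contrast materials in two-threshold
photon-counting CT.

Photon-counting detectors sort each detected x-ray into energy bins
defined by thresholds. With a fixed low threshold (20 keV) and a swept
upper threshold T, an acquisition yields a *low-energy image* (photons in
[20, T)) and a *high-energy image* (photons in [T, 120] at 120 kV). For
an element with a K-shell binding energy E_K in the diagnostic range, the
attenuation jumps upward at E_K, so the choice of T controls how much
just-above-edge signal each image captures. This package answers, by
desk-scale simulation, the questions an imaging physicist planning
contrast protocols asks: at which threshold does each material's contrast
peak, how does image noise migrate between the two bins as T moves, and
which threshold best separates a given *pair* of materials (the
precondition for multi-contrast imaging and material decomposition)?

## What is computed

A 30 cm water cylinder with 16 inserts (Ca 50 mg/mL, Fe 30 mg/mL, and
I, Ba, Sm, Eu, Gd, Tb, Yb, Lu, Ta, W, Pt, Au, Bi at 4 mg/mL, plus a
water control) is forward-projected with polychromatic Beer–Lambert
attenuation under a filtered 120 kV spectrum, optionally
Poisson-sampled, reconstructed per bin by filtered back projection,
water-linearized and HU-calibrated. For every threshold T ∈ {50, 55, …,
90} keV:

* **Noise** — SD of HU in a central water-background ROI, per bin image.
* **Contrast** — Contrast = μ_insert − μ_background (ROI means, HU), per
  material and bin image.
* **Separability** — per material pair, the linear Hotelling observer
  w = S⁻¹(x̄_A − x̄_B) applied to per-voxel (low HU, high HU) vectors
  gives test statistics λ, and

  s′ = (λ̄_A − λ̄_B) / sqrt(½ (σ²_λA + σ²_λB))

  quantifies how distinguishable the two materials are at that threshold.

Element attenuation (including every K-edge) comes from bundled tables
generated by the package's cross-section engine (Cromer–Liberman
photoabsorption + Klein–Nishina/form-factor scattering via `gemmi`);
water and air use NIST standard-reference tables. See `docs/methods.md`
for the full model and its assumptions.

## Worked example

```python
from kedgect.sweep import SweepConfig, run_sweep, peak_threshold

result = run_sweep(SweepConfig(preset="reduced", noise_free=True))
for material in ("Lu", "Ta", "W", "Pt", "Au", "Bi"):
    print(material, peak_threshold(result, material, "high"))
```

prints (keV):

```
Lu 65
Ta 65
W 70
Pt 80
Au 80
Bi 90
```

— each material's high-energy-image contrast peaks at the sweep threshold
nearest its K-edge (Lu 63.3, Ta 67.4, W 69.5, Pt 78.4, Au 80.7 keV);
bismuth's edge (90.5 keV) lies past the sweep end, so its contrast is
still rising at 90 keV. A threshold just at the edge concentrates the
above-edge attenuation jump into the high bin while keeping that bin as
photon-rich (and HU-efficient) as possible.

The noisy, seeded sweep (`noise_free=False`, photon budget calibrated so
the low bin reads ≈ 16 HU noise at T = 50) shows the threshold's noise
trade-off — low bin 16.0 → 5.7 HU and high bin 5.3 → 11.8 HU as T goes
50 → 90 keV — and yields the 105-pair separability tables; for the
lanthanides, peak s′ grows with the K-edge gap of the pair (Spearman
ρ = 0.90): close-edge pairs like Eu/Gd (Δ1.7 keV, s′ ≈ 2.7) are hard to
separate, distant pairs like Eu/Lu (Δ14.8 keV, s′ ≈ 23) easy.

## Analysis pipeline

Numbered drivers under `analysis/` run the study end to end and write
tables/figures under `results/`:

1. `01_build_phantom.py` — phantom geometry, ROI label raster, material
   table (K-edges, concentrations, groups).
2. `02_spectrum_model.py` — the filtered 120 kV spectrum and the two-bin
   photon shares per threshold.
3. `03_contrast_sweep.py` — noise-free sweep; contrast-vs-threshold
   per material group and the contrast-argmax table.
4. `04_noise_and_separability.py` — seeded noisy sweep; noise trends,
   pairwise s′ tables, best-threshold matrix and per-material profiles.

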