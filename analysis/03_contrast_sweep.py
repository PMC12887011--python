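"""Noise-free threshold sweep: where does each material's contrast peak?

Runs the 50-90 keV upper-threshold sweep without photon noise (reduced
256-px geometry), writes the tidy metrics table and the per-group contrast
figures under results/contrast_sweep/, and prints the contrast-argmax
threshold per material and bin next to the material's K-edge.

Finding: in the high-energy image every material whose K-edge falls inside
the sweep peaks at the threshold nearest its K-edge (Lu 65, Ta 65, W 70,
Pt 80, Au 80); bismuth's edge (90.5 keV) lies just beyond the sweep, so
its contrast still rises at 90 keV. In the low-energy image contrast
decreases with threshold for sub-50-keV-edge materials, while materials
with edges inside the band (e.g. Gd) jump once the threshold crosses the
edge and admits just-above-edge photons into the low bin.
"""

import pathlib

import pandas as pd

from kedgect import attenuation as att
from kedgect.sweep import SweepConfig, peak_threshold, render_report, run_sweep

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "contrast_sweep"

config = SweepConfig(preset="reduced", noise_free=True, seed=0)
result = run_sweep(config, outdir=OUT)
render_report(result, OUT)

rows = []
for material in sorted(result.metrics.material.unique()):
    sym = material if material != "water-control" else None
    rows.append({
        "material": material,
        "kedge_keV": None if sym is None else round(att.kedge_energy(sym), 1),
        "peak_low_keV": peak_threshold(result, material, "low"),
        "peak_high_keV": peak_threshold(result, material, "high"),
    })
table = pd.DataFrame(rows)
table.to_csv(OUT / "contrast_argmax.csv", index=False)

print(table.to_string(index=False))
print(f"\nsweep stage timings: { {k: round(v, 1) for k, v in result.timings_s.items()} }")
print(f"artifacts written under {OUT}")
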