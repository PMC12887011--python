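"""Noisy threshold sweep: noise trends and pairwise material separability.

Runs the seeded Poisson-noise sweep (photon budget calibrated to ~16 HU
low-bin water noise at threshold 50, four averaged realizations), writes
the noise/contrast tables, the 15 x 15 best-threshold separability matrix
and per-material separability profiles under results/noisy_sweep/, and
prints the two headline structural findings:

* noise migrates between the bin images as the threshold moves (the low
  bin gains photons and quietens, the high bin loses them and gets
  noisier);
* lanthanide pairs with close K-edges are the hardest to separate -
  peak s' grows with the K-edge gap (positive Spearman correlation).
"""

import itertools
import pathlib

from scipy.stats import spearmanr

from kedgect.crosssections import K_EDGE_KEV
from kedgect.sweep import SweepConfig, render_report, run_sweep

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "noisy_sweep"

config = SweepConfig(preset="reduced", noise_free=False, n_realizations=4, seed=1)
result = run_sweep(config, outdir=OUT)
render_report(result, OUT)

noise = result.metrics.drop_duplicates(["threshold_keV", "bin"])
for bin_name in ("low", "high"):
    sel = noise[noise.bin == bin_name].sort_values("threshold_keV")
    series = "  ".join(f"{t}:{v:.1f}" for t, v in zip(sel.threshold_keV, sel.noise_HU))
    print(f"{bin_name:4s} bin noise (HU) vs threshold: {series}")

lan = ["Sm", "Eu", "Gd", "Tb", "Yb", "Lu"]
dk, peak = [], []
for a, b in itertools.combinations(lan, 2):
    sel = result.separability[
        ((result.separability.material_A == a) & (result.separability.material_B == b))
        | ((result.separability.material_A == b) & (result.separability.material_B == a))]
    dk.append(abs(K_EDGE_KEV[a] - K_EDGE_KEV[b]))
    peak.append(sel.s_prime.max())
rho, p = spearmanr(dk, peak)
print(f"lanthanides: Spearman(peak s', |dK-edge|) = {rho:.2f} (p = {p:.1e})")
print(f"artifacts written under {OUT}")
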