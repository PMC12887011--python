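"""Regenerate the plain-text attenuation tables bundled under kedgect/data.

Run from the repository root:

    python scripts/make_attenuation_tables.py

Element tables are computed by the kedgect cross-section engine
(Cromer-Liberman photoabsorption + Klein-Nishina/form-factor scattering,
see kedgect.crosssections) on a 1 keV grid over 15-140 keV with duplicated
abscissae at each K-edge. Water and dry air are bundled directly from the
NIST Hubbell-Seltzer standard-reference material tables.

File format (documented, stable): comment lines start with '#'; data rows
are two whitespace-separated columns, photon energy in keV and mass
attenuation coefficient mu/rho in cm^2/g, sorted by energy, with each
absorption edge represented by two rows at the identical energy
(below-edge value first, above-edge value second).
"""

from __future__ import annotations

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from kedgect import crosssections as xs  # noqa: E402

DATA_DIR = pathlib.Path(__file__).resolve().parents[1] / "src" / "kedgect" / "data"

ELEMENTS = ["Al", "Ca", "Fe", "I", "Ba", "Sm", "Eu", "Gd", "Tb",
            "Yb", "Lu", "Ta", "W", "Pt", "Au", "Bi"]

# NIST X-ray mass attenuation tables (Hubbell & Seltzer), liquid water and
# dry air (near sea level): photon energy keV -> mu/rho cm^2/g.
NIST_WATER = [
    (10.0, 5.329), (15.0, 1.673), (20.0, 0.8096), (30.0, 0.3756),
    (40.0, 0.2683), (50.0, 0.2269), (60.0, 0.2059), (80.0, 0.1837),
    (100.0, 0.1707), (150.0, 0.1505), (200.0, 0.1370),
]
NIST_AIR = [
    (10.0, 5.120), (15.0, 1.614), (20.0, 0.7779), (30.0, 0.3538),
    (40.0, 0.2485), (50.0, 0.2080), (60.0, 0.1875), (80.0, 0.1662),
    (100.0, 0.1541), (150.0, 0.1356), (200.0, 0.1233),
]


def write_table(path: pathlib.Path, header: str, rows) -> None:
    rows = list(rows)
    lines = [f"# {line}" for line in header.strip().splitlines()]
    lines.append("# columns: energy_keV  mu_over_rho_cm2_per_g")
    for e, v in rows:
        lines.append(f"{e:.6f} {v:.8e}")
    path.write_text("\n".join(lines) + "\n")
    print(f"wrote {path} ({len(rows)} rows)")


def main() -> None:
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    for sym in ELEMENTS:
        grid, values = xs.element_curve(sym)
        header = (
            f"Total mass attenuation of {sym}, generated by "
            "kedgect.crosssections\n"
            "(Cromer-Liberman photoabsorption + Klein-Nishina incoherent with\n"
            "IT92 form-factor screening + Thomson coherent; gemmi data tables).\n"
            "Duplicated energies mark an absorption edge (below, then above)."
        )
        write_table(DATA_DIR / f"{sym}.txt", header, zip(grid, values))
    write_table(
        DATA_DIR / "water.txt",
        "Total mass attenuation of liquid water.\n"
        "Source: NIST standard reference tables (Hubbell & Seltzer).",
        NIST_WATER,
    )
    write_table(
        DATA_DIR / "air.txt",
        "Total mass attenuation of dry air (near sea level).\n"
        "Source: NIST standard reference tables (Hubbell & Seltzer).",
        NIST_AIR,
    )


if __name__ == "__main__":
    main()
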