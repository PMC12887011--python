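"""Analytic cylindrical phantom: a 30 cm water cylinder with circular inserts.

The study phantom holds 16 inserts: the 15 K-edge / biological elements at
their study concentrations (Ca 50 mg/mL, Fe 30 mg/mL, everything else
4 mg/mL matched to the clinical iodine level) plus one pure-water control
insert. The publication shows the geometry only as a figure, so insert
radius (1.25 cm) and the two-ring layout (radii 5 and 10 cm, atomic-number
order) are conventions of this package, not reconstructions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import attenuation
from .attenuation import SolutionMaterial, TABLE_ELEMENTS

__all__ = [
    "InsertSpec",
    "PhantomSpec",
    "build_paper_phantom",
    "build_water_cylinder",
    "material_at",
    "group_memberships",
    "CONCENTRATIONS_MG_PER_ML",
    "MATERIAL_GROUPS",
]

#: Study concentrations per element (mg/mL).
CONCENTRATIONS_MG_PER_ML = {sym: 4.0 for sym in TABLE_ELEMENTS}
CONCENTRATIONS_MG_PER_ML["Ca"] = 50.0
CONCENTRATIONS_MG_PER_ML["Fe"] = 30.0

#: Functional material groups; Gd and Yb each belong to two groups.
MATERIAL_GROUPS = {
    "biological_and_clinical": ["Ba", "Ca", "Gd", "Fe", "I"],
    "lanthanides": ["Sm", "Eu", "Gd", "Tb", "Yb", "Lu"],
    "candidates_and_nanomaterials": ["Bi", "Au", "Pt", "Ta", "W", "Yb"],
}

WATER_CONTROL_LABEL = "water-control"


@dataclass(frozen=True)
class InsertSpec:
    center_xy_cm: tuple[float, float]
    radius_cm: float
    material: SolutionMaterial
    label: str

    def __post_init__(self) -> None:
        if self.radius_cm <= 0:
            raise ValueError("insert radius must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    background_radius_cm: float = 15.0
    inserts: tuple[InsertSpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for ins in self.inserts:
            r = math.hypot(*ins.center_xy_cm)
            if r + ins.radius_cm > self.background_radius_cm:
                raise ValueError(f"insert {ins.label} extends outside the background")
        for i, a in enumerate(self.inserts):
            for b in self.inserts[i + 1:]:
                d = math.dist(a.center_xy_cm, b.center_xy_cm)
                if d <= a.radius_cm + b.radius_cm:
                    raise ValueError(f"inserts {a.label} and {b.label} overlap")

    @property
    def background_material(self) -> SolutionMaterial:
        return SolutionMaterial(None, 0.0)

    def insert(self, label: str) -> InsertSpec:
        for ins in self.inserts:
            if ins.label == label:
                return ins
        raise KeyError(label)

    def to_yaml(self) -> str:
        doc = {
            "background_radius_cm": self.background_radius_cm,
            "inserts": [
                {
                    "label": ins.label,
                    "center_xy_cm": list(ins.center_xy_cm),
                    "radius_cm": ins.radius_cm,
                    "solute": None if ins.material.solute is None else ins.material.solute.symbol,
                    "concentration_mg_per_mL": ins.material.concentration_mg_per_mL,
                }
                for ins in self.inserts
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PhantomSpec":
        doc = yaml.safe_load(text)
        inserts = []
        for d in doc["inserts"]:
            solute = None if d["solute"] is None else attenuation.get_element(d["solute"])
            mat = SolutionMaterial(solute, d["concentration_mg_per_mL"])
            inserts.append(InsertSpec(tuple(d["center_xy_cm"]), d["radius_cm"], mat, d["label"]))
        return cls(doc["background_radius_cm"], tuple(inserts))

    def label_map(self, grid_n: int, pixel_size_cm: float) -> np.ndarray:
        """Integer ROI raster: 0 air, 1 water background, 2+i insert i."""
        x, y = pixel_grid(grid_n, pixel_size_cm)
        out = np.zeros((grid_n, grid_n), dtype=np.int32)
        out[x * x + y * y <= self.background_radius_cm**2] = 1
        for i, ins in enumerate(self.inserts):
            cx, cy = ins.center_xy_cm
            out[(x - cx) ** 2 + (y - cy) ** 2 <= ins.radius_cm**2] = 2 + i
        return out


def pixel_grid(grid_n: int, pixel_size_cm: float) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates (x right, y up) of a square recon grid.

    The origin sits at pixel index ``grid_n // 2``, matching the rotation
    center used by scikit-image's radon/iradon pair.
    """
    c = (np.arange(grid_n) - grid_n // 2) * pixel_size_cm
    x = c[np.newaxis, :]
    y = -c[:, np.newaxis]
    return np.broadcast_to(x, (grid_n, grid_n)), np.broadcast_to(y, (grid_n, grid_n))


def build_paper_phantom(
    insert_radius_cm: float = 1.25,
    ring_radii_cm: tuple[float, float] = (5.0, 10.0),
    background_radius_cm: float = 15.0,
) -> PhantomSpec:
    """The 16-insert study phantom.

    Materials are placed in atomic-number order, the first five on the
    inner ring and the remaining ten plus the water control on the outer
    ring, at evenly spaced angles starting from +x. Deterministic.
    """
    labels = list(TABLE_ELEMENTS) + [WATER_CONTROL_LABEL]
    ring_of = [0] * 5 + [1] * 11
    counts = {0: 5, 1: 11}
    inserts = []
    ring_index = {0: 0, 1: 0}
    for label, ring in zip(labels, ring_of):
        angle = 2.0 * math.pi * ring_index[ring] / counts[ring]
        ring_index[ring] += 1
        r = ring_radii_cm[ring]
        center = (r * math.cos(angle), r * math.sin(angle))
        if label == WATER_CONTROL_LABEL:
            mat = SolutionMaterial(None, 0.0, name="water")
        else:
            mat = SolutionMaterial(attenuation.get_element(label),
                                   CONCENTRATIONS_MG_PER_ML[label])
        inserts.append(InsertSpec(center, insert_radius_cm, mat, label))
    return PhantomSpec(background_radius_cm, tuple(inserts))


def build_water_cylinder(background_radius_cm: float = 15.0) -> PhantomSpec:
    """Insert-free water cylinder used for HU calibration scans."""
    return PhantomSpec(background_radius_cm, tuple())


def material_at(phantom: PhantomSpec, x_cm: float, y_cm: float):
    """Material of the innermost region containing (x, y); air outside."""
    for ins in phantom.inserts:
        if math.dist((x_cm, y_cm), ins.center_xy_cm) <= ins.radius_cm:
            return ins.material
    if math.hypot(x_cm, y_cm) <= phantom.background_radius_cm:
        return phantom.background_material
    return attenuation.air()


def group_memberships() -> dict[str, list[str]]:
    """The three functional material groups (Gd and Yb appear twice)."""
    return {k: list(v) for k, v in MATERIAL_GROUPS.items()}
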