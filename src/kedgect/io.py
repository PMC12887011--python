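"""Artifact persistence: 32-bit float TIFF rasters with YAML sidecars.

Sinograms are stored with views as rows; reconstructed images in HU. The
sidecar ``<stem>.yaml`` carries the acquisition context (protocol, bin,
noise flag, pixel size) so an artifact can be reloaded without ambiguity.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .projector import AcquisitionProtocol, BinnedSinogram
from .recon import ReconImage
from .spectrum import EnergyBin

__all__ = ["save_sinogram", "load_sinogram", "save_image", "load_image",
           "save_label_map"]


def _protocol_doc(protocol: AcquisitionProtocol) -> dict:
    return asdict(protocol)


def save_sinogram(path, sinogram: BinnedSinogram) -> Path:
    path = Path(path)
    tifffile.imwrite(path, sinogram.values.astype(np.float32))
    sidecar = {
        "kind": "sinogram",
        "bin_keV": [sinogram.bin.lo_keV, sinogram.bin.hi_keV],
        "noise_free": sinogram.noise_free,
        "protocol": _protocol_doc(sinogram.protocol),
        "layout": "rows=views, columns=channels, unitless line integrals",
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))
    return path


def load_sinogram(path) -> BinnedSinogram:
    path = Path(path)
    values = np.asarray(tifffile.imread(path), dtype=float)
    doc = yaml.safe_load(path.with_suffix(".yaml").read_text())
    protocol = AcquisitionProtocol(**doc["protocol"])
    ebin = EnergyBin(*doc["bin_keV"])
    return BinnedSinogram(values, ebin, protocol, doc["noise_free"])


def save_image(path, image: ReconImage) -> Path:
    path = Path(path)
    tifffile.imwrite(path, image.pixels.astype(np.float32))
    sidecar = {
        "kind": "recon_image",
        "units": "HU",
        "pixel_size_mm": image.pixel_size_mm,
        "bin_keV": [image.bin.lo_keV, image.bin.hi_keV],
        "protocol": _protocol_doc(image.protocol),
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))
    return path


def load_image(path) -> ReconImage:
    path = Path(path)
    pixels = np.asarray(tifffile.imread(path), dtype=float)
    doc = yaml.safe_load(path.with_suffix(".yaml").read_text())
    protocol = AcquisitionProtocol(**doc["protocol"])
    return ReconImage(pixels, doc["pixel_size_mm"], EnergyBin(*doc["bin_keV"]), protocol)


def save_label_map(path, label_map: np.ndarray) -> Path:
    """Integer ROI raster (0 air, 1 background, 2+i insert i) as TIFF."""
    path = Path(path)
    tifffile.imwrite(path, label_map.astype(np.int32))
    return path
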