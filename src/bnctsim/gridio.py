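"""Reading and writing of co-registered dose grids.

Grids are stored as a compressed ``.npz`` bundle plus a JSON sidecar header
(shape, voxel size, scoring depth, slab thickness, history count and seed),
so externally produced per-component dose grids in the same layout can feed
the survival chain.  A CSV export of the azimuthally averaged radial profile
is provided for inspection and plotting.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .phantom import VoxelPhantom
from .transport import CHANNELS, DoseComponents

GRID_FILE = "dose_components.npz"
HEADER_FILE = "dose_header.json"


def write_dose_components(directory, components: DoseComponents,
                          phantom: VoxelPhantom) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(directory / GRID_FILE, **components.as_dict())
    header = {
        "shape": list(components.boron.shape),
        "fine_voxel_cm": phantom.config.fine_voxel,
        "scoring_depth_cm": phantom.config.scoring_depth,
        "slab_halfwidth_cm": components.slab_halfwidth,
        "lateral_extent_cm": phantom.config.lateral_extent,
        "n_histories": components.n_histories,
        "rng_seed": components.rng_seed,
        "units": "Gy per source particle",
        "channels": list(CHANNELS),
    }
    (directory / HEADER_FILE).write_text(json.dumps(header, indent=2))
    return directory


def read_dose_components(directory) -> tuple[DoseComponents, dict]:
    directory = Path(directory)
    header = json.loads((directory / HEADER_FILE).read_text())
    with np.load(directory / GRID_FILE) as bundle:
        components = DoseComponents(
            boron=bundle["boron"],
            thermal_neutron=bundle["thermal_neutron"],
            fast_neutron=bundle["fast_neutron"],
            gamma=bundle["gamma"],
            n_histories=int(header["n_histories"]),
            rng_seed=int(header["rng_seed"]),
            slab_halfwidth=float(header["slab_halfwidth_cm"]),
        )
    return components, header


def radial_profile(grid: np.ndarray, phantom: VoxelPhantom,
                   bin_width: float | None = None) -> pd.DataFrame:
    """Azimuthally averaged radial profile of a scoring-plane grid."""
    if bin_width is None:
        bin_width = phantom.config.fine_voxel
    r = phantom.plane_radii.ravel()
    k = np.floor(r / bin_width).astype(np.int64)
    counts = np.bincount(k)
    sums = np.bincount(k, weights=np.asarray(grid, dtype=float).ravel())
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (np.arange(counts.size) + 0.5) * bin_width
    return pd.DataFrame({"r_cm": centers, "value": mean, "n_cells": counts})


def export_profiles_csv(path, components: DoseComponents,
                        phantom: VoxelPhantom,
                        bin_width: float | None = None) -> Path:
    frames = []
    for name, grid in components.as_dict().items():
        df = radial_profile(grid, phantom, bin_width)
        df.insert(0, "component", name)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    path = Path(path)
    out.to_csv(path, index=False)
    return path
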