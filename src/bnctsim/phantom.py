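"""Voxelised brain phantom geometry and scoring-plane region masks.

The treatment volume is a rectangular brain phantom irradiated by a circular
neutron field travelling along +z.  Dose is scored on a single plane of
cell-sized voxels perpendicular to the beam; the gross tumour volume (GTV) is
a small sphere whose centre sits at the lateral midpoint of that plane.  Two
grids coexist: a coarse (3 mm) material grid used by particle transport and a
fine (20 um at full scale) scoring plane on which the microscopic-extension
field, dose and survival are evaluated.

All lengths are in centimetres unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

UM = 1e-4  # cm per micrometre
MM = 0.1   # cm per millimetre

DEFAULT_PENUMBRA_WIDTH = 0.5  # cm beyond the PTV edge


class ConfigurationError(ValueError):
    """A phantom or run configuration violates its invariants."""


def _require_positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ConfigurationError(f"{name} must be positive, got {value!r}")


def _require_commensurate(name: str, extent: float, step: float) -> int:
    n = round(extent / step)
    if n < 1 or abs(n * step - extent) > 1e-9 * max(1.0, extent):
        raise ConfigurationError(
            f"{name}={step!r} does not divide the phantom extent {extent!r}"
        )
    return n


@dataclass(frozen=True)
class PhantomConfig:
    """Dimensions and voxel sizes of the brain phantom.

    Defaults reproduce the study geometry: a 9 x 9 x 2.2 cm phantom, a
    scoring plane of 20 um cells at 2.0 cm depth, a 3 mm material grid,
    a 1 mm-radius GTV, microscopic extension reaching 4.1 cm beyond the
    GTV surface and a 0.4 cm PTV (setup) margin.
    """

    phantom_size: tuple[float, float, float] = (9.0, 9.0, 2.2)
    scoring_depth: float = 2.0
    fine_voxel: float = 20 * UM
    coarse_voxel: float = 3 * MM
    gtv_radius: float = 0.1
    me_extent: float = 4.1
    ptv_margin: float = 0.4

    def __post_init__(self) -> None:
        for name in ("scoring_depth", "fine_voxel", "coarse_voxel",
                     "gtv_radius", "me_extent", "ptv_margin"):
            _require_positive(name, getattr(self, name))
        if len(self.phantom_size) != 3:
            raise ConfigurationError("phantom_size must be a length triple")
        for i, side in enumerate(self.phantom_size):
            _require_positive(f"phantom_size[{i}]", side)
        if self.phantom_size[0] != self.phantom_size[1]:
            raise ConfigurationError(
                "phantom_size must have equal lateral sides (square scoring plane)"
            )
        if self.scoring_depth >= self.phantom_size[2]:
            raise ConfigurationError(
                "scoring_depth must lie inside the phantom depth"
            )
        _require_commensurate("fine_voxel", self.phantom_size[0], self.fine_voxel)
        _require_commensurate("coarse_voxel", self.phantom_size[0], self.coarse_voxel)

    @property
    def lateral_extent(self) -> float:
        return self.phantom_size[0]

    @property
    def depth(self) -> float:
        return self.phantom_size[2]


@dataclass
class VoxelPhantom:
    """A built phantom: grid shapes plus lazily cached plane coordinates.

    Voxel indices are 0-based; all distances are measured between voxel
    centres.  The tumour centre defines the coordinate origin laterally and
    sits at ``scoring_depth`` along the beam axis.
    """

    config: PhantomConfig
    beam_axis: str = "z"

    @property
    def scoring_plane_shape(self) -> tuple[int, int]:
        n = round(self.config.lateral_extent / self.config.fine_voxel)
        return (n, n)

    @property
    def coarse_grid_shape(self) -> tuple[int, int, int]:
        c = self.config
        n_lat = round(c.lateral_extent / c.coarse_voxel)
        # the final depth layer may be partial (clipped at the back face)
        n_z = int(np.ceil(c.depth / c.coarse_voxel - 1e-9))
        return (n_lat, n_lat, n_z)

    @cached_property
    def plane_offsets(self) -> np.ndarray:
        """Centre coordinates of scoring-plane cells relative to the tumour axis."""
        c = self.config
        n = self.scoring_plane_shape[0]
        return (np.arange(n) + 0.5) * c.fine_voxel - c.lateral_extent / 2.0

    @cached_property
    def plane_radii(self) -> np.ndarray:
        """Lateral (Euclidean, in-plane) distance of every cell centre from the tumour centre."""
        x = self.plane_offsets
        return np.hypot(x[:, None], x[None, :])


def build_phantom(config: PhantomConfig) -> VoxelPhantom:
    """Validate ``config`` and return the phantom with grid shapes resolved.

    Grids themselves are allocated lazily on first use.
    """
    return VoxelPhantom(config=config)


def radial_distance_field(phantom: VoxelPhantom) -> np.ndarray:
    """Distance of each scoring-plane cell from the GTV *surface*.

    Cells inside the GTV are clamped to zero; this is the argument of the
    microscopic-extension probability function.
    """
    return np.maximum(0.0, phantom.plane_radii - phantom.config.gtv_radius)


@dataclass
class RegionMasks:
    """Disjoint scoring-plane partition: in-beam (PTV), penumbra, out-of-field."""

    gtv: np.ndarray
    in_beam: np.ndarray
    penumbra: np.ndarray
    out_of_field: np.ndarray
    beam_radius: float
    penumbra_width: float = DEFAULT_PENUMBRA_WIDTH


def beam_radius_for_ctv(config: PhantomConfig, ctv_margin: float) -> float:
    """Beam (PTV) radius implied by a CTV margin: GTV + CTV + PTV margins."""
    _require_positive("ctv_margin", ctv_margin)
    return config.gtv_radius + ctv_margin + config.ptv_margin


def region_masks(
    phantom: VoxelPhantom,
    beam_radius: float,
    penumbra_width: float = DEFAULT_PENUMBRA_WIDTH,
) -> RegionMasks:
    """Build the three-region partition of the scoring plane.

    A cell belongs to a disc if its centre does; cells exactly on a boundary
    belong to the inner region.
    """
    _require_positive("beam_radius", beam_radius)
    half = phantom.config.lateral_extent / 2.0
    if beam_radius > half:
        raise ConfigurationError(
            f"beam_radius={beam_radius} exceeds half the lateral extent {half}"
        )
    r = phantom.plane_radii
    in_beam = r <= beam_radius
    penumbra = (r > beam_radius) & (r <= beam_radius + penumbra_width)
    out_of_field = ~(in_beam | penumbra)
    gtv = r <= phantom.config.gtv_radius
    return RegionMasks(
        gtv=gtv,
        in_beam=in_beam,
        penumbra=penumbra,
        out_of_field=out_of_field,
        beam_radius=beam_radius,
        penumbra_width=penumbra_width,
    )
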