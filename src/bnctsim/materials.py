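"""Boron bio-distribution and composite brain/boron materials.

Cellular boron-10 concentration follows the tumour-clonogen probability
linearly: ``c = 32.5 * MEP + 13`` ug/g, i.e. 13 ug/g in normal brain and
45.5 ug/g (3.5x) in tumour cells.  For transport the continuous concentration
is quantised into a 12-step ladder; each step is a brain composition (ICRU
brain elemental mass fractions) with a trace of boron-10 mixed in and the
remaining fractions rescaled to keep the total at one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import ConfigurationError, VoxelPhantom
from .mep import MEPField, MEPParams, mep_value

# Elemental mass fractions of adult brain (ICRU-44 composition as tabulated
# in the NIST STAR material listings).  Sums to 1.000000 exactly.
BRAIN_COMPOSITION: dict[str, float] = {
    "H": 0.110667,
    "C": 0.125420,
    "N": 0.013280,
    "O": 0.737723,
    "Na": 0.001840,
    "Mg": 0.000150,
    "P": 0.003540,
    "S": 0.001770,
    "Cl": 0.002360,
    "K": 0.003100,
    "Ca": 0.000090,
    "Fe": 0.000050,
    "Zn": 0.000010,
}

BRAIN_DENSITY = 1.03  # g/cm^3, ICRP adult brain


@dataclass(frozen=True)
class BoronModelParams:
    """Linear MEP -> boron-10 concentration model and its quantisation."""

    normal_concentration: float = 13.0  # ug/g in normal brain
    tumour_ratio: float = 3.5           # tumour-to-normal concentration ratio
    n_steps: int = 12

    def __post_init__(self) -> None:
        if self.normal_concentration <= 0:
            raise ConfigurationError("normal_concentration must be positive")
        if self.tumour_ratio < 1:
            raise ConfigurationError("tumour_ratio must be >= 1")
        if self.n_steps < 1:
            raise ConfigurationError("n_steps must be >= 1")

    @property
    def slope(self) -> float:
        """ug/g increase from MEP=0 to MEP=1 (32.5 at defaults)."""
        return self.normal_concentration * (self.tumour_ratio - 1.0)

    @property
    def tumour_concentration(self) -> float:
        return self.normal_concentration * self.tumour_ratio

    @property
    def step_width(self) -> float:
        return self.slope / self.n_steps


def boron_concentration(mep, params: BoronModelParams = BoronModelParams()):
    """Cellular boron-10 concentration (ug/g) for tumour probability ``mep``."""
    arr = np.asarray(mep, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("mep must lie in [0, 1]")
    out = params.slope * arr + params.normal_concentration
    return float(out) if np.isscalar(mep) or arr.ndim == 0 else out


def quantize_concentration(concentration,
                           params: BoronModelParams = BoronModelParams()):
    """Step index (1..n_steps) from equal-width bins over the concentration range.

    The top bin is closed, so the tumour concentration maps to the last step.
    """
    arr = np.asarray(concentration, dtype=float)
    lo, hi = params.normal_concentration, params.tumour_concentration
    tol = 1e-9 * hi
    if np.any(arr < lo - tol) or np.any(arr > hi + tol):
        raise ValueError(
            f"concentration outside the modelled range [{lo}, {hi}] ug/g"
        )
    step = np.floor((arr - lo) / params.step_width).astype(np.int64) + 1
    step = np.clip(step, 1, params.n_steps)
    return int(step) if np.isscalar(concentration) or arr.ndim == 0 else step


def step_concentration(step, params: BoronModelParams = BoronModelParams()):
    """Representative (bin-midpoint) concentration of a quantisation step."""
    arr = np.asarray(step)
    if np.any(arr < 1) or np.any(arr > params.n_steps):
        raise ValueError(f"step must lie in 1..{params.n_steps}")
    out = params.normal_concentration + (arr - 0.5) * params.step_width
    return float(out) if np.isscalar(step) or arr.ndim == 0 else out


@dataclass(frozen=True)
class MaterialSpec:
    """Elemental mass fractions (summing to one) plus mass density."""

    fractions: dict[str, float] = field(
        default_factory=lambda: dict(BRAIN_COMPOSITION))
    density: float = BRAIN_DENSITY

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"mass fractions must sum to 1 (got {total!r})"
            )
        if self.density <= 0:
            raise ConfigurationError("density must be positive")

    @property
    def boron_fraction(self) -> float:
        return self.fractions.get("B10", 0.0)


def material_for_concentration(concentration: float,
                               base: MaterialSpec | None = None) -> MaterialSpec:
    """Mix ``concentration`` ug/g of boron-10 into the base tissue.

    The boron mass fraction is ``concentration * 1e-6``; all base fractions
    are rescaled by the complement so the total stays at one.
    """
    if base is None:
        base = MaterialSpec()
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    w_b = concentration * 1e-6
    fractions = {el: f * (1.0 - w_b) for el, f in base.fractions.items()
                 if el != "B10"}
    if w_b > 0:
        fractions["B10"] = w_b
    return MaterialSpec(fractions=fractions, density=base.density)


def material_for_step(step: int,
                      params: BoronModelParams = BoronModelParams(),
                      base: MaterialSpec | None = None) -> MaterialSpec:
    """Composite material of one quantisation step (bin-midpoint boron load)."""
    return material_for_concentration(step_concentration(step, params), base)


def material_table(params: BoronModelParams = BoronModelParams(),
                   base: MaterialSpec | None = None) -> list[MaterialSpec]:
    """All ``n_steps`` composite materials, indexed by ``step - 1``."""
    return [material_for_step(s, params, base)
            for s in range(1, params.n_steps + 1)]


def assign_materials(phantom: VoxelPhantom,
                     mep: MEPField | MEPParams,
                     params: BoronModelParams = BoronModelParams()) -> np.ndarray:
    """Step index (1..n_steps) for every coarse voxel.

    Transport is three-dimensional, so each coarse voxel is classified by the
    3-D distance of its centre from the tumour centre (the scoring-plane MEP
    field itself uses lateral distance only; both use the same radial
    function).  Deterministic.
    """
    mep_params = mep.params if isinstance(mep, MEPField) else mep
    cfg = phantom.config
    nx, ny, nz = phantom.coarse_grid_shape
    lat = (np.arange(nx) + 0.5) * cfg.coarse_voxel - cfg.lateral_extent / 2.0
    zc = (np.arange(nz) + 0.5) * cfg.coarse_voxel
    d3 = np.sqrt(lat[:, None, None] ** 2 + lat[None, :, None] ** 2
                 + (zc[None, None, :] - cfg.scoring_depth) ** 2)
    x = np.maximum(0.0, d3 - cfg.gtv_radius)
    probs = mep_value(x, mep_params)
    probs[d3 <= cfg.gtv_radius] = 1.0
    conc = boron_concentration(probs, params)
    return quantize_concentration(conc, params).astype(np.int8)


@dataclass
class MaterialMap:
    """Coarse step-index grid together with the step material ladder."""

    step_grid: np.ndarray          # (nx, ny, nz) indices in 1..n_steps
    table: list[MaterialSpec]      # table[step - 1]

    def __post_init__(self) -> None:
        if self.step_grid.min() < 1 or self.step_grid.max() > len(self.table):
            raise ConfigurationError("step grid indices outside material table")


def build_material_map(phantom: VoxelPhantom,
                       mep: MEPField | MEPParams,
                       params: BoronModelParams = BoronModelParams(),
                       base: MaterialSpec | None = None) -> MaterialMap:
    """Convenience: assign step indices and build the matching material ladder."""
    return MaterialMap(step_grid=assign_materials(phantom, mep, params),
                       table=material_table(params, base))
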