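"""Microscopic-extension probability (MEP) field and its calibration.

Glioblastoma infiltrates normal brain well beyond the imaged tumour.  The MEP
model assigns every cell a probability of being a tumour clonogen as a
three-term Gaussian function of its radial distance ``x`` from the GTV
surface, truncated to zero beyond a hard cutoff (4.1 cm).  The field is an
expected-count (probability) field: clonogen numbers are sums of
probabilities, never Bernoulli draws.

The nine Gaussian coefficients of the underlying clinical fit are not
published; the defaults here are a documented placeholder with unit value at
the GTV surface, and :func:`calibrate_mep` rescales the two outer widths so
that the field reproduces a pair of target clonogen counts (full plane and
penumbra annulus).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .phantom import (
    ConfigurationError,
    DEFAULT_PENUMBRA_WIDTH,
    VoxelPhantom,
    radial_distance_field,
)


class CalibrationError(RuntimeError):
    """MEP width calibration failed to reach its targets."""


@dataclass(frozen=True)
class MEPParams:
    """Coefficients of the three-term Gaussian MEP function.

    ``amplitudes`` are dimensionless, ``centres`` and ``widths`` are in cm.
    Construction enforces MEP(0) = 1 (to 1e-9) and 0 <= MEP(x) <= 1 on a
    dense grid up to the cutoff; pass ``validate=False`` only for degenerate
    test parameter sets.
    """

    amplitudes: tuple[float, float, float] = (0.05, 0.75, 0.2)
    centres: tuple[float, float, float] = (0.0, 0.0, 0.0)
    widths: tuple[float, float, float] = (0.3, 1.4, 3.5)
    cutoff: float = 4.1
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.validate:
            return
        if any(c <= 0 for c in self.widths):
            raise ConfigurationError("MEP widths must all be positive")
        if self.cutoff <= 0:
            raise ConfigurationError("MEP cutoff must be positive")
        grid = np.linspace(0.0, self.cutoff, 4097)
        vals = self._raw(grid)
        if abs(vals[0] - 1.0) > 1e-9:
            raise ConfigurationError(
                f"MEP(0) must equal 1 (got {vals[0]!r}); adjust amplitudes/centres"
            )
        if vals.max() > 1.0 + 1e-9 or vals.min() < -1e-9:
            raise ConfigurationError("MEP must stay within [0, 1] up to the cutoff")

    def _raw(self, x: np.ndarray) -> np.ndarray:
        """Three-term Gaussian sum without cutoff or clamping."""
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for a, b, c in zip(self.amplitudes, self.centres, self.widths):
            out += a * np.exp(-(((x - b) / c) ** 2))
        return out


def mep_value(x, params: MEPParams):
    """Evaluate the MEP function at distance ``x`` (cm) from the GTV surface.

    Scalar or array input.  Negative ``x`` is an error: callers must clamp
    distances inside the GTV to zero first.  The value is exactly zero beyond
    the cutoff and clamped to [0, 1] against floating-point overshoot.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("x must be non-negative (clamp inside the GTV first)")
    vals = np.where(arr <= params.cutoff, params._raw(arr), 0.0)
    vals = np.clip(vals, 0.0, 1.0)
    return float(vals) if np.isscalar(x) or arr.ndim == 0 else vals


@dataclass
class MEPField:
    """Per-cell tumour-clonogen probabilities on the scoring plane."""

    values: np.ndarray
    params: MEPParams
    total_clonogens: float


def mep_field(phantom: VoxelPhantom, params: MEPParams) -> MEPField:
    """Evaluate the MEP over the scoring plane; GTV cells are forced to 1."""
    x = radial_distance_field(phantom)
    values = mep_value(x, params)
    values[phantom.plane_radii <= phantom.config.gtv_radius] = 1.0
    return MEPField(values=values, params=params,
                    total_clonogens=float(values.sum()))


def clonogen_count(fld: MEPField | np.ndarray, mask: np.ndarray) -> float:
    """Expected clonogen count: sum of MEP values over masked cells."""
    values = fld.values if isinstance(fld, MEPField) else np.asarray(fld)
    mask = np.asarray(mask)
    if mask.shape != values.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match field shape {values.shape}"
        )
    return float(values[mask].sum())


# --------------------------------------------------------------------------
# Radial lattice histogram: the field is radially symmetric, so plane sums
# reduce to sums over thin radius bins weighted by lattice cell counts.  The
# bin width is chosen to divide the region boundaries so no bin straddles a
# mask edge; evaluating at the per-bin mean radius makes the approximation
# second-order accurate (error << 1e-6 relative at default widths).

@dataclass
class _RadialHistogram:
    counts: np.ndarray    # lattice cells per radius bin
    mean_r: np.ndarray    # mean cell-centre radius per bin
    bin_width: float

    def field_values(self, params: MEPParams, gtv_radius: float) -> np.ndarray:
        x = np.maximum(0.0, self.mean_r - gtv_radius)
        vals = mep_value(x, params)
        vals[self.mean_r <= gtv_radius] = 1.0
        return vals


def _radial_histogram(phantom: VoxelPhantom, bin_width: float | None = None
                      ) -> _RadialHistogram:
    if bin_width is None:
        bin_width = phantom.config.fine_voxel / 4.0
    r = phantom.plane_radii.ravel()
    idx = np.floor(r / bin_width).astype(np.int64)
    counts = np.bincount(idx)
    sums = np.bincount(idx, weights=r)
    mean_r = sums / np.maximum(counts, 1)
    return _RadialHistogram(counts=counts, mean_r=mean_r, bin_width=bin_width)


def _histogram_counts(hist: _RadialHistogram, params: MEPParams,
                      gtv_radius: float, beam_radius: float,
                      penumbra_width: float) -> tuple[float, float]:
    vals = hist.field_values(params, gtv_radius)
    weighted = hist.counts * vals
    total = float(weighted.sum())
    pen = (hist.mean_r > beam_radius) & (hist.mean_r <= beam_radius + penumbra_width)
    return total, float(weighted[pen].sum())


def calibrate_mep(
    template: MEPParams,
    targets: tuple[float, float],
    phantom: VoxelPhantom,
    beam_radius: float,
    penumbra_width: float = DEFAULT_PENUMBRA_WIDTH,
    rel_tol: float = 1e-3,
) -> MEPParams:
    """Rescale the two outer Gaussian widths to match clonogen-count targets.

    ``targets`` is ``(total, penumbra)``: the expected clonogen count over the
    whole scoring plane and over the penumbra annulus just outside
    ``beam_radius``.  The template must have all centres at zero and
    amplitudes summing to one (so that MEP(0) = 1 is preserved under any
    width scaling).  The optimisation is deterministic (fixed start at unit
    multipliers, Levenberg-Marquardt on log-multipliers).

    Raises :class:`CalibrationError` if the targets are infeasible or the
    achieved counts miss either target by more than ``rel_tol`` relative.
    """
    total_target, penumbra_target = targets
    if total_target <= 0 or penumbra_target <= 0:
        raise CalibrationError("clonogen count targets must be positive")
    if penumbra_target >= total_target:
        raise CalibrationError(
            f"penumbra target {penumbra_target} must be below the total "
            f"target {total_target}"
        )
    if any(abs(b) > 0 for b in template.centres):
        raise ConfigurationError("calibration template requires all centres at 0")
    if abs(sum(template.amplitudes) - 1.0) > 1e-9:
        raise ConfigurationError("calibration template amplitudes must sum to 1")

    hist = _radial_histogram(phantom)
    gtv = phantom.config.gtv_radius
    c1, c2, c3 = template.widths

    def with_multipliers(z: np.ndarray) -> MEPParams:
        m2, m3 = np.exp(z)
        return replace(template, widths=(c1, c2 * m2, c3 * m3))

    def residuals(z: np.ndarray) -> np.ndarray:
        total, pen = _histogram_counts(
            hist, with_multipliers(z), gtv, beam_radius, penumbra_width
        )
        return np.array([total / total_target - 1.0,
                         pen / penumbra_target - 1.0])

    result = least_squares(residuals, x0=np.zeros(2), method="lm",
                           xtol=1e-14, ftol=1e-14, gtol=1e-14)
    achieved = residuals(result.x)
    if np.max(np.abs(achieved)) > rel_tol:
        total, pen = _histogram_counts(
            hist, with_multipliers(result.x), gtv, beam_radius, penumbra_width
        )
        raise CalibrationError(
            "calibration did not converge: achieved counts "
            f"(total={total:.1f}, penumbra={pen:.1f}) vs targets "
            f"(total={total_target}, penumbra={penumbra_target}); "
            f"relative misses {achieved}"
        )
    return with_multipliers(result.x)
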