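"""Linear-quadratic cell survival and region survival fractions.

Each cell's survival probability is its tumour-clonogen probability damped by
the linear-quadratic response to its weighted dose:

    SP = MEP * exp(-(alpha * d + beta * d^2))

Survival fractions are expected surviving clonogens in a region divided by
the total clonogen count before treatment (one shared denominator for all
regions), expressed in percent.  Everything is expected-value arithmetic:
sums of probabilities, no Bernoulli realisations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import RegionMasks, VoxelPhantom
from .mep import MEPField
from .dose import RBEDoseField

# Reference survival fractions (percent) of the companion photon-therapy
# model for the homogeneous-hypoxic tumour, used as published comparison
# inputs; the x-ray dose chain itself is out of scope here.
XRAY_REFERENCE_SF = {"in_beam": 3.22e-3, "penumbra": 6.71, "total": 12.79}
# Cumulative total SF (percent) by CTV margin for both modalities, as
# published: {modality: (2.0 cm margin, 2.5 cm margin)}.
CTV_REFERENCE_SF = {"bnct": (3.85, 1.78), "xray": (12.81, 3.47)}


@dataclass(frozen=True)
class LQParams:
    """Linear-quadratic radiosensitivity (glioblastoma population means)."""

    alpha: float = 0.281   # 1/Gy
    beta: float = 0.02     # 1/Gy^2
    oer: float = 1.0       # oxygen enhancement ratio; 1 for high-LET
    fractions: int = 1

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.oer < 1:
            raise ValueError("oer must be >= 1")
        if self.fractions < 1:
            raise ValueError("fractions must be >= 1")


def survival_probability(mep, dose, lq: LQParams = LQParams()):
    """Per-cell survival probability: MEP damped by the LQ exponent.

    ``dose`` is the weighted dose per fraction (RBE-Gy); hypoxia enters as a
    dose-dividing factor ``d_eff = d / OER``.
    """
    mep_arr = np.asarray(mep, dtype=float)
    dose_arr = np.asarray(dose, dtype=float)
    if np.any(dose_arr < 0):
        raise ValueError("dose must be non-negative")
    d_eff = dose_arr / lq.oer
    sp = mep_arr * np.exp(-lq.fractions * (lq.alpha * d_eff + lq.beta * d_eff ** 2))
    scalar = np.isscalar(mep) and np.isscalar(dose)
    return float(sp) if scalar else sp


@dataclass
class SurvivalField:
    """Per-cell survival probabilities on the scoring plane."""

    sp: np.ndarray
    phantom: VoxelPhantom
    lq: LQParams


def survival_field(mep: MEPField, dose: RBEDoseField, phantom: VoxelPhantom,
                   lq: LQParams = LQParams()) -> SurvivalField:
    if mep.values.shape != dose.values.shape:
        raise ValueError("MEP field and dose field shapes differ")
    return SurvivalField(sp=survival_probability(mep.values, dose.values, lq),
                         phantom=phantom, lq=lq)


def surviving_cells(fld: SurvivalField | np.ndarray, mask: np.ndarray) -> float:
    """Expected number of surviving clonogens in a masked region."""
    sp = fld.sp if isinstance(fld, SurvivalField) else np.asarray(fld)
    mask = np.asarray(mask)
    if mask.shape != sp.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match field shape {sp.shape}")
    return float(sp[mask].sum())


@dataclass
class SurvivalReport:
    """Region survival fractions (percent) and the underlying counts."""

    sf_within_beam: float
    sf_penumbra: float
    sf_out_of_field: float
    sf_total: float
    surviving: dict[str, float]
    total_clonogens_before: float
    penumbra_clonogens_before: float
    differential: pd.DataFrame | None = field(default=None, repr=False)

    def region_sfs(self) -> dict[str, float]:
        return {"in_beam": self.sf_within_beam, "penumbra": self.sf_penumbra,
                "out_of_field": self.sf_out_of_field, "total": self.sf_total}


def region_survival_fractions(fld: SurvivalField, masks: RegionMasks,
                              mep: MEPField) -> SurvivalReport:
    """Survival fractions for in-beam / penumbra / out-of-field regions.

    All three use one shared denominator: the full-plane clonogen count
    before treatment.
    """
    total_before = float(mep.values.sum())
    if total_before <= 0:
        raise ValueError("total clonogen count before treatment is zero")
    counts = {
        "in_beam": surviving_cells(fld, masks.in_beam),
        "penumbra": surviving_cells(fld, masks.penumbra),
        "out_of_field": surviving_cells(fld, masks.out_of_field),
    }
    counts["total"] = counts["in_beam"] + counts["penumbra"] + counts["out_of_field"]
    pct = {k: 100.0 * v / total_before for k, v in counts.items()}
    return SurvivalReport(
        sf_within_beam=pct["in_beam"],
        sf_penumbra=pct["penumbra"],
        sf_out_of_field=pct["out_of_field"],
        sf_total=pct["total"],
        surviving=counts,
        total_clonogens_before=total_before,
        penumbra_clonogens_before=float(mep.values[masks.penumbra].sum()),
    )


def differential_sf(fld: SurvivalField, mep: MEPField,
                    rim_width: float = 0.05) -> pd.DataFrame:
    """Differential survival fraction in concentric rims around the tumour centre.

    Each rim's expected surviving clonogens are divided by the total initial
    clonogen count; the curve is indexed by rim centre and outer radius (cm)
    and given in percent.
    """
    if rim_width <= 0:
        raise ValueError("rim_width must be positive")
    r = fld.phantom.plane_radii
    total_before = float(mep.values.sum())
    if total_before <= 0:
        raise ValueError("no clonogens before treatment")
    k = np.floor(r / rim_width).astype(np.int64)
    n_rims = int(k.max()) + 1
    surv = np.bincount(k.ravel(), weights=fld.sp.ravel(), minlength=n_rims)
    outer = (np.arange(n_rims) + 1) * rim_width
    return pd.DataFrame({
        "r_center_cm": outer - rim_width / 2.0,
        "r_outer_cm": outer,
        "sf_percent": 100.0 * surv / total_before,
    })


def sf_change(sf_small: float, sf_large: float) -> float:
    """Percent SF reduction when the CTV margin is extended.

    ``100 * (SF_small_margin - SF_large_margin) / SF_small_margin``.
    """
    if sf_small == 0:
        raise ValueError("sf_small must be non-zero")
    return 100.0 * (sf_small - sf_large) / sf_small


def _region_sfs(report) -> dict[str, float]:
    if isinstance(report, SurvivalReport):
        return report.region_sfs()
    return dict(report)


def compare_modalities(report_a, report_b) -> pd.DataFrame:
    """Per-region comparison of two treatments (computed reports or published SFs).

    Returns, per region present in both inputs, the two SFs, the ratio
    ``b / a`` and the percent change ``100 * (b - a) / b`` (the reduction of
    a relative to b).  Either argument may be a mapping from region name to
    SF percent, so published values can stand in for a computed report.
    """
    a = _region_sfs(report_a)
    b = _region_sfs(report_b)
    rows = []
    for region in [r for r in a if r in b]:
        if a[region] == 0 or b[region] == 0:
            raise ValueError(f"zero SF in region {region!r}; ratio undefined")
        rows.append({
            "region": region,
            "sf_a": a[region],
            "sf_b": b[region],
            "ratio_b_over_a": b[region] / a[region],
            "change_percent": 100.0 * (b[region] - a[region]) / b[region],
        })
    return pd.DataFrame(rows)


def summarize_replicates(reports: list[SurvivalReport]) -> pd.DataFrame:
    """Mean and standard deviation of region SFs over replicate dose runs."""
    if not reports:
        raise ValueError("no reports to summarise")
    frame = pd.DataFrame([r.region_sfs() for r in reports])
    return pd.DataFrame({"mean": frame.mean(), "sd": frame.std(ddof=1)
                         if len(reports) > 1 else 0.0 * frame.mean()})
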