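"""End-to-end orchestration: config -> phantom -> MEP -> materials -> transport
-> weighted dose -> survival report.

The full-scale study configuration (20 um scoring cells, billions of
histories) is not desk-reproducible; the ``reduced`` preset keeps the same
physics on a 100 um scoring plane with about a million histories and a
+-0.5 mm scoring-slab average, which is the configuration the bundled
analyses use.  MEP width calibration always runs against the 20 um lattice
regardless of the run preset, because the clonogen-count targets are defined
at cell scale.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__ as _version
from .phantom import (PhantomConfig, RegionMasks, VoxelPhantom, UM,
                      beam_radius_for_ctv, build_phantom, region_masks)
from .mep import MEPField, MEPParams, calibrate_mep, mep_field
from .materials import (BoronModelParams, MaterialMap, MaterialSpec,
                        build_material_map)
from .transport import (CrossSectionSet, DoseComponents, NeutronSource,
                        run_transport)
from .dose import (DEFAULT_PRESCRIPTION, RBEDoseField, TUMOUR_WEIGHTS,
                   RBEWeights, combine_rbe_dose, normalize_to_prescription)
from .survival import (LQParams, SurvivalReport, differential_sf,
                       region_survival_fractions, summarize_replicates,
                       survival_field)
from .gridio import export_profiles_csv, write_dose_components

# Clonogen-count calibration targets on the 20 um scoring plane:
# (full plane, penumbra annulus of the 2.5 cm beam).
DEFAULT_CLONOGEN_TARGETS = (2_908_500.0, 299_420.0)

PRESETS = {
    # fine voxel (cm), scoring-slab halfwidth (cm; None = bare slice),
    # radial boxcar half-width (cm) for the dose-profile estimator
    "full": {"fine_voxel": 20 * UM, "slab_halfwidth": None,
             "radial_smoothing": 0.02},
    "reduced": {"fine_voxel": 100 * UM, "slab_halfwidth": 0.05,
                "radial_smoothing": 0.1},
}


@dataclass
class RunConfig:
    """Everything one simulation run needs; see PRESETS for the scale knobs."""

    preset: str = "reduced"
    ctv_margin: float = 2.0          # cm
    n_histories: int = 1_000_000
    n_replicates: int = 4
    seed: int = 0
    prescription: float = DEFAULT_PRESCRIPTION
    calibrate: bool = True
    clonogen_targets: tuple[float, float] = DEFAULT_CLONOGEN_TARGETS
    mep: MEPParams = field(default_factory=MEPParams)
    boron: BoronModelParams = field(default_factory=BoronModelParams)
    lq: LQParams = field(default_factory=LQParams)
    weights: RBEWeights = field(default_factory=lambda: TUMOUR_WEIGHTS)
    xs: CrossSectionSet = field(default_factory=CrossSectionSet)
    phantom: PhantomConfig | None = None      # None -> defaults at preset scale
    source: NeutronSource | None = None       # None -> default epithermal beam
    slab_halfwidth: float | None = None       # None -> preset value
    radial_smoothing: float | None = None     # None -> preset value
    biased: bool = True
    radial_average: bool = True
    include_capture_gamma: bool = True
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.n_replicates < 1 or self.n_histories < 1:
            raise ValueError("n_histories and n_replicates must be >= 1")

    def phantom_config(self) -> PhantomConfig:
        if self.phantom is not None:
            return self.phantom
        return PhantomConfig(fine_voxel=PRESETS[self.preset]["fine_voxel"])

    def effective_slab_halfwidth(self) -> float | None:
        if self.slab_halfwidth is not None:
            return self.slab_halfwidth
        return PRESETS[self.preset]["slab_halfwidth"]

    def effective_radial_smoothing(self) -> float | None:
        if self.radial_smoothing is not None:
            return self.radial_smoothing
        return PRESETS[self.preset]["radial_smoothing"]


@dataclass
class PipelineResult:
    phantom: VoxelPhantom
    masks: RegionMasks
    mep_params: MEPParams
    mep: MEPField
    materials: MaterialMap
    components: list[DoseComponents]
    rbe_fields: list[RBEDoseField]
    factors: list[float]
    reports: list[SurvivalReport]
    summary: "object"              # pandas DataFrame: mean/sd per region
    provenance: dict


def _child_seeds(master_seed: int, n: int) -> list[int]:
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in children]


def _config_digest(config: RunConfig) -> str:
    blob = repr(config).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full chain and (optionally) write a run directory.

    Deterministic for a fixed seed: replicate transport seeds are spawned
    from the master seed and recorded in the provenance log.
    """
    pcfg = config.phantom_config()
    phantom = build_phantom(pcfg)
    beam_radius = beam_radius_for_ctv(pcfg, config.ctv_margin)
    masks = region_masks(phantom, beam_radius)

    params = config.mep
    if config.calibrate:
        calib_phantom = build_phantom(replace(pcfg, fine_voxel=20 * UM))
        # targets are tied to the 2.0 cm CTV penumbra geometry
        calib_radius = beam_radius_for_ctv(pcfg, 2.0)
        params = calibrate_mep(params, config.clonogen_targets,
                               calib_phantom, calib_radius)

    fld = mep_field(phantom, params)
    mmap = build_material_map(phantom, params, config.boron)
    source = config.source or NeutronSource.default_epithermal(beam_radius)

    seeds = _child_seeds(config.seed, config.n_replicates)
    components, rbe_fields, factors, reports = [], [], [], []
    for child_seed in seeds:
        comps = run_transport(
            phantom, mmap, source, config.xs,
            n_histories=config.n_histories, seed=child_seed,
            biased=config.biased, radial_average=config.radial_average,
            slab_halfwidth=config.effective_slab_halfwidth(),
            radial_smoothing=config.effective_radial_smoothing(),
            include_capture_gamma=config.include_capture_gamma,
        )
        rbe = combine_rbe_dose(comps, config.weights, tissue="tumour")
        rbe, comps, factor = normalize_to_prescription(
            rbe, comps, masks.gtv, config.prescription)
        sfield = survival_field(fld, rbe, phantom, config.lq)
        report = region_survival_fractions(sfield, masks, fld)
        report.differential = differential_sf(sfield, fld)
        components.append(comps)
        rbe_fields.append(rbe)
        factors.append(factor)
        reports.append(report)

    summary = summarize_replicates(reports)
    provenance = {
        "package_version": _version,
        "numpy_version": np.__version__,
        "config_digest": _config_digest(config),
        "master_seed": config.seed,
        "replicate_seeds": seeds,
        "preset": config.preset,
        "n_histories": config.n_histories,
        "ctv_margin_cm": config.ctv_margin,
        "beam_radius_cm": beam_radius,
        "prescription_rbe_gy": config.prescription,
        "calibrated_widths_cm": list(params.widths),
        "normalization_factors": factors,
    }
    result = PipelineResult(
        phantom=phantom, masks=masks, mep_params=params, mep=fld,
        materials=mmap, components=components, rbe_fields=rbe_fields,
        factors=factors, reports=reports, summary=summary,
        provenance=provenance,
    )
    if config.outdir is not None:
        _write_run_directory(Path(config.outdir), config, result)
    return result


def _write_run_directory(outdir: Path, config: RunConfig,
                         result: PipelineResult) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "provenance.json").write_text(
        json.dumps(result.provenance, indent=2))
    report_payload = {
        "summary": {region: {"mean": float(result.summary["mean"][region]),
                             "sd": float(result.summary["sd"][region])}
                    for region in result.summary.index},
        "replicates": [r.region_sfs() for r in result.reports],
        "total_clonogens_before": result.reports[0].total_clonogens_before,
        "penumbra_clonogens_before":
            result.reports[0].penumbra_clonogens_before,
    }
    (outdir / "report.json").write_text(json.dumps(report_payload, indent=2))
    result.reports[0].differential.to_csv(
        outdir / "differential_sf.csv", index=False)
    write_dose_components(outdir / "dose", result.components[0],
                          result.phantom)
    export_profiles_csv(outdir / "dose_profiles.csv", result.components[0],
                        result.phantom)


# --------------------------------------------------------------------------
# Miniature fixtures with closed-form structure, for fast oracle tests.

_TINY_PHANTOM = PhantomConfig(
    phantom_size=(0.9, 0.9, 0.6), scoring_depth=0.3, fine_voxel=0.01,
    coarse_voxel=0.3, gtv_radius=0.05, me_extent=0.3, ptv_margin=0.05)

FIXTURE_KINDS = ("uniform-dose", "gtv-only", "absorber-slab")


def make_fixture(kind: str, seed: int = 0) -> dict:
    """Build one of the documented miniature test inputs.

    ``uniform-dose``: tiny phantom with a spatially uniform 2 Gy weighted
    dose, so the survival chain has a closed-form answer everywhere.
    ``gtv-only``: degenerate MEP field that is 1 inside the GTV and 0
    elsewhere (clonogen count equals the lattice-disc cell count).
    ``absorber-slab``: a deep phantom filled with a pure boron-10 absorber,
    for analytic exponential-attenuation checks.
    """
    rng = np.random.default_rng(seed)
    if kind == "uniform-dose":
        phantom = build_phantom(_TINY_PHANTOM)
        params = MEPParams(cutoff=0.3)
        fld = mep_field(phantom, params)
        dose = RBEDoseField(values=np.full(phantom.scoring_plane_shape, 2.0),
                            weights=TUMOUR_WEIGHTS)
        masks = region_masks(phantom, beam_radius=0.2, penumbra_width=0.1)
        return {"phantom": phantom, "mep": fld, "dose": dose,
                "masks": masks, "lq": LQParams(), "rng": rng}
    if kind == "gtv-only":
        phantom = build_phantom(_TINY_PHANTOM)
        params = MEPParams(amplitudes=(0.0, 0.0, 0.0), cutoff=0.3,
                           validate=False)
        fld = mep_field(phantom, params)
        masks = region_masks(phantom, beam_radius=0.2, penumbra_width=0.1)
        return {"phantom": phantom, "mep": fld, "masks": masks, "rng": rng}
    if kind == "absorber-slab":
        phantom = build_phantom(PhantomConfig(
            phantom_size=(0.9, 0.9, 30.0), scoring_depth=15.0,
            fine_voxel=0.01, coarse_voxel=0.3, gtv_radius=0.05,
            me_extent=0.3, ptv_margin=0.05))
        absorber = MaterialSpec(fractions={"B10": 1.0}, density=0.01)
        shape = phantom.coarse_grid_shape
        mmap = MaterialMap(step_grid=np.ones(shape, dtype=np.int8),
                           table=[absorber])
        return {"phantom": phantom, "materials": mmap,
                "absorber": absorber, "rng": rng}
    raise ValueError(f"unknown fixture kind {kind!r}; "
                     f"expected one of {FIXTURE_KINDS}")
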