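"""YAML run-configuration loading.

All lengths in the config file carry explicit units (``"2.0 cm"``,
``"100 um"``); bare numbers are rejected for length fields so units are never
ambiguous.  Every section and key is optional; omitted values fall back to
the study defaults.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import yaml

from .phantom import ConfigurationError, PhantomConfig
from .mep import MEPParams
from .materials import BoronModelParams
from .survival import LQParams
from .dose import RBEWeights
from .transport import NeutronSource
from .pipeline import RunConfig

_LENGTH_UNITS = {"cm": 1.0, "mm": 0.1, "um": 1e-4, "µm": 1e-4, "m": 100.0}


def parse_length(value) -> float:
    """Parse a unit-annotated length string into centimetres."""
    if isinstance(value, str):
        parts = value.split()
        if len(parts) == 2 and parts[1] in _LENGTH_UNITS:
            return float(parts[0]) * _LENGTH_UNITS[parts[1]]
        raise ConfigurationError(
            f"length {value!r} must look like '<number> <unit>' with unit in "
            f"{sorted(_LENGTH_UNITS)}")
    raise ConfigurationError(
        f"length {value!r} must be a unit-annotated string, e.g. '2.0 cm'")


def _lengths(values) -> tuple[float, ...]:
    return tuple(parse_length(v) for v in values)


def load_run_config(path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig()

    run = raw.get("run", {})
    cfg = replace(
        cfg,
        preset=run.get("preset", cfg.preset),
        n_histories=int(run.get("n_histories", cfg.n_histories)),
        n_replicates=int(run.get("n_replicates", cfg.n_replicates)),
        seed=int(run.get("seed", cfg.seed)),
        prescription=float(run.get("prescription_rbe_gy", cfg.prescription)),
    )

    beam = raw.get("beam", {})
    if "ctv_margin" in beam:
        cfg = replace(cfg, ctv_margin=parse_length(beam["ctv_margin"]))

    if "phantom" in raw:
        ph = raw["phantom"]
        base = cfg.phantom_config()
        updates = {}
        if "size" in ph:
            updates["phantom_size"] = _lengths(ph["size"])
        for key in ("scoring_depth", "fine_voxel", "coarse_voxel",
                    "gtv_radius", "me_extent", "ptv_margin"):
            if key in ph:
                updates[key] = parse_length(ph[key])
        cfg = replace(cfg, phantom=replace(base, **updates))

    if "mep" in raw:
        mp = raw["mep"]
        cfg = replace(cfg, mep=MEPParams(
            amplitudes=tuple(mp.get("amplitudes", cfg.mep.amplitudes)),
            centres=_lengths(mp["centres"]) if "centres" in mp
            else cfg.mep.centres,
            widths=_lengths(mp["widths"]) if "widths" in mp
            else cfg.mep.widths,
            cutoff=parse_length(mp["cutoff"]) if "cutoff" in mp
            else cfg.mep.cutoff,
        ))

    if "boron" in raw:
        bo = raw["boron"]
        cfg = replace(cfg, boron=BoronModelParams(
            normal_concentration=float(bo.get("normal_concentration_ug_g",
                                              cfg.boron.normal_concentration)),
            tumour_ratio=float(bo.get("tumour_ratio", cfg.boron.tumour_ratio)),
            n_steps=int(bo.get("n_steps", cfg.boron.n_steps)),
        ))

    if "calibration" in raw:
        cal = raw["calibration"]
        cfg = replace(
            cfg,
            calibrate=bool(cal.get("enabled", cfg.calibrate)),
            clonogen_targets=(float(cal.get("total", cfg.clonogen_targets[0])),
                              float(cal.get("penumbra",
                                            cfg.clonogen_targets[1]))),
        )

    if "lq" in raw:
        lq = raw["lq"]
        cfg = replace(cfg, lq=LQParams(
            alpha=float(lq.get("alpha_per_gy", cfg.lq.alpha)),
            beta=float(lq.get("beta_per_gy2", cfg.lq.beta)),
            oer=float(lq.get("oer", cfg.lq.oer)),
            fractions=int(lq.get("fractions", cfg.lq.fractions)),
        ))

    if "weights" in raw:
        w = raw["weights"]
        cfg = replace(cfg, weights=RBEWeights(
            w_gamma=float(w.get("gamma", cfg.weights.w_gamma)),
            w_fast=float(w.get("fast", cfg.weights.w_fast)),
            w_thermal=float(w.get("thermal", cfg.weights.w_thermal)),
            w_boron=float(w.get("boron", cfg.weights.w_boron)),
        ))

    if "spectrum" in raw:
        sp = raw["spectrum"]
        beam_radius = (cfg.phantom_config().gtv_radius + cfg.ctv_margin
                       + cfg.phantom_config().ptv_margin)
        cfg = replace(cfg, source=NeutronSource(
            beam_radius=beam_radius,
            energies=[float(e) for e in sp["energies_ev"]],
            intensities=[float(i) for i in sp["intensities"]],
        ))

    return cfg
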