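"""Run-configuration schema, validation and output writing.

Configs are YAML mappings mirroring :class:`~continuum.engine.SimConfig`
plus run-control fields (``ticks``, ``snapshot_every``, output paths).
Validation is aggregated: every problem in the file is reported at once,
together with the neighborhood-size warnings (NM < 5: mate limitation;
NX < 5: noisy density) that flag scientifically questionable settings
without rejecting them.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .engine import RunResult, SimConfig
from .genetics import SelectionModel
from .kernels import Bounds, Kernel
from .landscape import RasterMap, read_raster, write_raster_csv
from .regulation import RegulationModel

__all__ = ["RunConfig", "ConfigError", "load_config", "validate_config", "write_outputs"]


class ConfigError(ValueError):
    """Aggregated configuration errors; ``.errors`` lists every problem."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.errors))


@dataclass
class RunConfig:
    """A validated run: the engine config plus run control and provenance."""

    sim: SimConfig
    ticks: int = 100
    snapshot_every: int = 0
    raw: dict = field(default_factory=dict)
    warnings: tuple = ()


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = Path(path).parent
    return validate_config(raw, base_dir=base)


def _kernel_from(spec, errors, where) -> Kernel | None:
    if spec is None:
        return None
    try:
        return Kernel(
            spec.get("family", "gaussian"),
            float(spec["scale"]),
            df=spec.get("df"),
            max_distance=spec.get("max_distance"),
        )
    except (KeyError, ValueError, TypeError) as e:
        errors.append(f"{where}: {e}")
        return None


def _regulation_from(spec, errors) -> RegulationModel | None:
    try:
        fam = spec["family"]
        params = {k: v for k, v in spec.items() if k != "family"}
        return RegulationModel(fam, params)
    except (KeyError, ValueError, TypeError) as e:
        errors.append(f"regulation: {e}")
        return None


def validate_config(raw: dict, base_dir=None) -> RunConfig:
    """Validate a raw config mapping into a :class:`RunConfig`.

    Raises :class:`ConfigError` listing *all* invalid fields; attaches
    neighborhood-size warnings instead of failing on them."""
    errors: list[str] = []
    notes: list[str] = []
    raw = dict(raw or {})
    base_dir = Path(base_dir) if base_dir is not None else Path(".")

    b = raw.get("bounds", {})
    bounds = None
    try:
        bounds = Bounds(
            float(b.get("x_min", 0.0)),
            float(b.get("x_max", 25.0)),
            float(b.get("y_min", 0.0)),
            float(b.get("y_max", 25.0)),
            b.get("boundary", "reprising"),
        )
    except (ValueError, TypeError, AttributeError) as e:
        errors.append(f"bounds: {e}")

    K = raw.get("K", 5.0)
    if not (isinstance(K, (int, float)) and K > 0):
        errors.append(f"K: must be a positive density (got {K!r})")

    kspec = raw.get("kernels", {})
    interaction = _kernel_from(kspec.get("interaction", {"scale": 1.0}), errors, "kernels.interaction")
    dispersal = _kernel_from(kspec.get("dispersal", {"scale": 1.0}), errors, "kernels.dispersal")
    mating = _kernel_from(kspec.get("mating"), errors, "kernels.mating")
    movement = _kernel_from(kspec.get("movement"), errors, "kernels.movement")

    regulation = _regulation_from(raw.get("regulation", {"family": "bh_mortality", "f": 1.0, "a": 1.0}), errors)

    sspec = raw.get("selection", {}) or {}
    try:
        selection = SelectionModel(
            s=float(sspec.get("s", 0.0)),
            h=float(sspec.get("h", 0.5)),
            mode=sspec.get("mode", "none"),
            mu_neutral=float(sspec.get("mu_neutral", 0.0)),
        )
    except (ValueError, TypeError) as e:
        errors.append(f"selection: {e}")
        selection = SelectionModel()

    maps = {}
    for key in ("k_map", "fecundity_map", "survival_map"):
        spec = (raw.get("maps") or {}).get(key)
        if spec is None:
            maps[key] = None
            continue
        try:
            maps[key] = read_raster(
                base_dir / spec["path"],
                format=spec.get("format"),
                value_range=spec.get("value_range"),
                bounds=bounds,
            )
        except (OSError, ValueError, KeyError) as e:
            errors.append(f"maps.{key}: {e}")
            maps[key] = None

    ticks = raw.get("ticks", 100)
    if not (isinstance(ticks, int) and ticks >= 0):
        errors.append(f"ticks: must be a nonnegative integer (got {ticks!r})")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append(f"seed: must be an integer (got {seed!r})")

    if errors:
        raise ConfigError(errors)

    # advisory neighborhood-size checks
    from .diagnostics import neighborhood_sizes

    sigma_m = mating.scale if mating is not None else interaction.scale
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        neighborhood_sizes(sigma_m, interaction.scale, float(K))
    notes.extend(str(w.message) for w in caught)
    for msg in notes:
        warnings.warn(msg, stacklevel=2)

    sim = SimConfig(
        bounds=bounds,
        K=float(K),
        regulation=regulation,
        interaction=interaction,
        dispersal=dispersal,
        mating=mating,
        movement=movement,
        selection=selection,
        k_map=maps["k_map"],
        fecundity_map=maps["fecundity_map"],
        survival_map=maps["survival_map"],
        dioecious=bool(raw.get("dioecious", False)),
        min_mating_age=int(raw.get("min_mating_age", 0)),
        seed=seed,
        fast_mode=bool(raw.get("fast_mode", False)),
        cell_size=raw.get("cell_size"),
        nonspatial=bool(raw.get("nonspatial", False)),
        n_loci=int(raw.get("n_loci", 1)),
        initial_allele_freq=float(raw.get("initial_allele_freq", 0.0)),
        initial_neutral_freq=float(raw.get("initial_neutral_freq", 0.5)),
        tuner_alpha=raw.get("tuner_alpha"),
        tuner_burn_in=int(raw.get("tuner_burn_in", 0)),
    )
    return RunConfig(
        sim=sim,
        ticks=int(ticks),
        snapshot_every=int(raw.get("snapshot_every", 0)),
        raw=raw,
        warnings=tuple(notes),
    )


def write_outputs(result: RunResult, outdir, run_config: RunConfig | None = None) -> dict:
    """Write the per-tick time series, any snapshots and a JSON manifest
    (seed, config hash, extinction flag) to ``outdir``.  Deterministic byte
    content for a fixed seed.  Returns the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.timeseries.to_csv(out / "timeseries.csv", index=False)
    for tick, snap in result.snapshots.items():
        snap.to_csv(out / f"snapshot_{tick:06d}.csv", index=False)
    raw = run_config.raw if run_config is not None else {}
    cfg_hash = hashlib.sha256(
        json.dumps(raw, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest = {
        "seed": int(result.config.seed),
        "config_hash": cfg_hash,
        "config": raw,
        "ticks_recorded": int(len(result.timeseries) - 1),
        "final_census": int(result.final.census),
        "extinct": bool(result.extinct),
        "warnings": list(run_config.warnings) if run_config is not None else [],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
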