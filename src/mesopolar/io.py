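"""Config files, model definition files, batch execution and manifests."""

from __future__ import annotations

import configparser
import datetime
import json
import re
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import particles, rdme, scenarios
from .model import (
    BimolecularReaction,
    Compartment,
    GeometryConstants,
    ModelError,
    ModelSpec,
    RateClass,
    SpeciesSpec,
    UnimolecularReaction,
)
from .trajectory import Trajectory

__all__ = [
    "ConfigError",
    "parse_model_file",
    "load_config",
    "write_totals",
    "batch_run",
]


class ConfigError(ValueError):
    """Schema violation in a config or model definition file."""


def _kv_items(text: str) -> dict[str, str]:
    out = {}
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise ConfigError(f"expected key=value, got {part!r}")
        k, v = part.split("=", 1)
        out[k.strip()] = v.strip()
    return out


_RXN_RE = re.compile(r"^(?P<lhs>[^:>]+)->(?P<rhs>[^:]*)(:(?P<params>.*))?$")


def parse_model_file(path) -> ModelSpec:
    """Read a model definition from a structured text file.

    Sections: ``[species]`` (``name = compartment=membrane, D=0.0045``,
    optional ``composition=cdc42:1;gef:1``), ``[reactions]`` (lines of the
    form ``name = A + B -> C : k_micro=..., rho=..., class=...`` or
    ``name = A -> B : k=..., class=...``), ``[geometry]`` and ``[initial]``.
    """
    cp = configparser.ConfigParser()
    cp.optionxform = str
    read = cp.read(path)
    if not read:
        raise ConfigError(f"cannot read model file {path}")
    for section in cp.sections():
        if section not in ("species", "reactions", "geometry", "initial"):
            raise ConfigError(f"unknown model section [{section}]")
    if "species" not in cp or "reactions" not in cp:
        raise ConfigError("model file needs [species] and [reactions] sections")

    species = []
    for name, val in cp["species"].items():
        kv = _kv_items(val)
        unknown = set(kv) - {"compartment", "D", "composition"}
        if unknown:
            raise ConfigError(f"species.{name}: unknown keys {sorted(unknown)}")
        comp = {}
        if "composition" in kv:
            for item in kv["composition"].split(";"):
                unit, cnt = item.split(":")
                comp[unit.strip()] = int(cnt)
        try:
            species.append(
                SpeciesSpec(
                    name,
                    Compartment(kv.get("compartment", "membrane")),
                    float(kv["D"]),
                    comp,
                )
            )
        except (KeyError, ValueError, ModelError) as exc:
            raise ConfigError(f"species.{name}: {exc}") from exc

    uni, bi = [], []
    for name, val in cp["reactions"].items():
        m = _RXN_RE.match(val.strip())
        if not m:
            raise ConfigError(f"reactions.{name}: cannot parse {val!r}")
        lhs = [s.strip() for s in m.group("lhs").split("+")]
        rhs = [s.strip() for s in m.group("rhs").split("+") if s.strip()]
        kv = _kv_items(m.group("params") or "")
        if "class" not in kv:
            raise ConfigError(f"reactions.{name}: missing class= tag")
        try:
            rate_class = RateClass(kv.pop("class"))
        except ValueError as exc:
            raise ConfigError(f"reactions.{name}: {exc}") from exc
        try:
            if len(lhs) == 1:
                uni.append(
                    UnimolecularReaction(
                        name, lhs[0], tuple(rhs), float(kv.pop("k")),
                        rate_class, reverse_of=kv.pop("reverse_of", None),
                    )
                )
            elif len(lhs) == 2:
                sources = None
                if "sources" in kv:  # e.g. sources=0;1
                    sources = tuple(
                        (int(x),) for x in kv.pop("sources").split(";")
                    )
                bi.append(
                    BimolecularReaction(
                        name, lhs[0], lhs[1], tuple(rhs),
                        float(kv.pop("k_micro")), float(kv.pop("rho")),
                        rate_class,
                        product_sources=sources,
                        product_at=int(kv.pop("product_at", 0)),
                    )
                )
            else:
                raise ConfigError(f"reactions.{name}: at most 2 reactants")
        except (KeyError, ValueError, ModelError) as exc:
            raise ConfigError(f"reactions.{name}: {exc}") from exc
        if kv:
            raise ConfigError(f"reactions.{name}: unknown keys {sorted(kv)}")

    geometry = None
    if "geometry" in cp:
        kv = dict(cp["geometry"])
        unknown = set(kv) - {"membrane_area", "membrane_thickness", "cytosol_volume"}
        if unknown:
            raise ConfigError(f"geometry: unknown keys {sorted(unknown)}")
        geometry = GeometryConstants(**{k: float(v) for k, v in kv.items()})

    initial = {}
    if "initial" in cp:
        for name, val in cp["initial"].items():
            initial[name] = int(val)

    try:
        return ModelSpec(
            species=tuple(species),
            unimolecular=tuple(uni),
            bimolecular=tuple(bi),
            geometry=geometry,
            initial_counts=initial,
        )
    except ModelError as exc:
        raise ConfigError(str(exc)) from exc


_GRID_KEYS = {"L", "h", "rate_mode", "t_end", "record_interval", "seed",
              "record_voxels"}
_PB_KEYS = {"L", "dt", "t_end", "record_interval", "seed", "epsilon",
            "record_positions"}
_MODEL_KEYS = {"file", "fixture"}
_BATCH_KEYS = {"n_replicates", "seed_base", "engine"}


def load_config(path):
    """Load and validate a run configuration.

    Sections: ``[model]`` (``file=...`` or ``fixture=name`` plus fixture
    arguments), ``[grid]`` (RDME settings), ``[particles]`` (particle
    settings), ``[batch]``.  Unknown keys are rejected with their key path;
    an RDME section in k_h mode is checked for grid feasibility at load time
    (reporting h_min when violated).
    """
    cp = configparser.ConfigParser()
    cp.optionxform = str
    if not cp.read(path):
        raise ConfigError(f"cannot read config file {path}")
    for section in cp.sections():
        if section not in ("model", "grid", "particles", "batch", "analysis"):
            raise ConfigError(f"unknown section [{section}]")
    if "model" not in cp:
        raise ConfigError("missing [model] section")

    mkv = dict(cp["model"])
    if "file" in mkv:
        model = parse_model_file(Path(path).parent / mkv.pop("file"))
        if mkv:
            raise ConfigError(f"model: unknown keys {sorted(mkv)}")
    elif "fixture" in mkv:
        name = mkv.pop("fixture")
        args = {}
        for k, v in mkv.items():
            try:
                args[k] = json.loads(v)
            except json.JSONDecodeError:
                args[k] = v
        try:
            model, defaults = scenarios.make_fixture(name, **args)
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"model.fixture: {exc}") from exc
    else:
        raise ConfigError("model: need file= or fixture=")

    out = {"model": model, "grid": None, "particles": None, "batch": None}
    if "grid" in cp:
        kv = dict(cp["grid"])
        unknown = set(kv) - _GRID_KEYS
        if unknown:
            raise ConfigError(f"grid: unknown keys {sorted(unknown)}")
        try:
            cfg = rdme.GridConfig(
                L=float(kv["L"]),
                h=float(kv["h"]),
                rate_mode=kv.get("rate_mode", "k_c"),
                t_end=float(kv.get("t_end", 1.0)),
                record_interval=float(kv.get("record_interval", 0.1)),
                seed=int(kv.get("seed", 0)),
                record_voxels=kv.get("record_voxels", "true").lower() != "false",
            )
            rdme.compile_model(model, cfg)  # validates h_min in k_h mode
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"grid: {exc}") from exc
        out["grid"] = cfg
    if "particles" in cp:
        kv = dict(cp["particles"])
        unknown = set(kv) - _PB_KEYS
        if unknown:
            raise ConfigError(f"particles: unknown keys {sorted(unknown)}")
        try:
            out["particles"] = particles.PbConfig(
                L=float(kv["L"]),
                dt=float(kv["dt"]),
                t_end=float(kv.get("t_end", 1.0)),
                record_interval=float(kv.get("record_interval", 0.1)),
                seed=int(kv.get("seed", 0)),
                epsilon=float(kv["epsilon"]) if "epsilon" in kv else None,
            )
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"particles: {exc}") from exc
    if "batch" in cp:
        kv = dict(cp["batch"])
        unknown = set(kv) - _BATCH_KEYS
        if unknown:
            raise ConfigError(f"batch: unknown keys {sorted(unknown)}")
        out["batch"] = {
            "n_replicates": int(kv.get("n_replicates", 1)),
            "seed_base": int(kv.get("seed_base", 0)),
            "engine": kv.get("engine", "rdme"),
        }
    return out


def write_totals(traj: Trajectory, path) -> None:
    """Per-species totals vs time as a TSV with a metadata header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# mesopolar totals; metadata: {json.dumps(traj.metadata)}\n")
        traj.totals_frame().to_csv(fh, sep="\t", index=False)


def batch_run(
    model: ModelSpec,
    config,
    n_replicates: int,
    seed_base: int,
    out_dir,
    engine: str = "rdme",
    save_trajectories: bool = False,
) -> dict:
    """Run an ensemble of independently seeded replicates.

    Writes per-run totals tables, an ensemble mean/SD table and a JSON
    manifest (config echo, seeds, wall time, outputs, rate-table digest)
    sufficient to reproduce the batch bit-for-bit.  Failed replicates are
    recorded and skipped.  Returns the manifest.
    """
    import dataclasses as _dc

    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = scenarios.child_seeds(seed_base, n_replicates)
    if len(set(seeds)) != len(seeds):
        import warnings

        warnings.warn("duplicate seeds in batch; replicates will be identical")
    runner = rdme.run if engine == "rdme" else particles.run
    t0 = time.time()
    entries = []
    totals = []
    times = None
    names = None
    for i, s in enumerate(seeds):
        cfg = _dc.replace(config, seed=s)
        entry = {"replicate": i, "seed": s}
        try:
            traj = runner(model, cfg)
        except Exception as exc:  # record and continue
            entry["error"] = str(exc)
            entries.append(entry)
            continue
        tot_path = out_dir / f"run_{i:04d}_totals.tsv"
        write_totals(traj, tot_path)
        entry["totals"] = tot_path.name
        if save_trajectories:
            traj_path = out_dir / f"run_{i:04d}.npz"
            traj.save(traj_path)
            entry["trajectory"] = traj_path.name
        entries.append(entry)
        totals.append(traj.totals.astype(float))
        times = traj.times
        names = traj.species_names
    if totals:
        arr = np.stack(totals)
        agg = pd.DataFrame({"time": times})
        for j, name in enumerate(names):
            agg[f"{name}_mean"] = arr[:, :, j].mean(axis=0)
            agg[f"{name}_sd"] = arr[:, :, j].std(axis=0, ddof=0)
        agg.to_csv(out_dir / "ensemble_totals.tsv", sep="\t", index=False)
    cfg_echo = {
        k: (v.value if hasattr(v, "value") else v)
        for k, v in vars(config).items()
    }
    manifest = {
        "package_version": __version__,
        "engine": engine,
        "config": cfg_echo,
        "seed_base": seed_base,
        "seeds": seeds,
        "started": datetime.datetime.fromtimestamp(t0).isoformat(),
        "wall_time_s": time.time() - t0,
        "runs": entries,
    }
    if engine == "rdme":
        compiled = rdme.compile_model(model, config)
        manifest["kc_table_digest"] = rdme._table_digest(compiled)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
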