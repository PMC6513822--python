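"""File plumbing: headered CSVs, run configuration, world persistence.

Every output file starts with a comment line recording the package
version, the run seed and a hash of the configuration, so any table can be
traced back to the exact run that produced it.  All files are plain UTF-8
CSV with a header row.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .constraints import ConstraintTable

WORLD_FILES = {
    "microdata": "microdata.csv",
    "diary": "diary.csv",
    "earnings": "earnings.csv",
    "midyear_adult": "midyear_adult.csv",
    "communal_adult": "communal_adult.csv",
    "midyear_child": "midyear_child.csv",
    "communal_child": "communal_child.csv",
    "region_of_zone": "region_of_zone.csv",
    "ground_truth": "ground_truth.csv",
    "deprivation": "deprivation_rank.csv",
    "regional_stats": "survey_regional_stats.csv",
}

CONSTRAINT_VARS_ON_DISK = ("household_type", "ethnicity", "student", "unemployment")


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_csv(
    df: pd.DataFrame, path: Path | str, seed: int, cfg_hash: str, index: bool = False
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# spendsim {__version__} seed={seed} config_hash={cfg_hash}\n")
        df.to_csv(fh, index=index)


def read_csv(path: Path | str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def load_config(path: Path | str) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    return cfg


def write_world(world, outdir: Path | str, seed: int) -> None:
    """Persist a generated synthetic world as the pipeline's input file set."""
    outdir = Path(outdir)
    cfg = {"n_zones": world.config.n_zones, "seed": world.config.seed,
           "year": world.config.year, "survey_size": world.config.survey_size}
    h = config_hash(cfg)

    write_csv(world.microdata, outdir / WORLD_FILES["microdata"], seed, h)
    write_csv(world.diary, outdir / WORLD_FILES["diary"], seed, h)
    write_csv(world.constraints.earnings, outdir / WORLD_FILES["earnings"], seed, h)
    for key in ("midyear_adult", "communal_adult", "midyear_child", "communal_child"):
        df = getattr(world.constraints, key)
        write_csv(
            df.rename_axis("zone_code").reset_index(),
            outdir / WORLD_FILES[key],
            seed,
            h,
        )
    for var in CONSTRAINT_VARS_ON_DISK:
        ct = world.constraints.raw[var]
        write_csv(
            ct.counts.rename_axis("zone_code").reset_index(),
            outdir / f"constraint_{var}.csv",
            seed,
            h,
        )
    write_csv(
        world.region_of_zone.rename_axis("zone_code").reset_index(),
        outdir / WORLD_FILES["region_of_zone"],
        seed,
        h,
    )
    truth = (
        world.ground_truth.true_zone_expenditure.rename_axis("zone_code")
        .reset_index()
        .melt(id_vars="zone_code", var_name="coicop", value_name="true_mean_gbp")
    )
    write_csv(truth, outdir / WORLD_FILES["ground_truth"], seed, h)
    write_csv(world.deprivation, outdir / WORLD_FILES["deprivation"], seed, h)
    write_csv(world.regional_stats, outdir / WORLD_FILES["regional_stats"], seed, h)


def read_world_inputs(indir: Path | str) -> dict:
    """Read a persisted world back into the pieces the model constructor
    takes.  Returns a dict of keyword-ready objects."""
    indir = Path(indir)

    def zframe(name: str) -> pd.DataFrame:
        return read_csv(indir / name).set_index("zone_code")

    micro = read_csv(indir / WORLD_FILES["microdata"], dtype={"id": str})
    diary = read_csv(indir / WORLD_FILES["diary"], dtype={"id": str, "coicop": str})
    raw = {
        var: ConstraintTable(var, zframe(f"constraint_{var}.csv"))
        for var in CONSTRAINT_VARS_ON_DISK
    }
    out = {
        "microdata": micro,
        "diary": diary,
        "raw_constraints": raw,
        "midyear_adult": zframe(WORLD_FILES["midyear_adult"]),
        "communal_adult": zframe(WORLD_FILES["communal_adult"]),
        "midyear_child": zframe(WORLD_FILES["midyear_child"]),
        "communal_child": zframe(WORLD_FILES["communal_child"]),
        "earnings": read_csv(indir / WORLD_FILES["earnings"]),
        "region_of_zone": zframe(WORLD_FILES["region_of_zone"])["region"],
    }
    return out
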