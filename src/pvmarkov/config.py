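"""Configuration files, shipped defaults and run manifests.

A run is described by a small YAML file; every file path inside it is
resolved relative to the config file's own location, so a config directory
is self-contained.  Each command-line run emits a JSON manifest with the
package version, a snapshot of the configuration and SHA-256 digests of the
input files, which is enough to reproduce the outputs exactly (outputs are
deterministic; the manifest timestamp is the only non-reproducible field).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import ModelConfig, RiskSet
from .life_table import LifeTable, load_life_table, synthesize_life_table
from .scenario import DEFAULT_RISK_CATALOG, RiskAlternative, RiskCatalog, SLOTS, base_case_risk_set
from .trajectory import Jak2Trajectory, default_trajectory, trajectory_from_mean_burden
from .validation import StudyProfile


def _package_version() -> str:
    try:
        return version("pvmarkov")
    except PackageNotFoundError:  # pragma: no cover - source checkout
        return "unknown"


def base_case_config(
    life_table: LifeTable | None = None,
    trajectory: Jak2Trajectory | None = None,
    start_age: float = 57.0,
    horizon_years: float = 20.0,
    **flags,
) -> ModelConfig:
    """The shipped base case: age 57, 20-year horizon, base-case risks,
    synthetic life table and the reference JAK2 trajectory."""
    return ModelConfig(
        start_age=start_age,
        horizon_years=horizon_years,
        risk_set=base_case_risk_set(),
        life_table=life_table if life_table is not None else synthesize_life_table(),
        trajectory=trajectory if trajectory is not None else default_trajectory(),
        **flags,
    )


def load_trajectory_csv(path) -> Jak2Trajectory:
    """Trajectory from CSV columns ``cycle,proportion_high`` (cycles 0..K)."""
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = {"cycle", "proportion_high"} - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV {path} lacks columns {sorted(missing)}")
    df = df.sort_values("cycle")
    cycles = df["cycle"].to_numpy(dtype=int)
    if cycles[0] != 0 or np.any(np.diff(cycles) != 1):
        raise ValueError(f"trajectory CSV {path} must cover contiguous cycles from 0")
    return Jak2Trajectory(
        proportion_high=df["proportion_high"].to_numpy(dtype=float), label=str(path)
    )


def load_risk_catalog_yaml(path) -> RiskCatalog:
    """Risk catalog from YAML: per slot, a list of source/low/high entries."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"risk catalog {path} must be a mapping of transition slots")
    alts = {}
    for slot, entries in raw.items():
        if slot not in SLOTS:
            raise ValueError(f"unknown transition slot {slot!r}; expected one of {SLOTS}")
        alts[slot] = [
            RiskAlternative(
                source=str(e["source"]),
                low=float(e["low"]),
                high=float(e.get("high", e["low"])),
                base_case=bool(e.get("base_case", False)),
            )
            for e in entries
        ]
    return RiskCatalog(alternatives=alts)


def load_study_yaml(path) -> StudyProfile:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"study profile {path} must be a mapping")
    try:
        return StudyProfile(
            label=str(raw.get("label", Path(path).stem)),
            median_age=float(raw["median_age"]),
            follow_up_years=(
                float(raw["follow_up_years"]) if "follow_up_years" in raw else None
            ),
            prop_high=float(raw["prop_high"]) if "prop_high" in raw else None,
            burden_pct=float(raw["burden_pct"]) if "burden_pct" in raw else None,
        )
    except KeyError as exc:
        raise ValueError(f"study profile {path} lacks required field {exc}") from exc


def _resolve(base: Path, value: str) -> Path:
    p = Path(value)
    return p if p.is_absolute() else base / p


def load_model_config(path) -> ModelConfig:
    """Build a :class:`ModelConfig` from a YAML file.

    Recognized keys: ``start_age``, ``horizon_years`` (required);
    ``life_table`` (path or ``synthetic``); ``trajectory`` (path,
    ``default``, or a ``mean_burden`` mapping with ``baseline``/``plateau``/
    ``sd``); ``fixed_group``; ``risk_set`` (``base_case`` or explicit
    probabilities); and the engine flags.  Paths are relative to the config
    file.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    base = path.parent
    for key in ("start_age", "horizon_years"):
        if key not in raw:
            raise ValueError(f"config {path} lacks required key {key!r}")

    lt_spec = raw.get("life_table", "synthetic")
    life_table = (
        synthesize_life_table() if lt_spec == "synthetic" else load_life_table(_resolve(base, lt_spec))
    )

    trajectory = None
    fixed_group = raw.get("fixed_group")
    traj_spec = raw.get("trajectory", None if fixed_group else "default")
    if traj_spec is not None and fixed_group is not None:
        raise ValueError(f"config {path} sets both trajectory and fixed_group")
    if traj_spec == "default":
        trajectory = default_trajectory()
    elif isinstance(traj_spec, dict):
        mb = traj_spec.get("mean_burden", traj_spec)
        trajectory = trajectory_from_mean_burden(
            baseline_burden=float(mb.get("baseline", 42.8)),
            plateau_burden=float(mb.get("plateau", 37.0)),
            sd=float(mb.get("sd", 20.0)),
        )
    elif traj_spec is not None:
        trajectory = load_trajectory_csv(_resolve(base, traj_spec))

    rs_spec = raw.get("risk_set", "base_case")
    if rs_spec == "base_case":
        risk_set = base_case_risk_set()
    elif isinstance(rs_spec, dict):
        risk_set = RiskSet(**{k: float(v) for k, v in rs_spec.items()})
    else:
        raise ValueError(f"config {path}: risk_set must be 'base_case' or a mapping")

    return ModelConfig(
        start_age=float(raw["start_age"]),
        horizon_years=float(raw["horizon_years"]),
        risk_set=risk_set,
        life_table=life_table,
        trajectory=trajectory,
        fixed_group=fixed_group,
        half_cycle_correction=bool(raw.get("half_cycle_correction", False)),
        same_cycle_progression_death=bool(raw.get("same_cycle_progression_death", False)),
        phase2_background_floor=bool(raw.get("phase2_background_floor", False)),
    )


def _config_snapshot(config: ModelConfig) -> dict:
    snap = {
        "start_age": config.start_age,
        "horizon_years": config.horizon_years,
        "fixed_group": config.fixed_group,
        "half_cycle_correction": config.half_cycle_correction,
        "same_cycle_progression_death": config.same_cycle_progression_death,
        "phase2_background_floor": config.phase2_background_floor,
        "risk_set": {
            k: v for k, v in asdict(config.risk_set).items() if k != "sources"
        },
        "risk_sources": dict(config.risk_set.sources),
        "life_table_source": config.life_table.source,
    }
    if config.trajectory is not None:
        snap["trajectory"] = {
            "label": config.trajectory.label,
            "proportion_high": [float(p) for p in config.trajectory.proportion_high],
        }
    return snap


def write_manifest(
    out_dir, config: ModelConfig | None = None, inputs: dict | None = None, extra: dict | None = None
) -> Path:
    """Write ``manifest.json`` describing a run; returns its path."""
    manifest = {
        "package": "pvmarkov",
        "version": _package_version(),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    if config is not None:
        manifest["config"] = _config_snapshot(config)
    if inputs:
        digests = {}
        for name, p in inputs.items():
            if p is None:
                continue
            digests[name] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
        manifest["input_sha256"] = digests
    if extra:
        manifest.update(extra)
    out = Path(out_dir) / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return out
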