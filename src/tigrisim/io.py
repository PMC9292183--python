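"""Configuration loading, provenance manifests, and CSV/JSON round-trips.

All tabular outputs are tidy long-format CSV.  Data files carry a small
provenance header (package version, config hash, seed) as ``#`` comment
lines, so two runs from identical configs and seeds produce byte-identical
files; wall-clock timestamps live only in the separate run manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .demography import DemographyParams
from .engine import SimulationConfig, StepRecord, Trajectory, config_hash

__all__ = [
    "ConfigError",
    "ConfigFileError",
    "ConfigValidationError",
    "RunManifest",
    "load_config",
    "save_config",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_endpoint_csv",
    "read_long_measurements",
]


class ConfigError(Exception):
    """Base class for configuration problems."""


class ConfigFileError(ConfigError):
    """Missing or unparsable configuration file."""


class ConfigValidationError(ConfigError):
    """Configuration parsed but violates an invariant."""


_CONFIG_KEYS = {
    "regime", "period", "initial_n", "juvenile_to_adult_ratio", "horizon",
    "n_realisations", "master_seed", "scale_factor",
    "newborn_same_day_hazards", "demography",
}
_DEMOGRAPHY_KEYS = {f.name for f in DemographyParams.__dataclass_fields__.values()}

_REGIME_ALIASES = {"det": "deterministic", "stoch": "stochastic"}


def load_config(path: str | Path) -> SimulationConfig:
    """Read and validate a YAML or JSON simulation config.

    Defaults fill every omitted field except ``regime`` and ``period``,
    which have no scientifically neutral default and are required.
    Unknown keys are rejected by name.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigFileError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigFileError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigFileError(f"config root must be a mapping, got {type(raw).__name__}")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> SimulationConfig:
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigValidationError(f"unknown config keys: {sorted(unknown)}")
    for required in ("regime", "period"):
        if required not in raw:
            raise ConfigValidationError(f"required config field missing: {required}")
    raw = dict(raw)
    raw["regime"] = _REGIME_ALIASES.get(raw["regime"], raw["regime"])
    demo_raw = raw.pop("demography", None)
    if demo_raw is not None:
        unknown = set(demo_raw) - _DEMOGRAPHY_KEYS
        if unknown:
            raise ConfigValidationError(
                f"unknown demography keys: {sorted(unknown)}")
        try:
            raw["demography"] = DemographyParams(**demo_raw)
        except ValueError as exc:
            raise ConfigValidationError(str(exc)) from exc
    try:
        return SimulationConfig(**raw)
    except (TypeError, ValueError) as exc:
        raise ConfigValidationError(str(exc)) from exc


def save_config(config: SimulationConfig, path: str | Path) -> None:
    path = Path(path)
    text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    path.write_text(text)


@dataclass
class RunManifest:
    """Provenance of one invocation: what ran, from which seed, into which files."""

    config_hash: str
    master_seed: int
    regime: str
    period: int
    version: str = __version__
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())
    outputs: list[str] = field(default_factory=list)

    @classmethod
    def for_run(cls, config: SimulationConfig, master_seed: int) -> "RunManifest":
        return cls(config_hash=config_hash(config), master_seed=master_seed,
                   regime=config.regime, period=config.period)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _provenance_header(config_hash_: str, seed: int) -> str:
    return (f"# tigrisim {__version__}\n"
            f"# config_hash={config_hash_}\n"
            f"# seed={seed}\n")


_STEP_FIELDS = list(StepRecord.__dataclass_fields__)


def write_trajectory_csv(trajectory: Trajectory, path: str | Path) -> None:
    """One row per day, columns exactly the step-record fields, full precision."""
    path = Path(path)
    df = trajectory.to_dataframe()
    with path.open("w") as fh:
        fh.write(_provenance_header(trajectory.config_hash, trajectory.seed))
        df.to_csv(fh, index=False, float_format="%.17g")


def read_trajectory_csv(path: str | Path) -> Trajectory:
    """Round-trip a trajectory summary written by :func:`write_trajectory_csv`.

    Endpoint trait samples are not part of the per-day table and come back
    empty; all step-record fields round-trip losslessly.
    """
    path = Path(path)
    meta = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, value = line.lstrip("# ").strip().partition("=")
                meta[key] = value
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:
        raise ValueError(f"malformed trajectory CSV {path}: {exc}") from exc
    missing = set(_STEP_FIELDS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(StepRecord(**{k: getattr(row, k) for k in _STEP_FIELDS}))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: bad row {i + 2}: {exc}") from exc
    last = records[-1]
    extinct = last.n_total == 0
    ext_time = None
    if extinct:
        ext_time = next(r.t for r in records if r.n_total == 0)
    return Trajectory(
        config_hash=meta.get("config_hash", ""),
        seed=int(meta.get("seed", -1)),
        records=records,
        endpoint_mu=np.empty(0),
        endpoint_f=np.empty(0),
        extinct=extinct,
        extinction_time=ext_time,
    )


def write_endpoint_csv(trajectories, path: str | Path) -> None:
    """Endpoint trait samples across an ensemble: one surviving individual
    per row (realisation_id, individual_id, mu, f)."""
    frames = []
    for i, tr in enumerate(trajectories):
        if tr.endpoint_mu.size:
            frames.append(pd.DataFrame({
                "realisation_id": i,
                "individual_id": np.arange(tr.endpoint_mu.size),
                "mu": tr.endpoint_mu,
                "f": tr.endpoint_f,
            }))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=["realisation_id", "individual_id", "mu", "f"]))
    header = _provenance_header(
        trajectories[0].config_hash if len(trajectories) else "",
        trajectories[0].seed if len(trajectories) else -1)
    with Path(path).open("w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.17g")


def read_long_measurements(path: str | Path, trait: str) -> list[np.ndarray]:
    """Replicate-grouped measurements of one trait from a long-format CSV
    (columns: treatment, replicate_id, individual_id, trait, value)."""
    df = pd.read_csv(path, comment="#")
    required = {"replicate_id", "trait", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    sub = df[df["trait"] == trait]
    if sub.empty:
        raise ValueError(f"{path}: no rows with trait {trait!r}")
    return [grp["value"].to_numpy()
            for _, grp in sub.groupby("replicate_id", sort=True)]
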