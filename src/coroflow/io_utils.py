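"""Configuration files, output headers and deterministic file writing.

Every output artifact carries a header comment with the tool version, the
run seed and a hash of the effective configuration, so two runs with the
same config and seed are byte-identical and self-describing.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .flow_solver import FluidProperties, SolverConfig


class ConfigError(ValueError):
    pass


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def file_header(seed, config_obj=None) -> str:
    h = config_hash(config_obj if config_obj is not None else {})
    return f"coroflow {__version__} seed={seed} config_sha256={h}"


def load_yaml(path) -> dict:
    try:
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return data


#: solver-config file keys: backend, nx, nr, tol, max_iter, K_e, mu, rho
def solver_from_dict(d: dict) -> tuple[SolverConfig, FluidProperties]:
    known = {"backend", "nx", "nr", "tol", "max_iter", "K_e", "mu", "rho"}
    bad = set(d) - known
    if bad:
        raise ConfigError(f"unknown solver config keys: {sorted(bad)}")
    fluid = FluidProperties(mu_pa_s=d.get("mu", 0.0035),
                            rho_kg_m3=d.get("rho", 1056.0))
    cfg = SolverConfig(
        backend=d.get("backend", "reduced_order"),
        nx=d.get("nx", 128), nr=d.get("nr", 32),
        tol=d.get("tol", 1e-6), max_iter=d.get("max_iter", 10_000),
        K_e=d.get("K_e", 1.52))
    return cfg, fluid


def write_dataframe(df: pd.DataFrame, path, header: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def write_json(obj, path, header: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"_meta": header}
    payload.update(obj)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_text(text: str, path, header: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"<!-- {header} -->\n{text}\n")
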