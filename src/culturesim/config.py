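"""Configuration documents and structured result output.

A run configuration is a YAML (or JSON) document with up to four sections::

    sim:                # any subset of SimParams fields
      p_inv: 0.001
      beta: 0.1
      p_loss: 0.1
      t_max: 200000
    populations: [200, 400]      # census sizes, in index order
    migration_matrix:            # optional pairwise per-individual probs
      - [0.0, 5.0e-6]
      - [5.0e-6, 0.0]
    sweep:                       # optional grid for the heat-map sweep
      neighbour_sizes: [200, 400]
      migration_probs: [1.0e-6, 1.0e-5]
      focal_size: 200
      replicates: 10
      variant: fraction_payload
    output:
      dir: results

Every key is validated before any simulation starts; unknown keys are
rejected by name, and an empty document resolves to the model defaults.
The fully resolved configuration is echoed into a metadata sidecar next to
each output table so that every artefact is reproducible from its sidecar
alone.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .experiments import SweepResult, SweepSpec
from .model_core import ConfigurationError, SimParams

__all__ = ["RunConfig", "load_config", "parse_config", "write_results"]

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimParams)}
_SWEEP_FIELDS = {
    "neighbour_sizes",
    "migration_probs",
    "focal_size",
    "replicates",
    "variant",
    "base_seed",
}
_TOP_FIELDS = {"sim", "populations", "migration_matrix", "sweep", "output"}
_OUTPUT_FIELDS = {"dir"}


@dataclass
class RunConfig:
    """A fully validated, fully resolved run configuration."""

    params: SimParams
    populations: list[int]
    migration_matrix: np.ndarray | None = None
    sweep: SweepSpec | None = None
    output_dir: str = "results"

    def to_dict(self) -> dict:
        """Plain-data form of the resolved configuration (round-trippable)."""
        doc: dict = {
            "sim": dataclasses.asdict(self.params),
            "populations": list(self.populations),
            "output": {"dir": self.output_dir},
        }
        if self.migration_matrix is not None:
            doc["migration_matrix"] = self.migration_matrix.tolist()
        if self.sweep is not None:
            doc["sweep"] = {
                "neighbour_sizes": list(self.sweep.neighbour_sizes),
                "migration_probs": list(self.sweep.migration_probs),
                "focal_size": self.sweep.focal_size,
                "replicates": self.sweep.replicates,
                "variant": self.sweep.variant,
                "base_seed": self.sweep.base_seed,
            }
        return doc


def _reject_unknown(section: str, doc: dict, allowed: set[str]) -> None:
    unknown = set(doc) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in {section}: {', '.join(sorted(map(str, unknown)))}"
        )


def parse_config(doc: dict | None) -> RunConfig:
    """Validate a parsed configuration document and resolve all defaults."""
    doc = doc or {}
    if not isinstance(doc, dict):
        raise ConfigurationError("configuration must be a mapping")
    _reject_unknown("configuration", doc, _TOP_FIELDS)

    sim_doc = doc.get("sim") or {}
    if not isinstance(sim_doc, dict):
        raise ConfigurationError("'sim' must be a mapping")
    _reject_unknown("'sim'", sim_doc, _SIM_FIELDS)
    try:
        params = SimParams(**sim_doc)
    except TypeError as exc:  # pragma: no cover - guarded by _reject_unknown
        raise ConfigurationError(str(exc)) from exc

    populations = doc.get("populations") or [200]
    if not isinstance(populations, list) or not all(
        isinstance(n, int) and n >= 1 for n in populations
    ):
        raise ConfigurationError(
            "'populations' must be a list of integers >= 1"
        )

    matrix = None
    if doc.get("migration_matrix") is not None:
        try:
            matrix = np.asarray(doc["migration_matrix"], dtype=float)
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(
                f"'migration_matrix' is not a numeric matrix: {exc}"
            ) from exc
        n = len(populations)
        if matrix.shape != (n, n):
            raise ConfigurationError(
                f"'migration_matrix' must be {n}x{n} to match 'populations'"
            )

    sweep = None
    if doc.get("sweep") is not None:
        sweep_doc = doc["sweep"]
        if not isinstance(sweep_doc, dict):
            raise ConfigurationError("'sweep' must be a mapping")
        _reject_unknown("'sweep'", sweep_doc, _SWEEP_FIELDS)
        sweep = SweepSpec(base_params=params, **sweep_doc)

    output_doc = doc.get("output") or {}
    if not isinstance(output_doc, dict):
        raise ConfigurationError("'output' must be a mapping")
    _reject_unknown("'output'", output_doc, _OUTPUT_FIELDS)
    output_dir = str(output_doc.get("dir", "results"))

    return RunConfig(
        params=params,
        populations=populations,
        migration_matrix=matrix,
        sweep=sweep,
        output_dir=output_dir,
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"configuration file not found: {path}")
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    return parse_config(doc)


def _metadata(config: RunConfig | None, seed: int | None) -> dict:
    from . import __version__

    return {
        "software": "culturesim",
        "version": __version__,
        "seed": seed,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "resolved_config": config.to_dict() if config is not None else None,
    }


def write_results(
    result,
    out_dir: str | Path,
    name: str = "results",
    config: RunConfig | None = None,
    seed: int | None = None,
) -> list[Path]:
    """Write an experiment result as tidy delimited tables plus a sidecar.

    ``result`` may be a :class:`SweepResult` (written as a per-replicate
    record table and a per-cell aggregate table), a DataFrame, or a dict
    from one of the experiment helpers (its ``records`` frame is written
    and the scalar summary lands in the sidecar).  Data tables contain no
    timestamps, so re-running the same configuration and seed reproduces
    them byte for byte; volatile provenance lives only in the JSON
    sidecar.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    meta = _metadata(config, seed)

    def _write_df(df: pd.DataFrame, stem: str) -> None:
        path = out_dir / f"{stem}.csv"
        df.to_csv(path, index=False)
        written.append(path)

    if isinstance(result, SweepResult):
        _write_df(result.records, f"{name}_records")
        _write_df(result.cells, f"{name}_cells")
    elif isinstance(result, pd.DataFrame):
        _write_df(result, name)
    elif isinstance(result, dict):
        records = result.get("records")
        if isinstance(records, pd.DataFrame):
            _write_df(records, f"{name}_records")
        meta["summary"] = {
            k: v for k, v in result.items() if not isinstance(v, pd.DataFrame)
        }
    else:
        raise TypeError(f"cannot write result of type {type(result).__name__}")

    sidecar = out_dir / f"{name}_metadata.json"
    sidecar.write_text(json.dumps(meta, indent=2, default=str) + "\n")
    written.append(sidecar)
    return written
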