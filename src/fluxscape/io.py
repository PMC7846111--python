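"""Model-spec and table I/O plus run manifests.

The model spec file is a structured text document (JSON or YAML — JSON being
a YAML subset, one loader covers both) with top-level keys ``metabolites``,
``reactions``, ``enzymes``, ``atp_registry`` and ``parameters``.  Round trips
are lossless field-wise.  Sample tables are plain CSV with '.' decimals and a
mandatory header in the documented column order.  Every pipeline output
directory receives one run manifest with the command, config snapshot,
master seed, version and SHA-256 digests of inputs and outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .model import (
    ConfigurationError,
    EnzymeSpec,
    ModelSpec,
    ReactionSpec,
)
from .sampling import SAMPLE_TABLE_COLUMNS, MutationFrequencyTable

__all__ = [
    "model_to_dict",
    "model_from_dict",
    "load_model_spec",
    "save_model_spec",
    "load_default_model_spec",
    "read_sample_table",
    "write_sample_table",
    "read_frequency_table",
    "write_frequency_table",
    "RunManifest",
    "write_manifest",
]

DEFAULT_MODEL_RESOURCE = "default_model.yaml"


def model_to_dict(model: ModelSpec) -> dict:
    return {
        "metabolites": list(model.metabolites),
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(r.stoichiometry),
                "atp_produced": r.atp_produced,
                "reversible": r.reversible,
                "enzyme_id": r.enzyme_id,
                "pathway_tag": r.pathway_tag,
                "lb": r.lb,
                "ub": r.ub,
            }
            for r in model.reactions
        ],
        "enzymes": [dataclasses.asdict(e) for e in model.enzymes],
        "atp_registry": list(model.atp_registry),
        "parameters": {
            "phi_max": model.phi_max,
            "kappa_t": model.kappa_t,
            "gam": model.gam,
            "ngam": model.ngam,
            "substrate_mw": model.substrate_mw,
            **model.parameters,
        },
    }


def model_from_dict(doc: dict) -> ModelSpec:
    try:
        params = dict(doc["parameters"])
        model = ModelSpec(
            metabolites=list(doc["metabolites"]),
            reactions=[ReactionSpec(**r) for r in doc["reactions"]],
            enzymes=[EnzymeSpec(**e) for e in doc["enzymes"]],
            atp_registry=tuple(doc["atp_registry"]),
            phi_max=float(params.pop("phi_max")),
            kappa_t=float(params.pop("kappa_t")),
            gam=float(params.pop("gam")),
            ngam=float(params.pop("ngam")),
            substrate_mw=float(params.pop("substrate_mw")),
            parameters=params,
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed model spec: {exc}") from exc
    model.validate()
    return model


def load_model_spec(path: str | Path) -> ModelSpec:
    """Load and validate a model spec from a JSON or YAML file."""
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)  # JSON is valid YAML
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    return model_from_dict(doc)


def save_model_spec(model: ModelSpec, path: str | Path) -> None:
    """Write a model spec; the format follows the file extension."""
    doc = model_to_dict(model)
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=1, sort_keys=False) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def load_default_model_spec() -> ModelSpec:
    """The shipped calibrated default model."""
    res = Path(__file__).parent / "data" / DEFAULT_MODEL_RESOURCE
    return load_model_spec(res)


def write_sample_table(table: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in SAMPLE_TABLE_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, index=False)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    missing = [c for c in SAMPLE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"sample table missing columns: {missing}")
    df["feasible"] = df["feasible"].astype(bool)
    df["aerotype"] = df["aerotype"].astype(str)
    return df


def write_frequency_table(freq: MutationFrequencyTable, path: str | Path) -> None:
    freq.to_frame().to_csv(path, index=False)


def read_frequency_table(path: str | Path) -> MutationFrequencyTable:
    return MutationFrequencyTable.from_frame(pd.read_csv(path))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Provenance record written next to every pipeline output."""

    command: str
    config: dict
    master_seed: int | None
    version: str
    inputs: dict[str, str]
    outputs: dict[str, str]
    started: str
    finished: str
    platform: str = dataclasses.field(default_factory=platform.platform)


def write_manifest(
    outdir: str | Path,
    command: str,
    config: dict,
    master_seed: int | None,
    inputs: list[str | Path],
    outputs: list[str | Path],
    started: datetime,
) -> Path:
    outdir = Path(outdir)
    manifest = RunManifest(
        command=command,
        config=config,
        master_seed=master_seed,
        version=__version__,
        inputs={str(p): _sha256(Path(p)) for p in inputs if Path(p).is_file()},
        outputs={str(p): _sha256(Path(p)) for p in outputs if Path(p).is_file()},
        started=started.astimezone(timezone.utc).isoformat(),
        finished=datetime.now(timezone.utc).isoformat(),
    )
    path = outdir / "manifest.json"
    path.write_text(json.dumps(dataclasses.asdict(manifest), indent=1) + "\n")
    return path
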