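"""File readers/writers and run provenance.

All formats are plain delimited text with header rows — the artifact's data
are small tables, and transparency beats compactness.

* item bank:        CSV with columns item_id,a,b,c,content_domain
* response matrix:  CSV, first column respondent_id, one column per item_id
* scenario config:  YAML or JSON mirroring CATConfig (+ optional grid lists
                    and a synthetic section mirroring SyntheticSpec)
* results:          one row per respondent; optional long-format interim trace

Every write goes through :class:`RunManifest`, which records the config
hash, input checksums, seed and tool version so any output file is traceable
to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from .engine import CATConfig
from .exceptions import ConfigurationError
from .irt import ItemBank
from .selection import SelectionPolicy
from .simulate import ResponseMatrix, SyntheticSpec

__all__ = [
    "read_item_bank",
    "write_item_bank",
    "read_response_matrix",
    "write_response_matrix",
    "read_config_file",
    "config_from_dict",
    "synthetic_spec_from_dict",
    "config_hash",
    "RunManifest",
]


def read_item_bank(path) -> ItemBank:
    """Read and validate an item bank CSV."""
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    bank = ItemBank.from_frame(frame, metadata=f"loaded from {path}")
    return bank


def write_item_bank(bank: ItemBank, path) -> None:
    bank.to_frame().to_csv(path, index=False)


def read_response_matrix(path) -> ResponseMatrix:
    frame = pd.read_csv(path, comment="#")
    return ResponseMatrix.from_frame(frame)


def write_response_matrix(matrix: ResponseMatrix, path) -> None:
    matrix.to_frame().to_csv(path, index=False)


_CONFIG_KEYS = {
    "se_threshold",
    "max_items",
    "min_items",
    "theta_min",
    "theta_max",
    "prior_mean",
    "prior_sd",
    "n_grid_points",
}
_POLICY_KEYS = {"method", "first_item_rule", "first_item_theta"}


def config_from_dict(d: dict) -> CATConfig:
    """Build a CATConfig from a plain mapping (e.g. a parsed YAML section)."""
    unknown = set(d) - _CONFIG_KEYS - {"policy"}
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {k: d[k] for k in _CONFIG_KEYS if k in d}
    if "policy" in d:
        p = d["policy"]
        bad = set(p) - _POLICY_KEYS
        if bad:
            raise ConfigurationError(f"unknown policy keys: {sorted(bad)}")
        kwargs["policy"] = SelectionPolicy(**p)
    return CATConfig(**kwargs)


def synthetic_spec_from_dict(d: dict) -> SyntheticSpec:
    valid = set(SyntheticSpec.__dataclass_fields__)
    unknown = set(d) - valid
    if unknown:
        raise ConfigurationError(f"unknown synthetic spec keys: {sorted(unknown)}")
    return SyntheticSpec(**d)


def read_config_file(path) -> dict:
    """Parse a YAML or JSON scenario file into a raw dict.

    Recognised top-level sections: ``cat`` (CATConfig fields), ``grid``
    (``se_thresholds``/``max_items`` lists), ``synthetic`` (SyntheticSpec
    fields).  A flat file with CATConfig fields at top level also works.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    return raw


def config_hash(config: CATConfig) -> str:
    """Stable short hash of a configuration, for provenance headers."""
    d = asdict(config)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every set of output files."""

    tool_version: str
    seed: int | None = None
    config_hash: str | None = None
    inputs: dict = field(default_factory=dict)  # path -> sha256
    outputs: dict = field(default_factory=dict)
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )

    def add_input(self, path) -> None:
        self.inputs[str(path)] = _file_sha256(path)

    def add_output(self, path) -> None:
        self.outputs[str(path)] = _file_sha256(path)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(**d)
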