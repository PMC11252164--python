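"""Config loading, validation and run manifests.

A config file is a YAML/JSON map of parameter symbols (exactly the
ModelParameters field names), an optional ``preset`` name supplying every
missing value, an optional ``variants`` block of mutant scalings, and an
optional ``genotype`` (string ``GENE:VARIANT:ZYGOSITY`` or mapping).  Unknown
keys are rejected by name.  Every CLI run emits a manifest with the fully
resolved configuration, seeds, package version, file digests and wall-clock
times, so any run can be reproduced from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .genotype import GenotypeSpec, parse_genotype
from .parameters import ModelParameters, VariantScalings, load_preset

__all__ = ["load_config", "RunManifest", "file_digest"]

_PARAM_KEYS = {f.name for f in dataclasses.fields(ModelParameters)} - {
    "variants", "preset"}
_TOP_KEYS = _PARAM_KEYS | {"preset", "variants", "genotype"}


def load_config(
    path: str | Path | None = None,
    *,
    preset: str | None = None,
    overrides: dict | None = None,
) -> tuple[ModelParameters, GenotypeSpec | None]:
    """Resolve parameters (and an optional genotype) from file + preset.

    Precedence: explicit ``overrides`` > file values > the named preset
    (file's ``preset`` key, else the ``preset`` argument, else ``revised``).
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)}; "
            f"valid keys are {sorted(_TOP_KEYS)}"
        )
    preset_name = raw.pop("preset", None) or preset or "revised"
    params = load_preset(preset_name)

    genotype = None
    g = raw.pop("genotype", None)
    if g is not None:
        if isinstance(g, str):
            genotype = parse_genotype(g)
        else:
            genotype = GenotypeSpec(**g)

    for vname, vs in (raw.pop("variants", None) or {}).items():
        base = params.variants.get(vname, VariantScalings())
        params.variants[vname] = dataclasses.replace(base, **vs)

    merged = {**raw, **(overrides or {})}
    bad = set(merged) - _PARAM_KEYS
    if bad:
        raise ValueError(f"unknown parameter key(s) {sorted(bad)}")
    if merged:
        params = params.replace(**merged)
    params.preset = preset_name
    params.validate()
    return params, genotype


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record emitted next to every CLI run's outputs."""

    subcommand: str
    config: dict
    seed: int | None = None
    version: str = __version__
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    started: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat())
    finished: str | None = None

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = file_digest(path)

    def add_output(self, path: str | Path) -> None:
        self.outputs[str(path)] = file_digest(path)

    def finish(self) -> None:
        self.finished = _dt.datetime.now(_dt.timezone.utc).isoformat()

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
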