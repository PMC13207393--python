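"""Shared run configuration: KDF cost, code parameters, constraint limits.

Loadable from a JSON or TOML file (see :func:`load_config`); the CLI layers
flag overrides on top.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field

from .constraints import ConstraintLimits
from .ecc import CodeConfig
from .errors import ConfigError
from .keyschedule import DEFAULT_KDF_ITERATIONS, LogisticParams


@dataclass(frozen=True)
class EncryptionConfig:
    """Everything the pipeline needs beyond the passphrase.

    ``ecc`` and ``constraints`` are opt-in at the library level (``None``
    disables the layer); the CLI enables both by default because its users
    are producing sequences for a noisy synthesis/sequencing channel.
    """

    kdf_iterations: int = DEFAULT_KDF_ITERATIONS
    ecc: CodeConfig | None = None
    constraints: ConstraintLimits | None = None
    logistic: LogisticParams = field(default_factory=LogisticParams)

    def __post_init__(self) -> None:
        if self.kdf_iterations < 1:
            raise ConfigError("kdf_iterations must be >= 1")


def _parse_mapping(doc: dict) -> EncryptionConfig:
    kwargs = {}
    if "kdf_iterations" in doc:
        kwargs["kdf_iterations"] = int(doc["kdf_iterations"])
    if doc.get("ecc") is not None:
        kwargs["ecc"] = CodeConfig(**doc["ecc"])
    if doc.get("constraints") is not None:
        kwargs["constraints"] = ConstraintLimits(**doc["constraints"])
    if doc.get("logistic") is not None:
        kwargs["logistic"] = LogisticParams(**doc["logistic"])
    try:
        return EncryptionConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | pathlib.Path) -> EncryptionConfig:
    """Read an :class:`EncryptionConfig` from a JSON or TOML file."""
    path = pathlib.Path(path)
    text = path.read_text()
    if path.suffix in (".toml", ".tml"):
        import tomllib
        doc = tomllib.loads(text)
    else:
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    return _parse_mapping(doc)
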