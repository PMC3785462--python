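"""Run records: reproducible, serializable results of CLI-level operations.

Every user-facing computation is wrapped in a :class:`RunRecord` carrying
the command name, the fully resolved parameters (including the seed), the
software version, wall-clock timing and the result payload. Given the same
platform RNG, a record's parameters reproduce its payload bit for bit.

A JSON schema for the record layout ships with the package
(``data/run_record.schema.json``); :func:`validate_record` checks a
serialized record against it (a minimal structural check: required keys
and primitive types).
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Any

from . import __version__

__all__ = ["RunRecord", "load_schema", "validate_record", "SchemaError"]

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "number": (int, float),
    "integer": int,
    "boolean": bool,
    "null": type(None),
}


class SchemaError(ValueError):
    """A serialized record does not match the shipped schema."""


@dataclass
class RunRecord:
    command: str
    params: dict[str, Any]
    seed: int | None
    result: dict[str, Any]
    elapsed_s: float = 0.0
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )
    software_version: str = __version__

    def to_dict(self) -> dict[str, Any]:
        return {
            "command": self.command,
            "params": self.params,
            "seed": self.seed,
            "result": self.result,
            "elapsed_s": self.elapsed_s,
            "timestamp": self.timestamp,
            "software_version": self.software_version,
        }

    def to_json(self, **kwargs: Any) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs, default=_jsonable)


def _jsonable(obj: Any) -> Any:
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def load_schema() -> dict[str, Any]:
    """The record schema shipped in the package data."""
    text = (
        resources.files("haplopower")
        .joinpath("data/run_record.schema.json")
        .read_text()
    )
    return json.loads(text)


def _check(obj: Any, schema: dict[str, Any], path: str) -> None:
    types = schema.get("type")
    if types is not None:
        allowed = types if isinstance(types, list) else [types]
        expected = tuple(
            t for name in allowed for t in (
                _TYPES[name] if isinstance(_TYPES[name], tuple) else (_TYPES[name],)
            )
        )
        if not isinstance(obj, expected) or (
            isinstance(obj, bool) and bool not in expected
        ):
            raise SchemaError(
                f"{path}: expected {types}, got {type(obj).__name__}"
            )
    if isinstance(obj, dict):
        for key in schema.get("required", []):
            if key not in obj:
                raise SchemaError(f"{path}: missing required key {key!r}")
        props = schema.get("properties", {})
        for key, sub in props.items():
            if key in obj:
                _check(obj[key], sub, f"{path}.{key}")


def validate_record(record: dict[str, Any], schema: dict[str, Any] | None = None) -> None:
    """Raise :class:`SchemaError` if ``record`` violates the shipped schema."""
    if schema is None:
        schema = load_schema()
    _check(record, schema, "$")
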