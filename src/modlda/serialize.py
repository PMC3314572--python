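"""Versioned JSON serialization of fitted models.

Floating-point fields are written with full ``repr`` precision, so a model
read back from disk reproduces its predictions bit-identically.  Files carry
a format tag and version; anything else — truncated files, foreign JSON,
future versions — raises :class:`ModelFormatError` rather than misparsing.
"""

from __future__ import annotations

import json
from pathlib import Path

from .mlda import MLDAModel
from .mpclr import MPCLRModel

__all__ = ["ModelFormatError", "write_model", "read_model"]

_FORMAT = "modlda-model"
_VERSION = 1
_TYPES = {"mlda": MLDAModel, "mpclr": MPCLRModel}


class ModelFormatError(ValueError):
    """Raised when a model file cannot be deserialized."""


def write_model(model, path) -> None:
    for name, cls in _TYPES.items():
        if isinstance(model, cls):
            model_type = name
            break
    else:
        raise TypeError(f"cannot serialize object of type {type(model).__name__}")
    payload = {
        "format": _FORMAT,
        "version": _VERSION,
        "model_type": model_type,
        "payload": model.to_dict(),
    }
    Path(path).write_text(json.dumps(payload))


def read_model(path):
    text = Path(path).read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"model file {path} is not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != _FORMAT:
        raise ModelFormatError(f"{path} is not a model file (missing format tag)")
    if doc.get("version") != _VERSION:
        raise ModelFormatError(
            f"unsupported model file version {doc.get('version')!r} in {path}"
        )
    cls = _TYPES.get(doc.get("model_type"))
    if cls is None:
        raise ModelFormatError(f"unknown model type {doc.get('model_type')!r} in {path}")
    try:
        return cls.from_dict(doc["payload"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"malformed model payload in {path}: {exc}") from exc
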