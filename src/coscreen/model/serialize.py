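"""Model persistence: a single array container holding the config (as JSON
text) plus every weight array, format-versioned.  Round trips are bitwise."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ..errors import IntegrityError
from .config import ModelConfig
from .core import DTICoEmbedder

FORMAT_VERSION = 1


def save_model(model: DTICoEmbedder, path: str | Path) -> None:
    arrays = {f"param_{i}": p for i, p in enumerate(model.params)}
    np.savez(
        path,
        __format_version__=np.array(FORMAT_VERSION),
        __config__=np.array(json.dumps(model.config.to_dict())),
        **arrays,
    )


def load_model(path: str | Path) -> DTICoEmbedder:
    try:
        data = np.load(path, allow_pickle=False)
    except Exception as exc:  # zipfile/format errors on truncated files
        raise IntegrityError(f"cannot read model file {path}: {exc}") from exc
    with data:
        if "__format_version__" not in data.files or "__config__" not in data.files:
            raise IntegrityError(f"{path} is not a model file (missing header)")
        version = int(data["__format_version__"])
        if version != FORMAT_VERSION:
            raise IntegrityError(
                f"model format version {version} != supported {FORMAT_VERSION}"
            )
        config = ModelConfig.from_dict(json.loads(str(data["__config__"])))
        model = DTICoEmbedder(config)
        n = len(model.params)
        try:
            values = [data[f"param_{i}"] for i in range(n)]
        except KeyError as exc:
            raise IntegrityError(f"{path} is missing weight arrays: {exc}") from exc
        model.set_params(values)
    return model


def model_fingerprint(model: DTICoEmbedder) -> str:
    """Short digest of config + weights, used to tag derived artifacts."""
    import hashlib

    h = hashlib.sha256()
    h.update(json.dumps(model.config.to_dict(), sort_keys=True).encode())
    for p in model.params:
        h.update(np.ascontiguousarray(p).tobytes())
    return h.hexdigest()[:16]
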