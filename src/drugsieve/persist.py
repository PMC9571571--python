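"""Model checkpoints: architecture metadata + parameter arrays in one .npz."""

from __future__ import annotations

import json

import numpy as np

from .embedding import EMBED_DIM
from .errors import SchemaError
from .extraction import DEFAULT_RESHAPE, build_architecture
from .net import Sequential
from .relevance import build_relevance_network


def save_model(path, model: Sequential, kind: str, **meta) -> None:
    """Persist a built model. ``kind`` is ``"extraction"`` or ``"relevance"``;
    extra ``meta`` (arch_id, input_reshape, architecture...) is what
    :func:`load_model` needs to rebuild the layer stack."""
    if not model.built:
        raise SchemaError("cannot save an unbuilt model")
    payload = {"__meta__": np.frombuffer(
        json.dumps({"kind": kind, "seed": model.seed, **meta}).encode(), dtype=np.uint8
    )}
    for i, layer in enumerate(model.layers):
        for name, arr in layer.params.items():
            payload[f"layer{i}/{name}"] = arr
    np.savez(path, **payload)


def load_model(path):
    """Rebuild a checkpointed model; returns ``(model, meta)``."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        kind = meta.get("kind")
        if kind == "extraction":
            model = build_architecture(
                meta["arch_id"],
                input_reshape=tuple(meta.get("input_reshape", DEFAULT_RESHAPE)),
                seed=meta["seed"],
            )
        elif kind == "relevance":
            model = build_relevance_network(
                seed=meta["seed"], architecture=meta.get("architecture", "conv")
            )
        else:
            raise SchemaError(f"{path}: unknown model kind {kind!r}")
        model.build((EMBED_DIM,))
        for i, layer in enumerate(model.layers):
            for name in layer.params:
                key = f"layer{i}/{name}"
                if key not in data:
                    raise SchemaError(f"{path}: missing parameter array {key}")
                layer.params[name] = data[key].astype(model.dtype)
    return model, meta
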