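"""Model persistence: a JSON architecture manifest plus an npz tensor store.

The manifest (human-readable) fully describes the layer stack, the
representation/decision partition, trainable flags and seeds; the
``.npz`` file holds the parameter tensors keyed by layer index.  The
pair is the unit handed between protocol steps or shipped to a serving
process.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .architectures import ArchitectureSpec, LayerSpec
from .network import ModelState

__all__ = ["save_model", "load_model"]


def save_model(state: ModelState, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.json`` and ``<prefix>.npz``; returns both paths."""
    prefix = Path(prefix)
    arch = state.architecture
    manifest = {
        "name": arch.name,
        "input_length": arch.input_length,
        "n_classes": arch.n_classes,
        "head_activation": arch.head_activation,
        "representation_end": arch.representation_end,
        "init_seed": state.init_seed,
        "layers": [asdict(l) for l in arch.layers],
    }
    json_path = prefix.with_suffix(".json")
    npz_path = prefix.with_suffix(".npz")
    json_path.write_text(json.dumps(manifest, indent=1))
    tensors = {}
    for i, params in enumerate(state.parameters):
        if params is None:
            continue
        tensors[f"layer{i}_W"] = params["W"]
        tensors[f"layer{i}_b"] = params["b"]
    np.savez(npz_path, **tensors)
    return json_path, npz_path


def load_model(prefix: str | Path) -> ModelState:
    """Rebuild a :class:`ModelState` saved by :func:`save_model`."""
    prefix = Path(prefix)
    manifest = json.loads(prefix.with_suffix(".json").read_text())
    layers = [LayerSpec(**l) for l in manifest["layers"]]
    arch = ArchitectureSpec(
        name=manifest["name"],
        layers=layers,
        representation_end=manifest["representation_end"],
        input_length=manifest["input_length"],
        n_classes=manifest["n_classes"],
        head_activation=manifest["head_activation"],
    )
    with np.load(prefix.with_suffix(".npz")) as store:
        parameters = []
        for i, spec in enumerate(layers):
            if spec.has_weights:
                parameters.append({"W": store[f"layer{i}_W"], "b": store[f"layer{i}_b"]})
            else:
                parameters.append(None)
    return ModelState(arch, parameters, init_seed=manifest["init_seed"])
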