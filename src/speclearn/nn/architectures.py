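"""The three 1D-CNN architecture specifications.

All three are 2D image classifiers re-expressed for 1D spectra: filters
slide along the m/z axis only, kernels are expanded relative to their
image counterparts because spectral features span more bins than image
edges span pixels, and convolutions are "valid" (no zero padding — binned
spectra start and end at zero, so nothing is lost at the borders).

=================  ==============================  ==================
name               stack                           weight layers
=================  ==============================  ==================
variant_lecun      2 conv(+pool), 2 dense          4
variant_lenet      3 conv(+pool), 2 dense          5
variant_vgg9       3 blocks of 2 conv, 3 dense     9
=================  ==============================  ==================

The layer list is split into a *representation* portion (everything up to
and including the last pooling layer) and a *decision* portion (flatten,
fully connected and output); transfer and cumulative learning manipulate
the two portions independently.

Exact filter counts and kernel lengths are implementation defaults, and
every size is overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["LayerSpec", "ArchitectureSpec", "build_architecture", "ARCHITECTURE_NAMES"]

ARCHITECTURE_NAMES = ("variant_lecun", "variant_lenet", "variant_vgg9")

WEIGHT_KINDS = ("conv1d", "dense", "output")


@dataclass
class LayerSpec:
    """One layer of a 1D-CNN: kind, size parameters and a trainable flag."""

    kind: str  # conv1d | maxpool1d | dense | flatten | activation | dropout | output
    filters: int | None = None
    kernel_length: int | None = None
    pool_length: int | None = None
    units: int | None = None
    rate: float | None = None
    slope: float | None = None
    trainable: bool = True

    @property
    def has_weights(self) -> bool:
        return self.kind in WEIGHT_KINDS


@dataclass
class ArchitectureSpec:
    """Ordered layer list plus the representation/decision partition index."""

    name: str
    layers: list[LayerSpec]
    representation_end: int  # layers[:representation_end] form the conv/pool stack
    input_length: int
    n_classes: int
    head_activation: str  # sigmoid | softmax

    @property
    def weight_layer_indices(self) -> list[int]:
        return [i for i, l in enumerate(self.layers) if l.has_weights]

    @property
    def conv_layer_indices(self) -> list[int]:
        return [i for i, l in enumerate(self.layers) if l.kind == "conv1d"]

    @property
    def n_weight_layers(self) -> int:
        return len(self.weight_layer_indices)

    def copy(self) -> "ArchitectureSpec":
        return ArchitectureSpec(
            self.name, [replace(l) for l in self.layers], self.representation_end,
            self.input_length, self.n_classes, self.head_activation,
        )


_DEFAULT_STACKS = {
    # (filters, kernel) conv blocks each followed by pool; dense unit list
    "variant_lecun": {"conv": [(16, 21), (32, 11)], "pool": 4, "dense": [128]},
    "variant_lenet": {"conv": [(16, 21), (32, 11), (64, 11)], "pool": 4, "dense": [256]},
    "variant_vgg9": {
        "conv_blocks": [[(32, 9), (32, 9)], [(64, 9), (64, 9)], [(128, 9), (128, 9)]],
        "pool": 4,
        "dense": [512, 256],
    },
}

LEAKY_SLOPE = 0.01
DENSE_DROPOUT = 0.5


def build_architecture(
    name: str,
    input_length: int,
    n_classes: int,
    overrides: dict | None = None,
) -> ArchitectureSpec:
    """Assemble an :class:`ArchitectureSpec` and validate its shape chain.

    The output head is a single sigmoid unit for binary problems and an
    ``n_classes``-unit softmax otherwise.  Raises a shape error naming the
    first layer whose valid convolution or pooling would underflow.
    """
    if name not in _DEFAULT_STACKS:
        raise ValueError(f"unknown architecture {name!r}; choose from {ARCHITECTURE_NAMES}")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if input_length < 64:
        raise ValueError(f"input_length must be >= 64, got {input_length}")
    cfg = dict(_DEFAULT_STACKS[name])
    if overrides:
        cfg.update(overrides)

    layers: list[LayerSpec] = []
    length = input_length
    if "conv_blocks" in cfg:
        blocks = cfg["conv_blocks"]
    else:
        blocks = [[fk] for fk in cfg["conv"]]
    for block in blocks:
        for filters, kernel in block:
            length = length - kernel + 1
            if length < 1:
                raise ValueError(
                    f"{name}: conv1d(kernel={kernel}) underflows at input length "
                    f"{length + kernel - 1}"
                )
            layers.append(LayerSpec("conv1d", filters=filters, kernel_length=kernel))
            layers.append(LayerSpec("activation", slope=LEAKY_SLOPE))
        pool = cfg["pool"]
        length = length // pool
        if length < 1:
            raise ValueError(f"{name}: maxpool1d(pool={pool}) underflows")
        layers.append(LayerSpec("maxpool1d", pool_length=pool))

    representation_end = len(layers)
    layers.append(LayerSpec("flatten"))
    for units in cfg["dense"]:
        layers.append(LayerSpec("dense", units=units))
        layers.append(LayerSpec("activation", slope=LEAKY_SLOPE))
        layers.append(LayerSpec("dropout", rate=DENSE_DROPOUT))
    head_activation = "sigmoid" if n_classes == 2 else "softmax"
    out_units = 1 if n_classes == 2 else n_classes
    layers.append(LayerSpec("output", units=out_units))

    return ArchitectureSpec(name, layers, representation_end, input_length,
                            n_classes, head_activation)


def layer_output_shapes(arch: ArchitectureSpec) -> list[tuple[int, int] | int]:
    """(channels, length) per layer, or flat width after the flatten layer."""
    shape: tuple[int, int] | int = (1, arch.input_length)
    out = []
    for spec in arch.layers:
        if spec.kind == "conv1d":
            c, l = shape
            shape = (spec.filters, l - spec.kernel_length + 1)
        elif spec.kind == "maxpool1d":
            c, l = shape
            shape = (c, l // spec.pool_length)
        elif spec.kind == "flatten":
            c, l = shape
            shape = c * l
        elif spec.kind in ("dense", "output"):
            shape = spec.units
        out.append(shape)
    return out
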