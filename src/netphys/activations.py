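"""Activation containers and exact receptive-field geometry.

The substrate of every analysis stage is an :class:`ActivationDataset`:
a rectified (post-ReLU) image x channel x height x width tensor with a
category label per image, exported from some convolutional layer.  This
module also computes, for any feed-forward stack of convolution/pooling
layers, the theoretical receptive field of a unit — the input region
that can influence it — by the standard kernel/stride/padding recursion.

Coordinate conventions: input pixel centers sit at integer coordinates
(pixel 0 at 0.0); receptive-field boxes are half-open ``[r0, r1) x
[c0, c1)`` in 0-based pixel indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "ActivationDataset",
    "RFGeometry",
    "channel_mean",
    "theoretical_rf",
    "output_grid",
    "unit_rf_bounds",
    "alexnet_conv_stack",
]


@dataclass(frozen=True)
class LayerSpec:
    """One convolution or pooling layer: square kernel, stride, zero padding."""

    kind: str  # "conv" | "pool"
    kernel: int
    stride: int = 1
    padding: int = 0
    out_channels: int | None = None  # only meaningful for conv layers

    def __post_init__(self):
        if self.kind not in ("conv", "pool"):
            raise ValueError(f"layer kind must be 'conv' or 'pool', got {self.kind!r}")
        if self.kernel < 1 or self.stride < 1:
            raise ValueError("kernel and stride must be >= 1")
        if self.padding < 0:
            raise ValueError("padding must be >= 0")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered feed-forward stack of conv/pool layers."""

    layers: tuple[LayerSpec, ...]

    def __post_init__(self):
        object.__setattr__(self, "layers", tuple(self.layers))
        if not self.layers:
            raise ValueError("architecture needs at least one layer")

    def __len__(self) -> int:
        return len(self.layers)

    @classmethod
    def from_dicts(cls, dicts) -> "ArchitectureSpec":
        return cls(tuple(LayerSpec(**d) for d in dicts))

    def to_dicts(self):
        return [
            {"kind": L.kind, "kernel": L.kernel, "stride": L.stride,
             "padding": L.padding, **({"out_channels": L.out_channels} if L.out_channels else {})}
            for L in self.layers
        ]


def alexnet_conv_stack() -> ArchitectureSpec:
    """Kernel/stride/padding geometry of the classic five-conv reference stack
    (conv 11/4/2; pool 3/2; conv 5/1/2; pool 3/2; conv 3/1/1 x3; final pool 3/2).

    The fifth convolution (index 6, pre-pool) is the layer the selectivity
    analyses read out: 256 channels on a 13 x 13 grid for 227 x 227 inputs.
    """
    return ArchitectureSpec(
        (
            LayerSpec("conv", 11, 4, 2, out_channels=64),
            LayerSpec("pool", 3, 2, 0),
            LayerSpec("conv", 5, 1, 2, out_channels=192),
            LayerSpec("pool", 3, 2, 0),
            LayerSpec("conv", 3, 1, 1, out_channels=384),
            LayerSpec("conv", 3, 1, 1, out_channels=256),
            LayerSpec("conv", 3, 1, 1, out_channels=256),
            LayerSpec("pool", 3, 2, 0),
        )
    )


@dataclass
class ActivationDataset:
    """Per-image, per-channel spatial activation maps with category labels.

    ``activations`` is (n_images, n_channels, h, w), nonnegative (the layer's
    rectification is assumed already applied; ``post_relu`` records this).
    """

    activations: np.ndarray
    categories: np.ndarray
    layer_name: str = "conv5"
    post_relu: bool = True
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.activations = np.asarray(self.activations, dtype=np.float32)
        if self.activations.ndim != 4:
            raise ValueError("activations must be image x channel x h x w")
        if self.activations.size == 0:
            raise ValueError("empty activation tensor")
        if np.any(self.activations < 0):
            raise ValueError("activations must be nonnegative (post-rectification)")
        self.categories = np.asarray(self.categories)
        if self.categories.shape[0] != self.activations.shape[0]:
            raise ValueError("label count must equal image count")

    @property
    def n_images(self) -> int:
        return self.activations.shape[0]

    @property
    def n_channels(self) -> int:
        return self.activations.shape[1]

    @property
    def map_shape(self) -> tuple[int, int]:
        return self.activations.shape[2], self.activations.shape[3]

    @property
    def category_names(self) -> np.ndarray:
        return np.unique(self.categories)

    def select(self, categories) -> "ActivationDataset":
        """Subset to the given category labels (image order preserved)."""
        wanted = set(np.atleast_1d(categories).tolist())
        mask = np.array([c in wanted for c in self.categories])
        if not mask.any():
            raise ValueError(f"no images in categories {sorted(wanted)!r}")
        return ActivationDataset(
            self.activations[mask], self.categories[mask], self.layer_name,
            self.post_relu, dict(self.metadata),
        )

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("activations", data=self.activations, dtype="float32")
            f.create_dataset(
                "categories", data=np.asarray(self.categories, dtype=object),
                dtype=h5py.string_dtype("utf-8"),
            )
            f.attrs["layer_name"] = self.layer_name
            f.attrs["post_relu"] = int(self.post_relu)

    @classmethod
    def load(cls, path) -> "ActivationDataset":
        with h5py.File(path, "r") as f:
            acts = f["activations"][()]
            cats = np.array([c.decode() if isinstance(c, bytes) else str(c)
                             for c in f["categories"][()]])
            layer = f.attrs.get("layer_name", "conv5")
            post = bool(f.attrs.get("post_relu", 1))
        return cls(acts, cats, str(layer), post)


def channel_mean(dataset: ActivationDataset) -> np.ndarray:
    """Spatial mean of every (image, channel) map -> image x channel matrix."""
    if dataset.activations.size == 0:
        raise ValueError("empty activation tensor")
    return dataset.activations.mean(axis=(2, 3), dtype=np.float64)


@dataclass(frozen=True)
class RFGeometry:
    """Receptive-field geometry of a layer's unit grid in input-pixel space.

    ``size``: side of the square receptive field; ``jump``: input-space
    stride between adjacent units; ``start``: center coordinate of unit
    (0, 0) (may be fractional for even kernels).
    """

    size: int
    jump: int
    start: float

    def __post_init__(self):
        if self.size < 1 or self.jump < 1:
            raise ValueError("size and jump must be >= 1")


def theoretical_rf(arch: ArchitectureSpec, upto_layer: int | None = None) -> RFGeometry:
    """Receptive-field geometry after the first ``upto_layer + 1`` layers.

    Standard recursion: size' = size + (kernel - 1) * jump,
    jump' = jump * stride, start' = start + ((kernel - 1)/2 - padding) * jump.
    Pooling layers participate identically to convolutions.
    """
    n = len(arch.layers)
    upto = n - 1 if upto_layer is None else int(upto_layer)
    if not 0 <= upto < n:
        raise IndexError(f"upto_layer {upto} outside architecture of {n} layers")
    size, jump, start = 1, 1, 0.0
    for L in arch.layers[: upto + 1]:
        size = size + (L.kernel - 1) * jump
        start = start + ((L.kernel - 1) / 2.0 - L.padding) * jump
        jump = jump * L.stride
    return RFGeometry(size=size, jump=jump, start=start)


def output_grid(arch: ArchitectureSpec, input_size: tuple[int, int],
                upto_layer: int | None = None) -> tuple[int, int]:
    """Spatial grid (h, w) of the layer's units for a given input size."""
    n = len(arch.layers)
    upto = n - 1 if upto_layer is None else int(upto_layer)
    if not 0 <= upto < n:
        raise IndexError(f"upto_layer {upto} outside architecture of {n} layers")
    h, w = input_size
    for L in arch.layers[: upto + 1]:
        h = (h + 2 * L.padding - L.kernel) // L.stride + 1
        w = (w + 2 * L.padding - L.kernel) // L.stride + 1
        if h < 1 or w < 1:
            raise ValueError("input too small for this architecture")
    return h, w


def unit_rf_bounds(geom: RFGeometry, unit: tuple[int, int], input_size: tuple[int, int],
                   grid_shape: tuple[int, int] | None = None) -> tuple[int, int, int, int]:
    """Half-open pixel box ``(r0, r1, c0, c1)`` of one unit's receptive field.

    The box is centered at ``start + unit * jump`` with side ``size`` and
    clipped to the image.  ``grid_shape`` (the layer's unit grid, e.g. the
    activation-map shape) enables the out-of-grid check.
    """
    r, c = unit
    if r < 0 or c < 0:
        raise IndexError(f"unit {unit} outside grid")
    if grid_shape is not None and (r >= grid_shape[0] or c >= grid_shape[1]):
        raise IndexError(f"unit {unit} outside grid {grid_shape}")
    H, W = input_size
    cr = geom.start + r * geom.jump
    cc = geom.start + c * geom.jump
    r0 = int(np.ceil(cr - geom.size / 2.0))
    c0 = int(np.ceil(cc - geom.size / 2.0))
    r1, c1 = r0 + geom.size, c0 + geom.size
    return max(r0, 0), min(r1, H), max(c0, 0), min(c1, W)


def unit_rf_box_unclipped(geom: RFGeometry, unit: tuple[int, int]) -> tuple[int, int, int, int]:
    """The same box before clipping (may extend outside the image)."""
    r, c = unit
    cr = geom.start + r * geom.jump
    cc = geom.start + c * geom.jump
    r0 = int(np.ceil(cr - geom.size / 2.0))
    c0 = int(np.ceil(cc - geom.size / 2.0))
    return r0, r0 + geom.size, c0, c0 + geom.size
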