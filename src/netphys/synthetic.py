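"""Synthetic inputs with planted, recoverable ground truth.

Every input the analysis pipeline consumes can be generated here with
known structure, so each downstream stage is testable by parameter
recovery: category-structured activation tensors with planted selective
channels of controlled gain, screening manifests with known per-rater
flag rates, vertex time series built as a known linear mixture of
HRF-processed channel regressors plus Gaussian noise, and a tiny
convolutional network with known geometry and an optional planted
localized filter for empirical-receptive-field recovery.

All generators are pure functions of their parameters and a seed.  One
global seed expands into per-component child seeds by a fixed splitting
rule (component-name offsets into a ``SeedSequence``), so stages are
individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activations import ActivationDataset, ArchitectureSpec, LayerSpec
from .brain_link import HRFSpec, build_design
from .screening import ScreeningManifest

__all__ = [
    "PlantedSelectivitySpec",
    "SyntheticBrainSpec",
    "VertexTimeSeries",
    "ToyNetwork",
    "gen_activation_dataset",
    "gen_manifest",
    "gen_vertex_timeseries",
    "gen_toy_network",
    "child_rng",
    "blob_template",
    "blob_image",
    "toy_arch",
]

# fixed seed-splitting rule: component name -> offset mixed into the SeedSequence
_COMPONENT_OFFSETS = {
    "activations": 1,
    "manifest": 2,
    "brain": 3,
    "network": 4,
    "behavior": 5,
}


def child_rng(seed: int, component: str) -> np.random.Generator:
    """Child generator for a named pipeline component under one global seed."""
    if component not in _COMPONENT_OFFSETS:
        raise ValueError(f"unknown component {component!r}")
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed),
                               spawn_key=(_COMPONENT_OFFSETS[component],))
    )


@dataclass(frozen=True)
class PlantedSelectivitySpec:
    """Ground truth for planted selective channels.

    The listed channels respond to the target category with mean gain x
    the baseline mean (multiplicative planting keeps maps nonnegative and
    mirrors gain-like selectivity); all other (channel, category) cells
    stay at baseline.
    """

    channel_ids: tuple
    target_category: int
    gain: float
    noise_sd: float

    def __post_init__(self):
        ids = tuple(int(c) for c in self.channel_ids)
        object.__setattr__(self, "channel_ids", ids)
        if len(set(ids)) != len(ids):
            raise ValueError("channel_ids must be distinct")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def gen_activation_dataset(n_categories: int, images_per_category: int,
                           n_channels: int, map_shape: tuple[int, int],
                           spec: PlantedSelectivitySpec, seed: int) -> ActivationDataset:
    """Category-structured rectified activation maps with planted channels.

    Baseline activations are |Normal(1, noise_sd)| per map pixel, so maps
    are nonnegative like post-ReLU outputs; planted channels draw
    |Normal(gain, noise_sd)| for target-category images.  Categories are
    labelled ``cat000`` ... in order; bit-identical output for identical
    arguments and seed.
    """
    if min(n_categories, images_per_category, n_channels, *map_shape) < 1:
        raise ValueError("all counts must be >= 1")
    if not 0 <= spec.target_category < n_categories:
        raise IndexError(f"target_category {spec.target_category} outside "
                         f"{n_categories} categories")
    if any(c < 0 or c >= n_channels for c in spec.channel_ids):
        raise IndexError(f"channel_ids {spec.channel_ids} outside {n_channels} channels")
    rng = child_rng(seed, "activations")
    n_img = n_categories * images_per_category
    h, w = map_shape
    mu = np.ones((n_img, n_channels, 1, 1))
    categories = np.repeat(
        [f"cat{k:03d}" for k in range(n_categories)], images_per_category
    )
    target_label = f"cat{spec.target_category:03d}"
    tgt_rows = np.flatnonzero(categories == target_label)
    for ch in spec.channel_ids:
        mu[tgt_rows, ch] = spec.gain
    acts = np.abs(rng.normal(loc=mu, scale=spec.noise_sd, size=(n_img, n_channels, h, w)))
    return ActivationDataset(acts.astype(np.float32), categories,
                             layer_name="synthetic_conv",
                             metadata={"planted_channels": list(spec.channel_ids),
                                       "target": target_label, "gain": spec.gain,
                                       "noise_sd": spec.noise_sd, "seed": int(seed)})


def gen_manifest(category_sizes: dict, flag_rates: tuple[float, float], seed: int,
                 val_fraction: float = 0.0) -> ScreeningManifest:
    """Screening manifest with independent Bernoulli per-rater flags.

    ``category_sizes`` maps category name -> image count; each rater flags
    each image independently at their rate.  ``val_fraction`` of each
    category (rounded down) is assigned to the validation split, the rest
    to training.
    """
    import pandas as pd

    r1, r2 = flag_rates
    if not (0 <= r1 <= 1 and 0 <= r2 <= 1):
        raise ValueError("flag rates must lie in [0, 1]")
    if not 0 <= val_fraction < 1:
        raise ValueError("val_fraction must lie in [0, 1)")
    rng = child_rng(seed, "manifest")
    rows = []
    for cat, n in category_sizes.items():
        n_val = int(n * val_fraction)
        for i in range(int(n)):
            rows.append({
                "image_id": f"{cat}_{i:05d}",
                "category": cat,
                "rater1": bool(rng.random() < r1),
                "rater2": bool(rng.random() < r2),
                "split": "val" if i < n_val else "train",
            })
    return ScreeningManifest(pd.DataFrame(rows))


@dataclass(frozen=True)
class SyntheticBrainSpec:
    """Ground truth for synthetic vertex time series.

    ``mixing`` is the vertex x channel weight matrix; each vertex series
    is its mixing row times the HRF-processed channel regressors plus
    Gaussian(0, noise_sd) noise at TR resolution.
    """

    mixing: np.ndarray
    tr_seconds: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0
    hrf: HRFSpec = field(default_factory=HRFSpec)

    def __post_init__(self):
        m = np.asarray(self.mixing, dtype=float)
        if m.ndim != 2 or not np.all(np.isfinite(m)):
            raise ValueError("mixing must be a finite vertex x channel matrix")
        object.__setattr__(self, "mixing", m)
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def n_vertices(self) -> int:
        return self.mixing.shape[0]


@dataclass
class VertexTimeSeries:
    """Synthetic vertex x TR matrix with its generating design and mixing."""

    data: np.ndarray
    design: np.ndarray  # TR x channel standardized regressors
    spec: SyntheticBrainSpec

    @property
    def n_vertices(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


def gen_vertex_timeseries(channel_series, spec: SyntheticBrainSpec) -> VertexTimeSeries:
    """Vertex time series as a known linear mixture of channel regressors.

    ``channel_series`` is channel x time sampled at ``spec.hrf.dt``; each
    channel passes through the regressor pipeline (log1p, HRF convolution,
    TR binning, z-score) and vertices mix the resulting design columns.
    """
    S = np.atleast_2d(np.asarray(channel_series, dtype=float))
    if spec.mixing.shape[1] != S.shape[0]:
        raise ValueError(
            f"mixing has {spec.mixing.shape[1]} columns but {S.shape[0]} channels given"
        )
    X = build_design(S, spec.hrf, spec.tr_seconds)  # TR x channel
    rng = child_rng(spec.seed, "brain")
    clean = spec.mixing @ X.T  # vertex x TR
    noise = rng.normal(0.0, spec.noise_sd, size=clean.shape) if spec.noise_sd > 0 else 0.0
    return VertexTimeSeries(clean + noise, X, spec)


class ToyNetwork:
    """Desk-scale feed-forward conv/pool network with known weights.

    Weights are a list aligned with the architecture's layers: conv layers
    hold (out_channels, in_channels, k, k) kernels (no bias), pool layers
    hold ``None`` (max pooling).  ReLU follows every convolution.
    """

    def __init__(self, arch: ArchitectureSpec, weights: list):
        self.arch = arch
        self.weights = weights

    def forward(self, image: np.ndarray) -> list[dict]:
        """Per-layer activations for one image.

        ``image`` is (H, W) or (C, H, W).  Returns one dict per layer with
        ``pre`` (pre-rectification for conv; pool output for pool) and
        ``post`` (after ReLU for conv; identical to pre for pool).
        """
        x = np.asarray(image, dtype=float)
        if x.ndim == 2:
            x = x[None]
        out = []
        for L, Wk in zip(self.arch.layers, self.weights):
            if L.kind == "conv":
                pre = _conv2d(x, Wk, L.stride, L.padding)
                post = np.maximum(pre, 0.0)
            else:
                pre = _maxpool2d(x, L.kernel, L.stride, L.padding)
                post = pre
            out.append({"pre": pre, "post": post})
            x = post
        return out


def _pad(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (p, p), (p, p)))


def _windows(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    # x: (C, H, W) -> (C, Ho, Wo, k, k)
    from numpy.lib.stride_tricks import sliding_window_view

    w = sliding_window_view(x, (k, k), axis=(1, 2))
    return w[:, ::stride, ::stride]


def _conv2d(x: np.ndarray, kernels: np.ndarray, stride: int, padding: int) -> np.ndarray:
    xp = _pad(x, padding)
    k = kernels.shape[-1]
    if xp.shape[1] < k or xp.shape[2] < k:
        raise ValueError("input smaller than kernel")
    win = _windows(xp, k, stride)  # (Cin, Ho, Wo, k, k)
    return np.einsum("oikl,ihwkl->ohw", kernels, win)


def _maxpool2d(x: np.ndarray, k: int, stride: int, padding: int) -> np.ndarray:
    xp = _pad(x, padding)
    win = _windows(xp, k, stride)
    return win.max(axis=(3, 4))


def gen_toy_network(arch: ArchitectureSpec, planted_filter=None, seed: int = 0) -> ToyNetwork:
    """Random-weight toy network, optionally with one planted kernel.

    ``planted_filter`` is ``(layer_index, channel, template)`` or
    ``(channel, template)`` (then the first conv layer): that output
    channel's input-channel-0 kernel is set to the template (a localized
    detector), giving a known empirical-receptive-field ground truth.
    Weights are reproducible under the seed.
    """
    rng = child_rng(seed, "network")
    weights: list = []
    in_ch = 1
    planted = None
    if planted_filter is not None:
        if len(planted_filter) == 2:
            planted = (None, int(planted_filter[0]), np.asarray(planted_filter[1], float))
        else:
            planted = (int(planted_filter[0]), int(planted_filter[1]),
                       np.asarray(planted_filter[2], float))
    first_conv = next(i for i, L in enumerate(arch.layers) if L.kind == "conv")
    for i, L in enumerate(arch.layers):
        if L.kind == "pool":
            weights.append(None)
            continue
        out_ch = L.out_channels or 1
        k = L.kernel
        Wk = rng.normal(0.0, 1.0 / np.sqrt(in_ch * k * k), size=(out_ch, in_ch, k, k))
        if planted is not None:
            layer_idx = planted[0] if planted[0] is not None else first_conv
            if i == layer_idx:
                ch, tmpl = planted[1], planted[2]
                if tmpl.shape != (k, k):
                    raise ValueError(
                        f"template shape {tmpl.shape} != kernel shape {(k, k)}"
                    )
                if not 0 <= ch < out_ch:
                    raise IndexError(f"planted channel {ch} outside {out_ch} channels")
                Wk[ch] = 0.0
                Wk[ch, 0] = tmpl
        weights.append(Wk)
        in_ch = out_ch
    return ToyNetwork(arch, weights)


def blob_template(size: int, sigma: float | None = None) -> np.ndarray:
    """Centered Gaussian blob kernel, peak 1 — a localized detector."""
    if size < 1:
        raise ValueError("size must be >= 1")
    sigma = sigma if sigma is not None else size / 4.0
    c = (size - 1) / 2.0
    rr, cc = np.mgrid[0:size, 0:size]
    return np.exp(-((rr - c) ** 2 + (cc - c) ** 2) / (2 * sigma**2))


def blob_image(shape: tuple[int, int], center: tuple[float, float],
               sigma: float = 1.5, amplitude: float = 1.0) -> np.ndarray:
    """Image containing one Gaussian blob at a known position."""
    H, W = shape
    rr, cc = np.mgrid[0:H, 0:W]
    r0, c0 = center
    return amplitude * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))


def toy_arch(kernel: int = 5, stride: int = 1, padding: int = 0,
             out_channels: int = 4) -> ArchitectureSpec:
    """Single-conv toy architecture, handy for fixtures."""
    return ArchitectureSpec((LayerSpec("conv", kernel, stride, padding,
                                       out_channels=out_channels),))
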