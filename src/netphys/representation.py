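"""Representational similarity analysis over channel-mean vectors.

Each image is summarized by the vector of its per-channel spatial mean
activations; pairwise Pearson correlations between these vectors,
Fisher-z transformed, index representational similarity.  Within- and
between-category summaries average the transformed correlations over
same-category pairs (unordered, self-pairs excluded) and cross-category
pairs respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .activations import ActivationDataset, channel_mean

__all__ = [
    "SimilarityMatrix",
    "CategorySimilarity",
    "channel_vectors",
    "fisher_z",
    "similarity_matrix",
    "category_similarity",
]

_CLIP = 1.0 - 1e-7  # keep atanh finite for duplicate vectors (r = 1 exactly)


def channel_vectors(dataset: ActivationDataset) -> np.ndarray:
    """Arrange each image's per-channel mean activations into a row vector."""
    return channel_mean(dataset)


def fisher_z(r):
    """Fisher z-transform atanh(r), with |r| clipped to 1 - 1e-7 first.

    Accepts scalars or arrays; |r| > 1 (beyond float tolerance) is an error.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    z = np.arctanh(np.clip(arr, -_CLIP, _CLIP))
    return float(z) if np.isscalar(r) or arr.ndim == 0 else z


@dataclass
class SimilarityMatrix:
    """Symmetric image x image matrix of Fisher-z pairwise similarities.

    The diagonal (self-similarity) is excluded from every summary.
    """

    z: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise ValueError("similarity matrix must be square")
        if self.labels.shape[0] != self.z.shape[0]:
            raise ValueError("one label per image required")
        if not np.allclose(self.z, self.z.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")

    @property
    def n_images(self) -> int:
        return self.z.shape[0]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("z", data=self.z)
            f.create_dataset("labels", data=np.asarray(self.labels, dtype=object),
                             dtype=h5py.string_dtype("utf-8"))

    @classmethod
    def load(cls, path) -> "SimilarityMatrix":
        with h5py.File(path, "r") as f:
            z = f["z"][()]
            labels = np.array([x.decode() if isinstance(x, bytes) else str(x)
                               for x in f["labels"][()]])
        return cls(z, labels)


def similarity_matrix(dataset: ActivationDataset) -> SimilarityMatrix:
    """Pairwise Fisher-z Pearson correlations between channel-mean vectors."""
    V = channel_vectors(dataset)
    if V.shape[1] < 2:
        raise ValueError("need >= 2 channels for a meaningful correlation")
    r = np.corrcoef(V)
    return SimilarityMatrix(fisher_z(r), dataset.categories)


@dataclass
class CategorySimilarity:
    """Within/between summary for one category pair."""

    cat_a: object
    cat_b: object
    within_a: float
    within_b: float
    between: float
    within_a_pairs: np.ndarray
    within_b_pairs: np.ndarray
    between_pairs: np.ndarray

    def summary(self) -> dict:
        return {
            "cat_a": str(self.cat_a), "cat_b": str(self.cat_b),
            "within_a": self.within_a, "within_b": self.within_b,
            "between": self.between,
            "n_within_a_pairs": int(self.within_a_pairs.size),
            "n_within_b_pairs": int(self.within_b_pairs.size),
            "n_between_pairs": int(self.between_pairs.size),
        }


def _within_pairs(z: np.ndarray, idx: np.ndarray) -> np.ndarray:
    sub = z[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return sub[iu]


def category_similarity(sim: SimilarityMatrix, cat_a, cat_b) -> CategorySimilarity:
    """Within-category and between-category mean Fisher-z similarity.

    Within means average over the C(n, 2) unordered same-category pairs;
    the between mean averages over all n_a * n_b cross pairs.
    """
    ia = np.flatnonzero(sim.labels == cat_a)
    ib = np.flatnonzero(sim.labels == cat_b)
    if ia.size < 2 or ib.size < 2:
        raise ValueError("both categories need >= 2 images for within summaries")
    wa = _within_pairs(sim.z, ia)
    wb = _within_pairs(sim.z, ib)
    bt = sim.z[np.ix_(ia, ib)].ravel()
    return CategorySimilarity(
        cat_a, cat_b,
        float(wa.mean()), float(wb.mean()), float(bt.mean()),
        wa, wb, bt,
    )
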