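"""Identification and quantification of category-selective channels.

A channel is a *candidate* for the target category (e.g. faces) when
that category evokes its strictly highest mean activation.  Candidacy is
then tested by a Mann-Whitney U test of the per-image channel means of
the target category against the runner-up category, Bonferroni-corrected
over all channels in the layer.  Selectivity of a significant channel is
quantified two ways:

* the *selective ratio* — target-category mean over the highest
  non-target mean (> 1 means target preference);
* *lifetime sparseness* S = (sum r_i / n)^2 / (sum r_i^2 / n) on the
  min-max-normalized category means r_i; S lies in (0, 1] and smaller S
  means narrower tuning (higher selectivity).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .activations import ActivationDataset, channel_mean
from .stats import bonferroni

__all__ = [
    "CategoryProfile",
    "SelectivityReport",
    "category_profile",
    "find_candidates",
    "mann_whitney_u",
    "test_channels",
    "selective_ratio",
    "lifetime_sparseness",
]

EXACT_MWU_LIMIT = 12  # exact enumeration when n1 + n2 <= this


@dataclass
class CategoryProfile:
    """channel x category matrix of mean activations."""

    means: np.ndarray
    category_names: np.ndarray

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.category_names = np.asarray(self.category_names)
        if self.means.ndim != 2:
            raise ValueError("means must be channel x category")
        if self.means.shape[1] != self.category_names.shape[0]:
            raise ValueError("category count mismatch")
        if not np.all(np.isfinite(self.means)) or np.any(self.means < 0):
            raise ValueError("means must be finite and nonnegative")

    @property
    def n_channels(self) -> int:
        return self.means.shape[0]

    def category_index(self, category) -> int:
        idx = np.flatnonzero(self.category_names == category)
        if idx.size == 0:
            raise ValueError(f"category {category!r} not in profile")
        return int(idx[0])


def category_profile(per_image_means: np.ndarray, categories) -> CategoryProfile:
    """Average per-image channel means within each category.

    ``per_image_means`` is image x channel (e.g. ``channel_mean`` output);
    returns a channel x category profile with categories in sorted order.
    """
    X = np.asarray(per_image_means, dtype=float)
    cats = np.asarray(categories)
    if X.ndim != 2 or X.shape[0] != cats.shape[0]:
        raise ValueError("per_image_means must be image x channel, one label per image")
    names = np.unique(cats)
    cols = []
    for k in names:
        rows = X[cats == k]
        if rows.shape[0] == 0:
            raise ValueError(f"category {k!r} has no images")
        cols.append(rows.mean(axis=0))
    return CategoryProfile(np.column_stack(cols), names)


def find_candidates(profile: CategoryProfile, target) -> np.ndarray:
    """Channels where the target category is the strict argmax of the profile.

    An exact tie with the runner-up disqualifies the channel.
    """
    t = profile.category_index(target)
    tgt = profile.means[:, t]
    others = np.delete(profile.means, t, axis=1)
    if others.shape[1] == 0:
        raise ValueError("need at least 2 categories")
    return np.flatnonzero(tgt > others.max(axis=1))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for sample x (midranks for ties)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = x.size
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of x vs y.

    U is the rank-sum statistic for x.  The p-value is computed by exact
    enumeration of all label assignments when n1 + n2 <= 12 (handles ties
    through midranks), otherwise by the tie-corrected normal approximation
    with continuity correction.  Two-sided p doubles the smaller tail,
    capped at 1.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    N = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    if N <= EXACT_MWU_LIMIT:
        total = math.comb(N, n1)
        rank_offset = n1 * (n1 + 1) / 2.0
        n_le = n_ge = 0
        eps = 1e-9
        for idx in itertools.combinations(range(N), n1):
            u = ranks[list(idx)].sum() - rank_offset
            if u <= u_obs + eps:
                n_le += 1
            if u >= u_obs - eps:
                n_ge += 1
        p = min(1.0, 2.0 * min(n_le, n_ge) / total)
        return u_obs, p

    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:  # all observations tied
        return u_obs, 1.0
    # continuity correction toward the mean
    z = (u_obs - mu - 0.5 * np.sign(u_obs - mu)) / math.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return u_obs, p


@dataclass
class SelectivityReport:
    """Per-channel selectivity test decisions and indices.

    ``frame`` has one row per channel: is_candidate, runner_up, U, p_raw,
    p_corrected, significant, selective_ratio, sparseness.  Bonferroni
    n_tests is the number of channels in the analyzed layer.
    """

    frame: pd.DataFrame
    target: object
    alpha: float
    n_tests: int
    metadata: dict = field(default_factory=dict)

    @property
    def significant_channels(self) -> np.ndarray:
        return self.frame.index[self.frame["significant"]].to_numpy()

    @property
    def n_significant(self) -> int:
        return int(self.frame["significant"].sum())

    @property
    def selective_ratio_of_significant(self) -> pd.Series:
        return self.frame.loc[self.frame["significant"], "selective_ratio"]

    def top_channels(self, k: int, by: str = "selective_ratio") -> np.ndarray:
        """Top-k significant channels ranked by ``by`` (default selective ratio)."""
        sig = self.frame[self.frame["significant"]]
        return sig.sort_values(by, ascending=False, kind="stable").index[:k].to_numpy()

    def summary(self) -> dict:
        sig = self.frame[self.frame["significant"]]
        return {
            "target": str(self.target),
            "alpha": self.alpha,
            "n_tests": self.n_tests,
            "n_channels": len(self.frame),
            "n_candidates": int(self.frame["is_candidate"].sum()),
            "n_significant": self.n_significant,
            "significant_channels": [int(c) for c in self.significant_channels],
            "mean_selective_ratio": float(sig["selective_ratio"].mean()) if len(sig) else None,
            "mean_sparseness": float(sig["sparseness"].mean()) if len(sig) else None,
            **self.metadata,
        }

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="channel")


def selective_ratio(profile: CategoryProfile, channel: int, target) -> float:
    """Target-category mean divided by the largest non-target mean."""
    t = profile.category_index(target)
    row = profile.means[channel]
    others = np.delete(row, t)
    if others.size == 0:
        raise ValueError("need at least 2 categories")
    runner = float(others.max())
    if runner == 0.0:
        warnings.warn(f"channel {channel}: runner-up mean is 0; selective ratio undefined")
        return float("nan")
    return float(row[t] / runner)


def lifetime_sparseness(profile_row) -> float:
    """Breadth-of-tuning index S in (0, 1] on min-max normalized means.

    S = (sum r_i / n)^2 / (sum r_i^2 / n).  A one-hot profile gives 1/n
    (maximally selective); a flat profile gives 1 (maximally broad).  A
    constant row has zero range; it is mapped to all-ones (S = 1) with a
    warning.
    """
    r = np.asarray(profile_row, dtype=float).ravel()
    n = r.size
    if n < 2:
        raise ValueError("need at least 2 categories")
    lo, hi = r.min(), r.max()
    if hi == lo:
        warnings.warn("constant activation profile: zero range, sparseness set to 1")
        r = np.ones(n)
    else:
        r = (r - lo) / (hi - lo)
    num = (r.sum() / n) ** 2
    den = (r**2).sum() / n
    return float(num / den)


def test_channels(dataset: ActivationDataset, target, alpha: float = 0.05,
                  n_tests: int | None = None) -> SelectivityReport:
    """Identify target-selective channels in an activation dataset.

    For every candidate channel (target = strict argmax of the category
    profile), the per-image channel means of the target category are tested
    against those of the runner-up category with a two-sided Mann-Whitney U
    test; p-values are Bonferroni-corrected over the number of channels in
    the layer.  The report covers all channels (non-candidates carry NaN
    test fields), with selective ratio and lifetime sparseness for each.
    """
    names = dataset.category_names
    if names.size < 2:
        raise ValueError("need at least 2 categories")
    if target not in names:
        raise ValueError(f"target category {target!r} not in dataset")
    X = channel_mean(dataset)  # image x channel
    profile = category_profile(X, dataset.categories)
    t_idx = profile.category_index(target)
    n_ch = profile.n_channels
    n_tests = n_ch if n_tests is None else int(n_tests)
    candidates = set(find_candidates(profile, target).tolist())

    rows = []
    tgt_mask = dataset.categories == target
    for ch in range(n_ch):
        others = np.delete(profile.means[ch], t_idx)
        other_names = np.delete(names, t_idx)
        runner = other_names[int(np.argmax(others))]
        ratio = selective_ratio(profile, ch, target)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            S = lifetime_sparseness(profile.means[ch])
        if ch in candidates:
            u, p = mann_whitney_u(X[tgt_mask, ch], X[dataset.categories == runner, ch])
            p_corr = bonferroni(p, n_tests)
            sig = bool(p_corr < alpha)
        else:
            u = p = p_corr = float("nan")
            sig = False
        rows.append({
            "is_candidate": ch in candidates, "runner_up": runner, "U": u,
            "p_raw": p, "p_corrected": p_corr, "significant": sig,
            "selective_ratio": ratio, "sparseness": S,
        })
    frame = pd.DataFrame(rows)
    frame.index.name = "channel"
    return SelectivityReport(
        frame=frame, target=target, alpha=alpha, n_tests=n_tests,
        metadata={"sampling_unit": "per-image channel mean",
                  "correction": "bonferroni over layer channels"},
    )
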