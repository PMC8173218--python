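"""Channel-to-brain encoding models.

Channel activation time series become fMRI regressors by the pipeline
log(x+1) -> convolution with a canonical hemodynamic response function
(double-gamma, positive peak at 4 s) -> down-sampling to the scanner TR
by bin averaging -> z-scoring.  Each brain vertex's time series is then
fit by ordinary least squares on these regressors, and the coefficient
of determination R^2 indexes the channel-brain correspondence at that
vertex; R^2 maps are averaged across stimulus clips.  Regions of
interest are the top-k vertices of a contrast map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "HRFSpec",
    "EncodingResult",
    "hrf_kernel",
    "channel_regressor",
    "build_design",
    "vertex_regression",
    "vertex_regression_map",
    "clip_average",
    "roi_topk",
    "regressor_count_match",
]


@dataclass(frozen=True)
class HRFSpec:
    """Double-gamma hemodynamic response kernel.

    The response gamma has its mode exactly at ``peak_seconds`` (shape =
    peak/scale + 1 with unit scale); an undershoot gamma peaking at
    ``undershoot_seconds`` is subtracted with weight ``ratio``.  The
    sampled kernel is normalized to unit peak.
    """

    peak_seconds: float = 4.0
    undershoot_seconds: float = 12.0
    ratio: float = 1.0 / 6.0
    dt: float = 0.1
    duration: float = 32.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.peak_seconds <= 0 or self.duration <= self.peak_seconds:
            raise ValueError("need 0 < peak_seconds < duration")


def hrf_kernel(spec: HRFSpec = HRFSpec()) -> np.ndarray:
    """Sampled double-gamma HRF with unit peak; kernel[0] = 0 (causal)."""
    t = np.arange(0.0, spec.duration + spec.dt / 2.0, spec.dt)
    g1 = sps.gamma.pdf(t, a=spec.peak_seconds + 1.0, scale=1.0)
    g2 = sps.gamma.pdf(t, a=spec.undershoot_seconds + 1.0, scale=1.0)
    h = g1 - spec.ratio * g2
    return h / h.max()


def channel_regressor(series, spec: HRFSpec, tr_seconds: float) -> np.ndarray:
    """Turn a channel activation time series into a standardized fMRI regressor.

    ``series`` holds nonnegative channel means sampled at ``spec.dt``.
    Pipeline: log(x+1) -> causal convolution with the HRF (leading edge of
    the full convolution, same length) -> TR-bin averaging -> z-score to
    mean 0, sd 1.  A series that is constant after the transform has zero
    variance and raises.
    """
    x = np.asarray(series, dtype=float).ravel()
    if np.any(x < 0):
        raise ValueError("series must be nonnegative (post-rectification means)")
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    logged = np.log1p(x)
    conv = np.convolve(logged, hrf_kernel(spec))[: x.size]
    bin_len = int(round(tr_seconds / spec.dt))
    if bin_len < 1 or abs(bin_len * spec.dt - tr_seconds) > 1e-9:
        raise ValueError("tr_seconds must be an integer multiple of spec.dt")
    n_tr = conv.size // bin_len
    if n_tr < 2:
        raise ValueError("series too short for the requested TR")
    binned = conv[: n_tr * bin_len].reshape(n_tr, bin_len).mean(axis=1)
    sd = binned.std()
    if sd == 0:
        raise ValueError("zero-variance regressor after transform")
    return (binned - binned.mean()) / sd


def build_design(channel_series: np.ndarray, spec: HRFSpec, tr_seconds: float) -> np.ndarray:
    """Stack channel regressors into a time x channel design matrix."""
    S = np.atleast_2d(np.asarray(channel_series, dtype=float))
    cols = [channel_regressor(S[c], spec, tr_seconds) for c in range(S.shape[0])]
    return np.column_stack(cols)


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    n = y.size
    Xi = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Xi, y, rcond=None)
    resid = y - Xi @ beta
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 0.0
    return 1.0 - float((resid**2).sum()) / ss_tot


def vertex_regression(vertex_ts, regressors) -> float:
    """OLS R^2 of one vertex time series on the regressor matrix.

    Includes an intercept; R^2 = 1 - SS_res / SS_tot.  A rank-deficient
    design is flagged with a warning and R^2 is computed on the reduced
    column space (least-squares pseudo-inverse).
    """
    y = np.asarray(vertex_ts, dtype=float).ravel()
    X = np.asarray(regressors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if y.size != X.shape[0]:
        raise ValueError("time-point mismatch between vertex and regressors")
    if y.size <= X.shape[1] + 1:
        raise ValueError("need more time points than regressors + intercept")
    if np.linalg.matrix_rank(np.column_stack([np.ones(y.size), X])) < X.shape[1] + 1:
        warnings.warn("rank-deficient design; R^2 computed on the reduced column space")
    return _ols_r2(y, X)


@dataclass
class EncodingResult:
    """Per-vertex R^2 map with its regressor provenance."""

    r2: np.ndarray
    regressor_ids: tuple
    n_timepoints: int
    per_clip: list = field(default_factory=list)

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        if np.any(self.r2 < -1e-12) or np.any(self.r2 > 1 + 1e-12):
            raise ValueError("R^2 must lie in [0, 1]")
        self.r2 = np.clip(self.r2, 0.0, 1.0)

    @property
    def n_vertices(self) -> int:
        return self.r2.size

    def summary(self) -> dict:
        return {
            "n_vertices": self.n_vertices,
            "n_timepoints": self.n_timepoints,
            "regressor_ids": [int(i) for i in self.regressor_ids],
            "mean_r2": float(self.r2.mean()),
            "max_r2": float(self.r2.max()),
        }


def vertex_regression_map(vertex_matrix, regressors, regressor_ids=None) -> EncodingResult:
    """R^2 of every row of a vertex x time matrix on a shared design."""
    V = np.asarray(vertex_matrix, dtype=float)
    if V.ndim != 2:
        raise ValueError("vertex matrix must be vertex x time")
    r2 = np.array([vertex_regression(V[v], regressors) for v in range(V.shape[0])])
    ids = tuple(range(np.atleast_2d(regressors).shape[1])) if regressor_ids is None \
        else tuple(regressor_ids)
    return EncodingResult(r2, ids, V.shape[1])


def clip_average(results: list[EncodingResult]) -> EncodingResult:
    """Vertex-wise arithmetic mean of per-clip R^2 maps."""
    if not results:
        raise ValueError("need at least one clip result")
    n = results[0].n_vertices
    if any(r.n_vertices != n for r in results):
        raise ValueError("mismatched vertex sets across clips")
    mean_r2 = np.mean([r.r2 for r in results], axis=0)
    return EncodingResult(
        mean_r2, results[0].regressor_ids,
        results[0].n_timepoints, per_clip=list(results),
    )


def roi_topk(zmap, k: int = 200) -> np.ndarray:
    """Indices of the k largest contrast values; boundary ties -> lowest index."""
    z = np.asarray(zmap, dtype=float).ravel()
    if k > z.size:
        raise ValueError(f"k={k} exceeds {z.size} vertices")
    order = np.lexsort((np.arange(z.size), -z))
    return np.sort(order[:k])


def regressor_count_match(report_a, report_b, by: str = "selective_ratio"):
    """Match regression-model complexity across two networks.

    Given two selectivity reports, keep all significant channels of the
    network with fewer, and the top-m (ranked by ``by``, default selective
    ratio) of the network with more, where m is the smaller count.
    Returns ``(channels_a, channels_b)`` as arrays.
    """
    na, nb = report_a.n_significant, report_b.n_significant
    if na == 0 or nb == 0:
        raise ValueError("both reports need at least one significant channel")
    m = min(na, nb)
    return report_a.top_channels(m, by=by), report_b.top_channels(m, by=by)
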