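"""Family-wise-corrected significance via lag-shift max-statistic permutations.

The null hypothesis is that the zero-lag alignment between the intracranial
envelope and the reconstructed source envelopes carries no information: per
permutation the reference envelope is circularly shifted by a random lag,
per-point correlations are recomputed (negatives zeroed), and the maximum
over the whole solution space is recorded. Thresholding the observed map at
the (1 - alpha) quantile of these maxima controls the family-wise error
over all solution points. Lags with circular distance <= 2 s from zero are
excluded because alpha envelopes are strongly autocorrelated on that scale
(their dynamics are on the order of seconds); lags that would align within
the same margin of a concatenation seam are excluded likewise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .imaging import EnvelopeField
from .metrics import CorrelationMap

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 10_000
DEFAULT_MIN_LAG_S = 2.0
DEFAULT_ALPHA = 0.01
#: Lag-matrix block size (permutations per matmul) to bound memory.
LAG_BLOCK = 1000


@dataclass
class PermutationNull:
    max_stats: np.ndarray       # (n_perm,) max-over-points correlation per draw
    lags: np.ndarray            # (n_perm,) drawn circular lags, samples
    n_perm: int
    min_lag_s: float
    seed: int | None
    exhaustive: bool = False


@dataclass
class SignificanceMap:
    significant: np.ndarray     # (n_points,) bool
    alpha: float
    threshold_r: float


def admissible_lags(n_frames: int, fs: float, min_lag_s: float = DEFAULT_MIN_LAG_S,
                    seams: tuple[int, ...] = ()) -> np.ndarray:
    """Circular lags (in frames) admissible for the surrogate distribution.

    A lag is admissible when its circular distance from zero — and from
    every concatenation-seam offset — exceeds ``min_lag_s``.
    """
    min_lag = int(np.floor(min_lag_s * fs))
    lags = np.arange(1, n_frames)
    keep = np.ones(len(lags), dtype=bool)
    for s in (0, *seams):
        circ = np.minimum((lags - s) % n_frames, (s - lags) % n_frames)
        keep &= circ > min_lag
    return lags[keep]


def build_null(
    field: EnvelopeField,
    ref_env: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    min_lag_s: float = DEFAULT_MIN_LAG_S,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermutationNull:
    """Max-statistic permutation null from circular lag shifts of the reference.

    Per permutation a uniform admissible lag is drawn (with replacement),
    the valid-frame reference series is circularly shifted, the per-point
    correlation map is recomputed with negatives zeroed, and its maximum
    over points is recorded. ``exhaustive=True`` evaluates every admissible
    lag exactly once instead of sampling.
    """
    ref_env = np.asarray(ref_env, dtype=float)
    if ref_env.shape != (field.n_frames,):
        raise ValueError("reference envelope must share the field's time base")
    v = field.valid
    E = field.env[:, v]
    y = ref_env[v]
    T = len(y)
    if field.n_frames / field.fs <= 2 * min_lag_s:
        raise ValueError("record too short for any admissible lag")
    lag_pool = admissible_lags(T, field.fs, min_lag_s, field.seams)
    if lag_pool.size == 0:
        raise ValueError("no admissible lags")
    if not exhaustive and n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low for stable FWE thresholds", stacklevel=2)

    if exhaustive:
        lags = lag_pool
    else:
        rng = np.random.default_rng(seed)
        lags = rng.choice(lag_pool, size=n_perm, replace=True)

    Ec = E - E.mean(axis=1, keepdims=True)
    En = np.linalg.norm(Ec, axis=1)
    En[En == 0] = np.inf  # degenerate points contribute r = 0
    yc = y - y.mean()     # circular shift preserves mean and norm
    yn = np.linalg.norm(yc)
    if yn == 0:
        raise ValueError("constant reference envelope")

    tidx = np.arange(T)
    max_stats = np.empty(len(lags))
    for b0 in range(0, len(lags), LAG_BLOCK):
        blk = lags[b0:b0 + LAG_BLOCK]
        shifted = yc[(tidx[:, None] - blk[None, :]) % T]   # (T, n_blk)
        r = (Ec @ shifted) / (En[:, None] * yn)
        np.maximum(r, 0.0, out=r)
        max_stats[b0:b0 + len(blk)] = r.max(axis=0)
    return PermutationNull(
        max_stats=max_stats,
        lags=np.asarray(lags),
        n_perm=len(lags),
        min_lag_s=min_lag_s,
        seed=seed,
        exhaustive=exhaustive,
    )


def significance_map(cmap: CorrelationMap, null: PermutationNull,
                     alpha: float = DEFAULT_ALPHA) -> SignificanceMap:
    """Threshold the observed map at the (1 - alpha) quantile of null maxima.

    The quantile is the empirical order statistic with upper interpolation
    (``numpy.quantile(..., method="higher")``) for bit-reproducibility; a
    point is significant iff its correlation strictly exceeds it.
    """
    if not 0 < alpha <= 0.5:
        raise ValueError("alpha must be in (0, 0.5]")
    threshold = float(np.quantile(null.max_stats, 1.0 - alpha, method="higher"))
    return SignificanceMap(
        significant=cmap.r > threshold,
        alpha=alpha,
        threshold_r=threshold,
    )
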