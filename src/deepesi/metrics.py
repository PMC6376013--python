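"""Envelope-correlation maps, lag curves, distance profiles and localization.

The reference intracranial alpha envelope is correlated (Pearson, zero lag)
with the reconstructed envelope at every solution point; negative values
are set to zero because they can stem from the spatial-threshold step.
Localization is quantified as the Euclidean distance from the true contact
position to the correlation maximum of the closest significant cluster,
plus the min-max contact-distance range over that cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .forward import SourceSpace
from .imaging import EnvelopeField

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMap:
    r: np.ndarray            # (n_points,), negatives zeroed, in [0, 1]
    r_raw: np.ndarray        # (n_points,), signed Pearson r
    reference: str           # reference channel id
    n_samples: int
    n_degenerate: int = 0    # points with undefined r (constant series)


@dataclass
class LocalizationReport:
    significant: bool
    peak_point: np.ndarray | None = None     # mm, r-maximum of selected cluster
    distance_mm: float | None = None         # contact -> cluster r-maximum
    significant_range_mm: tuple[float, float] | None = None
    cluster_size: int = 0
    peak_r: float | None = None


def _pearson_rows(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    """Pearson r of each row of X against y; degenerate rows -> 0."""
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    xn = np.linalg.norm(Xc, axis=1)
    yn = np.linalg.norm(yc)
    degen = (xn == 0) | (yn == 0)
    denom = np.where(degen, 1.0, xn * yn)
    r = (Xc @ yc) / denom
    r[degen] = 0.0
    return r, int(degen.sum())


def envelope_correlation_map(field: EnvelopeField, ref_env: np.ndarray,
                             reference: str = "intracranial") -> CorrelationMap:
    """Zero-lag Pearson correlation of every solution point with the reference.

    Both series must share the envelope time base; edge-flagged frames are
    excluded. Negative correlations are zeroed.
    """
    ref_env = np.asarray(ref_env, dtype=float)
    if ref_env.shape != (field.n_frames,):
        raise ValueError("reference envelope must share the field's time base")
    v = field.valid
    if v.sum() <= 2:
        raise ValueError("fewer than 3 valid frames")
    r_raw, n_degen = _pearson_rows(field.env[:, v], ref_env[v])
    if n_degen:
        logger.info("%d solution points had undefined correlation (set to 0)", n_degen)
    return CorrelationMap(
        r=np.maximum(r_raw, 0.0),
        r_raw=r_raw,
        reference=reference,
        n_samples=int(v.sum()),
        n_degenerate=n_degen,
    )


def cross_correlation_lags(a: np.ndarray, b: np.ndarray, max_lag_s: float,
                           fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r as a function of integer-sample lag in [-max_lag, +max_lag].

    Positive lag means ``b`` is delayed relative to ``a``. Each lag uses
    the overlapping portion of the two series.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    T = len(a)
    L = int(round(max_lag_s * fs))
    if not 0 < L < T // 4 + 1:
        raise ValueError("max_lag must be positive and < duration/4")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("cross-correlation of a constant series is undefined")
    lags = np.arange(-L, L + 1)
    r = np.empty(len(lags))
    for k, lag in enumerate(lags):
        if lag >= 0:
            x, y = a[: T - lag], b[lag:]
        else:
            x, y = a[-lag:], b[: T + lag]
        xc, yc = x - x.mean(), y - y.mean()
        denom = np.linalg.norm(xc) * np.linalg.norm(yc)
        r[k] = (xc @ yc) / denom if denom > 0 else 0.0
    return lags / fs, r


def distance_profile(cmap: CorrelationMap, src: SourceSpace, contact: np.ndarray,
                     bin_mm: float = 4.0, significant: np.ndarray | None = None):
    """Mean +/- SD of correlation as a function of distance to the contact.

    Bins of width ``bin_mm`` from 0 to the maximum distance; empty bins are
    reported as NaN. By default all solution points contribute; pass a
    significance mask to restrict to significant points.
    """
    if bin_mm <= 0:
        raise ValueError("bin width must be positive")
    contact = np.asarray(contact, dtype=float)
    if np.linalg.norm(contact) > np.linalg.norm(src.points, axis=1).max() + src.spacing:
        raise ValueError("contact lies outside the source space")
    r = cmap.r if significant is None else cmap.r[significant]
    pts = src.points if significant is None else src.points[significant]
    d = np.linalg.norm(pts - contact, axis=1)
    edges = np.arange(0.0, d.max() + bin_mm, bin_mm)
    idx = np.digitize(d, edges) - 1
    n_bins = len(edges) - 1
    mean = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    for b in range(n_bins):
        m = idx == b
        if m.any():
            mean[b] = r[m].mean()
            sd[b] = r[m].std()
    centers = edges[:-1] + bin_mm / 2
    return centers, mean, sd


def _clusters(src: SourceSpace, mask: np.ndarray) -> list[np.ndarray]:
    """Connected components of a point mask under 26-connectivity."""
    vol = np.zeros(src.grid_shape, dtype=bool)
    i, j, k = src.grid_index.T
    vol[i, j, k] = mask
    labels, n = ndimage.label(vol, structure=np.ones((3, 3, 3), dtype=int))
    point_label = labels[i, j, k]
    return [np.flatnonzero(point_label == lab) for lab in range(1, n + 1)]


def localization_report(cmap: CorrelationMap, significant: np.ndarray,
                        src: SourceSpace, contact: np.ndarray) -> LocalizationReport:
    """Distance from the contact to the closest significant cluster's maximum.

    Clusters are 26-connected components of significant solution points.
    The cluster whose nearest point is closest to the contact is selected;
    the reported distance runs from the contact to that cluster's
    correlation maximum, and the range is the min-max contact distance over
    the cluster's points.
    """
    contact = np.asarray(contact, dtype=float)
    if not np.any(significant):
        return LocalizationReport(significant=False)
    clusters = _clusters(src, np.asarray(significant, dtype=bool))
    d_contact = np.linalg.norm(src.points - contact, axis=1)
    best = min(clusters, key=lambda c: d_contact[c].min())
    peak = best[np.argmax(cmap.r[best])]
    return LocalizationReport(
        significant=True,
        peak_point=src.points[peak],
        distance_mm=float(d_contact[peak]),
        significant_range_mm=(float(d_contact[best].min()), float(d_contact[best].max())),
        cluster_size=len(best),
        peak_r=float(cmap.r[peak]),
    )


def window_robustness(field: EnvelopeField, ref_env: np.ndarray,
                      window_sizes_s: list[float],
                      reference: str = "intracranial") -> dict:
    """Correlation stability across non-overlapping analysis windows.

    For each window size, the record is tiled with non-overlapping windows
    from the start of the valid region; per window the correlation map is
    recomputed. Reported per size: mean +/- SD of the correlation at the
    full-record peak point, and the mean spatial Pearson correlation
    between each window map and the full-record map.
    """
    full = envelope_correlation_map(field, ref_env, reference)
    peak = int(np.argmax(full.r))
    valid_idx = np.flatnonzero(field.valid)
    out = {"full_map": full, "peak_point_index": peak, "per_size": {}}
    for size_s in window_sizes_s:
        w = int(round(size_s * field.fs))
        if w > len(valid_idx):
            raise ValueError(f"window of {size_s} s exceeds the valid record")
        vals, sims = [], []
        for start in range(0, len(valid_idx) - w + 1, w):
            sel = valid_idx[start:start + w]
            r_win, _ = _pearson_rows(field.env[:, sel], ref_env[sel])
            r_win = np.maximum(r_win, 0.0)
            vals.append(r_win[peak])
            sim, _ = _pearson_rows(r_win[None, :], full.r)
            sims.append(sim[0])
        out["per_size"][size_s] = {
            "n_windows": len(vals),
            "mean_r": float(np.mean(vals)),
            "sd_r": float(np.std(vals)),
            "map_similarity": float(np.mean(sims)),
        }
    return out
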