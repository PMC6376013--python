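"""Source-space alpha amplitude envelopes from scalp data.

The analytic (Hilbert) signal is computed per sensor, the inverse operator
is applied separately to its real and imaginary parts, the resulting
complex current is reduced to a magnitude per Cartesian component, and the
x/y/z magnitudes are combined by the Euclidean norm. The resulting field of
nonnegative envelopes is then spatially thresholded: at every time frame,
solution points below the frame's spatial mean are zeroed, limiting
spatial-leakage effects before correlation with intracranial envelopes.

Because inversion, magnitude and the per-frame threshold all act framewise,
retaining every k-th frame commutes exactly with those steps; envelopes are
therefore subsampled to a reduced rate (default 25 Hz, comfortably above
the <= 2 Hz bandwidth of the narrow-band envelope) before inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .inverse import InverseOperator, apply_inverse, check_average_reference
from .recording import Recording
from .spectral import analytic_signal, edge_duration_s

#: Envelope sampling rate after decimation (Hz).
DEFAULT_ENVELOPE_FS = 25.0
#: Time-chunk size (frames) for memory-bounded inversion.
CHUNK_FRAMES = 2000


@dataclass
class EnvelopeField:
    env: np.ndarray                  # (n_points, n_frames), nonnegative
    fs: float                        # envelope frame rate, Hz
    band: tuple[float, float]        # passband of the underlying carrier
    valid: np.ndarray                # (n_frames,) bool, False in edge transients
    thresholded: bool = False
    seams: tuple[int, ...] = ()      # frame offsets of concatenation seams

    def __post_init__(self) -> None:
        if np.any(self.env < 0):
            raise ValueError("envelopes must be nonnegative")
        if self.valid.shape != (self.env.shape[1],):
            raise ValueError("valid mask must have one entry per frame")

    @property
    def n_points(self) -> int:
        return self.env.shape[0]

    @property
    def n_frames(self) -> int:
        return self.env.shape[1]


def decimation_indices(n_samples: int, fs: float, target_fs: float | None) -> np.ndarray:
    """Retained sample indices for frame subsampling to ~``target_fs``."""
    if target_fs is None or target_fs >= fs:
        return np.arange(n_samples)
    step = int(round(fs / target_fs))
    return np.arange(0, n_samples, step)


def source_envelopes(
    op: InverseOperator,
    scalp_narrowband: Recording,
    envelope_fs: float | None = DEFAULT_ENVELOPE_FS,
) -> EnvelopeField:
    """Reconstruct per-point alpha envelopes from band-passed scalp data.

    The input must already be band-passed to the individualized alpha band
    and average-referenced. Returns an unthresholded nonnegative field at
    the (possibly reduced) envelope frame rate, with filter/Hilbert edge
    frames flagged invalid.
    """
    if scalp_narrowband.band is None:
        raise ValueError("scalp data must be band-passed first (no band recorded)")
    if scalp_narrowband.reference != "average":
        raise ValueError("scalp data must be average-referenced")
    check_average_reference(scalp_narrowband.data)

    analytic = analytic_signal(scalp_narrowband)
    fs = scalp_narrowband.fs
    idx = decimation_indices(analytic.shape[1], fs, envelope_fs)
    fs_env = fs / (idx[1] - idx[0]) if len(idx) > 1 else fs
    analytic = np.ascontiguousarray(analytic[:, idx])

    N = op.n_points
    T = analytic.shape[1]
    env = np.empty((N, T))
    for c0 in range(0, T, CHUNK_FRAMES):
        chunk = analytic[:, c0:c0 + CHUNK_FRAMES]
        J = apply_inverse(op, chunk).reshape(N, 3, -1)
        env[:, c0:c0 + chunk.shape[1]] = np.sqrt((np.abs(J) ** 2).sum(axis=1))

    edge = edge_duration_s(scalp_narrowband.band)
    t = idx / fs
    valid = (t >= edge) & (t < scalp_narrowband.duration - edge)
    # mark edge-adjacent frames around concatenation seams invalid as well
    for seam in scalp_narrowband.seams:
        valid &= np.abs(idx - seam) / fs >= edge
    seams_env = tuple(int(np.searchsorted(idx, s)) for s in scalp_narrowband.seams)
    return EnvelopeField(env=env, fs=fs_env, band=scalp_narrowband.band,
                         valid=valid, thresholded=False, seams=seams_env)


def spatial_threshold(field: EnvelopeField) -> EnvelopeField:
    """Zero all entries below their frame's spatial mean.

    At every time frame the mean over all solution points is taken and
    entries strictly below it are set to zero; entries at or above the mean
    are kept unchanged. Not idempotent by design (the mean of a thresholded
    frame differs), so double application is an error.
    """
    if field.thresholded:
        raise ValueError("field is already thresholded; the operation is not idempotent")
    mean = field.env.mean(axis=0, keepdims=True)
    env = np.where(field.env >= mean, field.env, 0.0)
    return replace(field, env=env, thresholded=True)
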