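"""Re-referencing and segment selection.

Scalp EEG is recalculated against the common average reference; intracranial
lead contacts are recalculated to bipolar derivations between adjacent
contacts. Artifact screening itself is out of scope: callers pass explicit
keep-intervals and the resulting concatenation seams are recorded so that
lag-based surrogate statistics can avoid drawing lags that wrap close to a
seam.
"""

from __future__ import annotations

import logging

import numpy as np

from .recording import Recording

logger = logging.getLogger(__name__)

#: Minimum total retained duration (s) before a below-minimum warning is raised.
MIN_SEGMENT_TOTAL_S = 240.0


def to_average_reference(rec: Recording) -> Recording:
    """Re-reference to the instantaneous mean over all channels.

    The common average reference subtracts, at every sample, the mean over
    all channels, so every column of the output sums to zero. Idempotent.
    """
    if rec.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    if rec.reference == "bipolar":
        raise ValueError("cannot average-reference bipolar derivations")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=data, reference="average")


def to_bipolar(rec: Recording, lead_layout: dict[str, list[str]]) -> Recording:
    """Recalculate lead contacts to adjacent bipolar derivations.

    Parameters
    ----------
    lead_layout
        Mapping from lead name to its contact labels ordered from the
        deepest to the most superficial contact. Each lead with n contacts
        yields n-1 bipolar channels.

    Sign convention: deeper contact minus shallower contact. Bipolar channel
    positions are the midpoints of the contributing contact pair. Any signal
    common to all contacts of a lead cancels exactly.
    """
    label_to_row = {lab: i for i, lab in enumerate(rec.labels)}
    rows, labels, positions = [], [], []
    for lead, contacts in lead_layout.items():
        if len(contacts) < 2:
            raise ValueError(f"lead {lead!r} needs at least 2 contacts")
        missing = [c for c in contacts if c not in label_to_row]
        if missing:
            raise ValueError(f"lead {lead!r}: unknown contacts {missing}")
        idx = [label_to_row[c] for c in contacts]
        for a, b in zip(idx[:-1], idx[1:]):
            rows.append(rec.data[a] - rec.data[b])
            labels.append(f"{rec.labels[a]}-{rec.labels[b]}")
            if rec.positions is not None:
                positions.append(0.5 * (rec.positions[a] + rec.positions[b]))
    pos = np.asarray(positions) if positions else None
    return rec.copy_with(
        data=np.asarray(rows), labels=labels, positions=pos, reference="bipolar"
    )


def select_segments(
    rec: Recording, keep_intervals: list[tuple[float, float]]
) -> Recording:
    """Concatenate the retained [t0, t1) intervals of a record.

    Intervals must be non-overlapping and lie within the record. Seam
    offsets between concatenated segments are recorded on the result. A
    warning is logged (and ``meta['below_min_duration']`` set) when the
    retained total falls short of four minutes, the floor used for stable
    envelope-correlation estimates.
    """
    ivs = sorted((float(t0), float(t1)) for t0, t1 in keep_intervals)
    if not ivs:
        raise ValueError("no keep intervals given")
    last_end = -np.inf
    for t0, t1 in ivs:
        if t1 <= t0:
            raise ValueError(f"empty interval [{t0}, {t1})")
        if t0 < 0 or t1 > rec.duration + 1e-9:
            raise ValueError(f"interval [{t0}, {t1}) outside record")
        if t0 < last_end:
            raise ValueError("keep intervals overlap")
        last_end = t1
    chunks, seams, offset = [], [], 0
    for t0, t1 in ivs:
        i0, i1 = int(round(t0 * rec.fs)), int(round(t1 * rec.fs))
        chunks.append(rec.data[:, i0:i1])
        offset += i1 - i0
        seams.append(offset)
    data = np.concatenate(chunks, axis=1)
    seams = tuple(seams[:-1])  # final offset is the record end, not a seam
    out = rec.copy_with(data=data, seams=seams)
    total_s = data.shape[1] / rec.fs
    if total_s < MIN_SEGMENT_TOTAL_S:
        logger.warning(
            "retained %.1f s < %.0f s minimum for stable envelope correlation",
            total_s,
            MIN_SEGMENT_TOTAL_S,
        )
        out.meta["below_min_duration"] = True
    return out
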