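"""File formats: session data, montages, matrices, ground truth, NIfTI maps.

Sessions are written as a documented raw binary matrix (float32,
channel-major) plus a JSON header carrying shape, dtype, sampling rate,
labels, units and reference — or read from EDF via MNE when an ``.edf``
path is given. Montages use the plain-text .sfp convention
(label x y z, mm, head-centred RAS). Ground truth is a JSON sidecar.
Correlation/significance maps can be rasterized to NIfTI volumes by
nearest-point scattering onto the source grid for viewing in standard
imaging tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .forward import SourceSpace
from .recording import Recording
from .simulate import GroundTruth

#: Units understood by read_session, with conversion factors to µV.
_UNIT_TO_UV = {"uV": 1.0, "µV": 1.0, "mV": 1000.0, "V": 1e6}


def save_matrix(path: str | Path, arr: np.ndarray, **header) -> None:
    """Raw little-endian float32/float64 binary + JSON header sidecar."""
    path = Path(path)
    arr = np.asarray(arr)
    dtype = "<f4" if arr.dtype == np.float32 else "<f8"
    arr.astype(dtype).tofile(path)
    meta = {"shape": list(arr.shape), "dtype": dtype, "order": "C", **header}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def load_matrix(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    arr = np.fromfile(path, dtype=meta["dtype"]).reshape(meta["shape"])
    return arr, meta


def write_sfp(path: str | Path, labels: list[str], positions: np.ndarray) -> None:
    """Whitespace montage text: label x y z per line (mm, head-centred RAS)."""
    lines = [
        f"{lab}\t{p[0]:.4f}\t{p[1]:.4f}\t{p[2]:.4f}"
        for lab, p in zip(labels, positions)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_sfp(path: str | Path) -> tuple[list[str], np.ndarray]:
    labels, pos = [], []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if len(parts) != 4:
            continue
        labels.append(parts[0])
        pos.append([float(x) for x in parts[1:]])
    if not labels:
        raise ValueError(f"no montage entries in {path}")
    return labels, np.asarray(pos)


def write_recording(path: str | Path, rec: Recording) -> None:
    """Binary+JSON session channel data (µV, float32) with metadata."""
    save_matrix(
        path,
        rec.data.astype(np.float32),
        fs=rec.fs,
        labels=list(rec.labels),
        units="uV",
        reference=rec.reference,
        seams=list(rec.seams),
    )
    if rec.positions is not None:
        write_sfp(Path(path).with_suffix(".sfp"), rec.labels, rec.positions)


def read_recording(path: str | Path) -> Recording:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    arr, meta = load_matrix(path)
    factor = _UNIT_TO_UV.get(meta.get("units", "uV"))
    if factor is None:
        raise ValueError(f"unknown units {meta.get('units')!r}")
    sfp = path.with_suffix(".sfp")
    positions = None
    if sfp.exists():
        labels, positions = read_sfp(sfp)
        if labels != meta["labels"]:
            raise ValueError("montage labels do not match the data header")
    return Recording(
        data=arr.astype(float) * factor,
        fs=float(meta["fs"]),
        labels=list(meta["labels"]),
        positions=positions,
        reference=meta.get("reference", "vertex"),
        seams=tuple(meta.get("seams", ())),
    )


def _read_edf(path: Path) -> Recording:
    import mne  # EDF parsing delegated to MNE

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE uses volts internally
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        labels=list(raw.ch_names),
        reference="vertex",
    )


def write_ground_truth(path: str | Path, gt: GroundTruth) -> None:
    payload = {
        "source_positions_mm": gt.source_positions.tolist(),
        "contact_positions_mm": gt.contact_positions.tolist(),
        "f_peak_hz": gt.f_peak,
        "orientations": gt.orientations.tolist(),
        "n_deep": int(gt.meta.get("n_deep", 2)),
        "moments": np.asarray(gt.meta.get("moments", [])).tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> dict:
    d = json.loads(Path(path).read_text())
    return {
        "source_positions": np.asarray(d["source_positions_mm"]),
        "contact_positions": np.asarray(d["contact_positions_mm"]),
        "f_peak": d["f_peak_hz"],
        "orientations": np.asarray(d["orientations"]),
        "n_deep": d["n_deep"],
    }


def write_leadfield(path: str | Path, L, reference: str = "average") -> None:
    """Persist a lead field as binary matrix + JSON header (µV per nA*m)."""
    save_matrix(path, L.gain, kind="leadfield", units="uV/nAm",
                reference=reference, n_points=L.n_points)


def read_leadfield(path: str | Path):
    from .forward import LeadField

    arr, meta = load_matrix(path)
    if meta.get("kind") != "leadfield":
        raise ValueError(f"{path} is not a lead-field matrix")
    return LeadField(gain=arr, average_referenced=meta.get("reference") == "average")


def write_source_space(path: str | Path, src: SourceSpace) -> None:
    """Source grid as CSV: index, x, y, z (mm)."""
    import pandas as pd

    df = pd.DataFrame(src.points, columns=["x_mm", "y_mm", "z_mm"])
    df.index.name = "index"
    df.to_csv(path)


def map_to_nifti(values: np.ndarray, src: SourceSpace, path: str | Path) -> None:
    """Rasterize a per-point map onto the source grid and save as NIfTI.

    The affine maps voxel indices to head-centred RAS mm at the grid
    spacing, so the volume overlays directly on mm-space anatomy.
    """
    import nibabel as nib

    vol = src.volume_mask(values=np.asarray(values, dtype=float))
    affine = np.diag([src.spacing] * 3 + [1.0])
    affine[:3, 3] = src.origin
    nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), str(path))
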