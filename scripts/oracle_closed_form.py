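"""Closed-form homogeneous-sphere dipole potential (generating-function
summation of the Legendre series), used as an independent reference by the
acceptance script."""

from __future__ import annotations

import numpy as np


def homogeneous_sphere_potential(sensors: np.ndarray, radius: float,
                                 sigma: float, pos: np.ndarray,
                                 moment: np.ndarray) -> np.ndarray:
    out = np.zeros(len(sensors))
    b = float(np.linalg.norm(pos))
    r0h = pos / b if b > 0 else np.array([0.0, 0.0, 1.0])
    f = b / radius
    for i, s in enumerate(sensors):
        rh = s / np.linalg.norm(s)
        u = float(np.clip(rh @ r0h, -1.0, 1.0))
        sg = np.sqrt(max(0.0, 1.0 - u * u))
        th = (rh - u * r0h) / sg if sg > 1e-12 else np.zeros(3)
        D = np.sqrt(1.0 - 2.0 * f * u + f * f)
        mr, mt = moment @ r0h, moment @ th
        if f > 0:
            S1 = 2.0 * (u - f) / D**3 + (1.0 / f) * (1.0 / D - 1.0)
        else:
            S1 = 3.0 * u
        S2 = 2.0 / D**3 + (D + 1.0) / (D * (1.0 - f * u + D))
        out[i] = (mr * S1 + mt * sg * S2) / (4.0 * np.pi * sigma * radius**2)
    return out * 1e3  # µV per nA*m with mm geometry
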