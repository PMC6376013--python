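"""Independent reference computations used by the tests.

These deliberately avoid the package's own series/matrix code paths:
closed-form expressions and brute-force loops only.
"""

from __future__ import annotations

import numpy as np


def homogeneous_sphere_potential(sensors: np.ndarray, radius: float,
                                 sigma: float, pos: np.ndarray,
                                 moment: np.ndarray) -> np.ndarray:
    """Closed-form surface potential of a dipole in a homogeneous,
    insulated conducting sphere (generating-function summation of the
    Legendre series), in µV per nA*m with mm geometry and S/m sigma.
    """
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
            S1 = 3.0 * u  # only the n=1 term survives at the centre
        S2 = 2.0 / D**3 + (D + 1.0) / (D * (1.0 - f * u + D))
        out[i] = (mr * S1 + mt * sg * S2) / (4.0 * np.pi * sigma * radius**2)
    return out * 1e3  # nA*m / mm^2 / (S/m) -> µV


def infinite_medium_dipole(points: np.ndarray, sigma: float, pos: np.ndarray,
                           moment: np.ndarray) -> np.ndarray:
    """Exact dipole potential in an unbounded homogeneous medium (µV)."""
    d = points - pos
    r = np.linalg.norm(d, axis=1)
    return 1e3 * (d @ moment) / (4.0 * np.pi * sigma * r**3)


def monopole_sphere_surface(sensor: np.ndarray, radius: float, sigma: float,
                            pos: np.ndarray, current: float) -> float:
    """Surface potential of a point current source in an insulated
    homogeneous sphere (classical closed form, up to an additive constant
    that cancels for source-sink pairs). µV per nA with mm geometry.

    V = I/(4 pi sigma R) * [2/D - 2 + ln(2 / (1 - f u + D))],
    D = |r - r0| / R, f = |r0| / R, u = cos(angle between r and r0).
    """
    b = float(np.linalg.norm(pos))
    f = b / radius
    rh = sensor / np.linalg.norm(sensor)
    u = float(np.clip(rh @ (pos / b if b > 0 else rh), -1.0, 1.0))
    D = np.sqrt(1.0 - 2.0 * f * u + f * f)
    series = 2.0 / D - 2.0 + np.log(2.0 / (1.0 - f * u + D))
    return 1e3 * current * series / (4.0 * np.pi * sigma * radius)


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def brute_force_lag_null(env: np.ndarray, ref: np.ndarray,
                         lags: np.ndarray) -> np.ndarray:
    """Max-over-points correlation per circular lag, by direct loops."""
    out = []
    T = len(ref)
    for lag in lags:
        shifted = np.roll(ref, lag)
        rs = []
        for row in env:
            if np.std(row) == 0 or np.std(shifted) == 0:
                rs.append(0.0)
            else:
                rs.append(max(0.0, pearson(row, shifted)))
        out.append(max(rs))
    return np.asarray(out)
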