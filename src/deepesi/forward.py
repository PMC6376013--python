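"""Three-shell concentric spherical head model and lead fields.

Sensor potentials for a current dipole inside the innermost (brain) shell
are computed from the classical Legendre-series solution of Laplace's
equation in a piecewise-homogeneous concentric-sphere conductor (brain,
skull, scalp) with an insulating exterior. Per spherical-harmonic degree n
the radial transfer through the shells is obtained by solving the small
linear system given by potential and radial-current continuity at the two
interfaces and the zero-flux condition at the scalp surface. The series is
truncated adaptively.

Geometry is head-centred RAS in millimetres with the sphere centre at the
origin. Conductivities are in S/m (default 0.33 for brain and scalp with
the skull 25x more resistive), dipole moments in nA*m, potentials in µV.
The lead-field interface accepts
any externally supplied gain matrix, so a realistic forward model can be
substituted without touching the rest of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Hard cap on the Legendre series order.
MAX_DEGREE = 200
#: Relative term-magnitude tolerance for adaptive truncation.
SERIES_RTOL = 1e-10


@dataclass
class HeadModel:
    """Concentric 3-shell sphere: brain, skull, scalp.

    Conductivities in S/m; the default 0.33 : 0.33/25 : 0.33 makes the
    skull 25x more resistive than brain and scalp.
    """

    shell_radii: tuple[float, float, float] = (80.0, 85.0, 92.0)  # mm
    conductivities: tuple[float, float, float] = (0.33, 0.33 / 25.0, 0.33)
    sensor_positions: np.ndarray | None = None  # (n_sensors, 3), on outer shell

    _transfer_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        r = self.shell_radii
        if not (0 < r[0] < r[1] < r[2]):
            raise ValueError("shell radii must be strictly increasing and positive")
        if any(c <= 0 for c in self.conductivities):
            raise ValueError("conductivities must be positive")
        if self.sensor_positions is not None:
            self.sensor_positions = np.asarray(self.sensor_positions, dtype=float)
            norms = np.linalg.norm(self.sensor_positions, axis=1)
            if np.any(np.abs(norms - r[2]) > 1e-6 * r[2]):
                raise ValueError("sensors must lie on the outer shell")

    @property
    def brain_radius(self) -> float:
        return self.shell_radii[0]


def conductivities_from_ratio(skull_ratio: float = 25.0,
                              base: float = 0.33) -> tuple[float, float, float]:
    """Brain/skull/scalp conductivities for a given skull resistivity ratio."""
    if skull_ratio <= 0 or base <= 0:
        raise ValueError("skull ratio and base conductivity must be positive")
    return (base, base / skull_ratio, base)


def _transfer_coefficients(head: HeadModel, n_max: int) -> np.ndarray:
    """Per-degree outer-surface transfer coefficients t_n, n = 1..n_max.

    For a unit primary (source) multipole coefficient x^{-(n+1)} in the
    innermost shell, t_n is the potential coefficient evaluated on the
    outer surface (radius normalized to 1). In the homogeneous limit
    (equal conductivities) t_n = (2n+1)/n.
    """
    cached = head._transfer_cache.get("t")
    if cached is not None and len(cached) >= n_max:
        return cached[:n_max]
    r1, r2, r3 = head.shell_radii
    s1, s2 = r1 / r3, r2 / r3
    c1, c2, c3 = head.conductivities
    t = np.empty(n_max)
    for n in range(1, n_max + 1):
        # unknowns u = (a1, a2, b2, a3, b3); potentials per layer:
        #   V1 = x^{-(n+1)} + a1 x^n
        #   V2 = a2 x^n + b2 x^{-(n+1)}
        #   V3 = a3 x^n + b3 x^{-(n+1)}
        A = np.zeros((5, 5))
        b = np.zeros(5)
        p1, dp1 = s1 ** -(n + 1), -(n + 1) * s1 ** -(n + 2)
        # continuity of V and sigma dV/dr at x = s1
        A[0] = [s1**n, -(s1**n), -(s1 ** -(n + 1)), 0, 0]
        b[0] = -p1
        A[1] = [c1 * n * s1 ** (n - 1), -c2 * n * s1 ** (n - 1),
                c2 * (n + 1) * s1 ** -(n + 2), 0, 0]
        b[1] = -c1 * dp1
        # continuity at x = s2
        A[2] = [0, s2**n, s2 ** -(n + 1), -(s2**n), -(s2 ** -(n + 1))]
        A[3] = [0, c2 * n * s2 ** (n - 1), -c2 * (n + 1) * s2 ** -(n + 2),
                -c3 * n * s2 ** (n - 1), c3 * (n + 1) * s2 ** -(n + 2)]
        # insulating exterior at x = 1
        A[4] = [0, 0, 0, n, -(n + 1)]
        # column scaling for conditioning at large n
        scale = np.max(np.abs(A), axis=0)
        scale[scale == 0] = 1.0
        try:
            u = np.linalg.solve(A / scale, b) / scale
        except np.linalg.LinAlgError as err:  # pragma: no cover
            raise ValueError(f"singular shell system at degree {n}") from err
        t[n - 1] = u[3] + u[4]
    head._transfer_cache["t"] = t
    return t


def _series_degree(b_hat: float, tol: float = SERIES_RTOL) -> int:
    """Truncation order: terms decay like (b/R)^n; keep a safety margin."""
    if b_hat < 1e-12:
        return 2
    n = int(np.ceil(np.log(tol) / np.log(b_hat))) + 20
    return int(np.clip(n, 20, MAX_DEGREE))


def dipole_kernel(head: HeadModel, pos: Sequence[float],
                  n_terms: int | None = None) -> np.ndarray:
    """Linear map from dipole moment to sensor potentials at one position.

    Returns K of shape (n_sensors, 3) with potentials = K @ moment.
    """
    if head.sensor_positions is None:
        raise ValueError("head model has no sensors")
    pos = np.asarray(pos, dtype=float)
    r3 = head.shell_radii[2]
    b = float(np.linalg.norm(pos))
    if b >= head.brain_radius:
        raise ValueError(
            f"source at radius {b:.2f} mm is on/outside the brain shell "
            f"({head.brain_radius:.2f} mm)"
        )
    b_hat = b / r3
    n_max = n_terms if n_terms is not None else _series_degree(b_hat)
    n_max = min(max(n_max, 1), MAX_DEGREE)
    t = _transfer_coefficients(head, n_max)

    sens = head.sensor_positions
    r_hat_s = sens / np.linalg.norm(sens, axis=1, keepdims=True)  # (S, 3)
    if b > 1e-12:
        r_hat_0 = pos / b
    else:
        r_hat_0 = np.array([0.0, 0.0, 1.0])  # degenerate: only n=1 survives
    u = np.clip(r_hat_s @ r_hat_0, -1.0, 1.0)          # cos(gamma), (S,)
    sin_g = np.sqrt(np.maximum(0.0, 1.0 - u * u))
    # tangential unit vector at the source pointing toward each sensor
    t_vec = r_hat_s - u[:, None] * r_hat_0[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        t_hat = np.where(sin_g[:, None] > 1e-12, t_vec / np.maximum(sin_g, 1e-300)[:, None], 0.0)

    # Legendre recursions: P_n(u) and P'_n(u)
    S = len(u)
    rad = np.zeros(S)   # sum of n * b^(n-1) t_n P_n
    tan = np.zeros(S)   # sum of b^(n-1) t_n sin(g) P'_n
    P_prev = np.ones(S)       # P_0
    P = u.copy()              # P_1
    dP_prev = np.zeros(S)     # P'_0
    dP = np.ones(S)           # P'_1
    bp = 1.0                  # b_hat^(n-1)
    for n in range(1, n_max + 1):
        coef = bp * t[n - 1]
        rad += coef * n * P
        tan += coef * sin_g * dP
        if n < n_max:
            P_next = ((2 * n + 1) * u * P - n * P_prev) / (n + 1)
            dP_next = dP_prev + (2 * n + 1) * P
            P_prev, P = P, P_next
            dP_prev, dP = dP, dP_next
            bp *= b_hat
    # µV per nA*m with sigma in S/m and radii in mm:
    # V[V] = (p*1e-9) / (4 pi sigma (r*1e-3)^2) * series  ->  1e3 factor in µV
    pref = 1e3 / (4.0 * np.pi * head.conductivities[0] * r3**2)
    K = pref * (rad[:, None] * r_hat_0[None, :] + tan[:, None] * t_hat)
    return K


def dipole_potential(head: HeadModel, pos: Sequence[float],
                     moment: Sequence[float],
                     n_terms: int | None = None) -> np.ndarray:
    """Sensor potentials of a dipole at ``pos`` (mm) with given moment.

    Linear in the moment; raises for sources on/outside the brain shell.
    """
    moment = np.asarray(moment, dtype=float)
    if not np.all(np.isfinite(moment)):
        raise ValueError("dipole moment must be finite")
    return dipole_kernel(head, pos, n_terms=n_terms) @ moment


@dataclass
class SourceSpace:
    """Regular grid of solution points clipped to the brain shell."""

    points: np.ndarray        # (N, 3), mm
    spacing: float            # grid step, mm
    grid_index: np.ndarray    # (N, 3) integer grid coordinates (nonnegative)
    grid_shape: tuple[int, int, int]
    origin: np.ndarray        # mm position of grid index (0,0,0)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def volume_mask(self, values: np.ndarray | None = None) -> np.ndarray:
        """Scatter per-point values (or occupancy) into the 3-D grid."""
        vol = np.zeros(self.grid_shape, dtype=float if values is not None else bool)
        i, j, k = self.grid_index.T
        vol[i, j, k] = values if values is not None else True
        return vol


def build_source_space(head: HeadModel, target_count: int = 5000) -> SourceSpace:
    """Regular 3-D grid of ~``target_count`` points inside the brain shell.

    Spacing is derived from the target count; the realized count is within
    20% of the target. Points are kept strictly inside the brain shell so
    the forward series converges everywhere, and deep (low-eccentricity)
    locations are always included.
    """
    if target_count < 10:
        raise ValueError("target_count must be >= 10")
    r_lim = head.brain_radius * 0.99

    def _grid(h):
        k = int(np.floor(r_lim / h))
        axis = np.arange(-k, k + 1) * h
        X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        inside = np.linalg.norm(pts, axis=1) < r_lim
        return axis, X.shape, pts, inside, int(inside.sum())

    h = (4.0 / 3.0 * np.pi * r_lim**3 / target_count) ** (1.0 / 3.0)
    best = None  # (|count-target|, h, grid parts)
    for _ in range(12):
        if h < 0.5:
            raise ValueError("target count unreachable at maximum grid resolution")
        axis, shape, pts, inside, count = _grid(h)
        if count >= target_count and (best is None or count - target_count < best[0]):
            best = (count - target_count, h, (axis, shape, pts, inside, count))
        if 0.8 * target_count <= count <= 1.2 * target_count:
            break
        # count ~ h^-3; damped update to avoid oscillating over the window
        h *= (max(count, 1) / target_count) ** (1.0 / 3.5)
    else:
        if best is None:
            raise ValueError(f"could not reach target count {target_count}")
        h = best[1]
        axis, shape, pts, inside, count = best[2]
    idx = np.column_stack(np.unravel_index(np.flatnonzero(inside), shape))
    return SourceSpace(
        points=pts[inside],
        spacing=h,
        grid_index=idx,
        grid_shape=shape,
        origin=np.array([axis[0]] * 3),
    )


@dataclass
class LeadField:
    """Sensors x (3 * points) gain matrix, point-major column order.

    Columns 3j..3j+2 are the average-referenced potentials of unit x/y/z
    dipoles at source point j (µV per unit moment).
    """

    gain: np.ndarray
    average_referenced: bool = True

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("lead field contains non-finite entries")
        if self.gain.shape[1] % 3:
            raise ValueError("gain must have 3 columns per source point")

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_points(self) -> int:
        return self.gain.shape[1] // 3


def build_leadfield(head: HeadModel, src: SourceSpace) -> LeadField:
    """Assemble the average-referenced lead field over the source grid."""
    if head.sensor_positions is None:
        raise ValueError("head model has no sensors")
    S = head.sensor_positions.shape[0]
    gain = np.empty((S, 3 * src.n_points))
    for j, pos in enumerate(src.points):
        try:
            K = dipole_kernel(head, pos)
        except ValueError as err:
            raise ValueError(f"source point {j}: {err}") from err
        gain[:, 3 * j:3 * j + 3] = K
    gain -= gain.mean(axis=0, keepdims=True)
    return LeadField(gain=gain, average_referenced=True)
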