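"""Synthetic resting sessions: deep and cortical alpha sources, scalp EEG
and intracranial lead recordings, with ground truth.

The generator emulates the statistical structure the analysis relies on:

* bilateral deep alpha sources (default 9 Hz) whose amplitude envelopes
  fluctuate on the scale of seconds and are correlated across hemispheres;
* additional cortical alpha sources whose envelopes are only loosely
  coupled to the deep ones;
* volume conduction to scalp sensors through the 3-shell spherical head
  model, plus white sensor noise;
* a 4-contact intracranial lead per hemisphere whose contacts record the
  local deep source with amplitude falling off with distance, referenced
  to a mastoid-like scalp potential (so the bipolar recalculation has a
  genuine common mode to reject), plus independent contact noise.

Envelopes are exponentiated Ornstein-Uhlenbeck processes: an AR(1) Gaussian
latent with autocorrelation time ``timescale`` passed through exp(sigma*x).
This keeps envelopes strictly positive and smooth, and makes the envelope
correlation of two processes a closed-form, invertible function of their
latent correlation, so target correlations can be calibrated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .forward import HeadModel, SourceSpace, dipole_kernel
from .recording import Recording

#: Log-amplitude SD of the envelope process (modulation depth ~40%).
ENVELOPE_SIGMA = 0.4
#: Spherical-cap fraction covered by the sensor net (z >= CAP_ZMIN on the
#: unit sphere, ~2.6 pi steradians, geodesic-net-like coverage).
CAP_ZMIN = -0.3
_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class SimulationConfig:
    sampling_rate: float = 1000.0          # Hz
    duration: float = 300.0                # s (5-min rest, eyes closed)
    n_sensors: int = 256
    alpha_peak: float = 9.0                # Hz, within the 8-10 Hz range
    envelope_timescale: float = 2.0        # s, envelope autocorrelation time
    interhemi_rho: float = 0.6             # target left/right deep envelope corr
    n_cortical_sources: int = 8
    cortico_deep_rho: float = 0.3          # cortical-deep envelope coupling
    sensor_noise_sd: float = 1.0           # µV
    lfp_noise_sd: float = 2.0              # µV
    deep_source_positions: tuple = ((-22.0, -12.0, 8.0), (22.0, -12.0, 8.0))  # mm
    contact_spacing: float = 1.5           # mm (4-contact leads)
    deep_moment: float = 120.0             # nA*m, bilateral deep dipole scale
    cortical_moment: float = 10.0          # nA*m per cortical source
    lfp_gain: float = 10.0                 # µV intracranial pickup scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 2 * (self.alpha_peak + 1):
            raise ValueError("sampling rate must exceed 2*(alpha_peak + 1)")
        if self.duration <= 0 or self.envelope_timescale <= 0:
            raise ValueError("duration and envelope timescale must be positive")
        n = self.duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration * sampling_rate must be an integer sample count")
        for rho in (self.interhemi_rho, self.cortico_deep_rho):
            if not 0 <= rho <= 1:
                raise ValueError("rho parameters must lie in [0, 1]")
        if self.n_sensors < 2:
            raise ValueError("need at least 2 sensors")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


@dataclass
class GroundTruth:
    source_positions: np.ndarray       # (n_sources, 3) mm, deep first
    source_envelopes: np.ndarray       # (n_sources, n_samples), nonnegative
    contact_positions: np.ndarray      # (2, 4, 3) mm, per hemisphere lead
    f_peak: float
    orientations: np.ndarray           # (n_sources, 3) unit dipole moments
    meta: dict = field(default_factory=dict)


def _ou_latent(n: int, fs: float, timescale: float, eps: np.ndarray) -> np.ndarray:
    """Stationary unit-variance AR(1) sampled from N(0,1) innovations."""
    phi = np.exp(-1.0 / (fs * timescale))
    drive = np.empty(n)
    drive[0] = eps[0]
    drive[1:] = np.sqrt(1.0 - phi * phi) * eps[1:]
    return sps.lfilter([1.0], [1.0, -phi], drive)


def _latent_rho(rho_env: float, sigma: float = ENVELOPE_SIGMA) -> float:
    """Gaussian latent correlation producing envelope correlation rho_env.

    For y_i = exp(sigma x_i) with unit-variance jointly Gaussian latents,
    corr(y1, y2) = (exp(sigma^2 rho) - 1) / (exp(sigma^2) - 1); this is the
    exact inverse of that map.
    """
    return float(np.log1p(rho_env * np.expm1(sigma**2)) / sigma**2)


def gen_envelope(timescale: float, duration: float, fs: float, seed: int,
                 sigma: float = ENVELOPE_SIGMA) -> np.ndarray:
    """Nonnegative amplitude envelope with seconds-scale autocorrelation.

    The 1/e autocorrelation lag is approximately ``timescale``; the mean is
    strictly positive. Deterministic given the seed.
    """
    if timescale <= 0 or duration <= 0:
        raise ValueError("timescale and duration must be positive")
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    x = _ou_latent(n, fs, timescale, rng.standard_normal(n))
    return np.exp(sigma * x)


def gen_correlated_envelopes(timescale: float, rho: float, duration: float,
                             fs: float, seed: int,
                             sigma: float = ENVELOPE_SIGMA):
    """Pair of envelopes with target Pearson correlation ``rho``.

    A shared and two private latent processes are mixed before
    exponentiation; the mixing weight is calibrated through the closed-form
    lognormal correlation so the realized envelope correlation converges to
    ``rho``. rho=1 returns identical series.
    """
    if not 0 <= rho <= 1:
        raise ValueError("rho must lie in [0, 1]")
    if timescale <= 0 or duration <= 0:
        raise ValueError("timescale and duration must be positive")
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    shared = _ou_latent(n, fs, timescale, rng.standard_normal(n))
    priv = [_ou_latent(n, fs, timescale, rng.standard_normal(n)) for _ in range(2)]
    a = np.sqrt(_latent_rho(rho, sigma))
    b = np.sqrt(max(0.0, 1.0 - a * a))
    return tuple(np.exp(sigma * (a * shared + b * p)) for p in priv)


def gen_alpha_source(envelope: np.ndarray, f_peak: float, fs: float,
                     seed: int) -> np.ndarray:
    """Narrow-band alpha oscillation: envelope times a cosine carrier.

    The carrier phase is drawn from the seed. Because the envelope is
    band-limited far below the carrier, the Hilbert envelope of the output
    recovers the input envelope (Bedrosian condition).
    """
    if not 0 < f_peak < fs / 2:
        raise ValueError(f"f_peak={f_peak} Hz must lie in (0, Nyquist={fs / 2}) Hz")
    envelope = np.asarray(envelope, dtype=float)
    if np.any(envelope < 0):
        raise ValueError("envelope must be nonnegative")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(len(envelope)) / fs
    return envelope * np.cos(2 * np.pi * f_peak * t + phase)


def sensor_layout(n_sensors: int, scalp_radius: float = 92.0) -> np.ndarray:
    """Deterministic quasi-uniform covering of the upper ~2.6 pi sr cap.

    Fibonacci-spiral points on the spherical cap z >= -0.3 (unit sphere),
    scaled to the scalp radius — a geodesic-net-like layout without claiming
    any specific commercial montage.
    """
    i = np.arange(n_sensors)
    z = 1.0 - (1.0 - CAP_ZMIN) * (i + 0.5) / n_sensors
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = i * _GOLDEN_ANGLE
    pts = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    return pts * scalp_radius


def default_head(n_sensors: int = 256, **kwargs) -> HeadModel:
    """3-shell head with the quasi-uniform cap sensor layout attached."""
    head = HeadModel(**kwargs)
    head.sensor_positions = sensor_layout(n_sensors, head.shell_radii[2])
    return head


def _lead_contacts(target: np.ndarray, head: HeadModel, spacing: float,
                   n_contacts: int = 4) -> np.ndarray:
    """Contact positions along a straight lead from a parietal entry point.

    The deepest contact sits at the target; contacts are collinear along
    the implantation trajectory, ``spacing`` mm apart.
    """
    entry = np.array([np.sign(target[0]) * 35.0, -50.0, 60.0])
    entry *= head.shell_radii[2] / np.linalg.norm(entry)
    direction = entry - target
    direction /= np.linalg.norm(direction)
    return target[None, :] + spacing * np.arange(n_contacts)[:, None] * direction


def simulate_session(cfg: SimulationConfig, head: HeadModel | None = None,
                     src: SourceSpace | None = None):
    """Generate one synthetic session.

    Returns ``(scalp, intracranial, ground_truth)``. The scalp recording is
    vertex-referenced (re-reference downstream); the intracranial recording
    is mastoid-referenced with one 4-contact lead per hemisphere. All series
    share a single time base. ``src`` is accepted for interface symmetry
    with the analysis stages but sources are placed independently of the
    solution grid.
    """
    if head is None:
        head = default_head(cfg.n_sensors)
    if head.sensor_positions is None or head.sensor_positions.shape[0] != cfg.n_sensors:
        raise ValueError("head model sensor count does not match the configuration")
    deep_pos = np.asarray(cfg.deep_source_positions, dtype=float)
    for p in deep_pos:
        if np.linalg.norm(p) >= head.brain_radius:
            raise ValueError(f"deep source {p} lies on/outside the brain shell")

    fs, n = cfg.sampling_rate, cfg.n_samples
    tau, sig = cfg.envelope_timescale, ENVELOPE_SIGMA
    ss = np.random.SeedSequence(cfg.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(6)]
    r_lat, r_phase, r_geom, r_sens, r_lfp, _ = rngs

    # --- envelopes: one shared latent couples hemispheres and cortex ---
    shared = _ou_latent(n, fs, tau, r_lat.standard_normal(n))
    a_d = np.sqrt(_latent_rho(cfg.interhemi_rho, sig))
    b_d = np.sqrt(max(0.0, 1.0 - a_d**2))
    deep_env = []
    for _ in range(len(deep_pos)):
        p = _ou_latent(n, fs, tau, r_lat.standard_normal(n))
        deep_env.append(np.exp(sig * (a_d * shared + b_d * p)))
    rho_cd_lat = _latent_rho(cfg.cortico_deep_rho, sig)
    a_c = 0.0 if a_d == 0 else min(1.0, rho_cd_lat / a_d)
    b_c = np.sqrt(max(0.0, 1.0 - a_c**2))
    cort_env = []
    for _ in range(cfg.n_cortical_sources):
        p = _ou_latent(n, fs, tau, r_lat.standard_normal(n))
        cort_env.append(np.exp(sig * (a_c * shared + b_c * p)))

    # --- geometry: cortical shell positions and dipole orientations ---
    cort_pos = []
    while len(cort_pos) < cfg.n_cortical_sources:
        v = r_geom.standard_normal(3)
        v /= np.linalg.norm(v)
        if v[2] > -0.2:  # cortex under the sensor cap
            cort_pos.append(v * 0.87 * head.brain_radius)
    cort_pos = np.asarray(cort_pos) if cort_pos else np.empty((0, 3))
    all_pos = np.vstack([deep_pos, cort_pos])
    orientations = r_geom.standard_normal((len(all_pos), 3))
    orientations /= np.linalg.norm(orientations, axis=1, keepdims=True)

    # --- normalized source time courses (envelope x carrier) ---
    t = np.arange(n) / fs
    envs = deep_env + cort_env
    courses = np.empty((len(all_pos), n))
    for i, env in enumerate(envs):
        phase = r_phase.uniform(0, 2 * np.pi)
        courses[i] = env * np.cos(2 * np.pi * cfg.alpha_peak * t + phase)
    moments = np.r_[np.full(len(deep_pos), cfg.deep_moment),
                    np.full(len(cort_pos), cfg.cortical_moment)]

    # --- scalp: volume conduction + vertex referencing + sensor noise ---
    gains = np.column_stack([
        dipole_kernel(head, pos) @ ori for pos, ori in zip(all_pos, orientations)
    ])  # (n_sensors, n_sources), unreferenced potentials per unit course
    scalp_raw = (gains * moments[None, :]) @ courses
    vertex = int(np.argmax(head.sensor_positions[:, 2]))
    scalp_data = scalp_raw - scalp_raw[vertex][None, :]
    if cfg.sensor_noise_sd > 0:
        scalp_data = scalp_data + cfg.sensor_noise_sd * r_sens.standard_normal(scalp_data.shape)
    scalp = Recording(
        data=scalp_data,
        fs=fs,
        labels=[f"E{i + 1:03d}" for i in range(cfg.n_sensors)],
        positions=head.sensor_positions.copy(),
        reference="vertex",
        meta={"vertex_index": vertex},
    )

    # --- intracranial leads: local pickup + mastoid common mode + noise ---
    mastoid = np.array([65.0, -40.0, -35.0])
    mastoid *= head.shell_radii[2] / np.linalg.norm(mastoid)
    mast_idx = int(np.argmin(np.linalg.norm(head.sensor_positions - mastoid, axis=1)))
    common = scalp_raw[mast_idx]
    contact_pos = np.stack([
        _lead_contacts(p, head, cfg.contact_spacing) for p in deep_pos
    ])
    ic_rows, ic_labels, ic_pos = [], [], []
    for h, hemi in enumerate("LR"[:len(deep_pos)]):
        for k in range(contact_pos.shape[1]):
            d = np.linalg.norm(contact_pos[h, k] - deep_pos[h])
            row = cfg.lfp_gain * courses[h] / (1.0 + d) - common
            if cfg.lfp_noise_sd > 0:
                row = row + cfg.lfp_noise_sd * r_lfp.standard_normal(n)
            ic_rows.append(row)
            ic_labels.append(f"{hemi}{k + 1}")
            ic_pos.append(contact_pos[h, k])
    intracranial = Recording(
        data=np.asarray(ic_rows),
        fs=fs,
        labels=ic_labels,
        positions=np.asarray(ic_pos),
        reference="mastoid",
    )

    gt = GroundTruth(
        source_positions=all_pos,
        source_envelopes=np.asarray(envs),
        contact_positions=contact_pos,
        f_peak=cfg.alpha_peak,
        orientations=orientations,
        meta={
            "moments": moments,
            "n_deep": len(deep_pos),
            "vertex_index": vertex,
            "mastoid_index": mast_idx,
        },
    )
    return scalp, intracranial, gt


def lead_layout_from_labels(labels: list[str]) -> dict[str, list[str]]:
    """Group contact labels like L1..L4/R1..R4 into per-lead orderings.

    Contacts are assumed numbered from the deepest (1) outward.
    """
    leads: dict[str, list[str]] = {}
    for lab in labels:
        leads.setdefault(lab.rstrip("0123456789"), []).append(lab)
    return {k: sorted(v, key=lambda s: int(s[len(k):])) for k, v in leads.items()}
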