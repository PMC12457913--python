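"""Synthetic landmark-trajectory generator for rolling samaras.

Rolling samaras descend on a helical path while spinning about two axes
at once: the span axis precesses about the vertical at rate ωp (tracing
the helix) and the blade simultaneously rolls about its own span axis at
the faster rate ωr.  This module generates the 3-D tracks of the four
landmarks a motion-capture pipeline would digitize (seed tip, wingtip
and the two chordal edges) for a rigid samara undergoing that idealized
dual-axis motion, optionally with a release transient and additive
tracking noise.  The generator is kinematic: it prescribes the motion
rather than integrating aerodynamic forces.

Geometry of the rigid model: the samara is a span segment of length S
with a perpendicular chord segment of length c at a fixed station; the
seed tip and wingtip are the span endpoints and the chordal edges sit at
±c/2 about the spanwise line.  The centre of rotation (COR) is the span
point at ``cor_fraction`` from the seed tip; it descends at exactly Vd
while tracing a horizontal circle of the precession radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .morphology import SPECIES_STATS, SamaraMorphology, draw_truncated
from .trajectory import LandmarkTrajectory

_Z = np.array([0.0, 0.0, 1.0])


# ----------------------------------------------------------------------
@dataclass
class KinematicGroundTruth:
    """Generator inputs: the true descent kinematics of one trial.

    Rates are positive magnitudes; ``roll_direction`` (±1) sets the sign
    of both the roll and the precession, reflecting the observed
    coupling in which the stochastic roll direction sets the direction
    of precession.
    """

    Vd_cm_s: float
    omega_p: float
    omega_r: float
    roll_direction: int = +1
    coning_angle_deg: float = 0.0
    precession_radius_cm: float | None = None  # None → 0.25·S at simulation
    cor_fraction: float = 0.6
    phase_precession: float = 0.0
    phase_roll: float = 0.0
    span_azimuth_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.roll_direction not in (+1, -1):
            raise ValueError("roll_direction must be +1 or -1")
        if self.omega_p < 0 or self.omega_r < 0:
            raise ValueError("rates are magnitudes; use roll_direction for sign")
        if self.omega_r < self.omega_p:
            raise ValueError("rolling is faster than precession (omega_r ≥ omega_p)")
        if not 0.0 <= self.cor_fraction <= 1.0:
            raise ValueError("cor_fraction must lie in [0, 1]")
        if not -90.0 < self.coning_angle_deg < 90.0:
            raise ValueError("coning angle must lie in (-90, 90) deg")
        if self.precession_radius_cm is not None and self.precession_radius_cm < 0:
            raise ValueError("precession radius must be non-negative")


#: Release-orientation presets: onset delays and spin-up time constants
#: (seconds) emulating the qualitative behaviour of the five static
#: release orientations — from the most favourable (chord parallel to
#: gravity, near-immediate roll) to span-vertical seed-down, which rolls
#: intermittently but never settles into levitation.
ORIENTATION_PRESETS: dict[int, dict[str, float]] = {
    1: dict(roll_onset_delay_s=0.035, precession_onset_delay_s=0.120,
            roll_tau_s=0.004, precession_tau_s=0.050, residual_descent_frac=0.0),
    2: dict(roll_onset_delay_s=0.105, precession_onset_delay_s=0.185,
            roll_tau_s=0.004, precession_tau_s=0.048, residual_descent_frac=0.0),
    3: dict(roll_onset_delay_s=0.175, precession_onset_delay_s=0.245,
            roll_tau_s=0.004, precession_tau_s=0.048, residual_descent_frac=0.0),
    4: dict(roll_onset_delay_s=0.230, precession_onset_delay_s=0.315,
            roll_tau_s=0.004, precession_tau_s=0.048, residual_descent_frac=0.0),
    5: dict(roll_onset_delay_s=0.150, precession_onset_delay_s=0.300,
            roll_tau_s=0.010, precession_tau_s=0.100, residual_descent_frac=0.20),
}


@dataclass
class TransientSpec:
    """Startup transient: exponential spin-up toward the steady rates.

    The roll phase stays zero until ``roll_onset_delay_s`` and then its
    rate relaxes toward ωr with time constant ``roll_tau_s``; precession
    follows the same law after its own (later) onset.  In the tunnel
    frame the vertical velocity starts at the full excess drop −Vd and
    decays to ``residual_descent_frac·(−Vd)`` in step with the
    precession spin-up, so stable precession levitates (residual 0) or
    never quite does (residual > 0, emulating the span-vertical
    seed-down release).
    """

    roll_onset_delay_s: float = 0.0
    precession_onset_delay_s: float = 0.0
    roll_tau_s: float = 0.0
    precession_tau_s: float = 0.0
    residual_descent_frac: float = 0.0
    orientation: int | None = None

    def __post_init__(self) -> None:
        for name in ("roll_onset_delay_s", "precession_onset_delay_s",
                     "roll_tau_s", "precession_tau_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.residual_descent_frac < 1.0:
            raise ValueError("residual_descent_frac must lie in [0, 1)")
        if self.roll_onset_delay_s > self.precession_onset_delay_s:
            raise ValueError("rolling must begin no later than precession")

    @classmethod
    def from_orientation(cls, orientation: int) -> "TransientSpec":
        if orientation not in ORIENTATION_PRESETS:
            raise ValueError("orientation index must be in 1..5")
        return cls(orientation=orientation, **ORIENTATION_PRESETS[orientation])


@dataclass
class SimulationConfig:
    """Sampling, frame and noise settings for one simulated trial."""

    duration_s: float = 1.0
    frame_rate: float = 1000.0
    noise_sd_cm: float = 0.0
    rng_seed: int | None = None
    frame: str = "free_fall"
    transient: TransientSpec | None = None
    chord_station_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.frame_rate <= 0:
            raise ValueError("duration and frame rate must be positive")
        if self.duration_s * self.frame_rate < 1:
            raise ValueError("duration × frame_rate must give ≥ 2 samples")
        if self.noise_sd_cm < 0:
            raise ValueError("noise SD must be non-negative")
        if self.noise_sd_cm > 0 and self.rng_seed is None:
            raise ValueError("rng_seed is mandatory when noise_sd_cm > 0")
        if self.frame not in ("free_fall", "tunnel"):
            raise ValueError("frame must be 'free_fall' or 'tunnel'")
        if not 0.0 <= self.chord_station_fraction <= 1.0:
            raise ValueError("chord_station_fraction must lie in [0, 1]")


# ----------------------------------------------------------------------
def _spun_up_phase(t: np.ndarray, omega: float, delay: float, tau: float) -> np.ndarray:
    """Accumulated phase of an exponential spin-up toward rate ``omega``.

    Rate is 0 for t < delay, then omega·(1 − e^{−(t−delay)/τ}); the
    integral is omega·[(t−delay) − τ(1 − e^{−(t−delay)/τ})].  τ = 0
    gives an instantaneous step.
    """
    dt = np.maximum(np.asarray(t, float) - delay, 0.0)
    if tau == 0.0:
        return omega * dt
    return omega * (dt - tau * (1.0 - np.exp(-dt / tau)))


def _settled_integral(t: np.ndarray, delay: float, tau: float) -> np.ndarray:
    """Integral of (1 − spun_up_fraction): total 'unsettled' time."""
    tt = np.asarray(t, float)
    dt = np.maximum(tt - delay, 0.0)
    base = np.minimum(tt, delay)
    if tau == 0.0:
        return base
    return base + tau * (1.0 - np.exp(-dt / tau))


def time_to_first_roll(omega_r: float, transient: TransientSpec) -> float:
    """Closed-form time at which the spun-up roll phase reaches 2π.

    Root of the phase integral of the exponential spin-up law; serves as
    the analytic counterpart of event detection on generated tracks.
    """
    if omega_r <= 0:
        raise ValueError("omega_r must be positive")
    d, tau = transient.roll_onset_delay_s, transient.roll_tau_s

    def phase(t: float) -> float:
        return float(_spun_up_phase(np.array([t]), omega_r, d, tau)[0]) - 2 * math.pi

    hi = d + 2 * math.pi / omega_r + 10 * tau + 1.0
    return float(brentq(phase, d, hi, xtol=1e-12))


# ----------------------------------------------------------------------
def _rigid_body_tracks(
    morph: SamaraMorphology,
    truth: KinematicGroundTruth,
    t: np.ndarray,
    psi: np.ndarray,
    phi_r: np.ndarray,
    z_cor: np.ndarray,
    chord_station_fraction: float,
) -> dict[str, np.ndarray]:
    """Landmark positions from precession azimuth ψ(t), roll phase φr(t)
    and the COR vertical track (all in the target frame)."""
    S, c = morph.S_cm, morph.c_cm
    rp = truth.precession_radius_cm
    if rp is None:
        rp = 0.25 * S
    theta = math.radians(truth.coning_angle_deg)
    f = truth.cor_fraction

    cor = np.column_stack([rp * np.cos(psi), rp * np.sin(psi), z_cor])

    psi_s = psi + truth.span_azimuth_offset
    u = np.column_stack([
        math.cos(theta) * np.cos(psi_s),
        math.cos(theta) * np.sin(psi_s),
        np.full_like(psi_s, math.sin(theta)),
    ])
    seed_tip = cor - f * S * u
    wingtip = cor + (1.0 - f) * S * u

    # chord basis in the plane perpendicular to the span: e2 horizontal
    # (vertical × span, normalized), e3 completes the right-handed triad
    e2 = np.cross(np.broadcast_to(_Z, u.shape), u)
    norm = np.linalg.norm(e2, axis=1, keepdims=True)
    if np.any(norm < 1e-12):
        raise ValueError("span axis may not be vertical")
    e2 /= norm
    e3 = np.cross(u, e2)
    chord_dir = np.cos(phi_r)[:, None] * e2 + np.sin(phi_r)[:, None] * e3

    station = seed_tip + chord_station_fraction * S * u
    half = 0.5 * c * chord_dir
    return dict(seed_tip=seed_tip, wingtip=wingtip,
                chord_left=station - half, chord_right=station + half)


def _add_noise(tracks: dict[str, np.ndarray], config: SimulationConfig) -> None:
    if config.noise_sd_cm > 0:
        rng = np.random.default_rng(config.rng_seed)
        for name in tracks:
            tracks[name] = tracks[name] + rng.normal(
                0.0, config.noise_sd_cm, size=tracks[name].shape)


def _time_grid(config: SimulationConfig) -> np.ndarray:
    n = int(round(config.duration_s * config.frame_rate)) + 1
    return np.arange(n) / config.frame_rate


def simulate_descent(
    morph: SamaraMorphology,
    truth: KinematicGroundTruth,
    config: SimulationConfig,
) -> LandmarkTrajectory:
    """Generate steady dual-axis descent tracks for the four landmarks.

    The span axis precesses about the vertical at ωp with the stated
    coning angle; the chord pair rotates about the span axis at ωr; the
    COR point descends at exactly Vd (free-fall frame) while tracing a
    circle of the precession radius.  Noise, if any, is added last.
    """
    t = _time_grid(config)
    s = truth.roll_direction
    psi = truth.phase_precession + s * truth.omega_p * t
    phi_r = truth.phase_roll + s * truth.omega_r * t
    z = -truth.Vd_cm_s * t if config.frame == "free_fall" else np.zeros_like(t)
    tracks = _rigid_body_tracks(morph, truth, t, psi, phi_r, z,
                                config.chord_station_fraction)
    _add_noise(tracks, config)
    return LandmarkTrajectory(frame_rate=config.frame_rate, t=t,
                              frame=config.frame,
                              meta=dict(kind="steady"), **tracks)


def simulate_release_transient(
    morph: SamaraMorphology,
    truth: KinematicGroundTruth,
    config: SimulationConfig,
) -> LandmarkTrajectory:
    """Generate a wind-tunnel release: drop first, roll, then precess.

    Requires ``config.frame == "tunnel"`` and a transient spec.  The
    roll phase is zero until the roll-onset delay and then spins up
    exponentially toward ωr; precession follows later; the tunnel-frame
    vertical velocity decays from the initial excess drop −Vd toward
    the residual as the precession rate approaches ωp.
    """
    if config.transient is None:
        raise ValueError("config.transient must be provided")
    if config.frame != "tunnel":
        raise ValueError("release transients are simulated in the tunnel frame")
    tr = config.transient
    if tr.roll_onset_delay_s >= config.duration_s:
        raise ValueError("roll-onset delay must fall inside the record")

    t = _time_grid(config)
    s = truth.roll_direction
    phi_r = truth.phase_roll + s * _spun_up_phase(
        t, truth.omega_r, tr.roll_onset_delay_s, tr.roll_tau_s)
    psi = truth.phase_precession + s * _spun_up_phase(
        t, truth.omega_p, tr.precession_onset_delay_s, tr.precession_tau_s)

    # vertical: v_z = -Vd*(r + (1-r)*(1 - spun_up_fraction)); integrate
    r = tr.residual_descent_frac
    unsettled = _settled_integral(t, tr.precession_onset_delay_s, tr.precession_tau_s)
    z = -truth.Vd_cm_s * (r * t + (1.0 - r) * unsettled)

    tracks = _rigid_body_tracks(morph, truth, t, psi, phi_r, z,
                                config.chord_station_fraction)
    _add_noise(tracks, config)
    return LandmarkTrajectory(frame_rate=config.frame_rate, t=t, frame="tunnel",
                              meta=dict(kind="transient",
                                        orientation=tr.orientation), **tracks)


# ----------------------------------------------------------------------
def ground_truth_from_means(species: str, **overrides) -> KinematicGroundTruth:
    """Ground truth at the published mean kinematics of one species."""
    st = SPECIES_STATS[species]
    kw = dict(Vd_cm_s=st["Vd_cm_s"][0], omega_p=st["omega_p"][0],
              omega_r=st["omega_r"][0])
    kw.update(overrides)
    return KinematicGroundTruth(**kw)


def sample_ground_truth(species: str, rng: np.random.Generator,
                        species_stats: dict | None = None,
                        **overrides) -> KinematicGroundTruth:
    """Draw one trial's kinematics from the per-species truncated normals.

    Vd, ωr and ωp come from normals truncated at ±3 SD; the roll
    direction is a fair coin; phases are uniform.
    """
    st = (species_stats or SPECIES_STATS)[species]
    kw = dict(
        Vd_cm_s=draw_truncated(rng, *st["Vd_cm_s"]),
        omega_p=draw_truncated(rng, *st["omega_p"]),
        omega_r=draw_truncated(rng, *st["omega_r"]),
        roll_direction=int(rng.choice([-1, 1])),
        phase_precession=float(rng.uniform(0, 2 * math.pi)),
        phase_roll=float(rng.uniform(0, 2 * math.pi)),
    )
    kw.update(overrides)
    if kw["omega_r"] < kw["omega_p"]:  # extreme tail draw; keep ordering
        kw["omega_r"], kw["omega_p"] = kw["omega_p"], kw["omega_r"]
    return KinematicGroundTruth(**kw)


# ----------------------------------------------------------------------
def generate_scaling_dataset(
    exponent: float,
    prefactor: float,
    x_range: tuple[float, float],
    n: int,
    noise_sd_log10: float,
    rng_seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (x, y) samples from y = k·x^β with log-normal scatter.

    x is uniform on ``x_range``; y = prefactor·x^exponent·10^ε with
    ε ~ N(0, noise_sd_log10²).  Noise-free data follow the power law
    exactly.
    """
    a, b = x_range
    if a <= 0 or b <= 0 or b <= a:
        raise ValueError("x_range must be positive with a < b")
    if n < 3:
        raise ValueError("need n ≥ 3 points")
    if noise_sd_log10 < 0:
        raise ValueError("noise SD must be non-negative")
    if prefactor <= 0:
        raise ValueError("prefactor must be positive")
    rng = np.random.default_rng(rng_seed)
    x = rng.uniform(a, b, size=n)
    eps = rng.normal(0.0, noise_sd_log10, size=n) if noise_sd_log10 > 0 else 0.0
    y = prefactor * x ** exponent * 10.0 ** eps
    return x, np.asarray(y, float)


def log10_uniform_variance(x_range: tuple[float, float]) -> float:
    """Population variance of log10(X) for X ~ Uniform(a, b), closed form."""
    a, b = x_range
    if a <= 0 or b <= a:
        raise ValueError("x_range must be positive with a < b")
    w = b - a
    e1 = (b * math.log(b) - a * math.log(a)) / w - 1.0
    f = lambda x: x * (math.log(x) ** 2 - 2 * math.log(x) + 2)
    e2 = (f(b) - f(a)) / w
    return (e2 - e1 ** 2) / math.log(10.0) ** 2


def noise_for_target_r2(exponent: float, x_range: tuple[float, float],
                        r2: float) -> float:
    """Log10 noise SD giving an expected log-scale R² for a power-law fit.

    With signal variance β²·Var(log10 X), R² = signal/(signal + σ²)
    implies σ = |β|·sd(log10 X)·sqrt((1−R²)/R²).
    """
    if not 0 < r2 < 1:
        raise ValueError("target R² must lie in (0, 1)")
    sig = exponent ** 2 * log10_uniform_variance(x_range)
    return math.sqrt(sig * (1.0 - r2) / r2)
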