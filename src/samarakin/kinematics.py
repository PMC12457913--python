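"""Kinematic estimators for dual-axis samara descent.

Given the tracked 3-D positions of the four landmarks, these routines
recover every descent quantity of interest: descent velocity Vd,
precession rate ωp and roll rate ωr with their common direction sign,
coning angle θ, centre-of-rotation location along the span, the
angle-of-attack time series α(t), the rolls-per-precession coupling
ratio and the release-transient event times (first full roll, onset of
stable precession).

Angular rates use phase-slope estimation: the relevant rotation phase
(azimuth of the wingtip about the helix axis for precession; angle of
the chord vector in the plane perpendicular to the span for roll) is
unwrapped and fitted with a least-squares line, which is unbiased for
non-integer numbers of cycles.  The roll rate is measured relative to
the co-precessing span frame (the canonical basis built from the
vertical and the instantaneous span axis); at zero coning angle this
coincides with the body roll rate about the span.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .trajectory import LandmarkTrajectory

_Z = np.array([0.0, 0.0, 1.0])

#: below this unwrapped-phase span (rad) a rotation is declared absent
_MIN_PHASE_SPAN = 1e-6
#: relative flatness of the COR objective below which COR is undefined
_COR_FLAT_RTOL = 1e-9


@dataclass
class ConingAngle:
    mean_deg: float
    series_deg: np.ndarray


@dataclass
class EventTimes:
    """Release-transient event times (tunnel frame).

    t_r: time to complete one full rolling cycle; t_p: time to stable
    precession, i.e. the start of the first window (one precession
    period long) of levitation without further descent.  A flag is
    False when the record ends before the event.
    """

    t_r: float
    t_p: float
    roll_reached: bool
    precession_reached: bool


@dataclass
class KinematicsEstimate:
    """All descent quantities recovered from one trajectory."""

    Vd_cm_s: float
    omega_p: float            # magnitude, rad/s
    omega_r: float            # magnitude, rad/s
    precession_sign: int
    roll_sign: int
    coning_angle_deg: float
    cor_fraction: float
    roll_per_precession: float
    alpha_deg: np.ndarray
    diagnostics: dict = field(default_factory=dict)


# ----------------------------------------------------------------------
# phase helpers
def _phase_slope(t: np.ndarray, phase: np.ndarray) -> tuple[float, float]:
    """Least-squares slope of an unwrapped phase, plus RMS residual."""
    coef = np.polyfit(t, phase, 1)
    resid = phase - np.polyval(coef, t)
    return float(coef[0]), float(np.sqrt(np.mean(resid ** 2)))


def _fit_circle_center(xy: np.ndarray) -> np.ndarray:
    """Algebraic (Kåsa) circle-fit centre of a planar point cloud.

    Falls back to the centroid when the design matrix is singular
    (e.g. a degenerate, zero-radius track).
    """
    x, y = xy[:, 0], xy[:, 1]
    A = np.column_stack([x, y, np.ones_like(x)])
    rhs = x ** 2 + y ** 2
    try:
        sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        return np.array([sol[0] / 2.0, sol[1] / 2.0])
    except np.linalg.LinAlgError:
        return xy.mean(axis=0)


def _precession_phase(traj: LandmarkTrajectory) -> tuple[np.ndarray, np.ndarray, float]:
    """Unwrapped azimuth of the wingtip about the helix axis.

    Returns (phase, axis centre, mean radius).  Axis = centroid of the
    horizontal wingtip track refined by a circle fit.
    """
    xy = traj.wingtip[:, :2]
    center = _fit_circle_center(xy)
    rel = xy - center
    radius = float(np.mean(np.linalg.norm(rel, axis=1)))
    phase = np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
    return phase, center, radius


def _span_units(traj: LandmarkTrajectory) -> np.ndarray:
    span = traj.span_vectors()
    norm = np.linalg.norm(span, axis=1, keepdims=True)
    if np.any(norm < 1e-9):
        raise ValueError("coincident span endpoints")
    return span / norm


def _chord_phase(traj: LandmarkTrajectory) -> np.ndarray:
    """Unwrapped angle of the chord vector in the span-normal plane."""
    u = _span_units(traj)
    e2 = np.cross(np.broadcast_to(_Z, u.shape), u)
    norm = np.linalg.norm(e2, axis=1, keepdims=True)
    if np.any(norm < 1e-9):
        raise ValueError("span axis vertical; chord basis undefined")
    e2 /= norm
    e3 = np.cross(u, e2)
    c = traj.chord_vectors()
    if np.any(np.linalg.norm(c, axis=1) < 1e-9):
        raise ValueError("zero-length chord")
    return np.unwrap(np.arctan2(np.einsum("ij,ij->i", c, e3),
                                np.einsum("ij,ij->i", c, e2)))


# ----------------------------------------------------------------------
def estimate_angular_rates(traj: LandmarkTrajectory) -> tuple[float, float]:
    """Signed precession and roll rates (rad/s) by phase-slope fits.

    Returns ``(omega_p_signed, omega_r_signed)``.  A rotation whose
    total unwrapped phase is negligible is reported as 0.0 (direction
    undefined).
    """
    phase_p, _, radius = _precession_phase(traj)
    if radius < 1e-9 or np.ptp(phase_p) < _MIN_PHASE_SPAN:
        omega_p = 0.0
    else:
        omega_p, _ = _phase_slope(traj.t, phase_p)
    phase_r = _chord_phase(traj)
    if np.ptp(phase_r) < _MIN_PHASE_SPAN:
        omega_r = 0.0
    else:
        omega_r, _ = _phase_slope(traj.t, phase_r)
    return omega_p, omega_r


def cumulative_rotation_rate(traj: LandmarkTrajectory, which: str = "roll") -> float:
    """Frame-wise cumulative-rotation rate (independent cross-check).

    Sums the signed frame-to-frame rotation angle (roll: chord angle in
    the span-normal plane; precession: wingtip azimuth) and divides by
    elapsed time.  Kept deliberately distinct from the phase-slope
    estimator used by :func:`estimate_angular_rates`.
    """
    if which == "roll":
        phase = _chord_phase(traj)
    elif which == "precession":
        phase, _, _ = _precession_phase(traj)
    else:
        raise ValueError("which must be 'roll' or 'precession'")
    steps = np.diff(phase)
    # re-wrap each step to (-pi, pi] then accumulate
    steps = (steps + np.pi) % (2 * np.pi) - np.pi
    return float(np.sum(steps) / (traj.t[-1] - traj.t[0]))


# ----------------------------------------------------------------------
def locate_center_of_rotation(traj: LandmarkTrajectory,
                              grid_step: float = 0.01) -> float:
    """Span fraction minimizing horizontal oscillation amplitude.

    Scans s ∈ [0, 1] for the point ``seed_tip + s·(wingtip−seed_tip)``
    with the smallest horizontal variance, then refines the grid
    minimum with a quadratic (parabolic) step.  Returns NaN when the
    objective is flat (rigid translation, no rotation).
    """
    s_grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    seed_xy = traj.seed_tip[:, :2]
    span_xy = traj.span_vectors()[:, :2]
    # J(s) = var_x + var_y of seed + s*span, quadratic in s
    pts = seed_xy[None, :, :] + s_grid[:, None, None] * span_xy[None, :, :]
    J = np.var(pts[:, :, 0], axis=1) + np.var(pts[:, :, 1], axis=1)
    jmax = float(J.max())
    if jmax < 1e-15 or (jmax - J.min()) / jmax < _COR_FLAT_RTOL:
        return float("nan")
    i = int(np.argmin(J))
    if 0 < i < len(s_grid) - 1:
        # parabolic refinement through the three bracketing samples
        denom = J[i - 1] - 2 * J[i] + J[i + 1]
        if denom > 0:
            shift = 0.5 * (J[i - 1] - J[i + 1]) / denom
            return float(np.clip(s_grid[i] + shift * grid_step, 0.0, 1.0))
    return float(s_grid[i])


def estimate_descent_velocity(traj: LandmarkTrajectory,
                              cor_fraction: float | None = None) -> float:
    """Descent speed (cm/s, positive down) of the COR-point track.

    Least-squares slope of the COR-point vertical coordinate over an
    integer number of precession cycles (the full record, with a
    warning, if less than one cycle is present).
    """
    if cor_fraction is None:
        cor_fraction = locate_center_of_rotation(traj)
        if math.isnan(cor_fraction):
            cor_fraction = 0.0  # rigid translation: every point equivalent
    z = traj.point_on_span(cor_fraction)[:, 2]
    t = traj.t
    omega_p, _ = estimate_angular_rates(traj)
    if omega_p != 0.0:
        period = 2 * math.pi / abs(omega_p)
        n_cycles = int(traj.duration / period)
        if n_cycles >= 1:
            n_keep = int(round(n_cycles * period * traj.frame_rate)) + 1
            t, z = t[:n_keep], z[:n_keep]
        else:
            warnings.warn("less than one precession cycle; using full record",
                          stacklevel=2)
    slope = float(np.polyfit(t, z, 1)[0])
    return -slope


def estimate_coning_angle(traj: LandmarkTrajectory) -> ConingAngle:
    """Elevation of the seed-tip→wingtip axis above the horizontal.

    Returns the mean over frames and the per-frame series (deg), so
    that slow coning drift remains inspectable.
    """
    u = _span_units(traj)
    series = np.degrees(np.arcsin(np.clip(u[:, 2], -1.0, 1.0)))
    return ConingAngle(mean_deg=float(series.mean()), series_deg=series)


# ----------------------------------------------------------------------
def local_flow_angle_deg(Vd_cm_s: float, S_cm: float, omega_p: float,
                         station: float = 0.75) -> float:
    """Flow angle from horizontal at the given span station (deg):
    arctan(Vd / (station·S·ωp))."""
    tangential = station * S_cm * abs(omega_p)
    if tangential == 0 and Vd_cm_s == 0:
        raise ValueError("zero flow vector")
    return math.degrees(math.atan2(abs(Vd_cm_s), tangential))


def angle_of_attack_series(traj: LandmarkTrajectory, Vd_cm_s: float,
                           omega_p_signed: float,
                           station: float = 0.75) -> np.ndarray:
    """Signed angle of attack α(t) in degrees, folded to (−90°, 90°].

    The local flow at the ``station`` span fraction has tangential
    magnitude ``station·S·ωp`` (opposing the precession motion) and
    vertical component Vd (upward, opposing descent).  α is the signed
    angle between the chord vector and the flow, measured about the
    span axis and folded by identifying the chord with its negation —
    a wing with no distinguished face.  The series jumps from 90° to
    −90° whenever the wing-surface normal aligns with the flow.
    """
    if Vd_cm_s == 0 and omega_p_signed == 0:
        raise ValueError("zero flow vector (Vd = omega_p = 0)")
    u = _span_units(traj)
    c = traj.chord_vectors()
    cnorm = np.linalg.norm(c, axis=1, keepdims=True)
    if np.any(cnorm < 1e-9):
        raise ValueError("zero-length chord")
    c = c / cnorm

    S = float(np.mean(np.linalg.norm(traj.span_vectors(), axis=1)))
    _, center, radius = _precession_phase(traj)
    pt = traj.point_on_span(station)
    rel = pt[:, :2] - center
    rnorm = np.linalg.norm(rel, axis=1, keepdims=True)
    if radius < 1e-9 or np.any(rnorm < 1e-12):
        # no precession: flow is purely vertical
        flow = np.tile([0.0, 0.0, abs(Vd_cm_s)], (traj.n_frames, 1))
    else:
        r_hat = np.hstack([rel / rnorm, np.zeros((traj.n_frames, 1))])
        t_hat = np.sign(omega_p_signed) * np.cross(
            np.broadcast_to(_Z, r_hat.shape), r_hat)
        flow = -station * S * abs(omega_p_signed) * t_hat
        flow[:, 2] += abs(Vd_cm_s)

    # project flow into the span-normal plane, signed angle flow→chord
    flow_perp = flow - np.einsum("ij,ij->i", flow, u)[:, None] * u
    fp = np.linalg.norm(flow_perp, axis=1)
    if np.any(fp < 1e-12):
        raise ValueError("flow parallel to span; angle of attack undefined")
    cos_a = np.einsum("ij,ij->i", flow_perp, c) / fp
    sin_a = np.einsum("ij,ij->i", np.cross(flow_perp, c), u) / fp
    raw = np.arctan2(sin_a, cos_a)
    folded = np.where(raw > np.pi / 2, raw - np.pi, raw)
    folded = np.where(folded <= -np.pi / 2, folded + np.pi, folded)
    return np.degrees(folded)


def rolls_per_precession(omega_r: float, omega_p: float) -> float:
    """Coupling ratio |ωr| / |ωp| (dimensionless)."""
    if omega_p == 0:
        raise ZeroDivisionError("precession rate is zero")
    return abs(omega_r) / abs(omega_p)


# ----------------------------------------------------------------------
def detect_transition_times(traj: LandmarkTrajectory, Vd_terminal_cm_s: float,
                            eps_v: float = 0.05) -> EventTimes:
    """Event times of a release transient in the tunnel frame.

    t_r is the first time the unwrapped roll phase accumulates 2π
    (linear interpolation between frames).  t_p is the start of the
    first sliding window, one precession period long, throughout which
    the COR-point vertical speed stays below ``eps_v·Vd_terminal`` —
    levitation without further descent.  Either event may be flagged
    not-reached when the record (or a free-fall-frame input, whose
    vertical speed never becomes small) ends first.
    """
    if Vd_terminal_cm_s <= 0:
        raise ValueError("Vd_terminal must be positive")
    t = traj.t

    # --- first full roll
    phase = _chord_phase(traj)
    acc = np.abs(phase - phase[0])
    idx = np.nonzero(acc >= 2 * np.pi)[0]
    if idx.size:
        i = int(idx[0])
        if i == 0:
            t_r, roll_reached = float(t[0]), True
        else:
            frac = (2 * np.pi - acc[i - 1]) / (acc[i] - acc[i - 1])
            t_r = float(t[i - 1] + frac * (t[i] - t[i - 1]))
            roll_reached = True
    else:
        t_r, roll_reached = float("nan"), False

    # --- stable precession (levitation)
    tail = slice(int(2 * traj.n_frames / 3), None)
    phase_tail = _precession_phase_window(traj, tail)
    if phase_tail is None or np.ptp(phase_tail) < _MIN_PHASE_SPAN:
        return EventTimes(t_r, float("nan"), roll_reached, False)
    omega_p_late, _ = _phase_slope(t[tail], phase_tail)
    if abs(omega_p_late) < _MIN_PHASE_SPAN:
        return EventTimes(t_r, float("nan"), roll_reached, False)
    period = 2 * math.pi / abs(omega_p_late)
    w = max(2, int(round(period * traj.frame_rate)))

    s = locate_center_of_rotation(traj)
    if math.isnan(s):
        s = 0.0
    z = traj.point_on_span(s)[:, 2]
    v_z = np.gradient(z, t)
    smooth = max(3, w // 10)
    v_z = uniform_filter1d(v_z, size=smooth, mode="nearest")
    ok = np.abs(v_z) < eps_v * Vd_terminal_cm_s
    if w > ok.size:
        return EventTimes(t_r, float("nan"), roll_reached, False)
    # rolling all-true test via cumulative sum
    cs = np.concatenate([[0], np.cumsum(ok)])
    runs = cs[w:] - cs[:-w]
    start = np.nonzero(runs == w)[0]
    if start.size == 0:
        return EventTimes(t_r, float("nan"), roll_reached, False)
    return EventTimes(t_r, float(t[int(start[0])]), roll_reached, True)


def _precession_phase_window(traj: LandmarkTrajectory, window: slice):
    xy = traj.wingtip[window, :2]
    if xy.shape[0] < 3:
        return None
    center = _fit_circle_center(xy)
    rel = xy - center
    if float(np.mean(np.linalg.norm(rel, axis=1))) < 1e-9:
        return None
    return np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))


# ----------------------------------------------------------------------
def analyze_trajectory(traj: LandmarkTrajectory,
                       alpha_station: float = 0.75) -> KinematicsEstimate:
    """Run every estimator on one trajectory and bundle the results."""
    omega_p_signed, omega_r_signed = estimate_angular_rates(traj)
    cor = locate_center_of_rotation(traj)
    vd = estimate_descent_velocity(
        traj, cor_fraction=None if math.isnan(cor) else cor)
    coning = estimate_coning_angle(traj)
    if omega_p_signed != 0.0:
        ratio = rolls_per_precession(omega_r_signed, omega_p_signed)
    else:
        ratio = float("nan")
    if vd != 0.0 or omega_p_signed != 0.0:
        alpha = angle_of_attack_series(traj, vd, omega_p_signed,
                                       station=alpha_station)
    else:
        alpha = np.full(traj.n_frames, np.nan)

    phase_p, _, radius = _precession_phase(traj)
    cycles = np.ptp(phase_p) / (2 * math.pi)
    _, resid_p = (_phase_slope(traj.t, phase_p)
                  if omega_p_signed != 0.0 else (0.0, float("nan")))
    return KinematicsEstimate(
        Vd_cm_s=vd,
        omega_p=abs(omega_p_signed),
        omega_r=abs(omega_r_signed),
        precession_sign=int(np.sign(omega_p_signed)) if omega_p_signed else 0,
        roll_sign=int(np.sign(omega_r_signed)) if omega_r_signed else 0,
        coning_angle_deg=coning.mean_deg,
        cor_fraction=cor,
        roll_per_precession=ratio,
        alpha_deg=alpha,
        diagnostics=dict(precession_cycles=float(cycles),
                         precession_radius_cm=float(radius),
                         precession_phase_rms=resid_p),
    )
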