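"""Landmark-trajectory container.

A rolling samara is tracked through four landmarks — the seed tip, the
wingtip and the two chordal edges at the station of maximum chord.  A
:class:`LandmarkTrajectory` holds the uniformly sampled 3-D positions of
those four points in a right-handed lab frame with the vertical axis
positive up; all coordinates are in cm and time in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LANDMARKS = ("seed_tip", "wingtip", "chord_left", "chord_right")

#: relative tolerance on time-step uniformity
_DT_RTOL = 1e-6


@dataclass
class LandmarkTrajectory:
    """Uniformly sampled 3-D tracks of the four samara landmarks.

    Attributes
    ----------
    frame_rate : float
        Sampling rate in Hz.
    t : (n,) ndarray
        Time in seconds, strictly increasing with constant step
        ``1/frame_rate``.
    seed_tip, wingtip, chord_left, chord_right : (n, 3) ndarray
        Positions in cm; columns are (x, y, z) with z positive up.
    frame : str
        ``"free_fall"`` (lab frame, samara descends) or ``"tunnel"``
        (terminal vertical wind subtracted, stable precession levitates).
    """

    frame_rate: float
    t: np.ndarray
    seed_tip: np.ndarray
    wingtip: np.ndarray
    chord_left: np.ndarray
    chord_right: np.ndarray
    frame: str = "free_fall"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in LANDMARKS:
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        n = self.t.size
        if n < 2:
            raise ValueError("trajectory needs at least 2 samples")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        step = 1.0 / self.frame_rate
        if not np.allclose(dt, step, rtol=_DT_RTOL, atol=_DT_RTOL * step):
            raise ValueError("time step is not uniform at 1/frame_rate")
        for name in LANDMARKS:
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise ValueError(f"{name} must have shape ({n}, 3)")
            if not np.all(np.isfinite(arr)):
                bad = int(np.argwhere(~np.isfinite(arr))[0, 0])
                raise ValueError(f"non-finite coordinate in {name} at row {bad}")
        if self.frame not in ("free_fall", "tunnel"):
            raise ValueError(f"unknown frame {self.frame!r}")

    # ------------------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def span_vectors(self) -> np.ndarray:
        """Seed-tip → wingtip vector per frame, cm."""
        return self.wingtip - self.seed_tip

    def chord_vectors(self) -> np.ndarray:
        """Chord-left → chord-right vector per frame, cm."""
        return self.chord_right - self.chord_left

    def point_on_span(self, s: float) -> np.ndarray:
        """Position of ``seed_tip + s·(wingtip − seed_tip)`` per frame."""
        return self.seed_tip + s * self.span_vectors()

    def to_tunnel(self, vd_cm_s: float) -> "LandmarkTrajectory":
        """Re-express a free-fall track in the tunnel frame.

        Adds the steady descent ``vd_cm_s·t`` back to every vertical
        coordinate so that steady precession levitates.
        """
        if self.frame == "tunnel":
            return self
        shift = np.zeros((self.n_frames, 3))
        shift[:, 2] = vd_cm_s * (self.t - self.t[0])
        kw = {name: getattr(self, name) + shift for name in LANDMARKS}
        return LandmarkTrajectory(frame_rate=self.frame_rate, t=self.t.copy(),
                                  frame="tunnel", meta=dict(self.meta), **kw)
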