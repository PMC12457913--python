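"""Delimited-table and configuration I/O.

Boundary conventions: all tables carry field units in their column
names (``_cm``, ``_mm``, ``_mg``, ``_cm2``, ``_cm_s``, ``_rad_s``,
``_s``, ``_deg`` suffixes); coordinates are right-handed with z up, so
descent is negative z.  Landmark tracks are 13-column CSV (time plus
four landmarks × x/y/z); morphology tables follow the published column
semantics (species, b_mm, m_mg, A_cm2 mandatory, span/chord optional
and derivable from area via the shape-factor convention).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .morphology import (ASPECT_RATIO_MEAN, SamaraMorphology, derive_span_chord)
from .synthetic import KinematicGroundTruth, SimulationConfig, TransientSpec
from .trajectory import LANDMARKS, LandmarkTrajectory

logger = logging.getLogger("samarakin")

TRACK_COLUMNS = ["time_s"] + [f"{lm}_{ax}_cm" for lm in LANDMARKS
                              for ax in ("x", "y", "z")]

#: tolerance on time-step uniformity, seconds
_DT_ATOL = 1e-6


def write_track_table(traj: LandmarkTrajectory, path) -> None:
    """Write a trajectory as 13-column CSV (one comment + one header line)."""
    data = {"time_s": traj.t}
    for lm in LANDMARKS:
        arr = getattr(traj, lm)
        for j, ax in enumerate(("x", "y", "z")):
            data[f"{lm}_{ax}_cm"] = arr[:, j]
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# samarakin landmark track; frame={traj.frame}; "
                 "right-handed lab coordinates, z up (descent negative z)\n")
        pd.DataFrame(data).to_csv(fh, index=False)


def read_track_table(path, frame: str | None = None) -> LandmarkTrajectory:
    """Read and validate a 13-column landmark-track CSV.

    The frame rate is inferred from the time spacing and checked for
    uniformity to within 1 µs; NaN coordinates and non-monotone time
    are rejected with the offending row index.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if df.isna().any().any():
        row = int(df.index[df.isna().any(axis=1)][0])
        raise ValueError(f"NaN coordinate at row {row}")
    t = df["time_s"].to_numpy(float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.nonzero(dt <= 0)[0][0]) + 1
        raise ValueError(f"non-monotone time at row {row}")
    if np.ptp(dt) > _DT_ATOL:
        raise ValueError("non-uniform time step (tolerance 1e-6 s)")
    frame_rate = 1.0 / float(np.median(dt))
    if frame is None:
        frame = "free_fall"
        # recover the frame tag from the comment line when present
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#") and "frame=tunnel" in first:
            frame = "tunnel"
    kw = {lm: df[[f"{lm}_{ax}_cm" for ax in ("x", "y", "z")]].to_numpy(float)
          for lm in LANDMARKS}
    return LandmarkTrajectory(frame_rate=frame_rate, t=t, frame=frame, **kw)


# ----------------------------------------------------------------------
MORPH_MANDATORY = ("species", "b_mm", "m_mg", "A_cm2")


def write_morphology_table(specimens: list[SamaraMorphology], path) -> None:
    from .morphology import morphology_frame
    morphology_frame(specimens).to_csv(path, index=False)


def read_morphology_table(path) -> list[SamaraMorphology]:
    """Read a morphology CSV into validated records.

    ``species, b_mm, m_mg, A_cm2`` are mandatory; absent span/chord are
    derived from area via the shape-factor convention (AR = 4.5) with
    a logged warning.  Non-positive dimensions are rejected with their
    row index.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in MORPH_MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")
    derive = "S_cm" not in df.columns or "c_cm" not in df.columns
    if derive:
        logger.warning("span/chord columns absent; deriving from area via "
                       "the shape-factor convention (AR=%.1f)", ASPECT_RATIO_MEAN)
    out = []
    for i, row in df.iterrows():
        for col in ("b_mm", "m_mg", "A_cm2"):
            if not row[col] > 0:
                raise ValueError(f"non-positive {col} at row {i}")
        if derive:
            S, c = derive_span_chord(float(row["A_cm2"]))
        else:
            S, c = float(row["S_cm"]), float(row["c_cm"])
        out.append(SamaraMorphology(species=str(row["species"]),
                                    b_mm=float(row["b_mm"]),
                                    m_mg=float(row["m_mg"]),
                                    A_cm2=float(row["A_cm2"]),
                                    S_cm=S, c_cm=c))
    return out


# ----------------------------------------------------------------------
def load_config(path) -> tuple[KinematicGroundTruth, SimulationConfig]:
    """Load a YAML simulation config (sections ``truth``, ``simulation``
    and optional ``transient``); absent keys fall back to the
    dataclass defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    truth = KinematicGroundTruth(**(raw.get("truth") or {}))
    sim_kw = dict(raw.get("simulation") or {})
    tr = raw.get("transient")
    if tr is not None:
        if "orientation" in tr and len(tr) == 1:
            sim_kw["transient"] = TransientSpec.from_orientation(tr["orientation"])
        else:
            sim_kw["transient"] = TransientSpec(**tr)
    return truth, SimulationConfig(**sim_kw)


def dump_config(truth: KinematicGroundTruth, config: SimulationConfig,
                path) -> None:
    raw = {"truth": dataclasses.asdict(truth),
           "simulation": {k: v for k, v in dataclasses.asdict(config).items()
                          if k != "transient"}}
    if config.transient is not None:
        raw["transient"] = dataclasses.asdict(config.transient)
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


# ----------------------------------------------------------------------
@dataclasses.dataclass
class RunManifest:
    """Provenance record written alongside every CLI output.

    Re-running the same subcommand with the recorded config and seed
    reproduces the outputs bit-identically.
    """

    subcommand: str
    config: dict
    rng_seed: int | None
    inputs: list[str]
    outputs: list[str]
    version: str
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.datetime.now(
                datetime.timezone.utc).isoformat()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def kinematics_record(est) -> dict:
    """Flatten a KinematicsEstimate to one results row (field units)."""
    return dict(
        Vd_cm_s=est.Vd_cm_s,
        omega_p_rad_s=est.omega_p,
        omega_r_rad_s=est.omega_r,
        precession_sign=est.precession_sign,
        roll_sign=est.roll_sign,
        coning_angle_deg=est.coning_angle_deg,
        cor_fraction=est.cor_fraction,
        roll_per_precession=est.roll_per_precession,
        alpha_mean_abs_deg=float(np.nanmean(np.abs(est.alpha_deg))),
        precession_cycles=est.diagnostics.get("precession_cycles"),
    )
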