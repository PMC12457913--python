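"""End-to-end simulated ensembles: draw → simulate → analyze.

An ensemble emulates the published study design: specimens drawn per
species from the published morphology and kinematics statistics,
several tracked flights per specimen, and the kinematic estimators run
on every simulated track.  Everything downstream (coupling-ratio and
descent statistics, thickness-scaling fits on recovered quantities)
operates on the resulting tidy table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kinematics import analyze_trajectory
from .morphology import SPECIES_STATS, sample_morphology_ensemble
from .synthetic import SimulationConfig, sample_ground_truth, simulate_descent


def run_ensemble(
    rng_seed: int,
    n_per_species: int = 10,
    trials_per_specimen: int = 3,
    duration_s: float = 0.5,
    frame_rate: float = 1000.0,
    noise_sd_cm: float = 0.05,
    species_stats: dict | None = None,
) -> pd.DataFrame:
    """Simulate and analyze a full ensemble of tracked flights.

    Each specimen gets morphology and per-specimen kinematics drawn
    from the per-species truncated normals; each trial re-draws the
    roll direction and phases and adds independent tracking noise.
    Returns one row per trial with the true (generator) and estimated
    quantities side by side.
    """
    stats = species_stats or SPECIES_STATS
    ss = np.random.SeedSequence(rng_seed)
    draw_seed, *spec_seeds = ss.spawn(1 + len(stats) * n_per_species)
    specimens = sample_morphology_ensemble(
        n_per_species, rng_seed=int(draw_seed.generate_state(1)[0] % 2**31),
        species_stats={sp: {k: stats[sp][k] for k in ("b_mm", "m_mg", "A_cm2")}
                       for sp in stats})
    rows = []
    for spec_id, morph in enumerate(specimens):
        truth_ss, *trial_ss = spec_seeds[spec_id].spawn(1 + trials_per_specimen)
        kin_rng = np.random.default_rng(truth_ss)
        # per-specimen rates; per-trial roll direction, phases and noise
        base = sample_ground_truth(morph.species, kin_rng, species_stats=stats)
        for trial in range(trials_per_specimen):
            trial_rng = np.random.default_rng(trial_ss[trial])
            truth = sample_ground_truth(
                morph.species, trial_rng, species_stats=stats,
                Vd_cm_s=base.Vd_cm_s, omega_p=base.omega_p,
                omega_r=base.omega_r)
            config = SimulationConfig(
                duration_s=duration_s, frame_rate=frame_rate,
                noise_sd_cm=noise_sd_cm,
                rng_seed=int(trial_ss[trial].generate_state(1)[0] % 2**31))
            est = analyze_trajectory(simulate_descent(morph, truth, config))
            rows.append(dict(
                species=morph.species, specimen=spec_id, trial=trial,
                b_mm=morph.b_mm, m_mg=morph.m_mg, A_cm2=morph.A_cm2,
                S_cm=morph.S_cm, c_cm=morph.c_cm,
                true_Vd_cm_s=truth.Vd_cm_s, true_omega_r=truth.omega_r,
                true_omega_p=truth.omega_p,
                true_roll_direction=truth.roll_direction,
                Vd_cm_s=est.Vd_cm_s, omega_r_rad_s=est.omega_r,
                omega_p_rad_s=est.omega_p,
                precession_sign=est.precession_sign, roll_sign=est.roll_sign,
                roll_per_precession=est.roll_per_precession,
                cor_fraction=est.cor_fraction,
                coning_angle_deg=est.coning_angle_deg,
            ))
    return pd.DataFrame(rows)


def ensemble_summary(df: pd.DataFrame) -> dict:
    """Grand means over all trials of the headline ensemble statistics."""
    return dict(
        n_trials=int(len(df)),
        mean_roll_per_precession=float(df["roll_per_precession"].mean()),
        sd_roll_per_precession=float(df["roll_per_precession"].std(ddof=1)),
        mean_Vd_cm_s=float(df["Vd_cm_s"].mean()),
        sd_Vd_cm_s=float(df["Vd_cm_s"].std(ddof=1)),
        mean_omega_r_rad_s=float(df["omega_r_rad_s"].mean()),
        mean_omega_p_rad_s=float(df["omega_p_rad_s"].mean()),
    )
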