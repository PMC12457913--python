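"""Samara morphology: per-specimen dimensions and ensemble sampling.

Three species of rolling samaras are covered by default — *Fraxinus
americana*, *Fraxinus excelsior* and *Liriodendron tulipifera*.  Their
published summary statistics (wing thickness b, mass m, planform area A,
and the descent kinematics measured alongside) serve as the default
generating distributions for synthetic ensembles.

Span is not part of the published morphology table, so it is derived
from planform area and aspect ratio through the shape-factor convention
``A = f·S·c`` with ``f = 0.75`` (a tapered planform covers about three
quarters of its bounding S×c rectangle); with the mean aspect ratio
AR = S/c = 4.5 this reproduces the reported *L. tulipifera* span of
3.6 cm from A = 2.141 cm².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: planform shape factor f in A = f·S·c
SHAPE_FACTOR = 0.75

#: mean and SD of span/chord aspect ratio across species
ASPECT_RATIO_MEAN = 4.5
ASPECT_RATIO_SD = 0.7

#: truncation of generating normals, in SDs
TRUNC_SD = 3.0


@dataclass
class SamaraMorphology:
    """Physical dimensions of one samara specimen (field units).

    b: wing thickness at max chord, mm; m: mass, mg; A: planform
    area, cm²; S: span, cm; c: max chord, cm.
    """

    species: str
    b_mm: float
    m_mg: float
    A_cm2: float
    S_cm: float
    c_cm: float

    def __post_init__(self) -> None:
        for name in ("b_mm", "m_mg", "A_cm2", "S_cm", "c_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        ar = self.S_cm / self.c_cm
        if not (1.0 < ar < 20.0):
            raise ValueError(f"aspect ratio S/c = {ar:.2f} outside (1, 20)")

    @property
    def aspect_ratio(self) -> float:
        return self.S_cm / self.c_cm


def derive_span_chord(A_cm2: float, aspect_ratio: float = ASPECT_RATIO_MEAN,
                      shape_factor: float = SHAPE_FACTOR) -> tuple[float, float]:
    """Span and chord (cm) from area via A = f·S·c with c = S/AR."""
    if A_cm2 <= 0 or aspect_ratio <= 0 or shape_factor <= 0:
        raise ValueError("area, aspect ratio and shape factor must be positive")
    S = float(np.sqrt(A_cm2 * aspect_ratio / shape_factor))
    return S, S / aspect_ratio


# ----------------------------------------------------------------------
# Published per-species summary statistics (mean, SD): thickness b (mm),
# mass m (mg), planform area A (cm²), descent speed Vd (cm/s), roll rate
# ωr (rad/s), precession rate ωp (rad/s).  N = 10 specimens per species.
SPECIES_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "F_americana": {
        "b_mm": (0.50, 0.02), "m_mg": (39.0, 3.0), "A_cm2": (1.867, 0.142),
        "Vd_cm_s": (131.0, 9.0), "omega_r": (442.6, 59.7), "omega_p": (79.6, 6.8),
    },
    "F_excelsior": {
        "b_mm": (0.41, 0.02), "m_mg": (60.0, 10.0), "A_cm2": (1.784, 0.115),
        "Vd_cm_s": (191.0, 21.0), "omega_r": (617.6, 76.6), "omega_p": (119.3, 13.4),
    },
    "L_tulipifera": {
        "b_mm": (0.46, 0.02), "m_mg": (47.0, 5.0), "A_cm2": (2.141, 0.183),
        "Vd_cm_s": (148.0, 15.0), "omega_r": (503.5, 66.4), "omega_p": (93.5, 16.6),
    },
}

SPECIES = tuple(SPECIES_STATS)


def _truncated_normal_mean(mean: float, sd: float, nsd: float = TRUNC_SD) -> float:
    """Mean of a normal truncated symmetrically at ±nsd (equals `mean`)."""
    if sd == 0:
        return mean
    return float(stats.truncnorm.mean(-nsd, nsd, loc=mean, scale=sd))


def draw_truncated(rng: np.random.Generator, mean: float, sd: float,
                   size: int | None = None, nsd: float = TRUNC_SD):
    """Draw from N(mean, sd²) truncated at ±nsd·sd, guaranteed positive.

    Truncation at ±3 SD keeps every published trait positive (all means
    exceed 3 SD).  A defensive re-draw loop guards pathological inputs.
    """
    if sd < 0:
        raise ValueError("SD must be non-negative")
    if sd == 0:
        out = np.full(size if size is not None else 1, mean, dtype=float)
    else:
        out = stats.truncnorm.rvs(-nsd, nsd, loc=mean, scale=sd,
                                  size=size if size is not None else 1,
                                  random_state=rng)
        out = np.atleast_1d(np.asarray(out, dtype=float))
        for _ in range(100):
            bad = out <= 0
            if not bad.any():
                break
            out[bad] = stats.truncnorm.rvs(-nsd, nsd, loc=mean, scale=sd,
                                           size=int(bad.sum()), random_state=rng)
        else:
            raise ValueError("could not draw positive values after 100 retries")
    if np.any(out <= 0):
        raise ValueError("non-positive draw after truncation")
    return out if size is not None else float(out[0])


def sample_morphology_ensemble(
    n_per_species: int,
    rng_seed: int,
    species_stats: dict | None = None,
    aspect_ratio: tuple[float, float] = (ASPECT_RATIO_MEAN, ASPECT_RATIO_SD),
) -> list[SamaraMorphology]:
    """Draw a reproducible morphology ensemble from per-species normals.

    b, m, A come from per-species normals truncated at ±3 SD; span
    derives from the sampled area and a sampled aspect ratio via the
    shape-factor convention, and chord is span / aspect ratio.

    Parameters
    ----------
    n_per_species : int
        Specimens to draw per species (same for every species).
    rng_seed : int
        Seed for the underlying generator; fixed seed → identical draws.
    species_stats : dict, optional
        ``{species: {trait: (mean, sd)}}`` table; defaults to the
        published statistics in :data:`SPECIES_STATS`.
    """
    if n_per_species < 1:
        raise ValueError("n_per_species must be ≥ 1")
    table = species_stats if species_stats is not None else SPECIES_STATS
    for sp, traits in table.items():
        for trait, (_, sd) in traits.items():
            if sd < 0:
                raise ValueError(f"negative SD for {sp}/{trait}")
    rng = np.random.default_rng(rng_seed)
    out: list[SamaraMorphology] = []
    ar_mean, ar_sd = aspect_ratio
    for sp, traits in table.items():
        for trait in ("b_mm", "m_mg", "A_cm2"):
            if trait not in traits:
                raise KeyError(f"species {sp!r} lacks trait {trait!r}")
        b = draw_truncated(rng, *traits["b_mm"], size=n_per_species)
        m = draw_truncated(rng, *traits["m_mg"], size=n_per_species)
        A = draw_truncated(rng, *traits["A_cm2"], size=n_per_species)
        ar = draw_truncated(rng, ar_mean, ar_sd, size=n_per_species)
        for i in range(n_per_species):
            S, c = derive_span_chord(A[i], ar[i])
            out.append(SamaraMorphology(species=sp, b_mm=float(b[i]),
                                        m_mg=float(m[i]), A_cm2=float(A[i]),
                                        S_cm=S, c_cm=c))
    return out


def morphology_frame(specimens: list[SamaraMorphology]) -> pd.DataFrame:
    """Tidy table of an ensemble, one row per specimen, field units."""
    return pd.DataFrame(
        {
            "species": [s.species for s in specimens],
            "b_mm": [s.b_mm for s in specimens],
            "m_mg": [s.m_mg for s in specimens],
            "A_cm2": [s.A_cm2 for s in specimens],
            "S_cm": [s.S_cm for s in specimens],
            "c_cm": [s.c_cm for s in specimens],
        }
    )
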