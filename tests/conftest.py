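import pytest

from samarakin import (
    SamaraMorphology,
    SimulationConfig,
    derive_span_chord,
    ground_truth_from_means,
    simulate_descent,
)
from samarakin.morphology import SPECIES_STATS


def morphology_from_means(species: str) -> SamaraMorphology:
    st = SPECIES_STATS[species]
    S, c = derive_span_chord(st["A_cm2"][0])
    return SamaraMorphology(species=species, b_mm=st["b_mm"][0],
                            m_mg=st["m_mg"][0], A_cm2=st["A_cm2"][0],
                            S_cm=S, c_cm=c)


@pytest.fixture(scope="session")
def tulip_morph() -> SamaraMorphology:
    return morphology_from_means("L_tulipifera")


@pytest.fixture(scope="session")
def americana_morph() -> SamaraMorphology:
    return morphology_from_means("F_americana")


@pytest.fixture(scope="session")
def americana_track(americana_morph):
    """1 s noiseless track at the F. americana mean kinematics."""
    truth = ground_truth_from_means("F_americana")
    config = SimulationConfig(duration_s=1.0, frame_rate=1000.0)
    return simulate_descent(americana_morph, truth, config), truth


@pytest.fixture(scope="session")
def tulip_track(tulip_morph):
    """0.5 s noiseless track at the L. tulipifera mean kinematics."""
    truth = ground_truth_from_means("L_tulipifera")
    config = SimulationConfig(duration_s=0.5, frame_rate=1000.0)
    return simulate_descent(tulip_morph, truth, config), truth
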