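import numpy as np
import pytest

from ciukit import analysis, calibration as cal, synthetic as syn


@pytest.fixture
def instrument():
    return syn.InstrumentParams()


@pytest.fixture
def apo_species():
    return syn.SpeciesParams(
        name="apo",
        ccs_compact=33.8,
        ccs_extended=37.3,
        v50_unfold=40.3,
        slope_unfold=0.8,
    )


@pytest.fixture
def ternary_species():
    return syn.SpeciesParams(
        name="ternary",
        ccs_compact=35.6,
        ccs_extended=39.1,
        v50_unfold=43.2,
        slope_unfold=0.8,
        ejection=syn.EjectionParams(v50_eject=42.0, slope_eject=1.0, coupling=2.5),
    )


@pytest.fixture
def calibration_model(instrument):
    return instrument.calibration_model()


def species_curve(sp, inst, seed=0, replicate=0, v50_offset=0.0):
    """Unfolding curve for one species/replicate via the full ATD pipeline."""
    model = inst.calibration_model()
    dists = []
    for k, v in enumerate(inst.voltage_grid):
        atd = syn.simulate_atd(sp, inst, float(v), seed + 7919 * k, v50_offset=v50_offset)
        dists.append(
            analysis.atd_to_ccs_distribution(atd, model, sp.mz, sp.charge, sp.mass)
        )
    return analysis.curve_from_distributions(dists, sp.name, replicate)


@pytest.fixture
def noise_free_apo_curve(apo_species, instrument):
    return species_curve(apo_species, instrument)
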