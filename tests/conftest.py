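import numpy as np
import pytest

from thermoplate import datasets, io, simulate
from thermoplate.pipeline import CorrectedSignal


@pytest.fixture(scope="session")
def heat_table():
    """The packaged 32 per-well total-heat values (uJ/cell)."""
    return datasets.load_heat_per_cell()


@pytest.fixture(scope="session")
def full_layout():
    return datasets.reference_layout()


@pytest.fixture
def one_column_layout():
    """2 references + 4 fed sample wells in a single column."""
    wells = [
        io.WellAssignment("A1", "reference"),
        io.WellAssignment("F1", "reference"),
    ] + [
        io.WellAssignment(f"{r}1", "sample", group="Cells + Glucose", cell_count=150_000)
        for r in "BCDE"
    ]
    return io.PlateLayout(tuple(wells), n_rows=6, n_cols=1)


def make_signal(times, powers, stage="baseline_corrected", well_id="B1", rate=1.0):
    return CorrectedSignal(
        well_id=well_id,
        times=np.asarray(times, dtype=float),
        powers=np.asarray(powers, dtype=float),
        stage=stage,
        sampling_rate_hz=rate,
    )


@pytest.fixture
def make_corrected_signal():
    return make_signal


@pytest.fixture(scope="session")
def fast_profiles():
    """Short-timescale kinetics for quick small simulations (2 h runs)."""
    return {
        "fed": simulate.KineticProfile(
            spike_amplitude_uW=10.0,
            spike_decay_tau_s=60.0,
            lag_s=2400.0,
            rise_tau_s=600.0,
            peak_pW_per_cell=48.0,
        ),
        "starved": simulate.KineticProfile(
            spike_amplitude_uW=10.0,
            spike_decay_tau_s=60.0,
            lag_s=1800.0,
            rise_tau_s=300.0,
            peak_pW_per_cell=48.0,
            exhaustion_s=4800.0,
            exhaustion_tau_s=600.0,
            hold=False,
        ),
    }


@pytest.fixture
def small_plate(fast_profiles):
    """A 2-column, 2 h, 1 Hz simulated plate with ground truth."""
    wells = []
    for col, group in ((1, "fed"), (2, "starved")):
        wells.append(io.WellAssignment(f"A{col}", "reference"))
        wells.append(io.WellAssignment(f"F{col}", "reference"))
        for row in "BCDE":
            wells.append(
                io.WellAssignment(f"{row}{col}", "sample", group=group, cell_count=150_000)
            )
    layout = io.PlateLayout(tuple(wells), n_rows=6, n_cols=2)
    config = simulate.SimulationConfig(
        layout=layout,
        profiles=fast_profiles,
        drift_per_column_uW_per_h=0.05,
        noise_sd_uW=0.05,
        duration_s=7200.0,
        sampling_rate_hz=1.0,
        seed=7,
        # references share the samples' loading-spike shape, as on a real
        # cartridge, so reference correction cancels it
        reference_profile=simulate.KineticProfile(
            spike_amplitude_uW=10.0, spike_decay_tau_s=60.0, peak_pW_per_cell=0.0
        ),
    )
    return simulate.simulate_plate(config)
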