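"""Synthetic 48-well cartridge datasets with known ground truth.

The simulator stands in for the microcalorimeter so the processing
pipeline and group statistics can be exercised offline.  Every well
(samples and references alike) receives:

* a loading-friction *spike* — an exponentially decaying transient from
  inserting the cartridge, identical across wells;
* a *column drift* — a slow linear instrumental trend shared by all
  wells of a column;
* additive i.i.d. Gaussian *noise*.

Sample wells additionally carry a phenomenological metabolic power
curve: zero during a lag phase (cells acclimating, typically 12-15 h),
then a saturating exponential rise toward ``peak_pW_per_cell`` times the
cell count, optionally followed by an exponential decay once the carbon
source is exhausted.  Cells relying on internal carbon stores peak near
48 pW/cell and exhaust around 32 h; externally fed groups plateau near
the 38 h mark and hold.  The closed-form time integral of this curve
(:func:`expected_total_heat`) is the ground truth that pipeline-recovery
tests compare against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    PlateLayout,
    Thermogram,
    ThermogramSet,
    well_sort_key,
    write_layout,
    write_thermograms,
)

__all__ = [
    "KineticProfile",
    "SimulationConfig",
    "WellTruth",
    "GroundTruth",
    "metabolic_power",
    "expected_total_heat",
    "simulate_plate",
    "default_profiles",
    "profiles_for_per_cell_heat",
    "write_simulation",
]

HOUR = 3600.0


@dataclass(frozen=True)
class KineticProfile:
    """Parametric per-cell power curve for one experimental group.

    ``hold=True`` means the plateau is held to the end of the run
    (``exhaustion_s`` must then be None); with ``hold=False`` the power
    decays exponentially (time constant ``exhaustion_tau_s``) after the
    fuel is exhausted at ``exhaustion_s``.
    """

    spike_amplitude_uW: float = 50.0
    spike_decay_tau_s: float = 600.0
    lag_s: float = 13.0 * HOUR  # middle of the observed 12-15 h onset band
    rise_tau_s: float = 4.0 * HOUR
    peak_pW_per_cell: float = 48.0
    exhaustion_s: float | None = None
    exhaustion_tau_s: float = 2.0 * HOUR
    hold: bool = True

    def __post_init__(self) -> None:
        for name in ("spike_decay_tau_s", "rise_tau_s", "exhaustion_tau_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lag_s < 0 or self.spike_amplitude_uW < 0:
            raise ValueError("lag_s and spike_amplitude_uW must be >= 0")
        if not 0 <= self.peak_pW_per_cell <= 100:
            raise ValueError("peak_pW_per_cell must lie in [0, 100]")
        if self.hold and self.exhaustion_s is not None:
            raise ValueError("hold=True is incompatible with a finite exhaustion_s")
        if not self.hold and self.exhaustion_s is None:
            raise ValueError("hold=False requires exhaustion_s")


def default_profiles() -> dict[str, KineticProfile]:
    """Kinetics emulating the four media groups of the 48 h experiment.

    Cells relying on stored carbon switch on after ~12 h, peak at
    ~48 pW/cell and exhaust near 32 h; glucose- and glutamine-fed cells
    start later, plateau near 38 h and hold.  Fed-group peak powers are
    set so the 48 h per-cell integrals land near the observed ~2.8 and
    ~1.9 uJ/cell group means, inside the 4-50 pW/cell envelope.
    """
    return {
        "No Cells": KineticProfile(peak_pW_per_cell=0.0),
        "Cells Only": KineticProfile(
            lag_s=12.0 * HOUR,
            rise_tau_s=2.0 * HOUR,
            peak_pW_per_cell=48.0,
            exhaustion_s=32.0 * HOUR,
            exhaustion_tau_s=4.0 * HOUR,
            hold=False,
        ),
        "Cells + Glucose": KineticProfile(
            lag_s=14.0 * HOUR, rise_tau_s=6.0 * HOUR, peak_pW_per_cell=28.0
        ),
        "Cells + Glutamine": KineticProfile(
            lag_s=14.0 * HOUR, rise_tau_s=6.0 * HOUR, peak_pW_per_cell=19.0
        ),
    }


def metabolic_power(profile: KineticProfile, t, cell_count: int):
    """Metabolic power (uW) of ``cell_count`` cells at time(s) ``t`` (s).

    Zero before ``lag_s``; then ``A * (1 - exp(-(t - lag)/rise_tau))``
    with asymptote ``A = peak_pW_per_cell * 1e-6 * cell_count`` uW;
    after ``exhaustion_s`` (if set) the power decays exponentially from
    its value at exhaustion.
    """
    t = np.asarray(t, dtype=float)
    amplitude = profile.peak_pW_per_cell * 1e-6 * cell_count  # pW -> uW
    dt = np.maximum(t - profile.lag_s, 0.0)
    power = amplitude * -np.expm1(-dt / profile.rise_tau_s)
    if profile.exhaustion_s is not None:
        e = profile.exhaustion_s
        p_exhaust = amplitude * -np.expm1(-max(e - profile.lag_s, 0.0) / profile.rise_tau_s)
        after = t > e
        power = np.where(
            after, p_exhaust * np.exp(-(t - e) / profile.exhaustion_tau_s), power
        )
    return power if power.ndim else float(power)


def expected_total_heat(
    profile: KineticProfile, cell_count: int, duration_s: float
) -> float:
    """Closed-form integral of :func:`metabolic_power` over [0, duration] (uJ)."""
    amplitude = profile.peak_pW_per_cell * 1e-6 * cell_count
    if amplitude == 0 or duration_s <= profile.lag_s:
        return 0.0
    tau = profile.rise_tau_s
    end_rise = duration_s if profile.exhaustion_s is None else min(
        duration_s, profile.exhaustion_s
    )
    total = 0.0
    if end_rise > profile.lag_s:
        u = end_rise - profile.lag_s
        total += amplitude * (u + tau * np.expm1(-u / tau))
    if profile.exhaustion_s is not None and duration_s > profile.exhaustion_s:
        p_exhaust = amplitude * -np.expm1(
            -max(profile.exhaustion_s - profile.lag_s, 0.0) / tau
        )
        taud = profile.exhaustion_tau_s
        total += p_exhaust * taud * -np.expm1(
            -(duration_s - profile.exhaustion_s) / taud
        )
    return float(total)


def profiles_for_per_cell_heat(
    targets_uJ_per_cell: Mapping[str, float],
    base: Mapping[str, KineticProfile] | None = None,
    cell_count: int = 150_000,
    duration_s: float = 48 * HOUR,
) -> dict[str, KineticProfile]:
    """Rescale peak powers so per-cell 48 h integrals hit given targets.

    The integral is linear in ``peak_pW_per_cell``, so matching a target
    per-cell total heat is a single multiplicative rescaling of each
    group's peak.  Groups absent from ``targets_uJ_per_cell`` keep their
    base profile.
    """
    base = dict(base or default_profiles())
    out: dict[str, KineticProfile] = {}
    for group, profile in base.items():
        if group not in targets_uJ_per_cell or profile.peak_pW_per_cell == 0:
            out[group] = profile
            continue
        current = expected_total_heat(profile, cell_count, duration_s) / cell_count
        scale = targets_uJ_per_cell[group] / current
        out[group] = KineticProfile(
            spike_amplitude_uW=profile.spike_amplitude_uW,
            spike_decay_tau_s=profile.spike_decay_tau_s,
            lag_s=profile.lag_s,
            rise_tau_s=profile.rise_tau_s,
            peak_pW_per_cell=profile.peak_pW_per_cell * scale,
            exhaustion_s=profile.exhaustion_s,
            exhaustion_tau_s=profile.exhaustion_tau_s,
            hold=profile.hold,
        )
    return out


@dataclass(frozen=True)
class WellTruth:
    well_id: str
    group: str | None
    cell_count: int
    true_total_uJ: float
    true_per_cell_uJ: float | None


@dataclass
class GroundTruth:
    """Programmed metabolic heat per well, from the analytic integral."""

    records: dict[str, WellTruth]
    profiles: dict[str, KineticProfile]

    def __getitem__(self, well_id: str) -> WellTruth:
        return self.records[well_id]

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.records.values(), key=lambda r: well_sort_key(r.well_id))
        return pd.DataFrame(
            {
                "well_id": [r.well_id for r in rows],
                "true_total_uJ": [r.true_total_uJ for r in rows],
                "true_per_cell_uJ": [r.true_per_cell_uJ for r in rows],
            }
        )


@dataclass
class SimulationConfig:
    """Full description of one simulated cartridge run.

    ``drift_per_column_uW_per_h`` is either a single slope applied to
    every column or a mapping from 1-based column number to slope; the
    drift is shared by all wells of a column, mimicking a column-wise
    instrumental trend.  All randomness derives from ``seed`` with a
    deterministic per-well substream, so equal seeds give identical
    plates.
    """

    layout: PlateLayout
    profiles: Mapping[str, KineticProfile] = field(default_factory=default_profiles)
    drift_per_column_uW_per_h: float | Mapping[int, float] = 0.05
    noise_sd_uW: float = 0.2
    duration_s: float = 48 * HOUR
    sampling_rate_hz: float = 1.0
    seed: int = 0
    reference_profile: KineticProfile = field(
        default_factory=lambda: KineticProfile(peak_pW_per_cell=0.0)
    )

    def __post_init__(self) -> None:
        if self.noise_sd_uW < 0:
            raise ValueError("noise_sd_uW must be >= 0")
        if self.duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("duration_s and sampling_rate_hz must be positive")
        missing = sorted(
            {w.group for w in self.layout.sample_wells if w.group not in self.profiles}
        )
        if missing:
            raise ValueError(f"no kinetic profile for groups: {missing}")

    def drift_for_column(self, col: int) -> float:
        """Drift slope (uW/h) of a 0-based column index."""
        d = self.drift_per_column_uW_per_h
        if isinstance(d, Mapping):
            return float(d.get(col + 1, 0.0))
        return float(d)


def simulate_plate(config: SimulationConfig) -> tuple[ThermogramSet, GroundTruth]:
    """Simulate a full cartridge run and its analytic ground truth."""
    n = int(round(config.duration_s * config.sampling_rate_hz))
    times = np.arange(n, dtype=float) / config.sampling_rate_hz

    traces: dict[str, Thermogram] = {}
    records: dict[str, WellTruth] = {}
    for well in config.layout.wells:
        profile = (
            config.profiles[well.group]
            if well.role == "sample"
            else config.reference_profile
        )
        power = profile.spike_amplitude_uW * np.exp(-times / profile.spike_decay_tau_s)
        power = power + config.drift_for_column(well.column) * times / HOUR
        if config.noise_sd_uW > 0:
            rng = np.random.default_rng([config.seed, well.row, well.column])
            power = power + rng.normal(0.0, config.noise_sd_uW, size=n)
        if well.role == "sample":
            power = power + metabolic_power(profile, times, well.cell_count)
            total = expected_total_heat(profile, well.cell_count, config.duration_s)
            records[well.well_id] = WellTruth(
                well_id=well.well_id,
                group=well.group,
                cell_count=well.cell_count,
                true_total_uJ=total,
                true_per_cell_uJ=(
                    total / well.cell_count if well.cell_count > 0 else None
                ),
            )
        traces[well.well_id] = Thermogram(
            well.well_id, times, power, config.sampling_rate_hz
        )

    tset = ThermogramSet(layout=config.layout, traces=traces)
    truth = GroundTruth(records=records, profiles=dict(config.profiles))
    return tset, truth


def write_simulation(
    tset: ThermogramSet, truth: GroundTruth, out_dir: str | Path
) -> dict[str, Path]:
    """Write a simulated plate as the text files the readers consume."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "thermograms": out_dir / "thermograms.csv",
        "layout": out_dir / "layout.yaml",
        "ground_truth": out_dir / "ground_truth.csv",
    }
    write_thermograms(tset.traces, paths["thermograms"])
    write_layout(tset.layout, paths["layout"])
    truth.to_frame().to_csv(paths["ground_truth"], index=False, float_format="%.6g")
    return paths
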