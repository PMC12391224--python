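"""Per-well thermogram processing: reference correction through integration.

Each sample well is processed in four stages:

1. *Reference correction* — subtract the pointwise mean of the same
   column's cell-free reference traces.  This removes the shared
   loading-friction spike, column-common instrumental drift and the
   media's own background heat.
2. *Trimming* — drop the equilibration window at the start (default
   30 min) and, optionally, steady-state data at the end.
3. *Baseline correction* — remove residual drift and offset so the
   quiescent signal sits at zero and the trace is non-negative.  In
   ``per_column_linear`` mode a least-squares line fit to the smoothed
   same-column signals over a quiescent window is subtracted first; in
   both modes a constant shift then pins the smoothed minimum to zero.
4. *Integration* — trapezoidal rule over the retained window; with
   seconds and microwatts the result is directly microjoules.

Total heat is finally normalised by the well's cell count; wells with
no cells keep their raw totals (per-cell heat is undefined there).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from sklearn.base import BaseEstimator, TransformerMixin

from .io import Thermogram, ThermogramSet, well_sort_key

__all__ = [
    "PipelineConfig",
    "CorrectedSignal",
    "HeatSummary",
    "PipelineError",
    "reference_correct",
    "trim",
    "baseline_correct",
    "integrate_total_heat",
    "normalize_per_cell",
    "process_plate",
    "PlateProcessor",
]

#: power values within this of zero (uW) are treated as non-negative
ZERO_TOL_UW = 1e-9

STAGES = ("reference_corrected", "trimmed", "baseline_corrected")


class PipelineError(ValueError):
    """A processing stage received invalid input."""


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the per-well processing chain.

    Parameters
    ----------
    trim_start_s:
        Seconds removed from the start of every trace; default 1800 s,
        the instrument's ~30 min thermal equilibration.
    trim_end_s:
        Optional cut-off (seconds from start) removing steady-state data
        at the end; None keeps the full trace.
    quiescent_window:
        ``(start_s, end_s)`` window in which the signal is assumed to be
        metabolically silent; used to estimate residual drift.  Default
        5-10 h, after the loading spike has dissipated and before cells
        start producing heat (lag is typically 12-15 h).
    smoothing_halfwidth_s:
        Half-width of the moving-average window used when locating the
        baseline, so a single noise excursion cannot define it.
    drift_mode:
        ``per_column_linear`` removes a straight-line drift estimated
        from all same-column signals before the constant shift;
        ``per_well_constant`` applies the constant shift only.
    """

    trim_start_s: float = 1800.0
    trim_end_s: float | None = None
    quiescent_window: tuple[float, float] = (5 * 3600.0, 10 * 3600.0)
    smoothing_halfwidth_s: float = 300.0
    drift_mode: str = "per_column_linear"

    def __post_init__(self) -> None:
        if self.trim_start_s < 0:
            raise PipelineError("trim_start_s must be >= 0")
        if self.trim_end_s is not None and self.trim_end_s <= self.trim_start_s:
            raise PipelineError("trim_end_s must exceed trim_start_s")
        lo, hi = self.quiescent_window
        if not lo < hi:
            raise PipelineError("quiescent_window must be an increasing (start, end) pair")
        if lo < self.trim_start_s:
            raise PipelineError("quiescent_window must start at or after trim_start_s")
        if self.trim_end_s is not None and hi > self.trim_end_s:
            raise PipelineError("quiescent_window must end at or before trim_end_s")
        if self.smoothing_halfwidth_s < 0:
            raise PipelineError("smoothing_halfwidth_s must be >= 0")
        if self.drift_mode not in ("per_column_linear", "per_well_constant"):
            raise PipelineError(f"unknown drift_mode {self.drift_mode!r}")


@dataclass
class CorrectedSignal:
    """A trace after a named pipeline stage."""

    well_id: str
    times: np.ndarray
    powers: np.ndarray
    stage: str
    sampling_rate_hz: float = 1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.powers = np.asarray(self.powers, dtype=float)
        if self.stage not in STAGES:
            raise PipelineError(f"unknown stage {self.stage!r}")
        if self.stage == "baseline_corrected" and self.powers.size:
            if float(self.powers.min()) < -ZERO_TOL_UW:
                raise PipelineError(
                    f"well {self.well_id}: baseline-corrected signal dips to "
                    f"{self.powers.min():.3g} uW; positivity contract violated"
                )


@dataclass(frozen=True)
class HeatSummary:
    """Per-well total heat after the full pipeline.

    ``heat_per_cell_uJ`` is None for wells with ``cell_count == 0``.
    """

    well_id: str
    group: str | None
    total_heat_uJ: float
    cell_count: int
    heat_per_cell_uJ: float | None


def _smooth(powers: np.ndarray, rate_hz: float, halfwidth_s: float) -> np.ndarray:
    size = 2 * int(round(halfwidth_s * rate_hz)) + 1
    if size <= 1:
        return powers
    return uniform_filter1d(powers, size=size, mode="nearest")


def reference_correct(
    sample: Thermogram, references: Sequence[Thermogram]
) -> CorrectedSignal:
    """Subtract the pointwise mean of the reference traces from a sample."""
    if not references:
        raise PipelineError(f"well {sample.well_id}: no reference traces supplied")
    for ref in references:
        if ref.times.shape != sample.times.shape or not np.array_equal(
            ref.times, sample.times
        ):
            raise PipelineError(
                f"well {sample.well_id}: reference {ref.well_id} is on a different time grid"
            )
    mean_ref = np.mean([r.powers for r in references], axis=0)
    return CorrectedSignal(
        well_id=sample.well_id,
        times=sample.times.copy(),
        powers=sample.powers - mean_ref,
        stage="reference_corrected",
        sampling_rate_hz=sample.sampling_rate_hz,
    )


def trim(signal: CorrectedSignal, config: PipelineConfig) -> CorrectedSignal:
    """Drop the loading window (and optionally the tail) from a trace."""
    if signal.stage != "reference_corrected":
        raise PipelineError(f"trim expects a reference_corrected signal, got {signal.stage}")
    keep = signal.times >= config.trim_start_s
    if config.trim_end_s is not None:
        keep &= signal.times <= config.trim_end_s
    if not keep.any():
        raise PipelineError(f"well {signal.well_id}: trimming removed every sample")
    return CorrectedSignal(
        well_id=signal.well_id,
        times=signal.times[keep],
        powers=signal.powers[keep],
        stage="trimmed",
        sampling_rate_hz=signal.sampling_rate_hz,
    )


def _quiescent_mask(times: np.ndarray, config: PipelineConfig) -> np.ndarray:
    lo, hi = config.quiescent_window
    mask = (times >= lo) & (times <= hi)
    if not mask.any():
        raise PipelineError(
            f"quiescent window [{lo:.0f}, {hi:.0f}] s lies outside the trace "
            f"[{times[0]:.0f}, {times[-1]:.0f}] s"
        )
    return mask


def baseline_correct(
    signal: CorrectedSignal,
    column_signals: Sequence[CorrectedSignal] | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> CorrectedSignal:
    """Remove residual drift and pin the smoothed baseline to zero.

    ``column_signals`` are the trimmed, reference-corrected traces of
    every well in the same cartridge column (the signal itself may be
    included); they are only used in ``per_column_linear`` mode, where a
    single least-squares line through their pooled smoothed quiescent
    points estimates the column's residual drift.
    """
    if signal.stage != "trimmed":
        raise PipelineError(
            f"baseline_correct expects a trimmed signal, got {signal.stage}"
        )
    powers = signal.powers.astype(float)

    if config.drift_mode == "per_column_linear":
        pool = list(column_signals) if column_signals else [signal]
        ts, ys = [], []
        for sig in pool:
            mask = _quiescent_mask(sig.times, config)
            smoothed = _smooth(sig.powers, sig.sampling_rate_hz, config.smoothing_halfwidth_s)
            ts.append(sig.times[mask])
            ys.append(smoothed[mask])
        t_all = np.concatenate(ts)
        y_all = np.concatenate(ys)
        slope, intercept = np.polyfit(t_all, y_all, 1)
        powers = powers - (slope * signal.times + intercept)
    else:
        _quiescent_mask(signal.times, config)  # contract check only

    smoothed = _smooth(powers, signal.sampling_rate_hz, config.smoothing_halfwidth_s)
    powers = powers - float(smoothed.min())
    # the shift pins the *smoothed* minimum to zero; raw noise excursions
    # below it are clipped so the positivity contract holds pointwise
    powers = np.maximum(powers, 0.0)

    return CorrectedSignal(
        well_id=signal.well_id,
        times=signal.times,
        powers=powers,
        stage="baseline_corrected",
        sampling_rate_hz=signal.sampling_rate_hz,
    )


def integrate_total_heat(signal: CorrectedSignal) -> float:
    """Trapezoidal total heat (uJ) of a baseline-corrected trace.

    Negative excursions within tolerance are clipped to zero first, so
    the result honours the positivity contract deterministically.
    """
    if signal.stage != "baseline_corrected":
        raise PipelineError(
            f"integrate_total_heat expects a baseline_corrected signal, got {signal.stage}"
        )
    if len(signal.times) < 2:
        raise PipelineError(f"well {signal.well_id}: need at least 2 samples to integrate")
    powers = np.maximum(signal.powers, 0.0)
    return float(np.trapezoid(powers, signal.times))


def normalize_per_cell(total_heat_uJ: float, cell_count: int) -> float | None:
    """Heat per cell (uJ/cell), or None when the well holds no cells."""
    if total_heat_uJ < 0:
        raise PipelineError("total heat must be >= 0")
    if cell_count < 0:
        raise PipelineError("cell_count must be >= 0")
    if cell_count == 0:
        return None
    return total_heat_uJ / cell_count


def process_plate(
    data: ThermogramSet, config: PipelineConfig = PipelineConfig()
) -> list[HeatSummary]:
    """Run the full four-stage pipeline over every sample well.

    Returns one :class:`HeatSummary` per sample well in stable
    column-major order (B1, C1, ..., B2, ...).
    """
    layout = data.layout
    summaries: list[HeatSummary] = []

    # trimmed, reference-corrected signals per column, for drift estimation
    by_column: dict[int, list[CorrectedSignal]] = {}
    corrected: dict[str, CorrectedSignal] = {}
    for well in layout.sample_wells:
        refs = layout.references_for_column(well.column)
        ref_traces = [data[r.well_id] for r in refs if r.well_id in data.traces]
        if not ref_traces:
            raise PipelineError(
                f"well {well.well_id}: no reference traces available in column {well.column + 1}"
            )
        try:
            sig = trim(reference_correct(data[well.well_id], ref_traces), config)
        except PipelineError as exc:
            raise PipelineError(f"well {well.well_id}: {exc}") from exc
        corrected[well.well_id] = sig
        by_column.setdefault(well.column, []).append(sig)

    for well in layout.sample_wells:
        sig = corrected[well.well_id]
        try:
            sig = baseline_correct(sig, by_column[well.column], config)
            total = integrate_total_heat(sig)
        except PipelineError as exc:
            raise PipelineError(f"well {well.well_id}: {exc}") from exc
        summaries.append(
            HeatSummary(
                well_id=well.well_id,
                group=well.group,
                total_heat_uJ=total,
                cell_count=well.cell_count,
                heat_per_cell_uJ=normalize_per_cell(total, well.cell_count),
            )
        )
    summaries.sort(key=lambda s: well_sort_key(s.well_id))
    return summaries


class PlateProcessor(TransformerMixin, BaseEstimator):
    """Scikit-learn style transformer wrapping :func:`process_plate`.

    ``transform`` maps a :class:`~thermoplate.io.ThermogramSet` to a
    tidy :class:`pandas.DataFrame` of per-well heat summaries, so the
    processing chain composes with sklearn-style parameter handling
    (``get_params`` / ``set_params``) and grid utilities.
    """

    def __init__(
        self,
        trim_start_s: float = 1800.0,
        trim_end_s: float | None = None,
        quiescent_window: tuple[float, float] = (5 * 3600.0, 10 * 3600.0),
        smoothing_halfwidth_s: float = 300.0,
        drift_mode: str = "per_column_linear",
    ) -> None:
        self.trim_start_s = trim_start_s
        self.trim_end_s = trim_end_s
        self.quiescent_window = quiescent_window
        self.smoothing_halfwidth_s = smoothing_halfwidth_s
        self.drift_mode = drift_mode

    def _config(self) -> PipelineConfig:
        return PipelineConfig(
            trim_start_s=self.trim_start_s,
            trim_end_s=self.trim_end_s,
            quiescent_window=tuple(self.quiescent_window),
            smoothing_halfwidth_s=self.smoothing_halfwidth_s,
            drift_mode=self.drift_mode,
        )

    def fit(self, X: ThermogramSet, y=None) -> "PlateProcessor":
        if not isinstance(X, ThermogramSet):
            raise TypeError("PlateProcessor operates on a ThermogramSet")
        self._config()  # validates parameters
        self.n_sample_wells_ = len(X.layout.sample_wells)
        self.n_reference_wells_ = len(X.layout.reference_wells)
        return self

    def transform(self, X: ThermogramSet):
        import pandas as pd

        summaries = process_plate(X, self._config())
        return pd.DataFrame(
            {
                "well_id": [s.well_id for s in summaries],
                "group": [s.group for s in summaries],
                "total_heat_uJ": [s.total_heat_uJ for s in summaries],
                "cells": [s.cell_count for s in summaries],
                "heat_per_cell_uJ": [s.heat_per_cell_uJ for s in summaries],
            }
        )
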