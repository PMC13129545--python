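"""Plate-reader trace processing: baseline subtraction, normalization,
half-times and the kinetic-ratio statistic.

The processing chain mirrors how DETECTR plate data are analysed:
negative-control (no-target) wells give a per-time-point baseline that is
subtracted from every sample well; traces are then normalized so that
their plateau corresponds to the 200 nM reporter concentration; the
half-time t0.5 of each well is the earliest sampled time at which the
signal strictly exceeds 50% of that well's own maximum (no interpolation:
resolution is the 1-min sampling interval).  The slowdown caused by a
nucleic-acid background is the kinetic ratio

    r = t0.5(with background) / t0.5(without background),

evaluated over all with/without replicate pairs (3 x 3 = 9 for
triplicates); the mean and standard deviation of those ratios summarise a
condition.  Groups of ratios are compared with a two-sided Welch t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, GridError, HalfTimeError, NormalizationError

PLATE_COLUMNS = ["time_min", "well_id", "fluorescence"]
SHEET_COLUMNS = ["well_id", "grna", "background", "background_conc_nM",
                 "replicate", "is_negative_control"]


@dataclass(frozen=True)
class Trace:
    """One well's fluorescence time series with its condition metadata."""

    times: np.ndarray
    values: np.ndarray
    well_id: str = ""
    grna: str = ""
    background: str = "none"     # none | dsDNA | ssRNA | V1..V4
    background_conc_nM: float = 0.0
    replicate: int = 0
    is_negative_control: bool = False

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.shape != values.shape:
            raise GridError(f"well {self.well_id!r}: times and values differ in length")
        if times.size and np.any(np.diff(times) <= 0):
            raise GridError(f"well {self.well_id!r}: times must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise DomainError(f"well {self.well_id!r}: non-finite fluorescence values")


@dataclass(frozen=True)
class HalfTimeResult:
    t05: float             # minutes, an element of the trace's grid
    threshold_value: float # the 50%-of-max level
    max_value: float


@dataclass(frozen=True)
class RatioResult:
    r_mean: float
    r_sd: float
    n_pairs: int
    t05_with: tuple[float, ...]
    t05_without: tuple[float, ...]


def _check_same_grid(traces: Sequence[Trace]) -> np.ndarray:
    grid = traces[0].times
    for tr in traces[1:]:
        if tr.times.shape != grid.shape or not np.allclose(tr.times, grid):
            raise GridError(f"well {tr.well_id!r} is on a different time grid")
    return grid


def subtract_negative_control(
    traces: Sequence[Trace],
    negative_controls: Sequence[Trace],
    mode: str = "pointwise",
) -> list[Trace]:
    """Subtract the negative-control baseline from each sample trace.

    ``pointwise`` subtracts the per-time-point mean of the control wells;
    ``scalar`` subtracts the single grand mean of all control values (the
    alternative reading of "the background value").  Resulting values may
    be transiently negative and are not clipped.
    """
    if not negative_controls:
        raise GridError("at least one negative-control trace is required")
    _check_same_grid(list(traces) + list(negative_controls))
    baseline = np.mean([nc.values for nc in negative_controls], axis=0)
    if mode == "scalar":
        baseline = np.full_like(baseline, baseline.mean())
    elif mode != "pointwise":
        raise DomainError(f"unknown subtraction mode {mode!r}")
    return [replace(tr, values=tr.values - baseline) for tr in traces]


def normalize_trace(trace: Trace, final_value: float = 200.0,
                    plateau_points: int = 30) -> Trace:
    """Scale a trace so its plateau equals ``final_value`` (200 nM reporter).

    The plateau is estimated as the mean of the last ``plateau_points``
    samples, which is robust to end-of-run noise.
    """
    if trace.values.size < 1:
        raise NormalizationError("empty trace")
    plateau = float(np.mean(trace.values[-plateau_points:]))
    if plateau <= 0:
        raise NormalizationError(
            f"well {trace.well_id!r}: non-positive plateau estimate {plateau:.3g}"
        )
    return replace(trace, values=trace.values * (final_value / plateau))


def half_time(trace: Trace) -> HalfTimeResult:
    """Earliest grid time at which the signal strictly exceeds half its max.

    The threshold is 50% of the per-sample maximum over the full record
    (not the normalization constant).  No interpolation is performed.
    """
    values = trace.values
    max_value = float(values.max()) if values.size else 0.0
    if max_value <= 0:
        raise HalfTimeError(f"well {trace.well_id!r}: no positive signal")
    threshold = 0.5 * max_value
    above = values > threshold
    if not above.any():  # unreachable for finite data with max > 0, kept for safety
        raise HalfTimeError(f"well {trace.well_id!r}: signal never exceeds 50% of max")
    idx = int(np.argmax(above))
    return HalfTimeResult(t05=float(trace.times[idx]),
                          threshold_value=threshold, max_value=max_value)


def kinetic_ratio(group_with: Sequence[Trace], group_without: Sequence[Trace]) -> RatioResult:
    """Pairwise-ratio slowdown statistic between two replicate groups.

    Every (with, without) replicate pair contributes one ratio
    t0.5(with)/t0.5(without); triplicates give 9.  Returns the mean and
    standard deviation (ddof=1 when more than one pair) of the ratios.

    Note the mean of pairwise ratios is not the ratio of mean half-times;
    only in the zero-spread case do r(A,B) and r(B,A) multiply to 1.
    """
    if not group_with or not group_without:
        raise DomainError("both groups need at least one trace")

    def _t05(tr: Trace) -> float:
        try:
            return half_time(tr).t05
        except HalfTimeError as exc:
            raise HalfTimeError(f"well {tr.well_id!r}: {exc}") from exc

    t_with = [_t05(tr) for tr in group_with]
    t_without = [_t05(tr) for tr in group_without]
    ratios = np.array([w / wo for w in t_with for wo in t_without])
    sd = float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0
    return RatioResult(
        r_mean=float(ratios.mean()), r_sd=sd, n_pairs=ratios.size,
        t05_with=tuple(t_with), t05_without=tuple(t_without),
    )


def pairwise_ratios(group_with: Sequence[Trace], group_without: Sequence[Trace]) -> np.ndarray:
    """The raw pairwise t0.5 ratios (inputs to a Welch comparison)."""
    t_with = [half_time(tr).t05 for tr in group_with]
    t_without = [half_time(tr).t05 for tr in group_without]
    return np.array([w / wo for w in t_with for wo in t_without])


def compare_ratios(ratios_a: Sequence[float], ratios_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test between two ratio sets."""
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("each ratio set needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise DomainError("both ratio sets have zero variance; Welch test undefined")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Plate CSV + sample sheet I/O (long format: time_min, well_id, fluorescence)

def write_plate_csv(plate: pd.DataFrame, path: str | Path) -> None:
    plate[PLATE_COLUMNS].to_csv(path, index=False)


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise GridError(f"plate CSV missing columns: {sorted(missing)}")
    return df


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet[SHEET_COLUMNS].to_csv(path, index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise GridError(f"sample sheet missing columns: {sorted(missing)}")
    return df


def traces_from_plate(plate: pd.DataFrame, sheet: pd.DataFrame) -> list[Trace]:
    """Assemble per-well Trace objects from a long-format plate and its sheet."""
    meta = sheet.set_index("well_id")
    traces = []
    for well_id, group in plate.groupby("well_id", sort=False):
        group = group.sort_values("time_min")
        if well_id not in meta.index:
            raise GridError(f"well {well_id!r} missing from the sample sheet")
        row = meta.loc[well_id]
        traces.append(Trace(
            times=group["time_min"].to_numpy(),
            values=group["fluorescence"].to_numpy(),
            well_id=str(well_id),
            grna=str(row["grna"]),
            background=str(row["background"]),
            background_conc_nM=float(row["background_conc_nM"]),
            replicate=int(row["replicate"]),
            is_negative_control=bool(row["is_negative_control"]),
        ))
    return traces


def analyze_plate(plate: pd.DataFrame, sheet: pd.DataFrame, *,
                  subtraction_mode: str = "pointwise",
                  final_value: float = 200.0) -> pd.DataFrame:
    """Full pipeline: subtract controls, normalize, t0.5, kinetic ratios.

    Negative controls are matched per (gRNA, background) condition when
    present, falling back to all control wells on the plate.  Returns one
    row per (gRNA, background != none) condition with r_mean, r_sd,
    n_pairs and the underlying half-times.
    """
    traces = traces_from_plate(plate, sheet)
    controls = [tr for tr in traces if tr.is_negative_control]
    samples = [tr for tr in traces if not tr.is_negative_control]
    if not controls:
        raise GridError("plate has no negative-control wells")

    def _preprocess(group: list[Trace]) -> list[Trace]:
        key = (group[0].grna, group[0].background)
        local = [c for c in controls if (c.grna, c.background) == key] or controls
        sub = subtract_negative_control(group, local, mode=subtraction_mode)
        return [normalize_trace(tr, final_value=final_value) for tr in sub]

    by_condition: dict[tuple[str, str], list[Trace]] = {}
    for tr in samples:
        by_condition.setdefault((tr.grna, tr.background), []).append(tr)

    processed = {key: _preprocess(group) for key, group in by_condition.items()}

    rows = []
    for (grna, background), group in processed.items():
        if background == "none":
            continue
        baseline_key = (grna, "none")
        if baseline_key not in processed:
            raise GridError(f"no background-free condition for gRNA {grna!r}")
        result = kinetic_ratio(group, processed[baseline_key])
        rows.append({
            "grna": grna, "background": background,
            "background_conc_nM": group[0].background_conc_nM,
            "r_mean": result.r_mean, "r_sd": result.r_sd,
            "n_pairs": result.n_pairs,
            "t05_with_min": ";".join(f"{t:g}" for t in result.t05_with),
            "t05_without_min": ";".join(f"{t:g}" for t in result.t05_without),
        })
    return pd.DataFrame(rows)
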